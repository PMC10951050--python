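"""Slide preprocessing: annotations, tessellation, quality control, stains.

An annotated slide is converted into a library of non-overlapping 512x512
tumor tiles.  The tile grid is anchored at the slide origin (0, 0) so that
re-annotating a slide never shifts tile identities; a tile is kept when at
least ``min_tumor_fraction`` of its area lies inside the tumor annotation.
Retained tiles pass a quality filter (background and blur rejection) and are
mapped to a common color reference with Macenko stain normalization:
stain vectors are estimated from the extreme angle percentiles of the
optical-density cloud projected on its top-2 singular plane, concentrations
are solved by least squares with non-negative projection, rescaled to the
target's reference concentrations and re-rendered with the target stain
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box as shapely_box
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from skimage.color import rgb2gray, rgb2hsv
from sklearn.base import BaseEstimator, TransformerMixin

TILE_EDGE_DEFAULT = 512


# ---------------------------------------------------------------------------
# annotations

@dataclass
class TumorAnnotation:
    """Tumor region of one slide in level-0 pixel coordinates (y down)."""

    slide_id: str
    geometry: BaseGeometry

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def polygons(self) -> list:
        if self.geometry.geom_type == "Polygon":
            return [self.geometry]
        return list(self.geometry.geoms)


def load_annotations(source, slide_id: str = "") -> TumorAnnotation:
    """Read a QuPath-style GeoJSON FeatureCollection of tumor polygons.

    ``source`` may be a path or an already parsed GeoJSON dict.  All polygon
    features are merged into a single annotation; coordinates are taken
    verbatim as level-0 pixels.  Non-polygon geometries and empty collections
    are errors.
    """
    if isinstance(source, (str, Path)):
        if not slide_id:
            slide_id = Path(source).stem
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = source
    if data.get("type") == "FeatureCollection":
        features = data.get("features", [])
    elif data.get("type") == "Feature":
        features = [data]
    else:
        features = [{"geometry": data}]
    geoms = []
    for feat in features:
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"annotation contains non-polygon geometry {geom.geom_type!r}"
            )
        geoms.append(geom)
    if not geoms:
        raise ValueError("annotation contains no polygon features")
    merged = unary_union(geoms)
    if merged.area <= 0:
        raise ValueError("annotation has zero area")
    return TumorAnnotation(slide_id=slide_id, geometry=merged)


# ---------------------------------------------------------------------------
# tessellation

@dataclass(frozen=True)
class TileSpec:
    """Grid-addressed tile: half-open box [x, x+T) x [y, y+T) at level 0."""

    slide_id: str
    grid_row: int
    grid_col: int
    tile_edge: int
    tumor_fraction: float
    label: str | None = None

    @property
    def x(self) -> int:
        return self.grid_col * self.tile_edge

    @property
    def y(self) -> int:
        return self.grid_row * self.tile_edge

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), half-open."""
        return (self.x, self.y, self.x + self.tile_edge, self.y + self.tile_edge)


def _slide_shape(slide) -> tuple[int, int]:
    """(height, width) from an image array or an explicit shape tuple."""
    if hasattr(slide, "shape"):
        return int(slide.shape[0]), int(slide.shape[1])
    h, w = slide
    return int(h), int(w)


def tessellate(
    slide,
    annotation: TumorAnnotation,
    tile_edge: int = TILE_EDGE_DEFAULT,
    min_tumor_fraction: float = 0.5,
    label: str | None = None,
) -> list[TileSpec]:
    """Tessellate the annotated tumor area into non-overlapping tiles.

    The grid is anchored at the slide origin; a tile is retained iff
    ``area(bbox intersect annotation) / tile_edge**2 >= min_tumor_fraction``
    (inclusive).  Output is sorted by (grid_row, grid_col).

    ``slide`` is either an image array or an ``(height, width)`` tuple.
    """
    height, width = _slide_shape(slide)
    minx, miny, maxx, maxy = annotation.geometry.bounds
    if minx < 0 or miny < 0 or maxx > width or maxy > height:
        raise ValueError(
            f"annotation bounds {annotation.geometry.bounds} exceed slide "
            f"dimensions {(width, height)}"
        )
    tiles: list[TileSpec] = []
    tile_area = float(tile_edge * tile_edge)
    row0 = int(np.floor(miny / tile_edge))
    row1 = int(np.ceil(maxy / tile_edge))
    col0 = int(np.floor(minx / tile_edge))
    col1 = int(np.ceil(maxx / tile_edge))
    geom = annotation.geometry
    for row in range(row0, row1):
        y = row * tile_edge
        if y + tile_edge > height:
            continue
        for col in range(col0, col1):
            x = col * tile_edge
            if x + tile_edge > width:
                continue
            cell = shapely_box(x, y, x + tile_edge, y + tile_edge)
            frac = geom.intersection(cell).area / tile_area
            if frac >= min_tumor_fraction:
                tiles.append(
                    TileSpec(
                        slide_id=annotation.slide_id,
                        grid_row=row,
                        grid_col=col,
                        tile_edge=tile_edge,
                        tumor_fraction=float(frac),
                        label=label,
                    )
                )
    return tiles


def extract_tile(image: np.ndarray, spec: TileSpec) -> np.ndarray:
    """Crop the pixels of a tile from the slide image (RGB, uint8)."""
    x0, y0, x1, y1 = spec.bbox
    return np.ascontiguousarray(image[y0:y1, x0:x1])


# ---------------------------------------------------------------------------
# quality control

@dataclass(frozen=True)
class QCDecision:
    accepted: bool
    reason: str | None = None


def qc_filter(
    tile: np.ndarray,
    bg_sat: float = 0.08,
    bg_val: float = 220.0,
    max_bg_fraction: float = 0.5,
    min_laplacian_var: float = 15.0,
) -> QCDecision:
    """Accept or reject a tile on background and blur statistics.

    A pixel is background iff its HSV saturation is below ``bg_sat`` and its
    value above ``bg_val`` (0-255 scale).  The tile is rejected with reason
    ``"background"`` when the background fraction exceeds ``max_bg_fraction``
    and with reason ``"blur"`` when the variance of the grayscale Laplacian
    falls below ``min_laplacian_var``.  Pure function of the pixels.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected an RGB tile, got shape {tile.shape}")
    hsv = rgb2hsv(tile)
    background = (hsv[..., 1] < bg_sat) & (hsv[..., 2] * 255.0 > bg_val)
    bg_fraction = float(background.mean())
    if bg_fraction > max_bg_fraction:
        return QCDecision(False, "background")
    gray = rgb2gray(tile) * 255.0
    lap_var = float(ndimage.laplace(gray).var())
    if lap_var < min_laplacian_var:
        return QCDecision(False, "blur")
    return QCDecision(True, None)


# ---------------------------------------------------------------------------
# Macenko stain estimation / normalization

@dataclass
class StainProfile:
    """Stain matrix (rows: hematoxylin, eosin unit OD directions) and the
    reference (99th-percentile) concentration per stain."""

    stain_matrix: np.ndarray  # (2, 3)
    max_concentrations: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_matrix, dtype=float)
        c = np.asarray(self.max_concentrations, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        if np.any(m < -1e-9):
            raise ValueError("stain OD directions must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            m = m / norms[:, None]
        if c.shape != (2,) or np.any(c <= 0):
            raise ValueError("max_concentrations must be two positive values")
        self.stain_matrix = np.clip(m, 0.0, None)
        self.stain_matrix /= np.linalg.norm(self.stain_matrix, axis=1)[:, None]
        self.max_concentrations = c


def canonical_he_profile() -> StainProfile:
    """Reference H&E profile: canonical OD vectors and concentration scale."""
    m = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]], dtype=float)
    m /= np.linalg.norm(m, axis=1)[:, None]
    return StainProfile(stain_matrix=m, max_concentrations=np.array([1.9705, 1.0308]))


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Optical density: ``-log10((I + 1) / 256)`` per channel."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped to valid 8-bit intensities."""
    out = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(out, 0, 255).astype(np.uint8)


def estimate_stains(
    tile: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    conc_percentile: float = 99.0,
) -> StainProfile:
    """Macenko stain estimation from one tile.

    Pixels with OD magnitude below ``od_threshold`` are discarded as
    non-tissue; the two stain directions are the extreme ``angle_percentile``
    angles of the OD cloud projected on the plane of its top-2 singular
    vectors; hematoxylin is the direction with the larger blue-channel OD.
    """
    od = rgb_to_od(np.asarray(tile).reshape(-1, 3))
    tissue = od[np.linalg.norm(od, axis=1) > od_threshold]
    if len(tissue) < 100:
        raise ValueError(
            f"insufficient tissue: {len(tissue)} pixels above OD threshold "
            f"{od_threshold} (need >= 100)"
        )
    # plane of the top-2 right singular vectors of the OD cloud
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2]
    basis = np.where(basis.sum(axis=1, keepdims=True) < 0, -basis, basis)
    proj = tissue @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angle_percentile)
    hi = np.percentile(phi, 100.0 - angle_percentile)
    v_lo = np.array([np.cos(lo), np.sin(lo)]) @ basis
    v_hi = np.array([np.cos(hi), np.sin(hi)]) @ basis
    directions = []
    for v in (v_lo, v_hi):
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("degenerate stain direction estimated")
        directions.append(v / n)
    # hematoxylin absorbs more in the blue channel
    if directions[0][2] >= directions[1][2]:
        h, e = directions
    else:
        e, h = directions
    matrix = np.vstack([h, e])
    conc = _concentrations(tissue, matrix)
    max_conc = np.percentile(conc, conc_percentile, axis=1)
    max_conc = np.maximum(max_conc, 1e-6)
    return StainProfile(stain_matrix=matrix, max_concentrations=max_conc)


def _concentrations(od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares stain concentrations with non-negative projection.

    Returns a (2, N) array for N OD pixels.
    """
    sol, *_ = np.linalg.lstsq(stain_matrix.T, od.T, rcond=None)
    return np.clip(sol, 0.0, None)


def normalize_stain(
    tile: np.ndarray,
    source: StainProfile,
    target: StainProfile | None = None,
) -> np.ndarray:
    """Map a tile from its source stain profile to the target reference.

    Concentrations are solved against the source stain matrix, rescaled by
    the ratio of reference concentrations, and re-rendered with the target
    matrix.  Defaults to the canonical H&E reference.
    """
    if target is None:
        target = canonical_he_profile()
    tile = np.asarray(tile)
    od = rgb_to_od(tile.reshape(-1, 3))
    conc = _concentrations(od, source.stain_matrix)
    scale = target.max_concentrations / source.max_concentrations
    conc = conc * scale[:, None]
    od_out = conc.T @ target.stain_matrix
    return od_to_rgb(od_out).reshape(tile.shape)


class MacenkoNormalizer(TransformerMixin, BaseEstimator):
    """Transformer mapping tiles to a common stain reference.

    ``fit`` either adopts the canonical H&E reference (no argument needed) or
    estimates the target profile from a reference tile.  ``transform``
    estimates each tile's own stain profile and normalizes it to the target;
    tiles with too little tissue for estimation are passed through unchanged.
    """

    def __init__(
        self,
        od_threshold: float = 0.15,
        angle_percentile: float = 1.0,
        conc_percentile: float = 99.0,
    ):
        self.od_threshold = od_threshold
        self.angle_percentile = angle_percentile
        self.conc_percentile = conc_percentile

    def fit(self, X=None, y=None) -> "MacenkoNormalizer":
        if X is None:
            self.target_profile_ = canonical_he_profile()
        else:
            ref = X[0] if isinstance(X, (list, tuple)) else np.asarray(X)
            if ref.ndim == 4:
                ref = ref[0]
            self.target_profile_ = estimate_stains(
                ref,
                od_threshold=self.od_threshold,
                angle_percentile=self.angle_percentile,
                conc_percentile=self.conc_percentile,
            )
        return self

    def transform(self, X) -> list[np.ndarray]:
        if not hasattr(self, "target_profile_"):
            self.fit()
        tiles = X if isinstance(X, (list, tuple)) else list(X)
        out = []
        for tile in tiles:
            try:
                profile = estimate_stains(
                    tile,
                    od_threshold=self.od_threshold,
                    angle_percentile=self.angle_percentile,
                    conc_percentile=self.conc_percentile,
                )
            except ValueError:
                out.append(np.asarray(tile))
                continue
            out.append(normalize_stain(tile, profile, self.target_profile_))
        return out


# ---------------------------------------------------------------------------
# readers / writers

def read_slide(path) -> np.ndarray:
    """Read a flat PNG/TIFF slide as an RGB uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        image = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        image = iio.imread(path)
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[2] == 4:
        image = image[..., :3]
    return image.astype(np.uint8)
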