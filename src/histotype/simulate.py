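"""Seeded synthetic cohorts: H-score tables and textured pseudo-slides.

Two generators make every pipeline stage testable without clinical data.

``gen_hscore_cohort`` emulates the three-subtype block structure of a marker
H-score table: luminal patients express the luminal panel (CK20, FOXA1,
GATA3) high and the basal panel low, basal patients the mirror image, and
indifferent patients both panels low.  Each patient gets a latent marker
mean and four noisy core replicates, truncated to the H-score range.

``gen_pseudo_slide`` paints class-distinctive H&E-like textures by mixing
two stain concentration fields through the canonical hematoxylin/eosin
optical-density vectors: the luminal texture is a dense field of dark
blue-purple nuclei on pink stroma, the basal texture oriented pink stromal
fibers with sparse bright keratin blobs and few nuclei.  These textures are
deliberately crude proxies - a controllable, linearly separable two-class
imaging problem, not histological realism.  Slides carry a tumor polygon
annotation, optional white-margin and blur artifacts for quality-control
tests, an optional global color shift simulating scanner variation, and a
per-tile ground-truth label grid; heterogeneous slides split the tumor into
two contiguous opposite-class regions.

All generators are pure functions of their parameter objects including the
seed; per-slide seeds are derived by hashing (master seed, slide index) so a
cohort is stable under count changes for existing indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .ihc import BASAL_MARKERS, LUMINAL_MARKERS
from .wsi import canonical_he_profile, od_to_rgb

# ---------------------------------------------------------------------------
# H-score cohorts

@dataclass(frozen=True)
class HScoreSimParams:
    """Three-latent-subtype H-score generator settings.

    Expressed markers are drawn around 220 (SD 40), silenced markers around
    20 (SD 15); the indifferent subtype sits at 15 (SD 10) on both panels.
    Four cores per patient with core-level noise SD 15; everything truncated
    to [0, 300].
    """

    n_per_subtype: int = 30
    high_mean: float = 220.0
    high_sd: float = 40.0
    low_mean: float = 20.0
    low_sd: float = 15.0
    indifferent_mean: float = 15.0
    indifferent_sd: float = 10.0
    cores_per_patient: int = 4
    core_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.high_mean, self.low_mean, self.indifferent_mean):
            if not 0 <= m <= 300:
                raise ValueError("marker means must lie in [0, 300]")
        for s in (self.high_sd, self.low_sd, self.indifferent_sd):
            if s <= 0:
                raise ValueError("marker SDs must be positive")
        if self.core_noise_sd < 0:
            raise ValueError("core_noise_sd must be >= 0")


def _marker_moments(params: HScoreSimParams, subtype: str, marker: str):
    if subtype == "indifferent":
        return params.indifferent_mean, params.indifferent_sd
    panel = LUMINAL_MARKERS if subtype == "luminal" else BASAL_MARKERS
    if marker in panel:
        return params.high_mean, params.high_sd
    return params.low_mean, params.low_sd


def gen_hscore_cohort(params: HScoreSimParams | None = None, **overrides):
    """Generate a per-core H-score table with planted subtype labels.

    Returns ``(measurements, labels)``: a DataFrame with columns
    ``patient_id, core_id, marker, h_score`` and a Series mapping patient id
    to its planted subtype.
    """
    if params is None:
        params = HScoreSimParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    markers = BASAL_MARKERS + LUMINAL_MARKERS
    rows = []
    labels = {}
    for subtype, prefix in (("luminal", "L"), ("basal", "B"), ("indifferent", "I")):
        for i in range(params.n_per_subtype):
            patient = f"{prefix}{i + 1:03d}"
            labels[patient] = subtype
            for marker in markers:
                mean, sd = _marker_moments(params, subtype, marker)
                latent = float(np.clip(rng.normal(mean, sd), 0.0, 300.0))
                for core in range(1, params.cores_per_patient + 1):
                    value = latent + rng.normal(0.0, params.core_noise_sd)
                    rows.append(
                        (patient, core, marker, float(np.clip(value, 0.0, 300.0)))
                    )
    measurements = pd.DataFrame(
        rows, columns=["patient_id", "core_id", "marker", "h_score"]
    )
    return measurements, pd.Series(labels, name="planted_label")


# ---------------------------------------------------------------------------
# pseudo-slides

@dataclass(frozen=True)
class PseudoSlideParams:
    """Textured pseudo-slide settings (dimensions in level-0 pixels)."""

    width: int = 3072
    height: int = 2048
    layout: str = "luminal"  # luminal | basal | heterogeneous
    split_fraction: float = 0.5  # luminal share of a heterogeneous slide
    tile_edge: int = 512
    nucleus_density: float = 4.5e-3  # nuclei per px^2 in luminal texture
    nucleus_radius: tuple[float, float] = (4.0, 8.0)
    basal_nucleus_density: float = 4.0e-4
    fiber_density: float = 2.5e-4  # fibers per px^2 in basal texture
    fiber_length: tuple[float, float] = (40.0, 120.0)
    keratin_blob_rate: float = 2.0e-5  # blobs per px^2 in basal texture
    white_margin: int = 0  # width of a white band at the left edge
    blur_patch: tuple[int, int, int, int] | None = None  # (y, x, h, w)
    blur_sigma: float = 8.0
    color_shift: tuple[float, float] = (1.0, 1.0)  # scanner scale on (H, E)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 2 * self.tile_edge or self.height < 2 * self.tile_edge:
            raise ValueError("slide dimensions must be at least twice the tile edge")
        if self.layout not in ("luminal", "basal", "heterogeneous"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class PseudoSlide:
    image: np.ndarray  # (H, W, 3) uint8
    annotation: dict  # GeoJSON FeatureCollection
    tile_labels: dict[tuple[int, int], str]
    params: PseudoSlideParams


def _paint_luminal(c_h, c_e, x0, x1, rng, params: PseudoSlideParams) -> None:
    """Dense dark nuclei on pink stroma within columns [x0, x1)."""
    h = c_h.shape[0]
    region_area = (x1 - x0) * h
    c_e[:, x0:x1] += 0.30
    n_nuclei = rng.poisson(params.nucleus_density * region_area)
    r_lo, r_hi = params.nucleus_radius
    for _ in range(n_nuclei):
        cy = rng.uniform(0, h)
        cx = rng.uniform(x0, x1)
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=c_h.shape, rotation=rot)
        keep = (cc >= x0) & (cc < x1)
        c_h[rr[keep], cc[keep]] = rng.uniform(1.1, 1.5)


def _paint_basal(c_h, c_e, x0, x1, rng, params: PseudoSlideParams) -> None:
    """Oriented pink fibers, bright keratin blobs, few nuclei in [x0, x1)."""
    h = c_h.shape[0]
    region_area = (x1 - x0) * h
    c_e[:, x0:x1] += 0.45
    n_fibers = rng.poisson(params.fiber_density * region_area)
    len_lo, len_hi = params.fiber_length
    for _ in range(n_fibers):
        cy = rng.uniform(0, h)
        cx = rng.uniform(x0, x1)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(len_lo, len_hi)
        dy = 0.5 * length * np.sin(angle)
        dx = 0.5 * length * np.cos(angle)
        for off in (-1, 0, 1):  # ~3 px fiber thickness
            r0 = int(np.clip(cy - dy + off, 0, h - 1))
            r1 = int(np.clip(cy + dy + off, 0, h - 1))
            k0 = int(np.clip(cx - dx, 0, c_h.shape[1] - 1))
            k1 = int(np.clip(cx + dx, 0, c_h.shape[1] - 1))
            rr, cc = draw_line(r0, k0, r1, k1)
            keep = (cc >= x0) & (cc < x1)
            c_e[rr[keep], cc[keep]] += rng.uniform(0.35, 0.55)
    n_nuclei = rng.poisson(params.basal_nucleus_density * region_area)
    r_lo, r_hi = params.nucleus_radius
    for _ in range(n_nuclei):
        rr, cc = draw_ellipse(
            rng.uniform(0, h),
            rng.uniform(x0, x1),
            rng.uniform(r_lo, r_hi),
            rng.uniform(r_lo, r_hi),
            shape=c_h.shape,
        )
        keep = (cc >= x0) & (cc < x1)
        c_h[rr[keep], cc[keep]] = rng.uniform(0.8, 1.1)
    n_blobs = rng.poisson(params.keratin_blob_rate * region_area)
    for _ in range(n_blobs):
        rr, cc = draw_ellipse(
            rng.uniform(0, h),
            rng.uniform(x0, x1),
            rng.uniform(12, 28),
            rng.uniform(12, 28),
            shape=c_h.shape,
        )
        keep = (cc >= x0) & (cc < x1)
        c_e[rr[keep], cc[keep]] *= 0.12  # keratin: nearly unstained, bright
        c_h[rr[keep], cc[keep]] *= 0.1


def _region_bounds(params: PseudoSlideParams) -> list[tuple[str, int, int]]:
    """(class, x0, x1) column ranges of the slide's texture regions."""
    if params.layout == "heterogeneous":
        split_x = int(round(params.split_fraction * params.width))
        return [("luminal", 0, split_x), ("basal", split_x, params.width)]
    return [(params.layout, 0, params.width)]


def gen_pseudo_slide(params: PseudoSlideParams | None = None, **overrides) -> PseudoSlide:
    """Render a pseudo-slide with annotation and per-tile ground truth.

    The tumor polygon is the full slide rectangle; per-tile labels are
    emitted for every tile at least half covered by one class region (the
    default 0.5 split of a heterogeneous slide falls on a tile boundary, so
    the truth grid splits into two contiguous blocks).
    """
    if params is None:
        params = PseudoSlideParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    c_h = np.zeros((h, w))
    c_e = np.zeros((h, w))
    for cls, x0, x1 in _region_bounds(params):
        if cls == "luminal":
            _paint_luminal(c_h, c_e, x0, x1, rng, params)
        else:
            _paint_basal(c_h, c_e, x0, x1, rng, params)
    # low-frequency stromal variation
    noise = gaussian_filter(rng.normal(0.0, 1.0, size=(h // 8, w // 8)), sigma=4)
    noise = np.kron(noise, np.ones((8, 8)))[:h, :w]
    c_e += 0.05 * noise * (c_e > 0)
    c_e = np.clip(c_e, 0.0, None)
    if params.white_margin > 0:
        c_h[:, : params.white_margin] = 0.0
        c_e[:, : params.white_margin] = 0.0
    c_h *= params.color_shift[0]
    c_e *= params.color_shift[1]
    profile = canonical_he_profile()
    od = (
        c_h[..., None] * profile.stain_matrix[0]
        + c_e[..., None] * profile.stain_matrix[1]
    )
    image = od_to_rgb(od)
    if params.blur_patch is not None:
        y, x, bh, bw = params.blur_patch
        patch = image[y : y + bh, x : x + bw].astype(float)
        for ch in range(3):
            patch[..., ch] = gaussian_filter(patch[..., ch], sigma=params.blur_sigma)
        image[y : y + bh, x : x + bw] = np.clip(patch, 0, 255).astype(np.uint8)

    annotation = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"classification": "Tumor"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[0, 0], [w, 0], [w, h], [0, h], [0, 0]]],
                },
            }
        ],
    }

    t = params.tile_edge
    tile_labels: dict[tuple[int, int], str] = {}
    for row in range(h // t):
        for col in range(w // t):
            x_lo, x_hi = col * t, (col + 1) * t
            best_cls, best_cover = None, 0.0
            for cls, x0, x1 in _region_bounds(params):
                cover = max(0, min(x_hi, x1) - max(x_lo, x0)) / t
                if cover > best_cover or (cover == best_cover and best_cls is None):
                    best_cls, best_cover = cls, cover
            if best_cover >= 0.5:
                tile_labels[(row, col)] = best_cls
    return PseudoSlide(
        image=image, annotation=annotation, tile_labels=tile_labels, params=params
    )


def gen_texture_tile(subtype: str, edge: int = 512, seed: int = 0, **overrides) -> np.ndarray:
    """One textured tile of the given class, for unit-testing classifiers."""
    params = PseudoSlideParams(
        width=max(2 * edge, edge), height=max(2 * edge, edge),
        layout=subtype, seed=seed, **overrides,
    )
    slide = gen_pseudo_slide(params)
    return slide.image[:edge, :edge]


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class SlideSpec:
    index: int
    slide_id: str
    patient_id: str
    label: str
    seed: int
    params: PseudoSlideParams


@dataclass
class CohortPlan:
    """Lazy cohort: slide specs plus metadata; images are materialized on
    demand so large cohorts never sit in memory at once."""

    slides: list[SlideSpec]
    metadata: pd.DataFrame
    seed: int

    def materialize(self, index: int) -> PseudoSlide:
        return gen_pseudo_slide(self.slides[index].params)


def _slide_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def gen_cohort(
    n_luminal: int,
    n_basal: int,
    n_heterogeneous: int = 0,
    seed: int = 0,
    width: int = 3072,
    height: int = 2048,
    association_strength: float = 0.8,
    **slide_overrides,
) -> CohortPlan:
    """Plan a pseudo-slide cohort with planted metadata associations.

    One slide per patient.  Metadata columns (tumor_type, pdl1_status,
    fgfr3_status) are drawn with a configurable association strength ``a``
    to the subtype: for instance a basal slide is PD-L1 positive with
    probability ``0.5 + a/2``.  ``a=1`` makes the association deterministic,
    ``a=0`` independence.
    """
    if not 0.0 <= association_strength <= 1.0:
        raise ValueError("association_strength must be in [0, 1]")
    labels = (
        ["luminal"] * n_luminal + ["basal"] * n_basal + ["heterogeneous"] * n_heterogeneous
    )
    meta_rng = np.random.default_rng(np.random.SeedSequence([seed, 987654321]))
    p_hi = 0.5 + association_strength / 2.0
    slides: list[SlideSpec] = []
    meta_rows = []
    for index, label in enumerate(labels):
        slide_id = f"S{index + 1:03d}"
        patient_id = f"P{index + 1:03d}"
        s_seed = _slide_seed(seed, index)
        params = PseudoSlideParams(
            width=width, height=height, layout=label, seed=s_seed, **slide_overrides
        )
        slides.append(SlideSpec(index, slide_id, patient_id, label, s_seed, params))
        if label == "basal":
            tumor_type = "solid" if meta_rng.random() < p_hi else "papillary"
            pdl1 = "positive" if meta_rng.random() < p_hi else "negative"
            fgfr3 = "mutated" if meta_rng.random() < 1 - p_hi else "wildtype"
        elif label == "luminal":
            tumor_type = "papillary" if meta_rng.random() < p_hi else "solid"
            pdl1 = "positive" if meta_rng.random() < 1 - p_hi else "negative"
            fgfr3 = "mutated" if meta_rng.random() < p_hi else "wildtype"
        else:  # heterogeneous: no planted association
            tumor_type = "papillary" if meta_rng.random() < 0.5 else "solid"
            pdl1 = "positive" if meta_rng.random() < 0.5 else "negative"
            fgfr3 = "mutated" if meta_rng.random() < 0.5 else "wildtype"
        meta_rows.append(
            {
                "slide_id": slide_id,
                "patient_id": patient_id,
                "true_label": label,
                "tumor_type": tumor_type,
                "pdl1_status": pdl1,
                "fgfr3_status": fgfr3,
            }
        )
    return CohortPlan(slides=slides, metadata=pd.DataFrame(meta_rows), seed=seed)


def write_cohort(plan: CohortPlan, out_dir, image_format: str = "png") -> pd.DataFrame:
    """Write a cohort to disk: slides, annotations, metadata, ground truth.

    Returns the slide index table that was written as ``slides.csv``.
    """
    import imageio.v3 as iio
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in plan.slides:
        slide = plan.materialize(spec.index)
        img_path = out / f"{spec.slide_id}.{image_format}"
        if image_format in ("tif", "tiff"):
            import tifffile

            tifffile.imwrite(img_path, slide.image)
        else:
            iio.imwrite(img_path, slide.image)
        ann_path = out / f"{spec.slide_id}.geojson"
        ann_path.write_text(json.dumps(slide.annotation))
        truth_path = out / f"{spec.slide_id}_truth.json"
        truth_path.write_text(
            json.dumps({f"{r}:{c}": lbl for (r, c), lbl in slide.tile_labels.items()})
        )
        rows.append(
            {
                "slide_id": spec.slide_id,
                "patient_id": spec.patient_id,
                "label": spec.label,
                "image": str(img_path),
                "annotation": str(ann_path),
                "truth": str(truth_path),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "slides.csv", index=False)
    plan.metadata.to_csv(out / "metadata.csv", index=False)
    return table
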