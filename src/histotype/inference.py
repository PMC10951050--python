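"""Slide-level aggregation, confidence banding, maps, heterogeneity.

The tile classifier emits a probability pair (p_luminal, p_basal) per tile;
the slide-level prediction p^WSI is the per-class arithmetic mean over the
slide's tiles and the call is the argmax class.  Calls are banded by the
winning probability: *high* confidence when max(p^WSI) >= 0.7, *low* when
max(p^WSI) <= 0.6 (i.e. the winning score sits in [0.4, 0.6] territory for
either class), and *intermediate* in the open gap (0.6, 0.7), so the bands
partition [0.5, 1].  For external cohorts, the three models of the
best-performing cross-validation repetition are ensembled by averaging their
slide-level predictions.  Tile-grid prediction maps support an algorithmic
screen for intratumoral heterogeneity via per-class connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

BAND_HIGH = "high"
BAND_INTERMEDIATE = "intermediate"
BAND_LOW = "low"

HIGH_THRESHOLD = 0.7
LOW_THRESHOLD = 0.6


#: absolute tolerance at band boundaries so that means like 0.55 + 0.65
#: landing at 0.6 up to rounding are classified by the exact-arithmetic rule
_BAND_EPS = 1e-9


def confidence_band(p_max: float) -> str:
    """Band of a winning slide-level probability: the three bands partition
    [0.5, 1] with inclusive boundaries at 0.7 (high) and 0.6 (low)."""
    if p_max >= HIGH_THRESHOLD - _BAND_EPS:
        return BAND_HIGH
    if p_max <= LOW_THRESHOLD + _BAND_EPS:
        return BAND_LOW
    return BAND_INTERMEDIATE


@dataclass
class SlidePrediction:
    slide_id: str
    p_wsi_luminal: float
    p_wsi_basal: float
    label: str
    confidence_band: str
    n_tiles: int
    tie: bool = False


def _validate_pairs(p_lum: np.ndarray, p_bas: np.ndarray) -> None:
    if np.any(p_lum < 0) or np.any(p_bas < 0):
        raise ValueError("tile probabilities must be non-negative")
    if np.any(np.abs(p_lum + p_bas - 1.0) > 1e-6):
        raise ValueError("tile probabilities must sum to 1 within 1e-6")


def aggregate_slide(tile_predictions: pd.DataFrame, slide_id: str | None = None) -> SlidePrediction:
    """Average tile predictions into a banded slide-level call.

    ``tile_predictions`` needs columns ``p_luminal, p_basal`` (and all rows
    must belong to one slide).  An exact 0.5/0.5 tie is labeled luminal,
    banded low, and flagged.
    """
    df = tile_predictions
    if len(df) == 0:
        raise ValueError("no tile predictions to aggregate")
    if slide_id is None:
        if "slide_id" in df.columns:
            ids = df["slide_id"].unique()
            if len(ids) > 1:
                raise ValueError(f"tile predictions span multiple slides: {ids}")
            slide_id = str(ids[0])
        else:
            slide_id = ""
    p_lum = df["p_luminal"].to_numpy(dtype=float)
    p_bas = df["p_basal"].to_numpy(dtype=float)
    _validate_pairs(p_lum, p_bas)
    mean_lum = float(p_lum.mean())
    mean_bas = float(p_bas.mean())
    tie = mean_lum == mean_bas
    label = "luminal" if mean_lum >= mean_bas else "basal"
    band = BAND_LOW if tie else confidence_band(max(mean_lum, mean_bas))
    return SlidePrediction(
        slide_id=slide_id,
        p_wsi_luminal=mean_lum,
        p_wsi_basal=mean_bas,
        label=label,
        confidence_band=band,
        n_tiles=len(df),
        tie=tie,
    )


def ensemble_predict(
    models,
    tiles,
    refs: pd.DataFrame | None = None,
    slide_id: str = "",
    allow_any_k: bool = False,
) -> SlidePrediction:
    """Slide call from an ensemble of cross-validation models.

    Each model predicts the slide's tiles and is aggregated to a slide-level
    mean; the ensemble call averages the models' slide-level predictions and
    takes the class with the highest average.  The standard ensemble is the
    three fold models of one repetition; other counts need
    ``allow_any_k=True``.
    """
    from .model import predict_tiles

    models = list(models)
    if len(models) != 3 and not allow_any_k:
        raise ValueError(
            f"expected the 3 fold models of one repetition, got {len(models)} "
            "(pass allow_any_k=True to override)"
        )
    per_model = []
    for model in models:
        preds = predict_tiles(model, tiles, refs=refs)
        agg = aggregate_slide(preds, slide_id=slide_id)
        per_model.append((agg.p_wsi_luminal, agg.p_wsi_basal))
    mean_lum = float(np.mean([p[0] for p in per_model]))
    mean_bas = float(np.mean([p[1] for p in per_model]))
    tie = mean_lum == mean_bas
    label = "luminal" if mean_lum >= mean_bas else "basal"
    band = BAND_LOW if tie else confidence_band(max(mean_lum, mean_bas))
    return SlidePrediction(
        slide_id=slide_id,
        p_wsi_luminal=mean_lum,
        p_wsi_basal=mean_bas,
        label=label,
        confidence_band=band,
        n_tiles=len(tiles),
        tie=tie,
    )


@dataclass
class PredictionMap:
    """Sparse tile-grid raster of winning class and probability."""

    slide_id: str
    entries: dict[tuple[int, int], tuple[str, float]] = field(default_factory=dict)

    @property
    def n_tiles(self) -> int:
        return len(self.entries)

    def grid_shape(self) -> tuple[int, int]:
        rows = max(r for r, _ in self.entries) + 1
        cols = max(c for _, c in self.entries) + 1
        return rows, cols


def build_prediction_map(tile_predictions: pd.DataFrame, slide_id: str | None = None) -> PredictionMap:
    """Arrange tile predictions on the slide grid.

    One entry per tile at (grid_row, grid_col) holding the winning class and
    its probability (in [0.5, 1]); duplicate coordinates are an error.
    """
    df = tile_predictions
    if slide_id is None:
        slide_id = str(df["slide_id"].iloc[0]) if "slide_id" in df.columns else ""
    p_lum = df["p_luminal"].to_numpy(dtype=float)
    p_bas = df["p_basal"].to_numpy(dtype=float)
    _validate_pairs(p_lum, p_bas)
    entries: dict[tuple[int, int], tuple[str, float]] = {}
    rows = df["grid_row"].to_numpy(dtype=int)
    cols = df["grid_col"].to_numpy(dtype=int)
    for r, c, pl, pb in zip(rows, cols, p_lum, p_bas):
        key = (int(r), int(c))
        if key in entries:
            raise ValueError(f"duplicate grid coordinate {key}")
        if pl >= pb:
            entries[key] = ("luminal", float(pl))
        else:
            entries[key] = ("basal", float(pb))
    if not entries:
        raise ValueError("no tile predictions given")
    return PredictionMap(slide_id=slide_id, entries=entries)


def render_prediction_map(pmap: PredictionMap, cell_px: int = 16) -> np.ndarray:
    """RGB overlay of a prediction map on white.

    Luminal tiles render red, basal blue, with alpha proportional to
    ``(p - 0.5) * 2`` so an uninformative 0.5 tile is invisible.
    """
    rows, cols = pmap.grid_shape()
    img = np.full((rows * cell_px, cols * cell_px, 3), 255.0)
    colors = {"luminal": np.array([255.0, 0.0, 0.0]), "basal": np.array([0.0, 0.0, 255.0])}
    for (r, c), (label, p) in pmap.entries.items():
        alpha = max(0.0, min(1.0, (p - 0.5) * 2.0))
        cell = (1.0 - alpha) * 255.0 + alpha * colors[label]
        img[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px] = cell
    return img.astype(np.uint8)


@dataclass
class HeterogeneityReport:
    slide_id: str
    n_tiles: int
    components: dict[str, list[int]]
    n_assigned: dict[str, int]
    is_candidate: bool
    min_component_fraction: float
    prob_floor: float


def detect_heterogeneity(
    pmap: PredictionMap,
    min_component_fraction: float = 0.2,
    prob_floor: float = 0.6,
) -> HeterogeneityReport:
    """Screen a prediction map for spatially coherent mixed-class regions.

    Tiles whose winning probability reaches ``prob_floor`` are assigned to
    their class; 4-connected components are computed per class on the tile
    grid.  The slide is a heterogeneity candidate iff both classes own at
    least one component covering ``min_component_fraction`` of all retained
    tiles.
    """
    if not pmap.entries:
        raise ValueError("empty prediction map")
    rows, cols = pmap.grid_shape()
    total = pmap.n_tiles
    components: dict[str, list[int]] = {}
    n_assigned: dict[str, int] = {}
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for cls in ("luminal", "basal"):
        mask = np.zeros((rows, cols), dtype=bool)
        for (r, c), (label, p) in pmap.entries.items():
            if label == cls and p >= prob_floor:
                mask[r, c] = True
        labeled, n_comp = ndimage.label(mask, structure=structure)
        sizes = (
            np.bincount(labeled.ravel())[1:].tolist() if n_comp else []
        )
        components[cls] = sorted(sizes, reverse=True)
        n_assigned[cls] = int(mask.sum())
    is_candidate = all(
        components[cls] and components[cls][0] >= min_component_fraction * total
        for cls in ("luminal", "basal")
    )
    return HeterogeneityReport(
        slide_id=pmap.slide_id,
        n_tiles=total,
        components=components,
        n_assigned=n_assigned,
        is_candidate=bool(is_candidate),
        min_component_fraction=min_component_fraction,
        prob_floor=prob_floor,
    )


def slide_predictions_frame(predictions) -> pd.DataFrame:
    """Tabulate SlidePrediction objects for CSV output."""
    return pd.DataFrame(
        [
            {
                "slide_id": p.slide_id,
                "p_wsi_luminal": p.p_wsi_luminal,
                "p_wsi_basal": p.p_wsi_basal,
                "label": p.label,
                "band": p.confidence_band,
                "n_tiles": p.n_tiles,
                "tie": p.tie,
            }
            for p in predictions
        ]
    )
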