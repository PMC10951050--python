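"""End-to-end orchestration: cohort -> tiles -> CV training -> evaluation.

``tile_slide`` turns one annotated slide into quality-filtered, stain-
normalized tumor tiles.  ``run_cv_experiment`` runs the full weakly
supervised experiment on a (synthetic or on-disk) cohort: patient-level
repeated k-fold cross-validation, per-fold class balancing, tile classifier
training, slide-level aggregation with confidence bands, fold metrics with
t-based confidence intervals, and per-repetition concatenated confusion
matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cv import balance_training_tiles, plan_folds
from .inference import aggregate_slide, slide_predictions_frame
from .model import TileClassifier, predict_tiles
from .stats import auroc, compute_fold_metrics, confusion_concat, summarize_metrics
from .wsi import (
    MacenkoNormalizer,
    extract_tile,
    load_annotations,
    qc_filter,
    tessellate,
)


def tile_slide(
    image: np.ndarray,
    annotation,
    slide_id: str = "",
    label: str | None = None,
    tile_edge: int = 512,
    min_tumor_fraction: float = 0.5,
    normalize: bool = True,
    normalizer: MacenkoNormalizer | None = None,
    qc_params: dict | None = None,
):
    """Tessellate, QC-filter and stain-normalize one annotated slide.

    ``annotation`` may be a :class:`~histotype.wsi.TumorAnnotation`, a
    GeoJSON dict, or a path.  Returns ``(specs, tiles, qc_table)`` where
    ``specs``/``tiles`` hold only the accepted tiles and ``qc_table``
    records the decision for every candidate tile.
    """
    from .wsi import TumorAnnotation

    if not isinstance(annotation, TumorAnnotation):
        annotation = load_annotations(annotation, slide_id=slide_id)
    specs = tessellate(
        image, annotation, tile_edge=tile_edge, min_tumor_fraction=min_tumor_fraction,
        label=label,
    )
    if normalize and normalizer is None:
        normalizer = MacenkoNormalizer().fit()
    kept_specs, kept_tiles, qc_rows = [], [], []
    for spec in specs:
        tile = extract_tile(image, spec)
        decision = qc_filter(tile, **(qc_params or {}))
        qc_rows.append(
            {
                "slide_id": spec.slide_id,
                "grid_row": spec.grid_row,
                "grid_col": spec.grid_col,
                "tumor_fraction": spec.tumor_fraction,
                "qc_status": "accept" if decision.accepted else decision.reason,
            }
        )
        if not decision.accepted:
            continue
        if normalize:
            tile = normalizer.transform([tile])[0]
        kept_specs.append(spec)
        kept_tiles.append(tile)
    return kept_specs, kept_tiles, pd.DataFrame(qc_rows)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_cv_experiment(
    cohort,
    seed: int = 7,
    n_folds: int = 3,
    n_repetitions: int = 1,
    epochs: int = 6,
    input_edge: int = 64,
    batch_size: int = 32,
    learning_rate: float = 0.05,
    normalize: bool = True,
    tile_edge: int = 512,
    keep_models: bool = True,
) -> dict:
    """Run the weakly supervised subtype experiment on a cohort.

    ``cohort`` is a :class:`~histotype.simulate.CohortPlan`; only its
    luminal/basal slides enter the cross-validation (the two most
    distinctive subtypes), with every tile inheriting the parent slide's
    label.  Returns a dict with the tile manifest, per-fold metrics, their
    t-based summaries, per-repetition concatenated slide predictions and
    confusion matrices, the concatenated slide-level AUROC per repetition,
    and the best repetition by mean accuracy.
    """
    manifest_rows = []
    tiles: list[np.ndarray] = []
    normalizer = MacenkoNormalizer().fit() if normalize else None
    for spec in cohort.slides:
        if spec.label not in ("luminal", "basal"):
            continue
        slide = cohort.materialize(spec.index)
        kept_specs, kept_tiles, _ = tile_slide(
            slide.image,
            slide.annotation,
            slide_id=spec.slide_id,
            label=spec.label,
            tile_edge=tile_edge,
            normalize=normalize,
            normalizer=normalizer,
        )
        for ts, tile in zip(kept_specs, kept_tiles):
            manifest_rows.append(
                {
                    "tile_index": len(tiles),
                    "slide_id": spec.slide_id,
                    "patient_id": spec.patient_id,
                    "grid_row": ts.grid_row,
                    "grid_col": ts.grid_col,
                    "tumor_fraction": ts.tumor_fraction,
                    "label": spec.label,
                }
            )
            tiles.append(tile)
    manifest = pd.DataFrame(manifest_rows)
    if manifest.empty:
        raise ValueError("cohort produced no luminal/basal tiles")

    plan = plan_folds(manifest, n_folds=n_folds, n_repetitions=n_repetitions, seed=seed)
    slide_labels = manifest.drop_duplicates("slide_id").set_index("slide_id")["label"]

    fold_metric_rows = []
    per_rep_predictions: dict[int, pd.DataFrame] = {}
    models: dict[tuple[int, int], TileClassifier] = {}
    for rep in range(n_repetitions):
        rep_frames = []
        for fold in range(n_folds):
            val_patients = set(plan.validation_patients(rep, fold))
            train_rows = manifest[~manifest["patient_id"].isin(val_patients)]
            val_rows = manifest[manifest["patient_id"].isin(val_patients)]
            balanced = balance_training_tiles(train_rows, seed=_derived_seed(seed, rep, fold))
            clf = TileClassifier(
                input_edge=input_edge,
                epochs=epochs,
                batch_size=batch_size,
                learning_rate=learning_rate,
                seed=_derived_seed(seed, rep, fold, 1),
            )
            clf.fit(
                [tiles[i] for i in balanced["tile_index"]],
                balanced["label"].to_numpy(),
            )
            if keep_models:
                models[(rep, fold)] = clf
            preds = predict_tiles(
                clf,
                [tiles[i] for i in val_rows["tile_index"]],
                refs=val_rows[["slide_id", "grid_row", "grid_col"]],
            )
            slide_preds = [
                aggregate_slide(group, slide_id=sid)
                for sid, group in preds.groupby("slide_id", sort=True)
            ]
            frame = slide_predictions_frame(slide_preds)
            frame["true_label"] = frame["slide_id"].map(slide_labels).to_numpy()
            frame["repetition"] = rep
            frame["fold"] = fold
            rep_frames.append(frame)
            metrics = compute_fold_metrics(
                frame["true_label"], frame["p_wsi_basal"], pos_label="basal"
            )
            fold_metric_rows.append({"repetition": rep, "fold": fold, **metrics})
        per_rep_predictions[rep] = pd.concat(rep_frames, ignore_index=True)

    fold_metrics = pd.DataFrame(fold_metric_rows)
    summaries = {}
    confusions = {}
    slide_aurocs = {}
    for rep in range(n_repetitions):
        rep_rows = fold_metrics[fold_metrics["repetition"] == rep]
        summaries[rep] = summarize_metrics(
            rep_rows.drop(columns=["repetition", "fold"])
        )
        frame = per_rep_predictions[rep]
        pred_frame = frame.rename(columns={"label": "pred_label"})
        confusions[rep] = confusion_concat(
            pred_frame[["slide_id", "fold", "true_label", "pred_label"]]
        )
        slide_aurocs[rep] = auroc(
            frame["p_wsi_basal"], frame["true_label"], pos_label="basal"
        )
    best_rep = max(summaries, key=lambda r: summaries[r]["accuracy"]["mean"])
    return {
        "manifest": manifest,
        "fold_plan": plan,
        "fold_metrics": fold_metrics,
        "summaries": summaries,
        "slide_predictions": per_rep_predictions,
        "confusions": confusions,
        "slide_auroc": slide_aurocs,
        "best_repetition": best_rep,
        "models": models,
    }
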