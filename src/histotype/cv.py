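"""Patient-level repeated cross-validation planning and tile balancing.

Tiles inherit their label from the parent slide, so splitting must happen at
the patient level to keep training and validation folds independent: all
tiles of a patient land in the same fold.  A plan holds ``n_repetitions``
independent shuffles of the patient set, each split into ``n_folds``
near-equal validation folds.  Within each training set, class imbalance is
removed by downsampling every class to the minority-class tile count.
All randomness is driven by the plan seed, so identical inputs give
bit-identical plans and balanced sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FoldPlan:
    """Repetition x fold partition of the patient set."""

    n_folds: int
    n_repetitions: int
    seed: int
    assignment: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)

    def validation_patients(self, repetition: int, fold: int) -> tuple[str, ...]:
        return self.assignment[(repetition, fold)]

    def train_patients(self, repetition: int, fold: int) -> tuple[str, ...]:
        held_out = set(self.assignment[(repetition, fold)])
        ordered: list[str] = []
        for f in range(self.n_folds):
            if f == fold:
                continue
            ordered.extend(self.assignment[(repetition, f)])
        assert not held_out & set(ordered)
        return tuple(ordered)

    @property
    def patients(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in range(self.n_folds):
            for p in self.assignment[(0, f)]:
                seen[p] = None
        return tuple(seen)

    def to_json(self, path=None) -> str:
        payload = {
            "n_folds": self.n_folds,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "assignment": {
                f"{rep}:{fold}": list(patients)
                for (rep, fold), patients in sorted(self.assignment.items())
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FoldPlan":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        assignment = {
            tuple(int(x) for x in key.split(":")): tuple(patients)
            for key, patients in payload["assignment"].items()
        }
        return cls(
            n_folds=payload["n_folds"],
            n_repetitions=payload["n_repetitions"],
            seed=payload["seed"],
            assignment=assignment,
        )


def _unique_patients(manifest) -> list[str]:
    if isinstance(manifest, pd.DataFrame):
        if "slide_id" in manifest.columns and "patient_id" in manifest.columns:
            per_slide = manifest.groupby("slide_id")["patient_id"].nunique()
            if (per_slide > 1).any():
                bad = per_slide[per_slide > 1].index[0]
                raise ValueError(f"slide {bad!r} maps to more than one patient")
        return manifest["patient_id"].drop_duplicates().tolist()
    return list(dict.fromkeys(manifest))


def plan_folds(
    manifest,
    n_folds: int = 3,
    n_repetitions: int = 3,
    seed: int = 0,
    stratify_by: pd.Series | dict | None = None,
) -> FoldPlan:
    """Plan a repeated patient-level cross-validation.

    ``manifest`` is a tile manifest DataFrame (with a ``patient_id`` column)
    or a plain sequence of patient ids; patient order of first appearance is
    the canonical ordering.  Each repetition shuffles the patients with its
    own seeded stream and splits them into ``n_folds`` near-equal validation
    sets (earlier folds take the remainder).  Splitting is plain random by
    default; pass ``stratify_by`` (patient -> label) to balance labels across
    folds when small classes would otherwise leave a fold class-empty.
    """
    patients = _unique_patients(manifest)
    if len(patients) < n_folds:
        raise ValueError(
            f"cannot split {len(patients)} patients into {n_folds} folds"
        )
    plan = FoldPlan(n_folds=n_folds, n_repetitions=n_repetitions, seed=seed)
    for rep in range(n_repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        if stratify_by is None:
            order = [patients[i] for i in rng.permutation(len(patients))]
            folds = [list(part) for part in np.array_split(order, n_folds)]
        else:
            lookup = dict(stratify_by) if not isinstance(stratify_by, dict) else stratify_by
            folds = [[] for _ in range(n_folds)]
            by_label: dict[str, list[str]] = {}
            for p in patients:
                by_label.setdefault(str(lookup[p]), []).append(p)
            offset = 0
            for label in sorted(by_label):
                members = by_label[label]
                shuffled = [members[i] for i in rng.permutation(len(members))]
                for i, p in enumerate(shuffled):
                    folds[(offset + i) % n_folds].append(p)
                offset += len(members)
        for fold, members in enumerate(folds):
            plan.assignment[(rep, fold)] = tuple(members)
    return plan


def balance_training_tiles(train_rows: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Equalize class tile counts by downsampling without replacement.

    Every class present in ``train_rows`` is downsampled to the minority
    class count with a seeded stream; the surviving rows keep their original
    order.  A training fold with fewer than two classes is an invalid plan
    and raises.
    """
    if "label" not in train_rows.columns:
        raise ValueError("train_rows must have a 'label' column")
    counts = train_rows["label"].value_counts()
    if len(counts) < 2:
        present = counts.index.tolist()
        raise ValueError(
            f"training fold contains only class(es) {present}; "
            "re-seed the plan or enable stratification"
        )
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep_positions: list[np.ndarray] = []
    positions = np.arange(len(train_rows))
    labels = train_rows["label"].to_numpy()
    for label in sorted(counts.index):
        pos = positions[labels == label]
        if len(pos) > n_min:
            pos = rng.choice(pos, size=n_min, replace=False)
        keep_positions.append(np.sort(pos))
    keep = np.sort(np.concatenate(keep_positions))
    return train_rows.iloc[keep]
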