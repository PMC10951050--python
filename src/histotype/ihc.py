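"""Protein-based subtyping from IHC H-scores.

Six differentiation markers of the urothelium are scored per tissue-microarray
core on the H-score scale (0-300, intensity times percent positive cells):
three luminal markers (CK20, FOXA1, GATA3) and three basal markers (CD44, CK5,
CK14).  Per patient, marker expression is the median H-score across the
available cores (four in a standard TMA design).  The patient x marker matrix
is standardized per marker (z-scores) and clustered with Ward agglomerative
clustering on Euclidean distance; the tree is cut into ``k`` clusters which
are named by a centroid rule: the cluster with the largest mean luminal-minus-
basal z-score is *luminal*, the one with the largest basal-minus-luminal
z-score is *basal*, and (for ``k=3``) the remaining cluster with low
expression of both panels is *indifferent*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

BASAL_MARKERS: tuple[str, ...] = ("CD44", "CK5", "CK14")
LUMINAL_MARKERS: tuple[str, ...] = ("CK20", "FOXA1", "GATA3")
#: canonical marker order used for all matrices
MARKERS: tuple[str, ...] = BASAL_MARKERS + LUMINAL_MARKERS

SUBTYPE_LUMINAL = "luminal"
SUBTYPE_BASAL = "basal"
SUBTYPE_INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class MarkerMeasurement:
    """One H-score measurement: a (patient, core, marker) triple."""

    patient_id: str
    core_id: int
    marker: str
    h_score: float

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(
                f"unknown marker {self.marker!r}; expected one of {MARKERS}"
            )
        if not (0.0 <= self.h_score <= 300.0):
            raise ValueError(
                f"h_score {self.h_score} outside [0, 300] "
                f"(patient {self.patient_id}, marker {self.marker})"
            )


def _as_measurement_frame(measurements) -> pd.DataFrame:
    """Coerce a list of MarkerMeasurement or a DataFrame to a validated frame."""
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            [
                (m.patient_id, m.core_id, m.marker, m.h_score)
                for m in measurements
            ],
            columns=["patient_id", "core_id", "marker", "h_score"],
        )
    required = {"patient_id", "core_id", "marker", "h_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    bad_markers = set(df["marker"]) - set(MARKERS)
    if bad_markers:
        raise ValueError(f"unknown markers: {sorted(bad_markers)}")
    scores = df["h_score"].to_numpy(dtype=float)
    if np.any(scores < 0) or np.any(scores > 300):
        raise ValueError("h_score values outside [0, 300]")
    dup = df.duplicated(subset=["patient_id", "core_id", "marker"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate (patient, core, marker) measurement: "
            f"({row['patient_id']}, {row['core_id']}, {row['marker']})"
        )
    return df


def aggregate_cores(measurements) -> pd.DataFrame:
    """Aggregate per-core H-scores to a patient x marker matrix of core medians.

    Parameters
    ----------
    measurements
        List of :class:`MarkerMeasurement` or a DataFrame with columns
        ``patient_id, core_id, marker, h_score``.

    Returns
    -------
    DataFrame indexed by ``patient_id`` (input order of first appearance) with
    one column per marker in canonical order; each value is the median H-score
    over the patient's available cores for that marker.

    Raises
    ------
    ValueError
        If a patient has no core at all for some marker.
    """
    df = _as_measurement_frame(measurements)
    if df.empty:
        raise ValueError("no measurements provided")
    patient_order = df["patient_id"].drop_duplicates().tolist()
    medians = df.groupby(["patient_id", "marker"], sort=False)["h_score"].median()
    matrix = medians.unstack("marker")
    for marker in MARKERS:
        if marker not in matrix.columns:
            matrix[marker] = np.nan
    matrix = matrix.loc[patient_order, list(MARKERS)]
    if matrix.isna().any().any():
        nul = matrix.isna()
        patient = nul.any(axis=1).idxmax()
        marker = nul.loc[patient].idxmax()
        raise ValueError(
            f"patient {patient!r} has no core measurement for marker {marker!r}"
        )
    matrix.index.name = "patient_id"
    matrix.columns.name = "marker"
    return matrix


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker z-scores: ``(x - column mean) / column sample SD`` (ddof=1).

    Raises ``ValueError`` for fewer than two patients or a zero-variance
    marker column, where subtyping is undefined.
    """
    if len(matrix) < 2:
        raise ValueError("standardization requires at least two patients")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"marker column {matrix.columns[zero[0]]!r} has zero variance; "
            "subtyping is undefined"
        )
    z = (values - mean) / sd
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def _name_clusters(z: pd.DataFrame, cluster_idx: np.ndarray, k: int) -> dict[int, str]:
    """Map cluster indices to subtype names via the centroid rule."""
    lum_cols = [c for c in z.columns if c in LUMINAL_MARKERS]
    bas_cols = [c for c in z.columns if c in BASAL_MARKERS]
    indices = np.unique(cluster_idx)
    lb = []
    for c in indices:
        member = z.iloc[cluster_idx == c]
        l_score = member[lum_cols].to_numpy().mean()
        b_score = member[bas_cols].to_numpy().mean()
        lb.append(l_score - b_score)
    lb = np.asarray(lb)
    luminal_cluster = indices[int(np.argmax(lb))]
    basal_cluster = indices[int(np.argmax(-lb))]
    if luminal_cluster == basal_cluster:
        raise ValueError(
            "centroid rule is tied: the same cluster maximizes both the "
            "luminal and the basal score; manual review required"
        )
    names = {int(luminal_cluster): SUBTYPE_LUMINAL, int(basal_cluster): SUBTYPE_BASAL}
    for c in indices:
        if int(c) not in names:
            names[int(c)] = SUBTYPE_INDIFFERENT
    return names


class HScoreSubtyper(ClusterMixin, BaseEstimator):
    """Assign luminal/basal/indifferent subtypes by hierarchical clustering.

    Ward linkage on Euclidean distance over per-marker z-scores, tree cut at
    ``k`` clusters, clusters named by the centroid rule (see module
    docstring).  ``k=3`` discovers the three subtypes; ``k=2`` restricts the
    naming to luminal vs basal.

    Parameters
    ----------
    k : int, default 3
        Number of clusters; must be 2 or 3.
    standardize_input : bool, default True
        If True, ``fit`` expects a raw H-score matrix and standardizes it;
        if False, the input is assumed to already hold per-marker z-scores.

    Attributes
    ----------
    labels_ : ndarray of str
        Subtype name per patient, in input row order.
    cluster_indices_ : ndarray of int
        0-based cluster index per patient (ordered by first appearance).
    cluster_names_ : dict
        Mapping cluster index -> subtype name.
    metadata_ : dict
        Linkage, distance and marker panels used, for sidecar serialization.
    """

    def __init__(self, k: int = 3, standardize_input: bool = True):
        self.k = k
        self.standardize_input = standardize_input

    def fit(self, X: pd.DataFrame, y=None) -> "HScoreSubtyper":
        if self.k not in (2, 3):
            raise ValueError(f"k must be 2 or 3, got {self.k}")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(MARKERS))
        if len(X) < self.k:
            raise ValueError(
                f"need at least k={self.k} patients, got {len(X)}"
            )
        z = standardize(X) if self.standardize_input else X.astype(float)
        link = linkage(z.to_numpy(), method="ward", metric="euclidean")
        raw = fcluster(link, t=self.k, criterion="maxclust")
        # relabel clusters 0..k-1 by order of first appearance in input order
        remap: dict[int, int] = {}
        for c in raw:
            if c not in remap:
                remap[c] = len(remap)
        idx = np.array([remap[c] for c in raw], dtype=int)
        names = _name_clusters(z, idx, self.k)
        self.cluster_indices_ = idx
        self.cluster_names_ = names
        self.labels_ = np.array([names[int(c)] for c in idx], dtype=object)
        self.patient_ids_ = np.asarray(z.index)
        self.metadata_ = {
            "linkage": "ward",
            "distance": "euclidean",
            "k": self.k,
            "luminal_markers": list(LUMINAL_MARKERS),
            "basal_markers": list(BASAL_MARKERS),
        }
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def assignments(self) -> pd.DataFrame:
        """Fitted assignments as a DataFrame (patient_id, cluster_index, label)."""
        check_is_fitted(self, "labels_")
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids_,
                "cluster_index": self.cluster_indices_,
                "label": self.labels_,
            }
        )


def cluster_subtypes(z: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Cluster an already standardized matrix into named subtypes.

    Thin wrapper over :class:`HScoreSubtyper` with ``standardize_input=False``;
    returns the assignment DataFrame.
    """
    est = HScoreSubtyper(k=k, standardize_input=False)
    est.fit(z)
    return est.assignments()
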