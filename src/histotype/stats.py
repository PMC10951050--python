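"""Evaluation metrics and association tests.

Fold-level classifier metrics (AUROC, accuracy, precision, recall, F1) are
computed with the basal subtype as the positive class and summarized across
the K validation folds of one cross-validation repetition as mean and 95%
confidence interval based on Student's t-distribution with K-1 degrees of
freedom.  Confusion matrices concatenate the predictions of all validation
folds of a repetition, so every slide is counted exactly once.

Association tests between subtype calls and categorical or continuous
metadata follow standard practice: Fisher's exact test for 2x2 categorical
tables, the Wilcoxon rank-sum test for two independent groups, the
Kruskal-Wallis test for more than two groups, and the one-tailed Wilcoxon
signed-rank test for paired samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

POSITIVE_CLASS = "basal"

METRIC_NAMES = ("auroc", "accuracy", "precision", "recall", "f1")

#: sample-size switch between exact enumeration and normal approximation
EXACT_N_MAX = 25


def auroc(scores, labels, pos_label: str = POSITIVE_CLASS) -> float:
    """Area under the ROC curve for ``pos_label`` as positive class.

    Equals the Mann-Whitney pair statistic
    ``(#[pos > neg] + 0.5 * #[pos == neg]) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == pos_label
    if pos.all() or (~pos).all():
        raise ValueError("AUROC needs both a positive and a negative example")
    return float(roc_auc_score(pos.astype(int), scores))


def compute_fold_metrics(
    y_true,
    scores,
    pos_label: str = POSITIVE_CLASS,
    threshold: float = 0.5,
    macro: bool = False,
) -> dict[str, float]:
    """AUROC/accuracy/precision/recall/F1 for one validation fold.

    ``scores`` are probabilities of ``pos_label``; predictions use a 0.5
    threshold.  By default precision/recall/F1 are for the positive (basal)
    class; ``macro=True`` averages the per-class values instead.
    """
    from sklearn.metrics import accuracy_score, precision_recall_fscore_support

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pos = (y_true == pos_label).astype(int)
    y_pred = (scores >= threshold).astype(int)
    average = "macro" if macro else "binary"
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_pos, y_pred, average=average, zero_division=0
    )
    return {
        "auroc": auroc(scores, y_true, pos_label=pos_label),
        "accuracy": float(accuracy_score(y_pos, y_pred)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def summarize_metrics(folds) -> dict[str, dict[str, float]]:
    """Mean and 95% t-based CI per metric over the folds of one repetition.

    ``folds`` is a sequence of per-fold metric dicts (or a DataFrame).  The
    interval is ``mean +/- t(0.975, K-1) * SD / sqrt(K)`` with the sample SD
    (ddof=1); for K=3 the multiplier is t(0.975, 2) ~= 4.30265.
    """
    df = pd.DataFrame(list(folds) if not isinstance(folds, pd.DataFrame) else folds)
    k = len(df)
    if k < 2:
        raise ValueError("need at least two folds to summarize")
    tq = float(sps.t.ppf(0.975, k - 1))
    out: dict[str, dict[str, float]] = {}
    for metric in df.columns:
        vals = df[metric].to_numpy(dtype=float)
        mean = float(vals.mean())
        half = tq * float(vals.std(ddof=1)) / np.sqrt(k)
        out[metric] = {
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
        }
    return out


@dataclass
class ConfusionMatrix:
    """2x2 true x predicted counts concatenated over the folds of a repetition."""

    counts: pd.DataFrame
    tpr: dict[str, float | None] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion_concat(
    fold_predictions: pd.DataFrame,
    classes: tuple[str, str] = ("luminal", "basal"),
) -> ConfusionMatrix:
    """Confusion matrix over concatenated validation folds.

    ``fold_predictions`` needs columns ``slide_id, true_label, pred_label``
    (an optional ``fold`` column is used for the leakage check).  A slide
    appearing more than once means the patient-level split leaked; that is a
    hard error.  Per-class true-positive rate is diagonal / row total, or
    ``None`` for an empty class row.
    """
    df = fold_predictions
    dup = df["slide_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"slide {df.loc[dup, 'slide_id'].iloc[0]!r} predicted more than "
            "once across folds (split leakage)"
        )
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for _, row in df.iterrows():
        counts.loc[row["true_label"], row["pred_label"]] += 1
    tpr: dict[str, float | None] = {}
    for cls in classes:
        row_total = int(counts.loc[cls].sum())
        tpr[cls] = (
            float(counts.loc[cls, cls]) / row_total if row_total > 0 else None
        )
    counts.index.name = "true"
    counts.columns.name = "predicted"
    return ConfusionMatrix(counts=counts, tpr=tpr)


_FISHER_ALTS = {
    "two_sided": "two-sided",
    "greater": "greater",
    "less": "less",
}


def fisher_exact_2x2(table, alternative: str = "two_sided") -> float:
    """Fisher's exact test p-value for a 2x2 contingency table.

    Exact hypergeometric enumeration over all tables with the observed
    margins; ``two_sided`` sums the probabilities of tables no more likely
    than the observed one, one-sided alternatives sum the corresponding tail.
    """
    if alternative not in _FISHER_ALTS:
        raise ValueError(f"alternative must be one of {sorted(_FISHER_ALTS)}")
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; Fisher test undefined")
    _, p = sps.fisher_exact(t, alternative=_FISHER_ALTS[alternative])
    return float(p)


def rank_tests(
    values=None,
    groups=None,
    pairs=None,
    kind: str = "rank_sum",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Nonparametric comparison tests with midrank tie handling.

    ``kind='rank_sum'``: Wilcoxon rank-sum / Mann-Whitney U between two
    independent groups (``groups`` = pair of sequences, or ``values`` plus a
    two-level ``groups`` label vector).  Returns (U of the first group, p).

    ``kind='kruskal_wallis'``: Kruskal-Wallis H across >2 groups
    (``groups`` = list of sequences).

    ``kind='signed_rank_one_tailed'``: one-tailed Wilcoxon signed-rank test
    on paired samples (``pairs`` = (x, y) or a sequence of differences);
    zero differences are dropped; the alternative is 'greater' unless
    specified.

    Exact enumeration is used for samples up to 25 observations, the normal
    approximation above that.
    """
    if kind == "rank_sum":
        x, y = _two_groups(values, groups)
        method = "exact" if max(len(x), len(y)) <= EXACT_N_MAX else "asymptotic"
        try:
            res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
        except ValueError:
            # exact method refuses ties; fall back to the tie-corrected normal
            res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if kind == "kruskal_wallis":
        if groups is None or len(groups) < 2:
            raise ValueError("kruskal_wallis needs at least two groups")
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if any(a.size == 0 for a in arrays):
            raise ValueError("empty group")
        if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
            return 0.0, 1.0  # identical groups: no between-group variation
        res = sps.kruskal(*arrays)
        return float(res.statistic), float(res.pvalue)
    if kind == "signed_rank_one_tailed":
        d = _paired_differences(pairs, values)
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("all paired differences are zero")
        alt = alternative if alternative in ("greater", "less") else "greater"
        method = "exact" if d.size <= EXACT_N_MAX else "approx"
        try:
            res = sps.wilcoxon(d, alternative=alt, method=method)
        except ValueError:
            res = sps.wilcoxon(d, alternative=alt, method="approx")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def _two_groups(values, groups):
    if groups is not None and len(groups) == 2 and not np.isscalar(groups[0]):
        x, y = (np.asarray(g, dtype=float) for g in groups)
    elif values is not None and groups is not None:
        values = np.asarray(values, dtype=float)
        labels = np.asarray(groups)
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ValueError("rank_sum needs exactly two groups")
        x = values[labels == uniq[0]]
        y = values[labels == uniq[1]]
    else:
        raise ValueError("provide two groups for rank_sum")
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    return x, y


def _paired_differences(pairs, values):
    if pairs is not None:
        pairs = np.asarray(pairs, dtype=float)
        if pairs.ndim == 2 and pairs.shape[0] == 2:
            return pairs[0] - pairs[1]
        if pairs.ndim == 2 and pairs.shape[1] == 2:
            return pairs[:, 0] - pairs[:, 1]
        return pairs.ravel()
    if values is not None:
        return np.asarray(values, dtype=float).ravel()
    raise ValueError("provide paired samples or differences")


def association_table(
    meta: pd.DataFrame,
    group_col: str,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Association of a two-level grouping with metadata columns.

    Categorical columns are tested with Fisher's exact test on the 2x2 table
    (the two most frequent levels are used when there are more); continuous
    columns with the rank-sum test.  Returns one row per variable with the
    test name and p-value.
    """
    levels = pd.unique(meta[group_col].dropna())
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly two levels")
    rows = []
    for col in categorical or []:
        sub = meta[[group_col, col]].dropna()
        tab = pd.crosstab(sub[group_col], sub[col])
        if tab.shape[1] > 2:
            keep = tab.sum(axis=0).nlargest(2).index
            tab = tab[keep]
        if tab.shape != (2, 2):
            rows.append({"variable": col, "test": "fisher_exact", "p_value": np.nan})
            continue
        p = fisher_exact_2x2(tab.to_numpy(), alternative="two_sided")
        rows.append({"variable": col, "test": "fisher_exact", "p_value": p})
    for col in continuous or []:
        sub = meta[[group_col, col]].dropna()
        g0 = sub.loc[sub[group_col] == levels[0], col]
        g1 = sub.loc[sub[group_col] == levels[1], col]
        _, p = rank_tests(groups=(g0, g1), kind="rank_sum")
        rows.append({"variable": col, "test": "rank_sum", "p_value": p})
    return pd.DataFrame(rows)
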