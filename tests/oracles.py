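"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths (and the scipy/sklearn
routines behind them): explicit pair counting for the ROC area, the
log-factorial hypergeometric formula for Fisher's exact test, BFS flood
fill for connected components, and per-pixel rasterization for tile
retention.
"""

import math

import numpy as np


def pair_counting_auroc(pos_scores, neg_scores) -> float:
    """ROC area by explicit double loop over all (positive, negative) pairs."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def log_factorial_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by direct enumeration of margin-consistent tables,
    each probability computed from the log-factorial hypergeometric formula."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_prob(x):
        return (
            (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1))
            + (
                math.lgamma(r2 + 1)
                - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - (c1 - x) + 1)
            )
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= p_obs + 1e-12:
            total += math.exp(lp)
    return min(1.0, total)


def flood_fill_components(cells: set) -> list[int]:
    """4-connected component sizes of a cell set, by BFS; sorted descending."""
    remaining = set(cells)
    sizes = []
    while remaining:
        stack = [remaining.pop()]
        size = 0
        while stack:
            r, c = stack.pop()
            size += 1
            for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if nb in remaining:
                    remaining.remove(nb)
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes, reverse=True)


def rasterized_retained_tiles(mask: np.ndarray, edge: int, threshold: float = 0.5) -> set:
    """Tiles retained by per-pixel rasterized overlap counting."""
    retained = set()
    for r in range(mask.shape[0] // edge):
        for c in range(mask.shape[1] // edge):
            frac = mask[r * edge : (r + 1) * edge, c * edge : (c + 1) * edge].mean()
            if frac >= threshold:
                retained.add((r, c))
    return retained
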