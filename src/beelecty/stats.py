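"""Rank statistics used across the pipeline.

Two statistics the analysis depends on are implemented from their
definitions so their conventions are explicit and testable:

* AUC as the rank-based probability that a randomly chosen positive case
  outscores a randomly chosen negative case, ties counting one half; and
* the paired Wilcoxon signed-rank test with the R conventions — zeros
  dropped, average ranks for ties, V = sum of positive ranks — with an
  exact null distribution for small samples (valid under ties, via a
  shift convolution over doubled midranks) and a continuity-corrected
  normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def auc_score(positive_scores, negative_scores) -> float:
    """P(score_pos > score_neg) + ½ P(tie), via midranks (Mann–Whitney)."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty for AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class WilcoxonResult:
    v: float  # sum of positive ranks
    p_value: float
    n_used: int  # pairs remaining after zero removal
    method: str  # "exact" | "normal"


def _exact_signed_rank_p(ranks2: np.ndarray, v2: float, alternative: str) -> float:
    """Exact p over the 2^n equiprobable sign assignments.

    ``ranks2`` are doubled midranks (integers even with average-rank ties);
    ``v2`` is the doubled observed V. The distribution of the doubled
    positive-rank sum is built by shift convolution.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = (dist + shifted) / 2.0
    v2 = int(round(v2))
    p_ge = dist[v2:].sum()
    p_le = dist[: v2 + 1].sum()
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        mean2 = total / 2.0
        # two-sided: total mass at least as far from the mean as observed
        lo = min(v2, int(math.floor(2 * mean2 - v2)))
        hi = max(v2, int(math.ceil(2 * mean2 - v2)))
        p = dist[: lo + 1].sum() + dist[hi:].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = 25,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped; tied absolute differences receive
    average ranks; V is the sum of ranks of positive differences. The
    exact distribution is used for n <= ``exact_threshold`` pairs after
    zero removal, otherwise a normal approximation with tie correction
    and a 0.5 continuity correction.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(v=0.0, p_value=1.0, n_used=0, method="exact")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())

    if n <= exact_threshold:
        p = _exact_signed_rank_p(2.0 * ranks, 2.0 * v, alternative)
        return WilcoxonResult(v=v, p_value=p, n_used=n, method="exact")

    mean = n * (n + 1) / 4.0
    # variance with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sd == 0:
        return WilcoxonResult(v=v, p_value=1.0, n_used=n, method="normal")
    if alternative == "greater":
        z = (v - mean - 0.5) / sd
        p = sps.norm.sf(z)
    elif alternative == "less":
        z = (v - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(v - mean) - 0.5) / sd
        p = 2.0 * sps.norm.sf(z)
    return WilcoxonResult(
        v=v, p_value=float(min(1.0, p)), n_used=n, method="normal"
    )
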