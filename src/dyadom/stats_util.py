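"""Small statistical helpers shared by the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WilcoxonResult", "paired_wilcoxon"]


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired signed-rank test result.

    ``statistic`` is the signed rank sum (W+ - W-), so swapping the paired
    samples flips its sign; ``v`` is the conventional W+ statistic.
    """

    statistic: float
    v: float
    p: float
    n: int
    note: str = ""


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test, zero differences dropped.

    Uses the exact null distribution for n <= 25 informative pairs without
    ties in |difference|, otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, 0, note="all differences zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return WilcoxonResult(
        statistic=w_plus - w_minus,
        v=w_plus,
        p=float(res.pvalue),
        n=n,
    )
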