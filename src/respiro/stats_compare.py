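"""Treatment comparisons: paired t-test, one-way ANOVA with Tukey HSD,
and standard errors. Degenerate zero-variance inputs — easily reached
with small-n microcosm data — return flagged results rather than NaN.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError
from .types import ComparisonResult

ALPHA = 0.05


def standard_error(x: Sequence[float]) -> float:
    """Sample standard deviation over sqrt(n)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InputError(f"standard error needs n >= 2, got n = {arr.size}")
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-tailed paired t-test (pairing by index)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(f"paired samples must be equal-length vectors ({a.shape} vs {b.shape})")
    if a.size < 2:
        raise InputError(f"paired t-test needs n >= 2, got n = {a.size}")
    d = a - b
    if d.std(ddof=1) == 0.0:
        stat = 0.0 if d.mean() == 0.0 else math.copysign(math.inf, d.mean())
        return ComparisonResult(
            groups=("a", "b"), statistic=stat, p_value=1.0,
            degenerate=True, test="paired_t",
        )
    res = sps.ttest_rel(a, b)
    return ComparisonResult(
        groups=("a", "b"),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="paired_t",
    )


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """One-way ANOVA; Tukey HSD pairwise comparisons when the omnibus
    test is significant (adjusted p from the studentized range
    distribution)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InputError("ANOVA needs at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise InputError(f"group {i} has n = {g.size} < 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    labels = list(labels)

    pooled_var = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    if pooled_var == 0.0:
        means = [g.mean() for g in arrays]
        if np.allclose(means, means[0]):
            return ComparisonResult(
                groups=labels, statistic=0.0, p_value=1.0,
                degenerate=True, test="anova",
            )
        return ComparisonResult(
            groups=labels, statistic=math.inf, p_value=0.0,
            pairwise=[
                (labels[i], labels[j], 0.0 if arrays[i].mean() != arrays[j].mean() else 1.0,
                 arrays[i].mean() != arrays[j].mean())
                for i in range(len(arrays)) for j in range(i + 1, len(arrays))
            ],
            degenerate=True, test="anova+tukey",
        )

    f_res = sps.f_oneway(*arrays)
    statistic = float(f_res.statistic)
    p_value = float(f_res.pvalue)
    pairwise = []
    test = "anova"
    if p_value < alpha:
        test = "anova+tukey"
        hsd = sps.tukey_hsd(*arrays)
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                adj_p = float(hsd.pvalue[i, j])
                pairwise.append((labels[i], labels[j], adj_p, adj_p < alpha))
    return ComparisonResult(
        groups=labels, statistic=statistic, p_value=p_value,
        pairwise=pairwise, test=test,
    )
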