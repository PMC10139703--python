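"""Paired per-chromosome comparisons and linear trend fits.

Between-group contrasts of per-chromosome statistics use a Shapiro-Wilk
normality gate on the pairwise differences: a paired t-test when the
differences are compatible with normality, a paired Wilcoxon signed-rank
test otherwise. Rank-profile trends are fit by ordinary least squares;
the reported R-squared is the adjusted form (which can be negative), with
the raw value also carried.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

DEFAULT_GATE_ALPHA = 0.05


@dataclass
class PairedComparison:
    metric: str
    group_a: str
    group_b: str
    n_pairs: int
    shapiro_p: float
    test_used: str  # "paired_t" | "paired_wilcoxon"
    p_value: float
    mean_diff: float
    degenerate: bool = False
    n_dropped: int = 0


@dataclass
class TrendFit:
    response: str
    predictor: str
    slope: float
    intercept: float
    adj_r2: float
    r2: float
    p_value: float
    n: int


def paired_compare(
    values_a: Mapping[str, float] | pd.Series,
    values_b: Mapping[str, float] | pd.Series,
    gate_alpha: float = DEFAULT_GATE_ALPHA,
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> PairedComparison:
    """Paired comparison of per-chromosome values with a normality gate.

    Chromosomes missing a value in either group are dropped pairwise
    (``n_dropped``). Identical pairs throughout give a degenerate result
    (p = 1, Wilcoxon branch). Two-sided p-values.
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    common = a.index.union(b.index)
    pairs = pd.DataFrame({"a": a.reindex(common), "b": b.reindex(common)})
    n_dropped = int(pairs.isna().any(axis=1).sum())
    pairs = pairs.dropna()
    n = len(pairs)
    if n < 3:
        raise ConfigurationError(f"need >= 3 complete pairs, got {n}")
    diffs = (pairs.b - pairs.a).to_numpy()

    if np.allclose(diffs, 0.0):
        return PairedComparison(metric, group_a, group_b, n, np.nan,
                                "paired_wilcoxon", 1.0, 0.0,
                                degenerate=True, n_dropped=n_dropped)

    if np.ptp(diffs) == 0:
        # constant nonzero differences: normality test undefined, but the
        # signed-rank test is well defined (all ranks same sign)
        shapiro_p = float("nan")
    else:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    if shapiro_p > gate_alpha:
        test_used = "paired_t"
        p = float(stats.ttest_rel(pairs.b, pairs.a).pvalue)
    else:
        test_used = "paired_wilcoxon"
        nz = diffs[diffs != 0]  # signed-rank convention: drop zero differences
        method = "exact" if len(nz) <= 25 else "approx"
        try:
            p = float(stats.wilcoxon(nz, method=method, correction=True).pvalue)
        except ValueError:
            p = float(stats.wilcoxon(nz, method="approx", correction=True).pvalue)
    return PairedComparison(metric, group_a, group_b, n, shapiro_p, test_used,
                            p, float(diffs.mean()), n_dropped=n_dropped)


def fit_linear_trend(x: Sequence[float], y: Sequence[float],
                     response: str = "y", predictor: str = "x") -> TrendFit:
    """OLS fit y = a + b*x with adjusted R-squared and slope p-value.

    Pairs with a NaN in either variable are dropped; at least 3 complete
    points and non-degenerate x are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ConfigurationError(f"need >= 3 complete points, got {n}")
    if np.ptp(x) == 0:
        raise ConfigurationError("zero variance in predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TrendFit(response, predictor, float(res.slope), float(res.intercept),
                    float(adj), float(r2), float(res.pvalue), n)


def comparisons_table(comparisons: Sequence[PairedComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def trends_table(trends: Sequence[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in trends])


def markdown_report(comparisons: Sequence[PairedComparison],
                    trends: Sequence[TrendFit] = ()) -> str:
    """Human-readable summary of every contrast and trend fit."""
    lines = ["# Statistical comparisons", ""]
    if comparisons:
        lines += [
            "| metric | A | B | n | test | mean diff (B-A) | p |",
            "|---|---|---|---|---|---|---|",
        ]
        for c in comparisons:
            test = c.test_used + (" (degenerate)" if c.degenerate else "")
            lines.append(
                f"| {c.metric} | {c.group_a} | {c.group_b} | {c.n_pairs} "
                f"| {test} | {c.mean_diff:.4g} | {c.p_value:.3g} |"
            )
        lines.append("")
    if trends:
        lines += [
            "## Linear trends", "",
            "| response | predictor | slope | R2 (adj) | p | n |",
            "|---|---|---|---|---|---|",
        ]
        for t in trends:
            lines.append(
                f"| {t.response} | {t.predictor} | {t.slope:.4g} "
                f"| {t.adj_r2:.3g} | {t.p_value:.3g} | {t.n} |"
            )
        lines.append("")
    return "\n".join(lines)
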