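"""Per-site differential methylation testing and classification.

The test is a per-site binomial logistic likelihood-ratio test of group
membership on methylated/unmethylated counts: with group as the only
covariate, the maximum-likelihood fit assigns each group its pooled
methylation proportion, so the likelihood-ratio statistic has the closed
form of a G-test on the group-collapsed 2x2 count table and is evaluated
vectorised over all sites (chi-square with 1 df). Degenerate sites fall
back to Fisher's exact test on the pooled table and are flagged.

Classification applies inclusive thresholds on the methylation difference
(percentage points) and the Benjamini-Hochberg FDR-corrected p-value;
sites are labelled ``hypo`` (lower in group B), ``hyper`` (higher in
group B) or ``non_DMC``.

Inducibility: a site counts as induced in a population when the native vs
salinity-transplanted comparison for that population is significant under
the same rule as the population comparison; the direction of the induced
change is ignored, only its absolute size is carried.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .meth_io import MethSiteMatrix

logger = logging.getLogger(__name__)

#: Minimum absolute methylation difference (percentage points) for a DMC.
DEFAULT_DM_THRESHOLD = 15.0
#: FDR-corrected p-value cutoff for a DMC.
DEFAULT_ALPHA = 0.05

SITE_CLASSES = ("non_DMC", "hypo", "hyper")
INDUCED_CLASSES = ("neither", "marine_only", "fw_only", "both")


def methylation_summary(matrix: MethSiteMatrix, group: Sequence[str]) -> pd.DataFrame:
    """Per-site mean and standard deviation of per-sample methylation.

    Returns a DataFrame indexed by (chrom, pos) with columns ``mean_pm``
    (mean percentage of methylated copies across the group's samples) and
    ``sd_meth`` (n-1 denominator standard deviation; NaN for groups of one).
    """
    group = list(group)
    if len(group) == 0:
        raise ConfigurationError("methylation_summary requires a non-empty group")
    unknown = set(group) - set(matrix.sample_ids)
    if unknown:
        raise ConfigurationError(f"unknown samples in group: {sorted(unknown)}")
    pm = matrix.pm()[group]
    out = pd.DataFrame(index=pm.index)
    out["mean_pm"] = pm.mean(axis=1)
    out["sd_meth"] = pm.std(axis=1, ddof=1) if len(group) >= 2 else np.nan
    return out


def _binomial_loglik(m: np.ndarray, t: np.ndarray, p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return m * np.log(p) + (t - m) * np.log1p(-p)


def test_dm(
    matrix: MethSiteMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    diff_mode: str = "pooled",
) -> pd.DataFrame:
    """Likelihood-ratio test of differential methylation per site.

    ``meth_diff`` is reported as group B minus group A, either as the
    difference of coverage-weighted pooled percentages (``diff_mode=
    "pooled"``, default) or of unweighted means of per-sample percentages
    (``diff_mode="mean"``). Unequal group sizes are allowed.

    Returns a DataFrame indexed by (chrom, pos) with columns ``meth_diff``,
    ``p_value`` and ``fallback`` (True where the chi-square statistic was
    degenerate and Fisher's exact test on the pooled table was used).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ConfigurationError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ConfigurationError("groups overlap")
    if diff_mode not in ("pooled", "mean"):
        raise ConfigurationError(f"unknown diff_mode {diff_mode!r}")

    m_a = matrix.meth[group_a].sum(axis=1).to_numpy(dtype=np.float64)
    u_a = matrix.unmeth[group_a].sum(axis=1).to_numpy(dtype=np.float64)
    m_b = matrix.meth[group_b].sum(axis=1).to_numpy(dtype=np.float64)
    u_b = matrix.unmeth[group_b].sum(axis=1).to_numpy(dtype=np.float64)
    t_a, t_b = m_a + u_a, m_b + u_b
    if np.any(t_a == 0) or np.any(t_b == 0):
        raise RuntimeError(
            "site with zero total counts in a group; upstream filtering violated"
        )

    p_a, p_b = m_a / t_a, m_b / t_b
    p_pool = (m_a + m_b) / (t_a + t_b)
    g = 2.0 * (
        _binomial_loglik(m_a, t_a, p_a)
        + _binomial_loglik(m_b, t_b, p_b)
        - _binomial_loglik(m_a, t_a, p_pool)
        - _binomial_loglik(m_b, t_b, p_pool)
    )
    g = np.maximum(g, 0.0)
    p_value = stats.chi2.sf(g, df=1)

    fallback = ~np.isfinite(p_value)
    if fallback.any():
        for i in np.flatnonzero(fallback):
            table = [[int(m_a[i]), int(u_a[i])], [int(m_b[i]), int(u_b[i])]]
            p_value[i] = stats.fisher_exact(table)[1]
        logger.warning("%d degenerate fits fell back to Fisher's exact test",
                       int(fallback.sum()))

    if diff_mode == "pooled":
        meth_diff = 100.0 * (p_b - p_a)
    else:
        pm = matrix.pm()
        meth_diff = (pm[group_b].mean(axis=1) - pm[group_a].mean(axis=1)).to_numpy()

    return pd.DataFrame(
        {"meth_diff": meth_diff, "p_value": p_value, "fallback": fallback},
        index=matrix.meth.index,
    )


def classify_sites(
    dm: pd.DataFrame,
    threshold: float = DEFAULT_DM_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Attach BH FDR q-values and direction classes to a test_dm result.

    A site is ``hypo`` iff ``meth_diff <= -threshold`` and ``q <= alpha``,
    ``hyper`` iff ``meth_diff >= +threshold`` and ``q <= alpha`` (inclusive
    boundaries), otherwise ``non_DMC``. q-values are computed over all sites
    in the input, which must be the complete set tested in one comparison.
    """
    if not (0 < threshold <= 100):
        raise ConfigurationError(f"threshold must be in (0, 100], got {threshold}")
    if not (0 < alpha <= 1):
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    if len(dm) == 0:
        raise ConfigurationError("cannot compute q-values on an empty result")
    out = dm.copy()
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    sig = out["q_value"] <= alpha
    out["site_class"] = "non_DMC"
    out.loc[sig & (out["meth_diff"] <= -threshold), "site_class"] = "hypo"
    out.loc[sig & (out["meth_diff"] >= threshold), "site_class"] = "hyper"
    return out


def classify_inducibility(
    population_dm: pd.DataFrame,
    marine_treatment_dm: pd.DataFrame,
    fw_treatment_dm: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-classify sites by induced methylation change in each population.

    All three inputs are outputs of :func:`classify_sites` (same thresholds).
    A site is induced in a population iff it is classified ``hypo`` or
    ``hyper`` in that population's native-vs-transplanted comparison; the
    direction of the induced change is ignored. Sites present in a treatment
    stream but absent from the population stream are skipped with a warning.

    Returns a DataFrame indexed like ``population_dm`` with columns
    ``induced_marine``, ``induced_fw``, ``induced_class`` and the absolute
    induced changes (NaN where not induced).
    """
    base = population_dm.index
    for name, df in (("marine", marine_treatment_dm), ("fw", fw_treatment_dm)):
        extra = df.index.difference(base)
        if len(extra):
            logger.warning(
                "%d sites in %s treatment comparison absent from population "
                "comparison; skipped", len(extra), name,
            )

    out = pd.DataFrame(index=base)
    for name, df in (("marine", marine_treatment_dm), ("fw", fw_treatment_dm)):
        aligned = df.reindex(base)
        induced = (aligned["site_class"].isin(("hypo", "hyper"))).fillna(False)
        out[f"induced_{name}"] = induced.to_numpy(dtype=bool)
        change = aligned["meth_diff"].abs()
        change[~induced] = np.nan
        out[f"abs_induced_change_{name}"] = change

    out["induced_class"] = np.select(
        [
            out.induced_marine & out.induced_fw,
            out.induced_marine & ~out.induced_fw,
            ~out.induced_marine & out.induced_fw,
        ],
        ["both", "marine_only", "fw_only"],
        default="neither",
    )
    return out
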