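"""Equal-width ranking of sites and per-rank diversity profiles.

Pooled-sequencing diversity estimates are unreliable at single sites, so
sites are binned into equal-width ranks of a per-site variable (mean
methylation, methylation variability, their between-population differences,
or absolute induced change) and one diversity estimate is computed per
rank. Ranks are computed separately per population and site category.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .pool_diversity import EstimatorParams, aggregate_diversity

DEFAULT_N_RANKS = 50
DEFAULT_MIN_COVERED_FRACTION = 0.60


def assign_ranks(values: Mapping[tuple[str, int], float] | pd.Series,
                 n_ranks: int = DEFAULT_N_RANKS) -> pd.DataFrame:
    """Assign each site to one of ``n_ranks`` equal-width bins of its value.

    Intervals partition [min, max]; each is left-closed right-open except
    the last, which is closed, so a value at an internal boundary joins the
    upper interval and the maximum joins the last rank. Sites with undefined
    (NaN) values are skipped; their count is reported in ``.attrs
    ["n_skipped"]``. All values identical is a configuration error.
    """
    if n_ranks < 2:
        raise ConfigurationError(f"n_ranks must be >= 2, got {n_ranks}")
    s = pd.Series(values, dtype=float)
    s.index.names = ["chrom", "pos"]
    n_skipped = int(s.isna().sum())
    s = s.dropna()
    if len(s) < 2 or s.min() == s.max():
        raise ConfigurationError(
            "ranking needs at least 2 distinct values (degenerate range)"
        )
    lo, hi = float(s.min()), float(s.max())
    width = (hi - lo) / n_ranks
    rank = np.floor((s.to_numpy() - lo) / width).astype(int) + 1
    rank = np.minimum(rank, n_ranks)  # the maximum closes the last interval
    out = pd.DataFrame({"value": s, "rank": rank}, index=s.index)
    out.attrs["n_skipped"] = n_skipped
    out.attrs["bin_edges"] = lo + width * np.arange(n_ranks + 1)
    return out


def rank_diversity(
    assignments: pd.DataFrame,
    records,
    params: EstimatorParams,
    min_covered_fraction: float = DEFAULT_MIN_COVERED_FRACTION,
) -> pd.DataFrame:
    """One diversity estimate per rank.

    ``assignments`` is the output of :func:`assign_ranks`. Ranks whose
    covered fraction falls below ``min_covered_fraction`` are excluded
    (flagged, not dropped); empty ranks appear with ``n_sites`` 0. Returns a
    per-rank table with the rank's mean ranking-variable value and its
    diversity estimate.
    """
    labels = {site: f"rank_{r:03d}" for site, r in assignments["rank"].items()}
    div = aggregate_diversity(records, labels, params,
                              min_covered_fraction=min_covered_fraction)
    mean_value = assignments.groupby("rank")["value"].mean()
    if "bin_edges" in assignments.attrs:
        n_ranks = len(assignments.attrs["bin_edges"]) - 1
    else:
        n_ranks = int(assignments["rank"].max())
    rows = []
    for r in range(1, n_ranks + 1):
        label = f"rank_{r:03d}"
        if label in div.index:
            d = div.loc[label]
            rows.append((r, float(mean_value.get(r, np.nan)), int(d.n_sites),
                         d.pi, d.theta_w, d.tajimas_d, d.covered_fraction,
                         bool(d.flagged)))
        else:
            rows.append((r, np.nan, 0, np.nan, np.nan, np.nan, 0.0, True))
    return pd.DataFrame(
        rows,
        columns=["rank", "mean_value", "n_sites", "pi", "theta_w", "tajimas_d",
                 "covered_fraction", "excluded"],
    ).set_index("rank")
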