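"""Pooled-sequencing nucleotide diversity estimation.

Parses SAMtools text pileups into quality-filtered per-position allele
counts and computes, over methylation-defined site sets ("labels"):

* per-site and label-aggregated nucleotide diversity pi, Watterson's theta
  and Tajima's D, with the min-count / min-coverage / max-coverage filters
  of pooled-sequencing practice;
* pairwise Fst between two pools in the classical heterozygosity-ratio
  form, site-averaged within labels or in genomic windows;
* detection and typing of biallelic SNPs at CpG sites (C-T/G-A transitions,
  the signature of deamination of methylated cytosines, versus all other
  allele pairs).

Per-site estimators
-------------------
With post-filter allele frequencies ``f_a`` at coverage ``M``:

    pi_site    = M/(M-1) * (1 - sum_a f_a^2)
    S_site     = 1 if >= 2 alleles remain else 0
    theta_site = S_site / a1(M),   a1(M) = sum_{i=1}^{M-1} 1/i

``pi_site`` equals the number of pairwise differences among the M reads
divided by C(M, 2) (tested exhaustively). Alleles supported by fewer than
``min_count`` reads are treated as sequencing error and removed before
anything else.

Pool correction
---------------
In ``pool_corrected`` mode the naive statistics are divided by the expected
value of the naive statistic for a segregating site in a pool of n haploid
genomes, relative to the pool's true heterozygosity, computed by exact
enumeration over the allele-count configurations reachable at coverage M:
derived-allele count k in 1..n-1 with neutral weight 1/k, reads binomial
(M, k/n), min-count filter applied. The enumeration is validated against a
Monte-Carlo oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_PLAIN = set(".,ACGTacgt")
_CT_GA_PAIRS = ({"C", "T"}, {"G", "A"})


@dataclass(frozen=True)
class AlleleCountRecord:
    """Quality-filtered A/C/G/T read counts at one position of one pool."""

    chrom: str
    pos: int  # 1-based
    counts: dict  # base -> count
    ref: str | None = None

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EstimatorParams:
    """Filters and pool geometry for the diversity estimators.

    ``pool_size`` is the number of haploid genomes in the pool (2x the
    number of diploid individuals). ``min_count`` is the minimal number of
    reads supporting an allele for it to be treated as real.
    """

    pool_size: int
    min_count: int = 2
    min_cov: int = 3
    max_cov: int = 1000
    correction_mode: str = "naive"  # "naive" | "pool_corrected"

    def __post_init__(self):
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")
        if self.min_cov < self.min_count:
            raise ConfigurationError("min_cov must be >= min_count")
        if self.pool_size < 2:
            raise ConfigurationError("pool_size must be >= 2")
        if self.correction_mode not in ("naive", "pool_corrected"):
            raise ConfigurationError(
                f"unknown correction_mode {self.correction_mode!r}"
            )


# ---------------------------------------------------------------------------
# pileup parsing
# ---------------------------------------------------------------------------

def _decode_read_bases(bases: str, quals: str, ref: str, min_qual: int,
                       path: str | None, lineno: int | None) -> dict:
    """Decode one pileup read-base column into filtered allele counts."""
    thresh = chr(min_qual + 33)
    counts = dict.fromkeys(BASES, 0)

    # fast path 1: all reference matches
    if set(bases) <= {".", ","}:
        if len(bases) != len(quals):
            raise ParseError("read-base/quality length mismatch", path, lineno)
        counts[ref] = sum(1 for q in quals if q >= thresh)
        return counts

    # fast path 2: plain bases, no indel/caret grammar
    if set(bases) <= _PLAIN:
        if len(bases) != len(quals):
            raise ParseError("read-base/quality length mismatch", path, lineno)
        for ch, q in zip(bases, quals):
            if q < thresh:
                continue
            counts[ref if ch in ".," else ch.upper()] += 1
        return counts

    # full grammar
    i = qi = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":  # start-of-read marker, next char is mapping quality
            i += 2
            continue
        if ch == "$":  # end-of-read marker
            i += 1
            continue
        if ch in "+-":  # indel: sign, length, then that many sequence chars
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"indel without length at column {i}", path, lineno)
            i = j + int(bases[i + 1:j])
            continue
        if qi >= len(quals):
            raise ParseError("read-base/quality length mismatch", path, lineno)
        q = quals[qi]
        qi += 1
        if ch in ".,":
            base = ref
        elif ch in "ACGTacgt":
            base = ch.upper()
        elif ch in "*Nn<>":
            base = None  # deletion placeholder / skip / ambiguous: never counted
        else:
            raise ParseError(f"unknown pileup symbol {ch!r}", path, lineno)
        if base is not None and q >= thresh:
            counts[base] += 1
        i += 1
    if qi != len(quals):
        raise ParseError("read-base/quality length mismatch", path, lineno)
    return counts


def parse_pileup(path: str | Path, min_qual: int = 20) -> Iterator[AlleleCountRecord]:
    """Stream allele-count records from a 6-column SAMtools pileup.

    Base qualities are phred+33; bases below ``min_qual`` are dropped.
    Records whose reference base is not one of A/C/G/T are skipped with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected 6 pileup columns, got {len(fields)}", str(path), lineno
                )
            chrom, pos_s, ref, _depth, bases, quals = fields[:6]
            ref = ref.upper()
            if ref not in BASES:
                logger.warning("%s:%d: reference base %r not in ACGT; record skipped",
                               path, lineno, ref)
                continue
            counts = _decode_read_bases(bases, quals, ref, min_qual,
                                        str(path), lineno)
            yield AlleleCountRecord(chrom, int(pos_s), counts, ref)


def pileup_to_table(path: str | Path, min_qual: int = 20) -> pd.DataFrame:
    """Parse a pileup into a DataFrame indexed by (chrom, pos) with columns
    A, C, G, T (filtered counts) and ref."""
    rows = [
        (r.chrom, r.pos, r.ref, r.counts["A"], r.counts["C"], r.counts["G"],
         r.counts["T"])
        for r in parse_pileup(path, min_qual)
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", *BASES])
    return df.set_index(["chrom", "pos"])


def records_to_table(records: Iterable[AlleleCountRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.ref, r.counts["A"], r.counts["C"], r.counts["G"],
         r.counts["T"])
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", *BASES])
    return df.set_index(["chrom", "pos"])


def _as_table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_table(records)


# ---------------------------------------------------------------------------
# harmonic numbers and Tajima constants
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _harmonic_table(n_max: int) -> np.ndarray:
    """h[m] = sum_{i=1}^{m} 1/i, h[0] = 0."""
    h = np.zeros(n_max + 1)
    h[1:] = np.cumsum(1.0 / np.arange(1, n_max + 1))
    return h


def a1(m: int) -> float:
    """Harmonic number sum_{i=1}^{m-1} 1/i."""
    return float(_harmonic_table(max(m, 2))[m - 1])


def tajima_constants(n: int) -> dict:
    """Classical constants a1..e2 of Tajima's D for sample size n."""
    if n < 2:
        raise ConfigurationError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1_ = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1_
    c2 = b2 - (n + 2) / (a1_ * n) + a2 / a1_**2
    e1 = c1 / a1_
    e2 = c2 / (a1_**2 + a2)
    return {"a1": a1_, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, s_total: int, n_eff: int,
              n_sites: int | None = None) -> float:
    """Tajima's D from a label's summed pairwise diversity and segregating
    site count, at effective sample size ``n_eff``.

    Returns NaN when there are no segregating sites (statistic undefined).
    ``n_sites`` is accepted for interface symmetry but the statistic depends
    only on the sums.
    """
    if s_total < 0:
        raise ValidationError(f"negative segregating-site count {s_total}")
    if s_total == 0:
        return float("nan")
    c = tajima_constants(n_eff)
    var = c["e1"] * s_total + c["e2"] * s_total * (s_total - 1)
    return float((pi_sum - s_total / c["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def _filtered_counts(counts: Mapping[str, int], min_count: int) -> np.ndarray:
    c = np.array([counts.get(b, 0) for b in BASES], dtype=np.int64)
    c[c < min_count] = 0
    return c


def site_estimators(rec: AlleleCountRecord | Mapping[str, int],
                    params: EstimatorParams):
    """Per-site (pi, theta, S) for one allele-count record.

    Alleles below ``min_count`` reads are removed; the site is excluded
    (returns None) when the remaining coverage falls outside
    [min_cov, max_cov].
    """
    counts = rec.counts if isinstance(rec, AlleleCountRecord) else rec
    c = _filtered_counts(counts, params.min_count)
    m = int(c.sum())
    if m < params.min_cov or m > params.max_cov:
        return None
    f = c / m
    n_alleles = int((c > 0).sum())
    pi = (m / (m - 1)) * (1.0 - float(np.sum(f**2))) if m >= 2 else 0.0
    s = 1 if n_alleles >= 2 else 0
    theta = s / a1(m) if s else 0.0
    if params.correction_mode == "pool_corrected":
        pi /= pi_correction(m, params.pool_size, params.min_count)
        theta /= theta_correction(m, params.pool_size, params.min_count)
    return pi, theta, s


def _site_stats_arrays(counts: np.ndarray, params: EstimatorParams):
    """Vectorised per-site statistics.

    ``counts``: (n_sites, 4) integer array. Returns (pi, theta, S, covered)
    arrays; pi/theta/S are 0 for uncovered sites.
    """
    c = counts.astype(np.int64).copy()
    c[c < params.min_count] = 0
    m = c.sum(axis=1)
    covered = (m >= params.min_cov) & (m <= params.max_cov)
    m_safe = np.maximum(m, 2)
    f = c / m_safe[:, None]
    pi = (m_safe / (m_safe - 1.0)) * (1.0 - (f**2).sum(axis=1))
    pi[m < 2] = 0.0
    s = ((c > 0).sum(axis=1) >= 2).astype(np.int64)
    harm = _harmonic_table(int(params.max_cov) + 1)
    theta = np.where(s > 0, s / harm[np.minimum(m_safe, params.max_cov + 1) - 1], 0.0)
    if params.correction_mode == "pool_corrected":
        for mval in np.unique(m[covered]):
            mask = m == mval
            pi[mask] /= pi_correction(int(mval), params.pool_size, params.min_count)
            theta[mask] /= theta_correction(int(mval), params.pool_size,
                                            params.min_count)
    pi = np.where(covered, pi, 0.0)
    theta = np.where(covered, theta, 0.0)
    s = np.where(covered, s, 0)
    return pi, theta, s, covered


# ---------------------------------------------------------------------------
# pool correction by exhaustive enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _segregating_enumeration(m: int, n: int, b: int):
    """Expectations of the naive statistics for a segregating pool site.

    Model: derived-allele count k in 1..n-1 with neutral weight 1/k; reads
    binomial(M, k/n) at a biallelic site; min-count filter b applied. Returns
    (E[naive pi], E[naive theta], E[pool heterozygosity], E[theta truth])
    where pool heterozygosity is (n/(n-1)) * 2*(k/n)*(1-k/n) and the per-site
    Watterson contribution of a segregating site in a sample of n is 1/a1(n).
    """
    ks = np.arange(1, n)
    w = 1.0 / ks
    w /= w.sum()
    rs = np.arange(0, m + 1)
    params = EstimatorParams(pool_size=n, min_count=b, min_cov=b,
                             max_cov=10 * m + 10, correction_mode="naive")
    pis = np.empty(m + 1)
    thetas = np.empty(m + 1)
    for r in rs:
        est = site_estimators({"C": int(r), "T": int(m - r)}, params)
        pis[r], thetas[r] = (0.0, 0.0) if est is None else (est[0], est[1])
    e_pi = e_theta = 0.0
    for k, wk in zip(ks, w):
        pmf = stats.binom.pmf(rs, m, k / n)
        e_pi += wk * float(pmf @ pis)
        e_theta += wk * float(pmf @ thetas)
    h = (n / (n - 1.0)) * 2.0 * (ks / n) * (1.0 - ks / n)
    e_h = float(w @ h)
    e_theta_truth = 1.0 / a1(n)
    return e_pi, e_theta, e_h, e_theta_truth


def pi_correction(m: int, n: int, b: int) -> float:
    """Divisor that makes the naive per-site pi unbiased for the pool
    heterozygosity of a segregating site under the enumeration model."""
    e_pi, _, e_h, _ = _segregating_enumeration(m, n, b)
    return e_pi / e_h


def theta_correction(m: int, n: int, b: int) -> float:
    """Analogous divisor for the naive per-site Watterson theta."""
    _, e_theta, _, e_truth = _segregating_enumeration(m, n, b)
    return e_theta / e_truth


# ---------------------------------------------------------------------------
# aggregation over labels
# ---------------------------------------------------------------------------

def aggregate_diversity(
    records,
    site_labels: Mapping[tuple[str, int], str],
    params: EstimatorParams,
    min_covered_fraction: float = 0.60,
    population: str | None = None,
) -> pd.DataFrame:
    """Label-aggregated diversity estimates.

    ``records`` is a stream of :class:`AlleleCountRecord` or a table from
    :func:`pileup_to_table`. Each labeled site contributes its per-site
    statistics when covered; ``pi`` and ``theta_w`` are per-covered-site
    averages; Tajima's D is computed from the label's sums at an effective
    sample size ``min(pool_size, median covered-site coverage)``. Labels
    whose covered fraction falls below ``min_covered_fraction`` are flagged.
    """
    table = _as_table(records)
    labels = pd.Series(site_labels)
    labels.index.names = ["chrom", "pos"]

    counts = table.reindex(labels.index)[list(BASES)].fillna(0).to_numpy()
    pi, theta, s, covered = _site_stats_arrays(counts, params)
    df = pd.DataFrame({
        "label": labels.to_numpy(),
        "pi": pi, "theta": theta, "s": s, "covered": covered,
        "coverage": counts.sum(axis=1),
    }, index=labels.index)

    out_rows = []
    for label, grp in df.groupby("label", sort=True):
        n_sites = len(grp)
        cov_grp = grp[grp.covered]
        n_covered = len(cov_grp)
        frac = n_covered / n_sites if n_sites else 0.0
        if n_covered == 0:
            out_rows.append((label, np.nan, np.nan, np.nan, 0, n_sites, 0.0, True))
            continue
        pi_sum = float(cov_grp.pi.sum())
        theta_sum = float(cov_grp.theta.sum())
        s_total = int(cov_grp.s.sum())
        n_eff = int(min(params.pool_size, np.median(cov_grp.coverage)))
        d = tajimas_d(pi_sum, s_total, max(n_eff, 2)) if s_total > 0 else np.nan
        out_rows.append((
            label, pi_sum / n_covered, theta_sum / n_covered, d,
            n_covered, n_sites, frac, frac < min_covered_fraction,
        ))
    out = pd.DataFrame(
        out_rows,
        columns=["label", "pi", "theta_w", "tajimas_d", "n_covered", "n_sites",
                 "covered_fraction", "flagged"],
    ).set_index("label")
    if population is not None:
        out.insert(0, "population", population)
    return out


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _pairwise_fst_sites(t1: pd.DataFrame, t2: pd.DataFrame,
                        params1: EstimatorParams, params2: EstimatorParams,
                        min_count_mode: str = "summed") -> pd.Series:
    """Per-site Fst for sites covered (post-filter) in both pools."""
    if min_count_mode not in ("summed", "per_pool"):
        raise ConfigurationError(f"unknown min_count_mode {min_count_mode!r}")
    common = t1.index.intersection(t2.index)
    c1 = t1.reindex(common)[list(BASES)].to_numpy(dtype=np.int64)
    c2 = t2.reindex(common)[list(BASES)].to_numpy(dtype=np.int64)
    if min_count_mode == "summed":
        # the min-count filter is applied to counts summed across pools
        tot = c1 + c2
        drop = tot < params1.min_count
        c1 = np.where(drop, 0, c1)
        c2 = np.where(drop, 0, c2)
    else:
        c1 = np.where(c1 < params1.min_count, 0, c1)
        c2 = np.where(c2 < params2.min_count, 0, c2)
    m1 = c1.sum(axis=1)
    m2 = c2.sum(axis=1)
    ok = ((m1 >= max(params1.min_cov, 2)) & (m1 <= params1.max_cov)
          & (m2 >= max(params2.min_cov, 2)) & (m2 <= params2.max_cov))
    m1s = np.maximum(m1, 2)
    m2s = np.maximum(m2, 2)
    f1 = c1 / m1s[:, None]
    f2 = c2 / m2s[:, None]
    h1 = (m1s / (m1s - 1.0)) * (1.0 - (f1**2).sum(axis=1))
    h2 = (m2s / (m2s - 1.0)) * (1.0 - (f2**2).sum(axis=1))
    fbar = 0.5 * (f1 + f2)
    mt = m1s + m2s
    ht = (mt / (mt - 1.0)) * (1.0 - (fbar**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (ht - 0.5 * (h1 + h2)) / ht
    fst = np.where(ok & (ht > 0), fst, np.nan)
    return pd.Series(fst, index=common, name="fst")


def pairwise_fst(
    recs1, recs2,
    site_labels: Mapping[tuple[str, int], str],
    params1: EstimatorParams,
    params2: EstimatorParams | None = None,
    min_count_mode: str = "summed",
    clamp: bool = False,
) -> pd.DataFrame:
    """Label-level pairwise Fst between two pools.

    Per site, Fst = (h_T - (h_1 + h_2)/2) / h_T with the small-sample factor
    M/(M-1) in each heterozygosity and total heterozygosity computed from
    mean allele frequencies; sites where h_T = 0 or covered in only one pool
    are skipped. The label value is the mean of defined per-site values;
    negative per-site values are retained so label means are unbiased
    (``clamp=True`` floors the label means at 0 for display).
    """
    params2 = params2 or params1
    t1, t2 = _as_table(recs1), _as_table(recs2)
    per_site = _pairwise_fst_sites(t1, t2, params1, params2, min_count_mode)
    labels = pd.Series(site_labels)
    labels.index.names = ["chrom", "pos"]
    df = pd.DataFrame({"label": labels, "fst": per_site.reindex(labels.index)})
    grouped = df.groupby("label")["fst"].agg(["mean", "count"])
    out = grouped.rename(columns={"mean": "fst", "count": "n_sites"})
    if clamp:
        out["fst"] = out["fst"].clip(lower=0.0)
    return out


def windowed_fst(recs1, recs2, params1: EstimatorParams,
                 params2: EstimatorParams | None = None,
                 window_size: int = 1_000_000, step_size: int = 1_000_000,
                 min_count_mode: str = "summed") -> pd.DataFrame:
    """Fst in sliding genomic windows (defaults: non-overlapping 1 Mb)."""
    params2 = params2 or params1
    t1, t2 = _as_table(recs1), _as_table(recs2)
    per_site = _pairwise_fst_sites(t1, t2, params1, params2, min_count_mode)
    rows = []
    chroms = per_site.index.get_level_values(0)
    positions = per_site.index.get_level_values(1).to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos = positions[sel]
        vals = per_site.to_numpy()[sel]
        if len(pos) == 0:
            continue
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_size - 1
            in_win = (pos >= start) & (pos <= end)
            v = vals[in_win]
            v = v[~np.isnan(v)]
            if len(v):
                rows.append((chrom, start, end, float(v.mean()), len(v)))
            start += step_size
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])


# ---------------------------------------------------------------------------
# biallelic SNP typing at CpG sites
# ---------------------------------------------------------------------------

def call_biallelic_snps(records, sites: Iterable[tuple[str, int]],
                        min_count: int = 2) -> pd.DataFrame:
    """Detect biallelic SNPs at the listed sites by count thresholding.

    Alleles with at least ``min_count`` reads are retained; a site yields a
    record iff exactly two alleles remain. ``snp_type`` is ``CT_GA`` when
    the unordered allele pair is {C,T} or {G,A}, else ``other``.
    """
    table = _as_table(records)
    sites = set(sites)
    idx = [s for s in table.index if s in sites]
    sub = table.loc[idx, list(BASES)] if idx else table.iloc[:0][list(BASES)]
    rows = []
    for (chrom, pos), counts in sub.iterrows():
        kept = counts[counts >= min_count]
        if len(kept) != 2:
            continue
        kept = kept.sort_values(ascending=False)
        major, minor = kept.index[0], kept.index[1]
        pair = {major, minor}
        snp_type = "CT_GA" if pair in _CT_GA_PAIRS else "other"
        rows.append((chrom, pos, major, minor, snp_type))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "major_allele", "minor_allele", "snp_type"]
    ).set_index(["chrom", "pos"])


def snp_type_percentages(snps: pd.DataFrame,
                         site_labels: Mapping[tuple[str, int], str],
                         all_sites: Mapping[str, int]) -> pd.DataFrame:
    """Percentage of labeled sites harboring each SNP type.

    ``all_sites`` maps label -> total labeled site count (the denominator:
    all labeled sites, polymorphic or not). Returns per-label columns
    ``pct_ctga`` and ``pct_other``.
    """
    labels = pd.Series(site_labels)
    labels.index.names = ["chrom", "pos"]
    rows = []
    snp_labels = labels.reindex(snps.index) if len(snps) else pd.Series(dtype=object)
    for label, total in all_sites.items():
        if total == 0:
            continue
        in_label = snps[snp_labels == label] if len(snps) else snps
        n_ctga = int((in_label["snp_type"] == "CT_GA").sum()) if len(in_label) else 0
        n_other = int((in_label["snp_type"] == "other").sum()) if len(in_label) else 0
        rows.append((label, 100.0 * n_ctga / total, 100.0 * n_other / total, total))
    return pd.DataFrame(
        rows, columns=["label", "pct_ctga", "pct_other", "n_sites"]
    ).set_index("label")
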