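"""Synthetic ground truth, RRBS coverage files, and pool pileups.

The generator emulates the statistical structure the analysis assumes — a
marine (ancestral) and a freshwater (derived, bottlenecked) stickleback
population observed through two instruments:

* RRBS: 11 gill samples (3 marine native, 3 freshwater native, 3 marine
  transplanted to low salinity, 2 freshwater transplanted to high
  salinity), each a Bismark-style coverage file of per-CpG
  methylated/unmethylated counts;
* pool-seq: one pileup per population (pools of 24 and 20 haploid genomes
  at mean depths 10.4x and 8x).

Per-site truth is drawn from configured class models: non-DMCs have a
bimodal methylation-frequency distribution (sites mostly near 0% or 100%
methylated) identical in both populations; freshwater-hypomethylated sites
shift from high methylation in marine to intermediate in freshwater;
freshwater-hypermethylated sites shift from low-intermediate to high. A
configurable fraction of sites per class is environmentally inducible
(methylation shifts in transplanted fish, direction random). Polymorphism
probability is class-dependent and C-T/G-A-enriched, with a bottleneck
factor shrinking it in freshwater. No genealogies are simulated: the
analysis under test consumes allele frequencies, so frequencies are drawn
directly and the truth is exact.

A single integer seed governs everything through named substreams, so the
truth table and each emitter are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .meth_io import SampleMeta

CLASSES = ("non_DMC", "hypo", "hyper")

#: RRBS design: (sample-count, population, treatment); one treated freshwater
#: sample fewer, mirroring the exclusion of a low-conversion sample.
DEFAULT_RRBS_DESIGN = (
    (3, "marine", "native"),
    (3, "freshwater", "native"),
    (3, "marine", "transplanted"),
    (2, "freshwater", "transplanted"),
)


def _default_chroms() -> dict:
    return {f"chr{i}": 25_000_000 for i in
            ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")}


def _default_n_sites() -> dict:
    # average per-chromosome class sizes of the real data times 10 chromosomes
    return {"non_DMC": 49_790, "hypo": 45_660, "hyper": 7_250}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Methylation fractions are on [0, 1]; the emitted files use percentages.
    ``meth_sd`` is the between-individual standard deviation of per-sample
    methylation, per class as (marine, freshwater). ``p_polymorphic`` is the
    marine per-class probability that a CpG site segregates; freshwater
    probabilities are scaled by ``bottleneck_factor`` (< 1: the derived
    population lost diversity). ``induced_fraction`` is per class as
    (marine, freshwater); induced sites shift methylation by a magnitude in
    ``induced_shift_range`` (random direction) in transplanted fish.
    """

    n_sites: Mapping[str, int] = field(default_factory=_default_n_sites)
    chroms: Mapping[str, int] = field(default_factory=_default_chroms)
    pool_haploids: Mapping[str, int] = field(
        default_factory=lambda: {"marine": 24, "freshwater": 20})
    pool_depth: Mapping[str, float] = field(
        default_factory=lambda: {"marine": 10.4, "freshwater": 8.0})
    rrbs_design: tuple = DEFAULT_RRBS_DESIGN
    rrbs_depth_mean: float = 15.0
    rrbs_min_cov_floor: int = 5  # 0 disables flooring

    # methylation model
    nondmc_beta: tuple = ((1.5, 12.0), (12.0, 1.5))  # bimodal mixture components
    nondmc_weights: tuple = (0.5, 0.5)
    hypo_marine_beta: tuple = (12.0, 3.0)
    hypo_marine_min: float = 0.35
    hyper_marine_beta: tuple = (3.0, 9.0)
    hyper_marine_max: float = 0.55
    dmc_delta_range: tuple = (0.25, 0.45)
    meth_sd: Mapping[str, tuple] = field(default_factory=lambda: {
        "non_DMC": (0.03, 0.04), "hypo": (0.05, 0.12), "hyper": (0.10, 0.05)})

    # inducibility model
    induced_fraction: Mapping[str, tuple] = field(default_factory=lambda: {
        "non_DMC": (0.02, 0.02), "hypo": (0.04, 0.08), "hyper": (0.28, 0.18)})
    induced_shift_range: tuple = (0.25, 0.40)

    # polymorphism model
    p_polymorphic: Mapping[str, float] = field(default_factory=lambda: {
        "non_DMC": 0.05, "hypo": 0.15, "hyper": 0.25})
    # environmentally inducible sites carry more standing variation: at a
    # site induced in a population, the polymorphism probability is scaled
    # by 1 + coupling * |shift| / max_shift (0 disables the coupling)
    induced_poly_coupling: float = 2.0
    bottleneck_factor: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    ct_ga_share: Mapping[str, float] = field(
        default_factory=lambda: {"marine": 0.90, "freshwater": 0.94})

    # RRBS SNP mask: extra fraction of sites carrying C-T SNPs in RRBS fish
    rrbs_snp_fraction: float = 0.02
    # RRBS enriches CpG-dense regions: sites come in clusters of
    # ``cluster_size`` with within-cluster spacing drawn from
    # ``intra_cluster_spacing`` (bp), clusters spread over the chromosome
    cluster_size: int = 25
    intra_cluster_spacing: tuple = (50, 300)
    flanks_per_site: int = 1
    pileup_qual_char: str = "I"  # phred 40, above any sensible filter

    seed: int = 0

    def __post_init__(self):
        for cls in CLASSES:
            if self.n_sites.get(cls, 0) < 0:
                raise ConfigurationError(f"negative site count for {cls}")
        for p in self.p_polymorphic.values():
            if not 0 <= p <= 1:
                raise ConfigurationError("polymorphism probabilities must be in [0,1]")
        if not 0 < self.bottleneck_factor <= 1.5:
            raise ConfigurationError("bottleneck_factor out of range")
        for d in self.pool_depth.values():
            if d <= 0:
                raise ConfigurationError("pool depths must be positive")

    @property
    def samples(self) -> list[SampleMeta]:
        out = []
        for count, pop, treatment in self.rrbs_design:
            short = "fw" if pop == "freshwater" else pop
            for i in range(1, count + 1):
                out.append(SampleMeta(f"{short}_{treatment}_{i}", pop, treatment))
        return out


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _place_sites(config: SimConfig, n_total: int, rng: np.random.Generator):
    """CpG-island-like site placement: clusters of densely spaced sites.

    Clusters are spread evenly (with jitter) along each chromosome;
    within a cluster, consecutive sites are tens to hundreds of bp apart,
    emulating the CpG-dense regions RRBS enriches for.
    """
    chroms = list(config.chroms)
    lengths = np.array([config.chroms[c] for c in chroms], dtype=float)
    alloc = np.floor(n_total * lengths / lengths.sum()).astype(int)
    alloc[0] += n_total - alloc.sum()
    lo, hi = config.intra_cluster_spacing
    max_span = config.cluster_size * hi
    chrom_col, pos_col = [], []
    for chrom, length, n in zip(chroms, lengths, alloc):
        n = int(n)
        if n == 0:
            continue
        n_clusters = max(1, -(-n // config.cluster_size))
        stride = int(length) // n_clusters
        if stride <= max_span:
            raise ConfigurationError(
                f"{chrom}: {n} sites exceed chromosome capacity at "
                f"length {int(length)}"
            )
        starts = (stride // 4
                  + stride * np.arange(n_clusters)
                  + rng.integers(0, stride // 4 + 1, size=n_clusters))
        sizes = np.full(n_clusters, config.cluster_size)
        sizes[-1] = n - config.cluster_size * (n_clusters - 1)
        positions = []
        for start, size in zip(starts, sizes):
            gaps = rng.integers(lo, hi + 1, size=int(size))
            positions.append(start + np.cumsum(gaps))
        chrom_col += [chrom] * n
        pos_col.append(np.concatenate(positions))
    return np.array(chrom_col), np.concatenate(pos_col).astype(np.int64)


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the per-site ground truth table.

    Indexed by (chrom, pos); one row per CpG site with its class, native
    methylation fraction per population, inducibility flags and signed
    induced shifts, per-population polymorphism state (alternate-allele
    population frequency and SNP type; reference base is C), and the RRBS
    SNP-mask flag. Reproducible from ``config.seed``.
    """
    rng = _rng(config, 1)
    counts = {cls: int(config.n_sites.get(cls, 0)) for cls in CLASSES}
    n_total = sum(counts.values())
    if n_total == 0:
        raise ConfigurationError("no sites configured")
    chrom_col, pos_col = _place_sites(config, n_total, rng)

    classes = np.concatenate([np.repeat(c, n) for c, n in counts.items()])
    rng.shuffle(classes)

    pm_marine = np.empty(n_total)
    pm_fw = np.empty(n_total)

    sel = classes == "non_DMC"
    n = int(sel.sum())
    if n:
        comp = rng.choice(len(config.nondmc_weights), size=n,
                          p=np.asarray(config.nondmc_weights))
        draws = np.empty(n)
        for ci, (a, b) in enumerate(config.nondmc_beta):
            m = comp == ci
            draws[m] = rng.beta(a, b, size=int(m.sum()))
        pm_marine[sel] = draws
        pm_fw[sel] = draws  # non-DMCs: no population difference

    sel = classes == "hypo"
    n = int(sel.sum())
    if n:
        a, b = config.hypo_marine_beta
        m = config.hypo_marine_min + (1 - config.hypo_marine_min) * rng.beta(a, b, n)
        delta = rng.uniform(*config.dmc_delta_range, size=n)
        pm_marine[sel] = m
        pm_fw[sel] = np.clip(m - delta, 0.0, 1.0)

    sel = classes == "hyper"
    n = int(sel.sum())
    if n:
        a, b = config.hyper_marine_beta
        m = config.hyper_marine_max * rng.beta(a, b, n)
        delta = rng.uniform(*config.dmc_delta_range, size=n)
        pm_marine[sel] = m
        pm_fw[sel] = np.clip(m + delta, 0.0, 1.0)

    induced = {}
    shift = {}
    for pop_i, pop in enumerate(("marine", "freshwater")):
        frac = np.array([config.induced_fraction[c][pop_i] for c in classes])
        ind = rng.random(n_total) < frac
        mag = rng.uniform(*config.induced_shift_range, size=n_total)
        sign = rng.choice([-1.0, 1.0], size=n_total)
        induced[pop] = ind
        shift[pop] = np.where(ind, sign * mag, 0.0)

    poly, freq, alt, snp_type = {}, {}, {}, {}
    max_shift = max(abs(config.induced_shift_range[0]),
                    abs(config.induced_shift_range[1]))
    for pop in ("marine", "freshwater"):
        p_base = np.array([config.p_polymorphic[c] for c in classes])
        if pop == "freshwater":
            p_base = p_base * config.bottleneck_factor
        if config.induced_poly_coupling > 0 and max_shift > 0:
            boost = (1.0 + config.induced_poly_coupling
                     * np.abs(shift[pop]) / max_shift)
            p_base = np.minimum(p_base * boost, 1.0)
        is_poly = rng.random(n_total) < p_base
        f = np.where(is_poly, rng.uniform(*config.maf_range, size=n_total), 0.0)
        is_ct = rng.random(n_total) < config.ct_ga_share[pop]
        alt_base = np.where(is_ct, "T", rng.choice(["A", "G"], size=n_total))
        poly[pop] = is_poly
        freq[pop] = f
        alt[pop] = np.where(is_poly, alt_base, "")
        snp_type[pop] = np.where(is_poly, np.where(is_ct, "CT_GA", "other"), "")

    masked = rng.random(n_total) < config.rrbs_snp_fraction

    truth = pd.DataFrame({
        "chrom": chrom_col, "pos": pos_col, "site_class": classes,
        "ref": "C",
        "pm_marine": pm_marine, "pm_fw": pm_fw,
        "induced_marine": induced["marine"], "induced_fw": induced["freshwater"],
        "shift_marine": shift["marine"], "shift_fw": shift["freshwater"],
        "poly_marine": poly["marine"], "freq_marine": freq["marine"],
        "alt_marine": alt["marine"], "snp_type_marine": snp_type["marine"],
        "poly_fw": poly["freshwater"], "freq_fw": freq["freshwater"],
        "alt_fw": alt["freshwater"], "snp_type_fw": snp_type["freshwater"],
        "masked": masked,
    }).set_index(["chrom", "pos"]).sort_index()
    return truth


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def emit_rrbs(truth: pd.DataFrame, config: SimConfig,
              outdir: str | Path) -> dict[str, Path]:
    """Write one Bismark-format coverage file per RRBS sample.

    Per site and sample: coverage ~ Poisson(depth mean), floored at the
    configured minimum; methylated count ~ Binomial(coverage, individual
    methylation), where the individual value is the population value plus
    between-individual noise (class-specific SD) and, for transplanted fish
    at sites inducible in their population, the signed induced shift.
    Returns {sample_id: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    n = len(truth)
    classes = truth["site_class"].to_numpy()
    sd_idx = {"marine": 0, "freshwater": 1}
    paths: dict[str, Path] = {}
    chrom = truth.index.get_level_values(0)
    pos = truth.index.get_level_values(1)

    for meta in config.samples:
        pop_short = "marine" if meta.population == "marine" else "fw"
        pm = truth[f"pm_{pop_short}"].to_numpy().copy()
        if meta.treatment == "transplanted":
            pm = pm + truth[f"shift_{pop_short}"].to_numpy()
        sd = np.array([config.meth_sd[c][sd_idx[meta.population]] for c in classes])
        pm_i = np.clip(pm + rng.normal(0.0, 1.0, n) * sd, 0.0, 1.0)
        cov = rng.poisson(config.rrbs_depth_mean, n)
        if config.rrbs_min_cov_floor > 0:
            cov = np.maximum(cov, config.rrbs_min_cov_floor)
        meth = rng.binomial(cov, pm_i)
        unmeth = cov - meth
        pct = np.where(cov > 0, 100.0 * meth / np.maximum(cov, 1), 0.0)
        df = pd.DataFrame({
            "chrom": chrom, "start": pos, "end": pos,
            "pct": np.round(pct, 6), "meth": meth, "unmeth": unmeth,
        })
        path = outdir / f"{meta.sample_id}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[meta.sample_id] = path
    return paths


def emit_poolseq(truth: pd.DataFrame, config: SimConfig,
                 outdir: str | Path) -> dict[str, Path]:
    """Write one SAMtools-style pileup per population pool.

    Two-stage sampling per polymorphic site: the realized alternate-allele
    count among the pool's n haploid genomes is binomial(n, population
    frequency); reads are then binomial draws over pool haplotypes at depth
    ~ Poisson(mean depth). One monomorphic flanking position per site (at
    the next base) exercises windowed statistics. Zero-depth positions are
    omitted, as in real pileups. Base qualities are emitted above any
    sensible quality filter. Returns {population: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 3)
    n = len(truth)
    chrom = truth.index.get_level_values(0).to_numpy()
    pos = truth.index.get_level_values(1).to_numpy()
    qual = config.pileup_qual_char
    paths: dict[str, Path] = {}

    for pop, short in (("marine", "marine"), ("freshwater", "fw")):
        n_hap = int(config.pool_haploids[pop])
        depth = rng.poisson(config.pool_depth[pop], n)
        freq = truth[f"freq_{short}"].to_numpy()
        alt = truth[f"alt_{short}"].to_numpy()
        k = rng.binomial(n_hap, freq)
        alt_reads = rng.binomial(depth, k / n_hap)
        ref_reads = depth - alt_reads

        lines: list[tuple[str, int, str]] = []
        for i in range(n):
            d = int(depth[i])
            if d == 0:
                continue
            bases = "." * int(ref_reads[i]) + (alt[i] or "T") * int(alt_reads[i])
            lines.append((chrom[i], int(pos[i]),
                          f"C\t{d}\t{bases}\t{qual * d}"))
        if config.flanks_per_site > 0:
            flank_depth = rng.poisson(config.pool_depth[pop],
                                      (config.flanks_per_site, n))
            flank_ref = rng.choice(list("ACGT"), size=(config.flanks_per_site, n))
            for j in range(config.flanks_per_site):
                for i in range(n):
                    d = int(flank_depth[j, i])
                    if d == 0:
                        continue
                    lines.append((chrom[i], int(pos[i]) + j + 1,
                                  f"{flank_ref[j, i]}\t{d}\t{'.' * d}\t{qual * d}"))
        lines.sort(key=lambda t: (t[0], t[1]))
        path = outdir / f"{short}.pileup"
        with open(path, "w") as fh:
            for c, p, rest in lines:
                fh.write(f"{c}\t{p}\t{rest}\n")
        paths[pop] = path
    return paths


def write_snp_mask(truth: pd.DataFrame, path: str | Path) -> Path:
    """Write the RRBS SNP mask (2-column chrom/pos TSV) from the truth."""
    path = Path(path)
    masked = truth[truth["masked"]]
    with open(path, "w") as fh:
        for chrom, pos in masked.index:
            fh.write(f"{chrom}\t{pos}\n")
    return path


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.reset_index().to_csv(path, sep="\t", index=False)
    return path


def generate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate truth and emit every input the pipeline consumes.

    Returns a manifest dict with the truth table, coverage-file paths,
    pileup paths, mask path and sample metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    rrbs_paths = emit_rrbs(truth, config, outdir / "rrbs")
    pool_paths = emit_poolseq(truth, config, outdir / "poolseq")
    mask_path = write_snp_mask(truth, outdir / "snp_mask.tsv")
    truth_path = write_truth(truth, outdir / "truth.tsv")
    return {
        "truth": truth, "truth_path": truth_path,
        "rrbs": rrbs_paths, "poolseq": pool_paths,
        "snp_mask": mask_path, "samples": config.samples,
    }
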