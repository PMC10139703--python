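"""End-to-end orchestration: filtering -> DM -> matching -> diversity -> stats.

Stage order mirrors the analysis workflow: build the filtered methylation
site matrix; run the three differential-methylation comparisons (population,
marine salinity treatment, freshwater salinity treatment) and classify
inducibility; subsample distance-matched non-DMCs; label sites by
chromosome x category; estimate per-label diversity, Fst and SNP-type
percentages from the pool pileups; build rank profiles; and run the paired
statistical comparisons and trend fits into a markdown report.

Every stage writes its output as TSV into the run directory, so any stage
can be re-run from saved intermediates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .meth_io import (DEFAULT_EXCLUDED_CHROMS, MethSiteMatrix, SampleMeta,
                      build_site_matrix, read_bismark_coverage, read_snp_mask)
from .dm_classify import (classify_inducibility, classify_sites,
                          methylation_summary, test_dm)
from .pool_diversity import (EstimatorParams, aggregate_diversity,
                             call_biallelic_snps, pairwise_fst,
                             pileup_to_table, snp_type_percentages)
from .rank_profile import assign_ranks, rank_diversity
from .site_match import subsample_non_dmcs
from .stats_report import (fit_linear_trend, markdown_report, paired_compare,
                           comparisons_table, trends_table)
from .synth_data import SimConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their conventional defaults."""

    # inputs (real-data mode); ignored when `sim` is set
    coverage_files: dict = field(default_factory=dict)  # sample_id -> path
    sample_meta: list = field(default_factory=list)  # list of SampleMeta/dicts
    pileup_marine: str | None = None
    pileup_fw: str | None = None
    snp_mask: str | None = None

    # synthetic mode
    sim: SimConfig | None = None

    # thresholds
    dm_threshold: float = 15.0
    alpha: float = 0.05
    min_cov_rrbs: int = 5
    min_qual: int = 20
    min_cov_pool: int = 3
    min_count: int = 2
    max_cov: int = 1000
    match_window: int = 2000
    n_ranks: int = 50
    covered_fraction_floor: float = 0.60
    excluded_chroms: tuple = tuple(sorted(DEFAULT_EXCLUDED_CHROMS))
    pool_haploids_marine: int = 24
    pool_haploids_fw: int = 20
    correction_mode: str = "naive"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.dm_threshold <= 100):
            raise ConfigurationError(
                f"dm_threshold must be in (0, 100], got {self.dm_threshold}")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.min_cov_rrbs < 1 or self.min_cov_pool < self.min_count:
            raise ConfigurationError("coverage thresholds out of domain")
        if self.match_window <= 0 or self.n_ranks < 2:
            raise ConfigurationError("match_window/n_ranks out of domain")
        if not (0 <= self.covered_fraction_floor <= 1):
            raise ConfigurationError("covered_fraction_floor must be in [0, 1]")
        self.sample_meta = [
            m if isinstance(m, SampleMeta) else SampleMeta(**m)
            for m in self.sample_meta
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True, default_flow_style=None)

    def params_for(self, population: str) -> EstimatorParams:
        n = self.pool_haploids_marine if population == "marine" \
            else self.pool_haploids_fw
        return EstimatorParams(pool_size=n, min_count=self.min_count,
                               min_cov=self.min_cov_pool, max_cov=self.max_cov,
                               correction_mode=self.correction_mode)


def _save(df: pd.DataFrame, path: Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


class PipelineRun:
    """A single pipeline execution writing into ``outdir``."""

    def __init__(self, config: PipelineConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._stage = "init"
        handler = logging.FileHandler(self.outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("methdiv").addHandler(handler)
        self._log_handler = handler
        logger.info("methdiv %s, seed %d", __version__, config.seed)
        config.to_yaml(self.outdir / "config_used.yaml")

    # each public method is one CLI subcommand's worth of work ------------

    def simulate(self) -> dict:
        self._stage = "simulate"
        sim = self.config.sim or SimConfig(seed=self.config.seed)
        manifest = generate_dataset(sim, self.outdir / "data")
        logger.info("simulated %d sites on %d chromosomes",
                    len(manifest["truth"]), len(sim.chroms))
        self.config.coverage_files = {
            sid: str(p) for sid, p in manifest["rrbs"].items()}
        self.config.sample_meta = list(manifest["samples"])
        self.config.pileup_marine = str(manifest["poolseq"]["marine"])
        self.config.pileup_fw = str(manifest["poolseq"]["freshwater"])
        self.config.snp_mask = str(manifest["snp_mask"])
        return manifest

    def filter_sites(self) -> MethSiteMatrix:
        self._stage = "filter"
        cfg = self.config
        if not cfg.coverage_files:
            raise ConfigurationError("no coverage files configured")
        mask = read_snp_mask(cfg.snp_mask) if cfg.snp_mask else set()
        calls = {sid: read_bismark_coverage(p)
                 for sid, p in cfg.coverage_files.items()}
        native = [m.sample_id for m in cfg.sample_meta if m.treatment == "native"]
        matrix = build_site_matrix(
            calls, cfg.sample_meta, snp_mask=mask, min_cov=cfg.min_cov_rrbs,
            excluded_chroms=cfg.excluded_chroms, drop_invariant_over=native,
        )
        logger.info("filter: retained %d sites across %d samples "
                    "(mask size %d)", len(matrix), len(matrix.samples), len(mask))
        matrix.to_tsv(self.outdir / "site_matrix.tsv")
        self.matrix = matrix
        return matrix

    def dm(self) -> pd.DataFrame:
        self._stage = "dm"
        cfg, matrix = self.config, self.matrix
        g = matrix.sample_ids_for
        comparisons = {
            "population": (g("marine", "native"), g("freshwater", "native")),
            "marine_treatment": (g("marine", "native"), g("marine", "transplanted")),
            "fw_treatment": (g("freshwater", "native"),
                             g("freshwater", "transplanted")),
        }
        self.dm_results = {}
        for name, (ga, gb) in comparisons.items():
            if not ga or not gb:
                logger.warning("dm: comparison %s skipped (empty group)", name)
                continue
            res = classify_sites(test_dm(matrix, ga, gb),
                                 threshold=cfg.dm_threshold, alpha=cfg.alpha)
            self.dm_results[name] = res
            _save(res, self.outdir / f"dm_{name}.tsv")
            counts = res["site_class"].value_counts().to_dict()
            logger.info("dm %s: %s", name, counts)
        pop = self.dm_results["population"]
        if {"marine_treatment", "fw_treatment"} <= set(self.dm_results):
            self.inducibility = classify_inducibility(
                pop, self.dm_results["marine_treatment"],
                self.dm_results["fw_treatment"])
            _save(self.inducibility, self.outdir / "inducibility.tsv")
        else:
            self.inducibility = None
        return pop

    def match(self):
        self._stage = "match"
        pop = self.dm_results["population"]
        dmcs = set(pop.index[pop.site_class != "non_DMC"])
        non_dmcs = set(pop.index[pop.site_class == "non_DMC"])
        sub = subsample_non_dmcs(dmcs, non_dmcs, window=self.config.match_window,
                                 seed=self.config.seed)
        logger.info("match: %d DMCs -> %d matched non-DMCs",
                    len(dmcs), len(sub.selected))
        rows = [(d[0], d[1], "" if s is None else s[0],
                 np.nan if s is None else s[1])
                for d, s in sorted(sub.provenance.items())]
        pd.DataFrame(rows, columns=["dmc_chrom", "dmc_pos", "sel_chrom",
                                    "sel_pos"]).to_csv(
            self.outdir / "matched_non_dmcs.tsv", sep="\t", index=False)
        self.matched = sub
        return sub

    def build_labels(self) -> dict:
        """Site -> 'chrom|class' labels over DMCs plus matched non-DMCs."""
        self._stage = "labels"
        pop = self.dm_results["population"]
        labels = {}
        for (chrom, pos), cls in pop["site_class"].items():
            if cls != "non_DMC":
                labels[(chrom, pos)] = f"{chrom}|{cls}"
        for chrom, pos in self.matched.selected:
            labels[(chrom, pos)] = f"{chrom}|non_DMC"
        pd.DataFrame(
            [(c, p, l) for (c, p), l in sorted(labels.items())],
            columns=["chrom", "pos", "label"],
        ).to_csv(self.outdir / "site_labels.tsv", sep="\t", index=False)
        self.labels = labels
        return labels

    def load_pileups(self):
        self._stage = "pileups"
        cfg = self.config
        self.pool_tables = {
            "marine": pileup_to_table(cfg.pileup_marine, min_qual=cfg.min_qual),
            "freshwater": pileup_to_table(cfg.pileup_fw, min_qual=cfg.min_qual),
        }
        for pop, t in self.pool_tables.items():
            logger.info("pileup %s: %d positions", pop, len(t))
        return self.pool_tables

    def diversity(self) -> pd.DataFrame:
        self._stage = "diversity"
        cfg = self.config
        parts = []
        for pop in ("marine", "freshwater"):
            div = aggregate_diversity(
                self.pool_tables[pop], self.labels, cfg.params_for(pop),
                min_covered_fraction=cfg.covered_fraction_floor, population=pop)
            parts.append(div)
        self.div_table = pd.concat(parts)
        split = self.div_table.index.str.split("|", expand=True)
        self.div_table["chrom"] = split.get_level_values(0)
        self.div_table["site_class"] = split.get_level_values(1)
        _save(self.div_table, self.outdir / "diversity_by_category.tsv")
        return self.div_table

    def fst(self) -> pd.DataFrame:
        self._stage = "fst"
        cfg = self.config
        self.fst_table = pairwise_fst(
            self.pool_tables["marine"], self.pool_tables["freshwater"],
            self.labels, cfg.params_for("marine"), cfg.params_for("freshwater"))
        split = self.fst_table.index.str.split("|", expand=True)
        self.fst_table["chrom"] = split.get_level_values(0)
        self.fst_table["site_class"] = split.get_level_values(1)
        _save(self.fst_table, self.outdir / "fst_by_category.tsv")
        return self.fst_table

    def snps(self) -> pd.DataFrame:
        self._stage = "snps"
        cfg = self.config
        sites = set(self.labels)
        totals: dict[str, int] = {}
        for site, label in self.labels.items():
            totals[label] = totals.get(label, 0) + 1
        parts = []
        for pop in ("marine", "freshwater"):
            snps = call_biallelic_snps(self.pool_tables[pop], sites,
                                       min_count=cfg.min_count)
            pct = snp_type_percentages(snps, self.labels, totals)
            pct.insert(0, "population", pop)
            parts.append(pct)
        self.snp_table = pd.concat(parts)
        split = self.snp_table.index.str.split("|", expand=True)
        self.snp_table["chrom"] = split.get_level_values(0)
        self.snp_table["site_class"] = split.get_level_values(1)
        _save(self.snp_table, self.outdir / "snp_percentages.tsv")
        return self.snp_table

    def ranks(self) -> dict:
        """Rank profiles of pi against mean methylation and inducibility."""
        self._stage = "ranks"
        cfg = self.config
        matrix = self.matrix
        pop_dm = self.dm_results["population"]
        self.rank_tables: dict[str, pd.DataFrame] = {}

        summaries = {
            "marine": methylation_summary(matrix, matrix.sample_ids_for(
                "marine", "native")),
            "freshwater": methylation_summary(matrix, matrix.sample_ids_for(
                "freshwater", "native")),
        }
        labeled_sites = pd.MultiIndex.from_tuples(sorted(self.labels),
                                                  names=["chrom", "pos"])
        for pop in ("marine", "freshwater"):
            for cls in ("non_DMC", "hypo", "hyper"):
                cls_sites = [s for s in labeled_sites
                             if self.labels[s].endswith(f"|{cls}")]
                if len(cls_sites) < cfg.n_ranks * 2:
                    continue
                vals = summaries[pop]["mean_pm"].reindex(
                    pd.MultiIndex.from_tuples(cls_sites))
                try:
                    ranks = assign_ranks(vals, n_ranks=cfg.n_ranks)
                except ConfigurationError:
                    continue
                prof = rank_diversity(ranks, self.pool_tables[pop],
                                      cfg.params_for(pop),
                                      min_covered_fraction=cfg.covered_fraction_floor)
                key = f"mean_pm_{pop}_{cls}"
                self.rank_tables[key] = prof
                _save(prof, self.outdir / f"ranks_{key}.tsv")

        if self.inducibility is not None:
            for pop, short in (("marine", "marine"), ("freshwater", "fw")):
                ind = self.inducibility
                induced = ind[ind[f"induced_{short}"]]
                # only DMCs count as inducible sites for the rank profile
                dmc = pop_dm.index[pop_dm.site_class != "non_DMC"]
                induced = induced.loc[induced.index.intersection(dmc)]
                if len(induced) < cfg.n_ranks:
                    continue
                vals = induced[f"abs_induced_change_{short}"]
                try:
                    ranks = assign_ranks(vals, n_ranks=cfg.n_ranks)
                except ConfigurationError:
                    continue
                prof = rank_diversity(ranks, self.pool_tables[pop],
                                      cfg.params_for(pop),
                                      min_covered_fraction=cfg.covered_fraction_floor)
                key = f"inducibility_{pop}"
                self.rank_tables[key] = prof
                _save(prof, self.outdir / f"ranks_{key}.tsv")
        return self.rank_tables

    def stats(self):
        self._stage = "stats"
        comparisons, trends = [], []
        div = self.div_table

        def chrom_values(pop, cls, col):
            sel = div[(div.population == pop) & (div.site_class == cls)
                      & ~div.flagged]
            return sel.set_index("chrom")[col].dropna()

        for metric in ("pi", "theta_w", "tajimas_d"):
            for cls in ("non_DMC", "hypo", "hyper"):
                a = chrom_values("marine", cls, metric)
                b = chrom_values("freshwater", cls, metric)
                if min(len(a), len(b)) >= 3:
                    comparisons.append(paired_compare(
                        a, b, metric=f"{metric}[{cls}]",
                        group_a="marine", group_b="freshwater"))
        for pop in ("marine", "freshwater"):
            for cls in ("hypo", "hyper"):
                a = chrom_values(pop, "non_DMC", "pi")
                b = chrom_values(pop, cls, "pi")
                if min(len(a), len(b)) >= 3:
                    comparisons.append(paired_compare(
                        a, b, metric=f"pi[{pop}]", group_a="non_DMC",
                        group_b=cls))

        fst = self.fst_table
        for cls in ("hypo", "hyper"):
            a = fst[fst.site_class == "non_DMC"].set_index("chrom")["fst"].dropna()
            b = fst[fst.site_class == cls].set_index("chrom")["fst"].dropna()
            if min(len(a), len(b)) >= 3:
                comparisons.append(paired_compare(
                    a, b, metric="fst", group_a="non_DMC", group_b=cls))

        snp = self.snp_table
        for cls in ("non_DMC", "hypo", "hyper"):
            a = snp[(snp.population == "marine") & (snp.site_class == cls)
                    ].set_index("chrom")["pct_ctga"]
            b = snp[(snp.population == "freshwater") & (snp.site_class == cls)
                    ].set_index("chrom")["pct_ctga"]
            if min(len(a), len(b)) >= 3:
                comparisons.append(paired_compare(
                    a, b, metric=f"pct_ctga[{cls}]",
                    group_a="marine", group_b="freshwater"))

        for pop in ("marine", "freshwater"):
            key = f"inducibility_{pop}"
            if key in getattr(self, "rank_tables", {}):
                prof = self.rank_tables[key]
                ok = prof[~prof.excluded]
                if len(ok) >= 3:
                    trends.append(fit_linear_trend(
                        ok.mean_value, ok.pi,
                        response=f"pi[{pop}]",
                        predictor="abs_induced_change"))

        self.comparisons, self.trends = comparisons, trends
        comparisons_table(comparisons).to_csv(
            self.outdir / "comparisons.tsv", sep="\t", index=False)
        trends_table(trends).to_csv(self.outdir / "trends.tsv", sep="\t",
                                    index=False)
        (self.outdir / "report.md").write_text(
            markdown_report(comparisons, trends))
        return comparisons, trends

    def close(self):
        logging.getLogger("methdiv").removeHandler(self._log_handler)
        self._log_handler.close()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineRun:
    """Execute every stage in order; aborts naming the failing stage."""
    run = PipelineRun(config, outdir)
    try:
        if config.sim is not None or not config.coverage_files:
            run.simulate()
        run.filter_sites()
        run.dm()
        run.match()
        run.build_labels()
        run.load_pileups()
        run.diversity()
        run.fst()
        run.snps()
        run.ranks()
        run.stats()
    except Exception as exc:
        logger.error("stage %r failed: %s", run._stage, exc)
        raise RuntimeError(f"pipeline stage {run._stage!r} failed: {exc}") from exc
    finally:
        run.close()
    return run
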