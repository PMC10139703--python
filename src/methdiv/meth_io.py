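"""Reading and filtering of per-CpG methylation count data.

Consumes Bismark-style coverage files (one per sample; tab-separated
``chrom, start, end, percent_methylated, count_methylated, count_unmethylated``
with 1-based inclusive coordinates) and assembles a unified multi-sample site
matrix after applying the study's site filters:

* minimum coverage in *every* sample,
* exclusion of configured chromosomes (mitochondrial and sex chromosomes),
* removal of sites in a SNP mask (sites carrying C-T/G-A polymorphisms in the
  bisulfite-sequenced individuals, which would otherwise inflate unmethylated
  counts),
* removal of sites with no methylation variation (uniformly 0% or 100%)
  across a designated set of comparison samples.

The percent column of the coverage file is advisory only; methylation levels
are always recomputed from the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

#: Chromosomes dropped by default: mitochondrial plus the two sex chromosomes.
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrM", "chrXIX", "chrY"})

#: Default minimum per-sample coverage for a site to be retained.
DEFAULT_MIN_COVERAGE = 5


@dataclass(frozen=True)
class MethCall:
    """A single CpG methylation observation in one sample."""

    chrom: str
    pos: int  # 1-based
    count_meth: int
    count_unmeth: int

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def pm(self) -> float:
        """Percentage of methylated copies, recomputed from counts."""
        return 100.0 * self.count_meth / self.coverage


@dataclass(frozen=True)
class SampleMeta:
    """Identity and design cell of one bisulfite-sequenced sample."""

    sample_id: str
    population: str  # "marine" | "freshwater"
    treatment: str  # "native" | "transplanted"

    def __post_init__(self):
        if self.population not in ("marine", "freshwater"):
            raise ConfigurationError(
                f"unknown population {self.population!r} for sample {self.sample_id!r}"
            )
        if self.treatment not in ("native", "transplanted"):
            raise ConfigurationError(
                f"unknown treatment {self.treatment!r} for sample {self.sample_id!r}"
            )


def read_bismark_coverage(path: str | Path) -> Iterator[MethCall]:
    """Stream methylation calls from a Bismark coverage file.

    Lines must have six tab-separated fields; ``start`` must equal ``end``
    (single-cytosine records). Yields one :class:`MethCall` per line in file
    order. Raises :class:`ParseError` naming the offending line for malformed
    input and :class:`ValidationError` for negative counts.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"expected 6 tab-separated fields, got {len(fields)}",
                    str(path), lineno,
                )
            chrom, start_s, end_s, _percent, meth_s, unmeth_s = fields
            try:
                start = int(start_s)
                end = int(end_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", str(path), lineno) from exc
            if start != end:
                raise ParseError(
                    f"start != end ({start} != {end}); expected single-cytosine records",
                    str(path), lineno,
                )
            if meth < 0 or unmeth < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative methylation counts ({meth}, {unmeth})"
                )
            if meth + unmeth < 1:
                raise ValidationError(f"{path}:{lineno}: zero total coverage")
            yield MethCall(chrom, start, meth, unmeth)


def read_snp_mask(path: str | Path) -> set[tuple[str, int]]:
    """Read a SNP mask file into a set of 1-based (chrom, pos) coordinates.

    Two dialects are accepted and auto-detected per line count:

    * two columns ``chrom<TAB>pos`` — positions taken as 1-based;
    * BED (three or more columns) — 0-based half-open intervals, expanded to
      1-based positions ``start+1 .. end``.
    """
    path = Path(path)
    mask: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 2:
                    mask.add((fields[0], int(fields[1])))
                elif len(fields) >= 3:
                    start, end = int(fields[1]), int(fields[2])
                    for p in range(start + 1, end + 1):
                        mask.add((fields[0], p))
                else:
                    raise ValueError("need at least 2 columns")
            except ValueError as exc:
                raise ParseError(f"malformed mask line: {exc}", str(path), lineno) from exc
    return mask


class MethSiteMatrix:
    """Per-site methylated/unmethylated counts across samples.

    Rows are CpG sites indexed by ``(chrom, pos)`` in (chrom, pos) sorted
    order; columns are sample ids. Access the two count layers as the
    DataFrames :attr:`meth` and :attr:`unmeth`.
    """

    def __init__(self, meth: pd.DataFrame, unmeth: pd.DataFrame,
                 samples: Sequence[SampleMeta]):
        if list(meth.columns) != [s.sample_id for s in samples]:
            raise ValidationError("count columns do not match sample metadata")
        if not meth.index.equals(unmeth.index):
            raise ValidationError("meth/unmeth site indexes differ")
        self.meth = meth
        self.unmeth = unmeth
        self.samples = list(samples)

    # -- basic views ------------------------------------------------------
    @property
    def sites(self) -> list[tuple[str, int]]:
        return list(self.meth.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def coverage(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def pm(self) -> pd.DataFrame:
        """Percentage of methylated copies per site and sample."""
        cov = self.meth + self.unmeth
        return 100.0 * self.meth / cov

    def sample_ids_for(self, population: str | None = None,
                       treatment: str | None = None) -> list[str]:
        return [
            s.sample_id for s in self.samples
            if (population is None or s.population == population)
            and (treatment is None or s.treatment == treatment)
        ]

    def __len__(self) -> int:
        return len(self.meth)

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV (``meth:unmeth`` per sample) plus a JSON
        sidecar ``<path>.samples.json`` holding the sample metadata."""
        path = Path(path)
        out = pd.DataFrame(index=self.meth.index)
        for sid in self.sample_ids:
            out[sid] = (
                self.meth[sid].astype(str) + ":" + self.unmeth[sid].astype(str)
            )
        out.index.names = ["chrom", "pos"]
        out.reset_index().to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".samples.json")
        with open(sidecar, "w") as fh:
            json.dump([asdict(s) for s in self.samples], fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethSiteMatrix":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".samples.json")
        with open(sidecar) as fh:
            samples = [SampleMeta(**d) for d in json.load(fh)]
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df = df.set_index(["chrom", "pos"])
        meth = pd.DataFrame(index=df.index)
        unmeth = pd.DataFrame(index=df.index)
        for sid in (s.sample_id for s in samples):
            parts = df[sid].str.split(":", expand=True).astype(np.int64)
            meth[sid] = parts[0]
            unmeth[sid] = parts[1]
        return cls(meth, unmeth, samples)


def _calls_to_frame(sample_id: str, calls: Iterable[MethCall]) -> pd.DataFrame:
    rows = [(c.chrom, c.pos, c.count_meth, c.count_unmeth) for c in calls]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValidationError(
            f"duplicate site {dup.chrom}:{dup.pos} in sample {sample_id!r}"
        )
    return df.set_index(["chrom", "pos"])


def build_site_matrix(
    calls_per_sample: Mapping[str, Iterable[MethCall]],
    meta: Sequence[SampleMeta],
    snp_mask: set[tuple[str, int]] | None = None,
    min_cov: int = DEFAULT_MIN_COVERAGE,
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
    drop_invariant_over: Sequence[str] | None = None,
) -> MethSiteMatrix:
    """Assemble the filtered multi-sample site matrix.

    A site is retained iff it (a) is present with coverage ``>= min_cov`` in
    every sample, (b) is not on an excluded chromosome, (c) is not in
    ``snp_mask``, and (d) — when ``drop_invariant_over`` names a subset of
    samples — is not uniformly 0% nor uniformly 100% methylated across those
    samples. Sites absent from a sample count as coverage 0 there.
    """
    if min_cov < 1:
        raise ConfigurationError(f"min_cov must be >= 1, got {min_cov}")
    sample_ids = [s.sample_id for s in meta]
    if len(set(sample_ids)) != len(sample_ids):
        raise ConfigurationError("duplicate sample_id in metadata")
    missing = [sid for sid in sample_ids if sid not in calls_per_sample]
    if missing:
        raise ConfigurationError(f"no call stream for samples: {missing}")
    if drop_invariant_over is not None:
        unknown = set(drop_invariant_over) - set(sample_ids)
        if unknown:
            raise ConfigurationError(
                f"drop_invariant_over names unknown samples: {sorted(unknown)}"
            )

    frames = {sid: _calls_to_frame(sid, calls_per_sample[sid]) for sid in sample_ids}

    # intersect sites with sufficient coverage in every sample
    common: pd.Index | None = None
    for sid in sample_ids:
        f = frames[sid]
        ok = f.index[(f.meth + f.unmeth) >= min_cov]
        common = ok if common is None else common.intersection(ok)
    assert common is not None

    excluded_chroms = set(excluded_chroms)
    keep = [
        (c, p) for (c, p) in common
        if c not in excluded_chroms and (snp_mask is None or (c, p) not in snp_mask)
    ]
    keep_idx = pd.MultiIndex.from_tuples(
        sorted(keep), names=["chrom", "pos"]
    ) if keep else pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])

    meth = pd.DataFrame(
        {sid: frames[sid].meth.reindex(keep_idx) for sid in sample_ids}
    ).astype(np.int64, errors="ignore")
    unmeth = pd.DataFrame(
        {sid: frames[sid].unmeth.reindex(keep_idx) for sid in sample_ids}
    ).astype(np.int64, errors="ignore")

    if drop_invariant_over:
        sub_m = meth[list(drop_invariant_over)]
        sub_u = unmeth[list(drop_invariant_over)]
        all_zero = (sub_m == 0).all(axis=1)
        all_full = (sub_u == 0).all(axis=1)
        variant = ~(all_zero | all_full)
        meth, unmeth = meth[variant], unmeth[variant]

    meth = meth.astype(np.int64)
    unmeth = unmeth.astype(np.int64)
    return MethSiteMatrix(meth[sample_ids], unmeth[sample_ids], meta)
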