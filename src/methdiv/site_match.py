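"""Distance-matched subsampling of non-DMCs and feature annotation.

Because nucleotide diversity varies along a chromosome, comparing DMCs to
an arbitrary genome-wide sample of non-differentially methylated sites
would confound methylation class with genomic location. The matched
subsampler instead draws, for each DMC, one non-DMC uniformly at random
from within a fixed window around it (default +/-2 kb) on the same
chromosome, then deduplicates the union.

Feature annotation flags each site by membership in user-supplied BED
intervals (CpG islands, promoters, gene bodies, ...); a site in none of
the supplied features is flagged intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ParseError

DEFAULT_MATCH_WINDOW = 2_000


@dataclass
class MatchedSubsample:
    """Result of matched non-DMC subsampling.

    ``provenance`` maps each DMC to the site drawn for it (or None when its
    window held no candidate); ``selected`` is the deduplicated union.
    """

    selected: set
    provenance: dict
    seed: int

    @property
    def selected_sorted(self) -> list:
        return sorted(self.selected)


def subsample_non_dmcs(
    dmcs: Iterable[tuple[str, int]],
    non_dmcs: Iterable[tuple[str, int]],
    window: int = DEFAULT_MATCH_WINDOW,
    seed: int = 0,
) -> MatchedSubsample:
    """For each DMC, draw one non-DMC within ``window`` bp, then deduplicate.

    Draws are independent across DMCs (the same non-DMC may be drawn twice
    and is kept once). DMCs are visited in sorted order and draws consume a
    single seeded stream, so results are reproducible.
    """
    if window <= 0:
        raise ConfigurationError(f"window must be positive, got {window}")
    dmcs = sorted(set(dmcs))
    non_dmcs = sorted(set(non_dmcs))
    overlap = set(dmcs) & set(non_dmcs)
    if overlap:
        raise ConfigurationError(
            f"{len(overlap)} sites appear in both DMC and non-DMC sets"
        )

    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in non_dmcs:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    by_chrom = {c: np.asarray(p, dtype=np.int64) for c, p in by_chrom.items()}

    rng = np.random.default_rng(seed)
    provenance: dict = {}
    selected: set = set()
    for chrom, pos in dmcs:
        cands = by_chrom.get(chrom)
        if cands is None:
            provenance[(chrom, pos)] = None
            continue
        lo = int(np.searchsorted(cands, pos - window, side="left"))
        hi = int(np.searchsorted(cands, pos + window, side="right"))
        if hi == lo:
            provenance[(chrom, pos)] = None
            continue
        pick = (chrom, int(cands[lo + int(rng.integers(hi - lo))]))
        provenance[(chrom, pos)] = pick
        selected.add(pick)
    return MatchedSubsample(selected=selected, provenance=provenance, seed=seed)


def _read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees
    keyed on 1-based inclusive coordinates."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line needs >= 3 columns", str(path), lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric BED coordinates: {exc}",
                                 str(path), lineno) from exc
            if end <= start:
                continue
            # 0-based half-open [start, end) -> 1-based inclusive [start+1, end]
            trees.setdefault(fields[0], IntervalTree()).addi(start + 1, end + 1)
    return trees


def annotate_features(
    sites: Iterable[tuple[str, int]],
    features: Mapping[str, str | Path | dict[str, IntervalTree]],
) -> pd.DataFrame:
    """Flag each site by feature membership; adds an ``intergenic`` column
    true where the site overlaps none of the supplied features.

    ``features`` maps feature name to a BED path (or pre-built trees).
    """
    trees = {
        name: (_read_bed(src) if not isinstance(src, dict) else src)
        for name, src in features.items()
    }
    sites = list(sites)
    idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "pos"]) if sites else \
        pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
    out = pd.DataFrame(index=idx)
    for name, per_chrom in trees.items():
        flags = [
            bool(per_chrom.get(chrom) and per_chrom[chrom].overlaps_point(pos))
            for chrom, pos in sites
        ]
        out[name] = flags
    out["intergenic"] = ~out[list(trees)].any(axis=1) if trees else True
    return out
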