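# Methods

This note documents the models, estimators and numerical conventions behind
`methdiv`, the design choices made where several conventions are in use, and
what the synthetic data do and do not establish about behaviour on real
data.

## Site filtering (meth_io)

Coverage files are the Bismark dialect: 1-based inclusive coordinates,
`start == end` for single cytosines. The file's percent column is ignored
and methylation percentages are always recomputed from the counts, to avoid
carrying rounding inconsistencies. Positions are taken as given and never
strand-merged (merging, where wanted, is assumed done upstream by the
methylation caller). A site is retained iff it is covered at least
`min_cov` (default 5) in **every** sample — a site absent from one sample
counts as coverage 0 there, with no imputation — is not on an excluded
chromosome (default: mitochondrial plus the two sex chromosomes, `chrM`,
`chrXIX`, `chrY`), is not in the SNP mask, and is not uniformly 0% or 100%
methylated across the designated comparison samples. The SNP mask accepts
either a two-column 1-based `chrom pos` TSV or BED (0-based half-open,
converted). Filtering is idempotent and monotone in `min_cov` and mask
size; both properties are tested.

## Differential methylation (dm_classify)

Per site, methylated/unmethylated counts are modelled binomially with group
as the only covariate. The maximum-likelihood fit of that logistic model
assigns each group its coverage-weighted pooled proportion, so the
likelihood-ratio statistic reduces to a closed form (a G-test on the
group-collapsed 2×2 table) and is evaluated vectorised; p-values come from
χ²(1). Fisher's exact test on the pooled table is the fallback for
degenerate fits, flagged in the output. The methylation difference is the
difference of coverage-weighted pooled percentages, B − A (an unweighted
mean-of-sample-percentages mode is available). Under a shared-binomial null
with intermediate methylation and ~15× per-sample coverage the test is well
calibrated (fraction of p ≤ 0.05 ≈ 0.049–0.054 over 10⁴ sites); the
χ² approximation degrades, conservatively, for sites with near-0/100%
methylation where counts are nearly monomorphic.

Multiple testing uses Benjamini–Hochberg, chosen over sliding-window or
resampling FDR schemes for determinism and transparency. Classification is
inclusive at both boundaries: a site is a DMC iff |Δmethylation| ≥ 15
percentage points **and** q ≤ 0.05; the sign of Δ splits hypo from hyper.
The same rule is applied to the two treatment comparisons, and q-values are
computed per comparison. A site counts as *induced* in a population iff its
native-vs-transplanted comparison is significant; the direction of induced
change is deliberately ignored and only |Δ| is carried.

No overdispersion correction is applied by default: with 2–3 samples per
group the dispersion estimate is unstable. The cost is visible in the
synthetic runs as an inflated false-flag rate for inducibility (~20–30% of
induced calls are at truly non-induced sites when between-individual noise
is high), a known behaviour of count-based DM callers at these group sizes.

## Pooled diversity estimators (pool_diversity)

Pileup decoding implements the full read-base grammar (`^` + mapping
quality, `$`, indel runs, `*`/`N` placeholders consume a quality but never
count); base qualities are phred+33 and bases under `min_qual` (default 20)
are dropped. Alleles supported by fewer than `min_count` (default 2) reads
are treated as sequencing error and removed; a site is excluded when the
remaining coverage M falls outside [`min_cov`, `max_cov`] = [3, 1000].

Per covered site, with post-filter frequencies f_a at coverage M:

- π̂ = (M/(M−1)) (1 − Σ f_a²), identically the number of pairwise read
  differences over C(M,2) — verified exhaustively for all configurations
  with M ≤ 8;
- S = 1 if ≥2 alleles remain, θ̂ = S/a₁(M).

Category/rank (label) values are per-covered-site averages; labels with a
covered fraction below 0.60 are flagged for exclusion. Tajima's D uses the
classical constants at an effective sample size n_eff = min(pool size,
median covered-site coverage of the label) — a declared reconstruction, as
pooled adaptations of the D variance differ between tools; D is reported
only when S > 0.

**Pool correction.** The naive π̂ is biased for the pool's heterozygosity:
downward by the min-count filter (minor alleles hidden below b reads) and
by the finite pool. In `pool_corrected` mode both statistics are divided by
a factor K(M, n, b) computed by exact enumeration under a declared model: a
segregating site has derived-allele count k ∈ {1..n−1} among the pool's n
haploid genomes with neutral weight 1/k, reads are binomial(M, k/n), and
the same estimator (with the min-count filter) is applied; K is the ratio
of the expected naive statistic to the expected pool heterozygosity
(n/(n−1))·2(k/n)(1−k/n). With b = 1 this reduces to K = (n−1)/n exactly.
The enumeration is validated against Monte-Carlo simulation over a grid of
(n, depth, b) ∈ {20,24} × {5,10} × {1,2} at 10⁵ sites per cell (agreement
within 3 standard errors). The default mode is `naive`, since the analyses
here compare categories within a common (M, n, b) regime where the bias is
a common factor; the correction matters when absolute levels are compared
across regimes.

**Fst.** Per site, h_k = (M_k/(M_k−1))(1 − Σ f_{a,k}²) within each pool,
h_T from the unweighted mean allele frequencies with the combined factor
M_T/(M_T−1), M_T = M₁+M₂, and Fst = (h_T − (h₁+h₂)/2)/h_T, defined only
where h_T > 0. The min-count filter is applied to counts summed across
pools by default (per-pool mode available). Label values are means of
defined per-site values; negative per-site values are **retained** so label
means stay unbiased (a clamp-at-zero display option exists). A consequence
of the M_T/(M_T−1) convention worth knowing: identical pools give a
slightly negative value of order −1/(2M), vanishing as coverage grows — the
estimator indicates "no differentiation" asymptotically, not as an exact
zero. Pool sizes are accepted per pool (24 and 20 haploids by default)
rather than the single shared value some tools require.

**SNP typing.** At listed CpG sites, alleles with ≥ `min_count` reads are
kept; exactly two retained alleles make a biallelic SNP, typed `CT_GA` iff
the unordered pair is {C,T} or {G,A} (the deamination signature on either
strand), else `other`. This count-threshold detector replaces genotype-
caller-based SNP extraction; it needs no ploidy model and its inputs are
the same filtered counts as the diversity estimators. Percentages are per
labeled site set, with all labeled sites (polymorphic or not) as the
denominator.

## Matched subsampling and annotation (site_match)

For each DMC (visited in sorted order, consuming one seeded stream), one
non-DMC within ±2 kb on the same chromosome is drawn uniformly; draws are
independent across DMCs and the union is deduplicated. The 2 kb default
follows the more specific of the two windows in circulation for this
procedure; it is exposed as a parameter. Uniformity over candidates is
tested by χ² over 10⁴ seeds. Feature annotation flags sites by membership
in user-supplied BED intervals (converted to 1-based inclusive);
`intergenic` is the complement of all supplied features.

## Ranks (rank_profile)

Ranks are equal-width bins (default 50) over [min, max] of the ranking
variable, computed separately per population and site category. Intervals
are left-closed right-open, except the last which is closed; a value on an
internal boundary joins the upper interval. Equal-width (not
equal-frequency) matches the binning convention of the original analysis;
ranking over each population's own value range is the default, with a
shared-range option. Ranks below the 0.60 covered-fraction floor are
flagged excluded, and empty ranks are emitted with n = 0 so profiles always
have the full rank count.

## Statistics (stats_report)

Paired per-chromosome comparisons first test the pairwise differences with
Shapiro–Wilk at a fixed gate of 0.05 (the conventional level; configurable):
normal → paired t, non-normal → paired Wilcoxon signed-rank (exact
distribution for ≤25 nonzero differences, normal approximation with
continuity correction above; zero differences dropped). All-zero
differences short-circuit to a degenerate result with p = 1. Trend fits are
OLS; the headline R² is the **adjusted** value, 1 − (1−R²)(n−1)/(n−2),
which can be negative for fits worse than a constant; the raw R² is also
emitted.

## Synthetic data (synth_data)

The generator draws exact per-site truth and emits the files the pipeline
consumes. Defaults encode the emulated study:

- **Design**: 11 RRBS samples (3 marine native, 3 freshwater native, 3
  marine transplanted, 2 freshwater transplanted — one treated freshwater
  sample fewer, mirroring the upstream exclusion of a low-conversion
  sample); pools of 24 and 20 haploid genomes at mean depths 10.4× and 8×.
- **Scale**: class counts default to ten chromosomes times the per-
  chromosome class sizes of the emulated data (49,790 / 45,660 / 7,250 for
  non-DMC / hypo / hyper ≈ 10⁵ sites), which a full pipeline run processes
  in ~30 s on one CPU.
- **Placement**: sites come in clusters (25 sites, 50–300 bp apart) spread
  along each chromosome, emulating the CpG-dense regions RRBS enriches —
  this density is what makes ±2 kb matched subsampling meaningful.
- **Methylation**: non-DMCs are a 50/50 bimodal Beta mixture (modes near 0
  and 100%), identical in both populations; hypo sites go high → lower by a
  shift drawn from [25, 45] points; hyper sites go low-intermediate →
  higher likewise, so every true DMC has |Δ| ≥ 25 before boundary clipping.
  Between-individual noise is Gaussian with class- and population-specific
  SD (larger for hypo sites in freshwater, mirroring the variance gain that
  accompanies methylation loss), clipped to [0, 100].
- **Inducibility**: per class and population, a configured fraction of
  sites (2% / 4–8% / 18–28% for non-DMC / hypo / hyper) shifts by 25–40
  points (random direction) in transplanted fish.
- **Polymorphism**: class-dependent probabilities (5% / 15% / 25%) scaled
  in freshwater by a bottleneck factor 0.7; minor allele frequencies
  uniform on [0.05, 0.5]; the C-T/G-A share is 0.90 (marine) and 0.94
  (freshwater). Induced sites carry more standing variation (probability
  multiplier 1 + 2|shift|/max-shift), encoding the diversity–inducibility
  coupling the analysis is designed to detect. Pool reads are two-stage:
  realized pool allele count ~ Binomial(n, population frequency), then
  reads ~ Binomial(depth, k/n). No genealogies are simulated — the analysis
  consumes frequencies, so drawing them directly keeps the truth exact and
  the generator desk-scale.
- A single seed governs everything through named substreams, so the truth
  table and each emitter regenerate independently and byte-identically.

**What passing tests show, and what they do not.** The generator has no
linkage, no read-level errors beyond the quality threshold, no reference
bias, no strand asymmetry (site reference bases are all C) and no
correlation of allele frequencies between populations (each population's
polymorphism is drawn independently, so synthetic Fst reflects independent
pools, not shared ancestry). End-to-end recovery therefore demonstrates
that the estimators and classifiers are correct and well calibrated under
the declared sampling models — not that they are robust to alignment
artefacts or population structure in real data.

**Frozen operating points.** Under the default conditions the DM caller
recovers 86% of true DMCs at a 2% false discovery proportion (frozen in the
regression suite at ≥80% / ≤10%, stable across seeds and a 5× scale
change). Inducibility calling is weaker — 62–66% sensitivity for realized
shifts ≥25 points in marine (n=3 treated) and 48–50% in freshwater (n=2
treated) — because the treated groups are small and the BH threshold over
~10⁵ mostly-null tests is stringent; the calibrated floors (≥0.55 / ≥0.42)
are frozen as regression tests. For the same reason the pipeline's
rank-level inducibility trend fits on default synthetic data are noise-
dominated (≈40 induced sites per rank and a noisy rank variable); the
dedicated rank-trend check instead uses 50 ranks × 500 sites with
heterozygosity linear in the ranking variable, where the positive slope is
recovered at p < 0.001.

## Problem sizes used by the checks

Exhaustive π oracle: all allele configurations with coverage ≤ 8. Tajima
constants: exact rational arithmetic, n = 2..10. Pool-correction grid: 10⁵
simulated sites per (n, depth, b) cell. DM null calibration: 10⁴ sites,
n = 3 vs 3. End-to-end recovery: ~10⁵ sites (the default generator scale).
Rank trend: 50 ranks × 500 sites. Matched-subsampling uniformity: 10⁴
seeds on a 5-candidate fixture. The full suite runs in under a minute on
one CPU.

## Known limitations

- The binomial LRT ignores between-individual overdispersion; with n = 2–3
  per group this inflates inducibility false flags (documented above).
- The pool correction's neutral 1/k weighting is a modelling choice; data
  from strongly non-equilibrium populations violate it (as they do for the
  original toolkit's corrections).
- Tajima's D at pooled data is approximate in n_eff; compare values only
  within a common coverage regime.
- The Fst estimator's small negative bias for undifferentiated pools is
  inherent to the chosen convention and matters at low coverage.
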