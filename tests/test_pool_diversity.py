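import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from methdiv import (AlleleCountRecord, ConfigurationError, EstimatorParams,
                     ParseError, ValidationError, aggregate_diversity,
                     call_biallelic_snps, pairwise_fst, parse_pileup,
                     pileup_to_table, site_estimators, snp_type_percentages,
                     tajima_constants, tajimas_d, windowed_fst)
from methdiv.pool_diversity import (pi_correction, records_to_table,
                                    theta_correction)

NAIVE = dict(min_count=1, min_cov=2, max_cov=10_000)


def params(pool_size=24, **kw):
    return EstimatorParams(pool_size=pool_size, **kw)


def pileup_file(tmp_path, lines):
    p = tmp_path / "test.pileup"
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestParsePileup:
    def test_all_reference_bases(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t4\t.,.,\tIIII"])
        (rec,) = parse_pileup(p)
        assert rec.counts == {"A": 0, "C": 4, "G": 0, "T": 0}
        assert rec.coverage == 4

    def test_quality_filter_drops_low_quality_base(self, tmp_path):
        # qualities I,#,I,I = phred 40,2,40,40: the T at phred 2 is dropped
        p = pileup_file(tmp_path, ["chrI\t10\tC\t4\t.T..\tI#II"])
        (rec,) = parse_pileup(p, min_qual=20)
        assert rec.counts == {"A": 0, "C": 3, "G": 0, "T": 0}

    def test_insertion_consumed_without_counting(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t2\t.+2AT.\tII"])
        (rec,) = parse_pileup(p)
        assert rec.counts["C"] == 2
        assert rec.coverage == 2

    def test_deletion_run_and_star(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t3\t.-1A.*\tIII"])
        (rec,) = parse_pileup(p)
        # '*' consumes a quality but never counts as an allele
        assert rec.counts["C"] == 2
        assert rec.coverage == 2

    def test_caret_and_dollar_markers(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tG\t3\t^I.,$a\tIII"])
        (rec,) = parse_pileup(p)
        assert rec.counts == {"A": 1, "C": 0, "G": 2, "T": 0}

    def test_lowercase_bases_count_as_upper(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t4\t.,tT\tIIII"])
        (rec,) = parse_pileup(p)
        assert rec.counts == {"A": 0, "C": 2, "G": 0, "T": 2}

    def test_length_mismatch_raises_with_position(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t4\t....\tII"])
        with pytest.raises(ParseError, match=":1"):
            list(parse_pileup(p))

    def test_unknown_ref_base_skips_record(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tN\t2\t..\tII",
                                   "chrI\t11\tA\t2\t..\tII"])
        recs = list(parse_pileup(p))
        assert [(r.chrom, r.pos) for r in recs] == [("chrI", 11)]

    def test_table_form(self, tmp_path):
        p = pileup_file(tmp_path, ["chrI\t10\tC\t4\t..TT\tIIII",
                                   "chrII\t5\tA\t2\t..\tII"])
        t = pileup_to_table(p)
        assert t.loc[("chrI", 10), "T"] == 2
        assert t.loc[("chrII", 5), "A"] == 2


class TestSiteEstimators:
    def test_two_two_split(self):
        pi, theta, s = site_estimators({"C": 2, "T": 2},
                                       params(min_count=2, min_cov=2))
        # 4 pairwise differences among 4 reads / C(4,2)=6
        assert pi == pytest.approx(4 / 6)
        assert s == 1
        assert theta == pytest.approx(1 / (1 + 1 / 2 + 1 / 3))

    def test_min_count_removes_singleton(self):
        pi, theta, s = site_estimators({"C": 9, "T": 1},
                                       params(min_count=2, min_cov=3))
        assert pi == 0.0 and theta == 0.0 and s == 0

    def test_below_min_coverage_excluded(self):
        assert site_estimators({"C": 2}, params(min_count=2, min_cov=3)) is None

    def test_above_max_coverage_excluded(self):
        assert site_estimators({"C": 2000},
                               params(min_count=2, min_cov=3,
                                      max_cov=1000)) is None

    def test_exhaustive_pairwise_difference_oracle(self):
        """Naive per-site pi equals pairwise-difference enumeration for
        every allele-count configuration with coverage <= 8."""
        p = params(**NAIVE)
        for total in range(2, 9):
            for c in itertools.product(range(total + 1), repeat=4):
                if sum(c) != total:
                    continue
                reads = [b for b, n in zip("ACGT", c) for _ in range(n)]
                diffs = sum(1 for x, y in itertools.combinations(reads, 2)
                            if x != y)
                expected = diffs / (total * (total - 1) / 2)
                got = site_estimators(dict(zip("ACGT", c)), p)
                assert got is not None
                assert got[0] == pytest.approx(expected, abs=1e-12)


class TestTajima:
    def test_constants_match_rational_closed_forms(self):
        """a1..e2 agree with exact rational arithmetic for n = 2..10."""
        for n in range(2, 11):
            a1 = sum(Fraction(1, i) for i in range(1, n))
            a2 = sum(Fraction(1, i * i) for i in range(1, n))
            b1 = Fraction(n + 1, 3 * (n - 1))
            b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            got = tajima_constants(n)
            for key, exact in [("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2),
                               ("c1", c1), ("c2", c2), ("e1", e1), ("e2", e2)]:
                assert got[key] == pytest.approx(float(exact), rel=1e-12), \
                    f"{key} at n={n}"

    def test_a1_example(self):
        assert tajima_constants(4)["a1"] == pytest.approx(11 / 6)

    def test_zero_numerator_gives_zero_d(self):
        a1 = tajima_constants(10)["a1"]
        assert tajimas_d(pi_sum=5 / a1, s_total=5, n_eff=10) == pytest.approx(0.0)

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(0.0, 0, 10))

    def test_negative_s_rejected(self):
        with pytest.raises(ValidationError):
            tajimas_d(1.0, -1, 10)

    def test_excess_rare_variants_negative_d(self):
        # many segregating sites but almost no pairwise diversity
        assert tajimas_d(pi_sum=0.5, s_total=20, n_eff=20) < 0


class TestPoolCorrection:
    def test_b1_correction_is_pool_factor(self):
        # without a min-count filter the only bias is the n/(n-1) pool factor
        assert pi_correction(10, 20, 1) == pytest.approx(19 / 20, rel=1e-9)

    def test_correction_shrinks_with_filter(self):
        assert pi_correction(5, 20, 2) < pi_correction(5, 20, 1)

    def test_monte_carlo_oracle_single_cell(self, rng):
        """Enumerated correction agrees with Monte-Carlo simulation of
        segregating pool sites (one (n, depth, b) cell; grid in acceptance)."""
        n, m, b = 20, 10, 2
        k_vals = np.arange(1, n)
        w = 1.0 / k_vals
        w /= w.sum()
        nsim = 40_000
        k = rng.choice(k_vals, nsim, p=w)
        reads = rng.binomial(m, k / n)
        p = params(pool_size=n, min_count=b, min_cov=b)
        pis = np.array([site_estimators({"C": int(r), "T": int(m - r)}, p)[0]
                        for r in reads])
        corrected = pis / pi_correction(m, n, b)
        h = (n / (n - 1)) * 2 * (k / n) * (1 - k / n)
        se = corrected.std(ddof=1) / np.sqrt(nsim)
        assert abs(corrected.mean() - h.mean()) < 3 * se

    def test_theta_correction_positive_and_below_pi_equivalent(self):
        assert 0 < theta_correction(10, 20, 2) < 1.5


def label_all(table, label="x"):
    return {site: label for site in table.index}


class TestAggregateDiversity:
    def recs(self, spec):
        """spec: [(chrom, pos, counts)]"""
        return records_to_table(
            [AlleleCountRecord(c, p, {b: cnt.get(b, 0) for b in "ACGT"}, "C")
             for c, p, cnt in spec])

    def test_monomorphic_label(self):
        t = self.recs([("chrI", i, {"C": 10}) for i in range(1, 6)])
        out = aggregate_diversity(t, label_all(t), params(min_cov=3))
        row = out.loc["x"]
        assert row.pi == 0.0 and row.theta_w == 0.0
        assert np.isnan(row.tajimas_d)
        assert row.covered_fraction == 1.0 and not row.flagged

    def test_low_covered_fraction_flagged(self):
        t = self.recs([("chrI", 1, {"C": 10}), ("chrI", 2, {"C": 2}),
                       ("chrI", 3, {"C": 1})])
        out = aggregate_diversity(t, label_all(t), params(min_cov=3),
                                  min_covered_fraction=0.60)
        assert out.loc["x"].covered_fraction == pytest.approx(1 / 3)
        assert bool(out.loc["x"].flagged)

    def test_unlabeled_uncovered_site_counts_toward_fraction(self):
        t = self.recs([("chrI", 1, {"C": 10, "T": 5})])
        labels = {("chrI", 1): "x", ("chrI", 99): "x"}  # absent from pileup
        out = aggregate_diversity(t, labels, params(min_cov=3))
        assert out.loc["x"].covered_fraction == pytest.approx(0.5)

    def test_additivity_over_partition(self, rng):
        """Coverage-weighted recombination of two labels' sums equals the
        whole-set sums."""
        spec = [("chrI", i, {"C": int(rng.integers(2, 20)),
                             "T": int(rng.integers(0, 8))})
                for i in range(1, 41)]
        t = self.recs(spec)
        p = params(min_cov=3)
        whole = aggregate_diversity(t, label_all(t), p)
        half_labels = {site: ("a" if site[1] <= 20 else "b")
                       for site in t.index}
        halves = aggregate_diversity(t, half_labels, p)
        for col in ("pi", "theta_w"):
            combined = (halves[col] * halves.n_covered).sum()
            assert combined == pytest.approx(
                float(whole[col].iloc[0]) * int(whole.n_covered.iloc[0]))

    def test_pool_corrected_mode_scales_up(self):
        t = self.recs([("chrI", i, {"C": 6, "T": 4}) for i in range(1, 11)])
        naive = aggregate_diversity(t, label_all(t), params(min_cov=3))
        corr = aggregate_diversity(
            t, label_all(t), params(min_cov=3, correction_mode="pool_corrected"))
        assert corr.loc["x"].pi > naive.loc["x"].pi


class TestFst:
    def recs(self, spec):
        return records_to_table(
            [AlleleCountRecord(c, p, {b: cnt.get(b, 0) for b in "ACGT"}, "C")
             for c, p, cnt in spec])

    def test_identical_pools_near_zero_vanishing_with_coverage(self):
        """Identical pools show no differentiation: the estimator is
        non-positive, bounded by ~1/(M-1), and shrinks as coverage grows."""
        vals = []
        for depth in (25, 100, 400):
            t = self.recs([("chrI", 1, {"C": depth, "T": depth})])
            out = pairwise_fst(t, t, {("chrI", 1): "x"}, params(min_cov=3))
            f = float(out.loc["x"].fst)
            assert f <= 0.0
            assert abs(f) < 1.0 / (depth - 1)
            vals.append(abs(f))
        assert vals == sorted(vals, reverse=True)

    def test_fixed_difference_tends_to_one(self):
        fsts = []
        for depth in (10, 50, 400):
            t1 = self.recs([("chrI", 1, {"C": depth})])
            t2 = self.recs([("chrI", 1, {"T": depth})])
            out = pairwise_fst(t1, t2, {("chrI", 1): "x"}, params(min_cov=3))
            fsts.append(float(out.loc["x"].fst))
        assert fsts == sorted(fsts)
        assert fsts[-1] > 0.99

    def test_hand_computed_toy_value(self):
        # pool1 C:10 monomorphic, pool2 C:5/T:5:
        # h1=0, h2=(10/9)*0.5, hT=(20/19)*(1-0.75^2-0.25^2) -> 0.2963
        t1 = self.recs([("chrI", 1, {"C": 10})])
        t2 = self.recs([("chrI", 1, {"C": 5, "T": 5})])
        out = pairwise_fst(t1, t2, {("chrI", 1): "x"}, params(min_cov=3))
        h2 = (10 / 9) * 0.5
        ht = (20 / 19) * (1 - 0.75**2 - 0.25**2)
        assert out.loc["x"].fst == pytest.approx((ht - h2 / 2) / ht)
        assert out.loc["x"].fst == pytest.approx(0.296, abs=5e-4)

    def test_symmetry_under_pool_relabeling(self, rng):
        spec1 = [("chrI", i, {"C": int(rng.integers(3, 30)),
                              "T": int(rng.integers(0, 10))})
                 for i in range(1, 21)]
        spec2 = [("chrI", i, {"C": int(rng.integers(3, 30)),
                              "T": int(rng.integers(0, 10))})
                 for i in range(1, 21)]
        t1, t2 = self.recs(spec1), self.recs(spec2)
        labels = label_all(t1)
        p = params(min_cov=3)
        ab = pairwise_fst(t1, t2, labels, p)
        ba = pairwise_fst(t2, t1, labels, p)
        assert ab.loc["x"].fst == pytest.approx(ba.loc["x"].fst)

    def test_invariant_under_allele_name_permutation(self):
        t1 = self.recs([("chrI", 1, {"C": 12, "T": 4})])
        t2 = self.recs([("chrI", 1, {"C": 5, "T": 9})])
        u1 = self.recs([("chrI", 1, {"G": 12, "A": 4})])
        u2 = self.recs([("chrI", 1, {"G": 5, "A": 9})])
        labels = {("chrI", 1): "x"}
        p = params(min_cov=3)
        assert pairwise_fst(t1, t2, labels, p).loc["x"].fst == pytest.approx(
            pairwise_fst(u1, u2, labels, p).loc["x"].fst)

    def test_site_covered_in_one_pool_skipped(self):
        t1 = self.recs([("chrI", 1, {"C": 10}), ("chrI", 2, {"C": 10, "T": 5})])
        t2 = self.recs([("chrI", 2, {"C": 10, "T": 2})])
        out = pairwise_fst(t1, t2, label_all(t1), params(min_cov=3))
        assert out.loc["x"].n_sites == 1

    def test_summed_min_count_rescues_split_support(self):
        # T has 1 read in each pool: dropped per-pool, kept when summed
        t1 = self.recs([("chrI", 1, {"C": 10, "T": 1})])
        t2 = self.recs([("chrI", 1, {"C": 10, "T": 1})])
        labels = {("chrI", 1): "x"}
        p = params(min_cov=3, min_count=2)
        summed = pairwise_fst(t1, t2, labels, p, min_count_mode="summed")
        per_pool = pairwise_fst(t1, t2, labels, p, min_count_mode="per_pool")
        # summed keeps the site polymorphic (identical pools -> ~0); per-pool
        # drops the T everywhere, the site is monomorphic, Fst undefined
        assert summed.loc["x"].fst == pytest.approx(0.0, abs=0.06)
        assert np.isnan(per_pool.loc["x"].fst)
        # and the summed mode saw a polymorphic site where per-pool did not
        t2b = self.recs([("chrI", 1, {"C": 4, "T": 7})])
        s2 = pairwise_fst(t1, t2b, labels, p, min_count_mode="summed")
        assert s2.loc["x"].fst > 0

    def test_windowed_mode(self):
        spec = [("chrI", i, {"C": 20, "T": 10}) for i in (1, 500, 1_500_000)]
        t1, t2 = self.recs(spec), self.recs(spec)
        out = windowed_fst(t1, t2, params(min_cov=3), window_size=1_000_000,
                           step_size=1_000_000)
        assert len(out) == 2
        assert out.n_sites.tolist() == [2, 1]
        assert (out.fst.abs() < 0.05).all()  # identical pools: ~0


class TestSnpTyping:
    def recs(self, spec):
        return records_to_table(
            [AlleleCountRecord(c, p, {b: cnt.get(b, 0) for b in "ACGT"}, "C")
             for c, p, cnt in spec])

    def test_ct_and_ga_pairs_grouped(self):
        t = self.recs([("chrI", 1, {"C": 8, "T": 4}),
                       ("chrI", 2, {"G": 7, "A": 3}),
                       ("chrI", 3, {"C": 8, "A": 4})])
        out = call_biallelic_snps(t, set(t.index), min_count=2)
        assert out.loc[("chrI", 1), "snp_type"] == "CT_GA"
        assert out.loc[("chrI", 2), "snp_type"] == "CT_GA"
        assert out.loc[("chrI", 3), "snp_type"] == "other"

    def test_monomorphic_and_triallelic_excluded(self):
        t = self.recs([("chrI", 1, {"C": 10}),
                       ("chrI", 2, {"C": 8, "T": 2, "A": 2}),
                       ("chrI", 3, {"C": 9, "T": 1})])  # T below min_count
        out = call_biallelic_snps(t, set(t.index), min_count=2)
        assert len(out) == 0

    def test_restricted_to_listed_sites(self):
        t = self.recs([("chrI", 1, {"C": 8, "T": 4}),
                       ("chrI", 2, {"C": 8, "T": 4})])
        out = call_biallelic_snps(t, {("chrI", 1)}, min_count=2)
        assert list(out.index) == [("chrI", 1)]

    def test_percentages(self):
        t = self.recs(
            [("chrI", i, {"C": 8, "T": 4}) for i in (1, 2)]
            + [("chrI", 3, {"C": 8, "G": 4})]
            + [("chrI", i, {"C": 10}) for i in range(4, 11)])
        labels = {site: "x" for site in t.index}
        snps = call_biallelic_snps(t, set(t.index), min_count=2)
        pct = snp_type_percentages(snps, labels, {"x": 10})
        assert pct.loc["x"].pct_ctga == pytest.approx(20.0)
        assert pct.loc["x"].pct_other == pytest.approx(10.0)

    def test_no_snps_gives_zero_percent(self):
        t = self.recs([("chrI", i, {"C": 10}) for i in range(1, 6)])
        snps = call_biallelic_snps(t, set(t.index), min_count=2)
        pct = snp_type_percentages(snps, label_all(t), {"x": 5})
        assert pct.loc["x"].pct_ctga == 0.0
        assert pct.loc["x"].pct_other == 0.0
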