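import numpy as np
import pytest
from scipy import stats

from hlacc.allele_stats import (
    AlleleCountTable,
    GenotypePairTable,
    count_alleles,
    genotype_pair_frequencies,
    pair_table_margins,
)
from hlacc.nomenclature import parse_allele_name
from hlacc.popgen import hwe_test, ld_coefficient, ld_scan
from hlacc.simulate import control_pair_fixture


def _pairs(locus, counts, resolution=1):
    parsed = {
        tuple(sorted((parse_allele_name(a), parse_allele_name(b)))): c
        for (a, b), c in counts.items()
    }
    return GenotypePairTable(locus, resolution, parsed, sum(counts.values()))


class TestHWE:
    def test_all_homozygous_biallelic_chi2_equals_n(self):
        # p = q = 0.5, every subject homozygous: chi2 = n in closed form
        for n in (8, 20, 100):
            pairs = _pairs("A", {("A*01", "A*01"): n // 2, ("A*02", "A*02"): n // 2})
            res = hwe_test(pairs)
            assert res.chi2 == pytest.approx(n)
            assert res.df == 1

    def test_perfect_hwe_integers(self):
        pairs = _pairs("A", {("A*01", "A*01"): 4, ("A*01", "A*02"): 8,
                             ("A*02", "A*02"): 4})
        res = hwe_test(pairs, min_expected=0.0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_biallelic_matches_textbook_formula(self):
        counts = {("A*01", "A*01"): 30, ("A*01", "A*02"): 40, ("A*02", "A*02"): 30}
        pairs = _pairs("A", counts)
        n = 100
        p = (2 * 30 + 40) / 200
        q = 1 - p
        expected = [n * p * p, 2 * n * p * q, n * q * q]
        observed = [30, 40, 30]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        res = hwe_test(pairs)
        assert res.chi2 == pytest.approx(chi2)
        assert res.df == 1

    def test_relabeling_invariance(self):
        counts = {("A*01", "A*01"): 10, ("A*01", "A*02"): 5, ("A*02", "A*03"): 15,
                  ("A*03", "A*03"): 10}
        relabeled = {("A*11", "A*11"): 10, ("A*11", "A*25"): 5, ("A*25", "A*30"): 15,
                     ("A*30", "A*30"): 10}
        r1 = hwe_test(_pairs("A", counts))
        r2 = hwe_test(_pairs("A", relabeled))
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.df == r2.df

    def test_too_few_subjects(self):
        pairs = _pairs("A", {("A*01", "A*02"): 3})
        with pytest.raises(ValueError, match="at least 5"):
            hwe_test(pairs)

    def test_single_allele_not_testable(self):
        pairs = _pairs("A", {("A*01", "A*01"): 10})
        with pytest.raises(ValueError, match="fewer than 2"):
            hwe_test(pairs)

    def test_mismatched_locus_rejected(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "A", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        with pytest.raises(ValueError, match="share locus"):
            hwe_test(pairs, freqs)

    def test_null_sampling_approximately_uniform(self):
        # three common alleles, n = 500: all classes have expectation >> 1,
        # so the statistic should be calibrated chi-square with df = 3
        rng = np.random.default_rng(11)
        freqs = [0.5, 0.3, 0.2]
        names = [parse_allele_name(a) for a in ("A*01", "A*02", "A*03")]
        pair_keys, probs = [], []
        for i in range(3):
            for j in range(i, 3):
                pair_keys.append(tuple(sorted((names[i], names[j]))))
                probs.append(freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j])
        n, reps = 500, 400
        pvals = []
        draws = rng.multinomial(n, probs, size=reps)
        for row in draws:
            counts = {k: int(c) for k, c in zip(pair_keys, row) if c > 0}
            pairs = GenotypePairTable("A", 1, counts, n)
            pvals.append(hwe_test(pairs).p)
        pvals = np.asarray(pvals)
        rate = np.mean(pvals < 0.05)
        assert 0.02 <= rate <= 0.09
        # coarse uniformity: KS against U(0,1) should not reject wildly
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_reference_cohort_directions(self, ref_cohort):
        mg = hwe_test(genotype_pair_frequencies(ref_cohort, "DRB1", 1))
        ctrl = hwe_test(control_pair_fixture("DRB1"))
        assert mg.p < 0.05
        assert ctrl.p > 0.05


class TestLD:
    def test_definitional_identity(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        key = (parse_allele_name("B*40"), parse_allele_name("B*47"))
        res = ld_coefficient(pairs, freqs, key)
        assert res.d_pct == res.observed_pct - res.expected_pct
        assert 0 <= res.observed_pct <= 100

    def test_published_b40_b47(self, ref_cohort):
        # independent arithmetic oracle: 5.00 - (10.00 * 2.50)/100 = 4.75
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        res = ld_coefficient(pairs, freqs,
                             (parse_allele_name("B*40"), parse_allele_name("B*47")))
        assert res.d_pct == pytest.approx(4.75)

    def test_published_b07_b35(self, ref_cohort):
        # oracle: 5.00 - (3.75 * 13.75)/100 = 4.484375
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        res = ld_coefficient(pairs, freqs,
                             (parse_allele_name("B*07"), parse_allele_name("B*35")))
        assert res.d_pct == pytest.approx(5.0 - 3.75 * 13.75 / 100)

    def test_independent_pair_gives_zero(self):
        pairs = _pairs("B", {("B*07", "B*08"): 8, ("B*07", "B*07"): 1,
                             ("B*08", "B*08"): 16})
        # choose frequencies so P_XY = P_X * P_Y exactly for the het pair
        fmap = {parse_allele_name("B*07"): 0.4, parse_allele_name("B*08"): 0.8}
        res = ld_coefficient(pairs, fmap,
                             (parse_allele_name("B*07"), parse_allele_name("B*08")))
        assert res.d_pct == pytest.approx(0.0)

    def test_missing_allele_rejected(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        with pytest.raises(KeyError):
            ld_coefficient(pairs, freqs,
                           (parse_allele_name("B*14"), parse_allele_name("B*40")))


class TestLDScan:
    def test_threshold_4_finds_published_pairs(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        found = {tuple(str(a) for a in r.pair) for r in ld_scan(pairs, freqs, 4.0)}
        assert found == {("B*40", "B*47"), ("B*07", "B*35")}

    def test_threshold_100_empty(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "B", 1)
        freqs = count_alleles(ref_cohort, "B", 1)
        assert ld_scan(pairs, freqs, 100.0) == []

    def test_control_fixture_b15_b35(self):
        ctrl = control_pair_fixture("B")
        freqs = pair_table_margins(ctrl)
        found = {tuple(str(a) for a in r.pair) for r in ld_scan(ctrl, freqs, 2.0)}
        assert ("B*15", "B*35") in found

    def test_sorted_descending(self, ref_cohort):
        pairs = genotype_pair_frequencies(ref_cohort, "DRB1", 1)
        freqs = count_alleles(ref_cohort, "DRB1", 1)
        ds = [r.d_pct for r in ld_scan(pairs, freqs, 0.0)]
        assert ds == sorted(ds, reverse=True)

    def test_observed_pcts_sum_to_100(self, ref_cohort):
        for locus in ("A", "B", "DRB1"):
            pairs = genotype_pair_frequencies(ref_cohort, locus, 1)
            freqs = count_alleles(ref_cohort, locus, 1)
            total = sum(r.observed_pct for r in ld_scan(pairs, freqs, -100.0))
            assert total == pytest.approx(100.0)
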