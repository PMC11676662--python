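import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hlacc.allele_stats import AlleleCountTable, count_alleles
from hlacc.association import (
    ContingencyTable,
    associate_allele_set,
    bh_adjust,
    build_contingency,
    chi_square_2x2,
    compare_carrier_phenotypes,
    format_p,
    odds_ratio_ci,
    one_sample_proportion_z,
)
from hlacc.nomenclature import parse_allele_name
from hlacc.refdata import TABLE3_TRAITS


class TestBuildContingency:
    def test_rounded_control_count_uncorrected(self):
        t = build_contingency(2, 80, 0.0008, 2468)
        assert t.cells == (2, 78, 2, 2466)
        assert not t.corrected
        # oracle: these cells reproduce the published OR 31.6154
        assert odds_ratio_ci(t)[0] == pytest.approx(31.6154, abs=5e-5)

    def test_rounding_to_nearest(self):
        t = build_contingency(13, 80, 0.0644, 2468)
        assert t.c == 159  # 158.9392 -> 159
        assert odds_ratio_ci(t)[0] == pytest.approx(2.8177, abs=5e-5)

    def test_zero_cell_triggers_correction(self):
        t = build_contingency(2, 80, 0.0, 12020)
        assert t.cells == (2.5, 78.5, 0.5, 12020.5)
        assert t.corrected
        assert odds_ratio_ci(t)[0] == pytest.approx(765.6369, abs=5e-5)

    def test_zero_case_count_corrected(self):
        t = build_contingency(0, 60, 0.0004, 2468)
        assert t.cells == (0.5, 60.5, 1.5, 2467.5)
        assert odds_ratio_ci(t)[0] == pytest.approx(13.5950, abs=5e-5)

    def test_ties_round_half_up(self):
        t = build_contingency(10, 80, 0.5, 3)  # 1.5 -> 2
        assert t.c == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_contingency(2, 80, 0.1, 0)
        with pytest.raises(ValueError):
            build_contingency(81, 80, 0.1, 100)
        with pytest.raises(ValueError):
            build_contingency(2, 80, 1.5, 100)


class TestOddsRatioCI:
    def test_published_corrected_table(self):
        or_, lo, hi, z, p = odds_ratio_ci(ContingencyTable(2.5, 78.5, 0.5, 12020.5, True))
        assert round(or_, 4) == 765.6369
        assert round(lo, 4) == 36.4590
        assert round(hi, 4) == 16078.3238
        assert round(z, 3) == 4.275
        assert p < 1e-4

    def test_published_uncorrected_table(self):
        or_, *_ = odds_ratio_ci(ContingencyTable(1, 79, 2081, 11791))
        assert round(or_, 4) == 0.0717

    def test_balanced_table(self):
        or_, lo, hi, z, p = odds_ratio_ci(ContingencyTable(10, 10, 10, 10))
        assert or_ == 1.0
        assert lo == pytest.approx(1 / hi)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio_ci(ContingencyTable(0, 10, 10, 10))

    @given(
        st.integers(1, 500), st.integers(1, 500),
        st.integers(1, 500), st.integers(1, 500),
    )
    def test_transposition_inverts(self, a, b, c, d):
        or1, lo1, hi1, z1, _ = odds_ratio_ci(ContingencyTable(a, b, c, d))
        or2, lo2, hi2, z2, _ = odds_ratio_ci(ContingencyTable(c, d, a, b))
        assert or2 == pytest.approx(1 / or1)
        assert lo2 == pytest.approx(1 / hi1)
        assert hi2 == pytest.approx(1 / lo1)
        assert z2 == pytest.approx(-z1)


class TestChiSquare:
    def test_published_carrier_pvalues(self):
        _, p = chi_square_2x2(ContingencyTable(5, 3, 6, 26), yates=True)
        assert round(p, 3) == 0.042
        _, p = chi_square_2x2(ContingencyTable(8, 0, 24, 8), yates=True)
        assert round(p, 2) == 0.28

    def test_equal_proportions(self):
        chi2, p = chi_square_2x2(ContingencyTable(10, 10, 10, 10))
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_marginal_flagged_not_raised(self):
        chi2, p = chi_square_2x2(ContingencyTable(0, 10, 0, 10))
        assert math.isnan(chi2) and math.isnan(p)

    @given(
        st.integers(1, 200), st.integers(1, 200),
        st.integers(1, 200), st.integers(1, 200),
    )
    def test_matches_closed_form(self, a, b, c, d):
        chi2, _ = chi_square_2x2(ContingencyTable(a, b, c, d))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed)

    @given(
        st.integers(1, 200), st.integers(1, 200),
        st.integers(1, 200), st.integers(1, 200),
    )
    def test_matches_scipy(self, a, b, c, d):
        for yates in (False, True):
            chi2, p = chi_square_2x2(ContingencyTable(a, b, c, d), yates=yates)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=yates)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_type_i_error_under_null(self):
        # case and control allele counts drawn from the same frequency
        rng = np.random.default_rng(20_240)
        p0, n_case, n_ctrl, reps = 0.10, 160, 12_000, 1000
        rejections = 0
        a_draws = rng.binomial(n_case, p0, size=reps)
        c_draws = rng.binomial(n_ctrl, p0, size=reps)
        for a, c in zip(a_draws, c_draws):
            _, p = chi_square_2x2(
                ContingencyTable(int(a), n_case - int(a), int(c), n_ctrl - int(c))
            )
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestOneSampleZ:
    def test_published_values(self):
        _, p = one_sample_proportion_z(1, 80, 0.001)
        assert round(p, 3) == 0.001
        _, p = one_sample_proportion_z(2, 80, 0.093)
        assert round(p, 3) == 0.036

    def test_null_gives_p_one(self):
        z, p = one_sample_proportion_z(8, 80, 0.1)
        assert z == 0.0
        assert p == 1.0

    def test_degenerate_p0_rejected(self):
        with pytest.raises(ValueError):
            one_sample_proportion_z(1, 80, 0.0)
        with pytest.raises(ValueError):
            one_sample_proportion_z(1, 80, 1.0)


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_ties_share_value(self):
        out = bh_adjust([0.04, 0.04, 0.04, 0.04])
        assert len(set(round(x, 12) for x in out)) == 1

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, ps):
        expected = multipletests(ps, method="fdr_bh")[1]
        assert bh_adjust(ps) == pytest.approx(list(expected), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms())
    def test_permutation_invariant(self, ps, rnd):
        base = dict(zip(range(len(ps)), bh_adjust(ps)))
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        shuffled = bh_adjust([ps[i] for i in idx])
        for pos, i in enumerate(idx):
            assert shuffled[pos] == pytest.approx(base[i])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_and_dominates_raw(self, ps):
        out = bh_adjust(ps)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        for lo, hi in zip(order, order[1:]):
            assert out[lo] <= out[hi] + 1e-12
        for raw, adj in zip(ps, out):
            assert adj >= raw - 1e-12
            assert adj <= 1.0


class TestAssociateAlleleSet:
    def test_published_corrected_or(self, ref_cohort, panel_lowres):
        table = count_alleles(ref_cohort, "B", 1)
        results = {str(r.allele): r for r in associate_allele_set(table, panel_lowres)}
        r = results["B*47"]
        assert round(r.odds_ratio, 4) == 765.6369
        assert r.zero_cell_corrected
        assert r.yates

    def test_dsn_subgroup_or(self, dsn_cohort, panel_lowres):
        table = count_alleles(dsn_cohort, "B", 1)
        results = {str(r.allele): r for r in associate_allele_set(table, panel_lowres)}
        assert round(results["B*47"].odds_ratio, 4) == 2060.6571

    def test_identical_frequencies_give_null_result(self):
        from hlacc.cohort import FrequencyPanel, LocusPanel

        allele = parse_allele_name("B*08")
        other = parse_allele_name("B*44")
        case = AlleleCountTable("B", 1, {allele: 10, other: 90}, 100)
        panel = FrequencyPanel("null", 1, {
            "B": LocusPanel(10_000, {allele: 0.10, other: 0.90}),
        })
        results = {str(r.allele): r for r in associate_allele_set(case, panel)}
        r = results["B*08"]
        assert r.odds_ratio == pytest.approx(1.0, rel=1e-2)
        assert r.p > 0.5

    def test_resolution_mismatch_rejected(self, ref_cohort, panel_highres):
        table = count_alleles(ref_cohort, "B", 1)
        with pytest.raises(ValueError, match="resolution"):
            associate_allele_set(table, panel_highres)

    def test_results_sorted_and_union(self, ref_cohort, panel_lowres):
        table = count_alleles(ref_cohort, "B", 1)
        results = associate_allele_set(table, panel_lowres)
        names = [str(r.allele) for r in results]
        assert names == sorted(names)
        # B*14 only in the panel; B*73 carried but 0.00% there: both present
        assert "B*14" in names and "B*73" in names

    def test_corrected_p_dominates_raw(self, ref_cohort, panel_lowres):
        table = count_alleles(ref_cohort, "DRB1", 1)
        for r in associate_allele_set(table, panel_lowres):
            if not math.isnan(r.p):
                assert r.p_corrected >= r.p - 1e-12

    def test_ci_brackets_or(self, ref_cohort, panel_lowres):
        table = count_alleles(ref_cohort, "A", 1)
        for r in associate_allele_set(table, panel_lowres):
            assert r.ci_low <= r.odds_ratio <= r.ci_high
            assert r.odds_ratio > 0


class TestCarrierPhenotypes:
    def test_published_comparison(self, ref_cohort):
        results = {r.trait: r for r in
                   compare_carrier_phenotypes(ref_cohort, "B*40", TABLE3_TRAITS)}
        auto = results["autoimmune_comorbidity"]
        assert (auto.carriers_with, auto.carriers_total) == (5, 8)
        assert (auto.noncarriers_with, auto.noncarriers_total) == (6, 32)
        assert round(auto.p, 3) == 0.042
        fem = results["female"]
        assert (fem.carriers_with, fem.noncarriers_with) == (8, 24)
        assert round(fem.p, 2) == 0.28

    def test_degenerate_trait_flagged(self, ref_cohort):
        results = compare_carrier_phenotypes(
            ref_cohort, "B*40", [("always", lambda m: True)]
        )
        assert results[0].degenerate
        assert math.isnan(results[0].p)

    def test_requires_both_groups(self, ref_cohort):
        with pytest.raises(ValueError, match="carrier"):
            compare_carrier_phenotypes(ref_cohort, "B*14", TABLE3_TRAITS)

    def test_null_trait_p_uniformish(self):
        # independent trait in a balanced synthetic cohort: p should not
        # concentrate near 0 under repetition
        from hlacc.cohort import GenotypeRecord, SubjectMeta

        rng = np.random.default_rng(7)
        small = []
        reps = 200
        for rep in range(reps):
            cohort = []
            carrier_geno = (parse_allele_name("B*40"), parse_allele_name("B*08"))
            other_geno = (parse_allele_name("B*44"), parse_allele_name("B*08"))
            traits = rng.random(40) < 0.5
            carriers = rng.random(40) < 0.5
            for i in range(40):
                sid = f"S{i}"
                record = GenotypeRecord(sid, {"B": carrier_geno if carriers[i] else other_geno})
                meta = SubjectMeta(sid, "F" if traits[i] else "M", 30, "EOMG",
                                   "IIA", "RAchPos", "normal_ct", False)
                cohort.append((record, meta))
            if not (0 < carriers.sum() < 40 and 0 < traits.sum() < 40):
                continue
            res = compare_carrier_phenotypes(cohort, "B*40",
                                             [("female", lambda m: m.sex == "F")])[0]
            small.append(res.p < 0.05)
        # Yates makes the test conservative; rejection rate must stay small
        assert np.mean(small) <= 0.07


class TestFormatting:
    def test_format_p(self):
        assert format_p(0.12345) == "0.1235"
        assert format_p(9e-6) == "< 0.00001"
        assert format_p(float("nan")) == "NA"
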