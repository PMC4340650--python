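"""Generation accounting, Fisher exact, ANOVA, CV, correlation, coexistence."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import diauxkit as dk
from diauxkit import stats as dst
from diauxkit.errors import DegenerateDataError, ParameterError


def brute_force_fisher(table):
    """Enumerate all 2x2 tables with the observed margins; tails from
    exact rational hypergeometric masses."""
    a, b = table[0]
    c, d = table[1]
    N, K, n = a + b + c + d, a + b, a + c
    k_lo, k_hi = max(0, K + n - N), min(K, n)
    total = comb(N, n)
    masses = {k: comb(K, k) * comb(N - K, n - k) for k in
              range(k_lo, k_hi + 1)}
    p_greater = sum(m for k, m in masses.items() if k >= a) / total
    p_less = sum(m for k, m in masses.items() if k <= a) / total
    return p_greater, p_less


class TestGenerationAccounting:
    @pytest.mark.parametrize("dilution, expected", [
        (512.0, 9.0), (1.0, 0.0), (8.0, 3.0),
    ])
    def test_generations_per_passage(self, dilution, expected):
        assert dst.generations_per_passage(dilution) == expected

    def test_protocol_dilution_from_volumes(self):
        """1.25 ul into 640 ul is a 512-fold dilution."""
        assert 640.0 / 1.25 == 512.0
        assert dst.generations_per_passage(640.0 / 1.25) == 9.0

    @pytest.mark.parametrize("n, dilution, expected", [
        (113, 512.0, 1017.0), (0, 512.0, 0.0), (10, 1024.0, 100.0),
    ])
    def test_total_generations(self, n, dilution, expected):
        assert dst.total_generations(n, dilution) == expected

    def test_additive_over_concatenation(self):
        assert dst.total_generations(70, 512) + dst.total_generations(
            43, 512) == dst.total_generations(113, 512)

    def test_dilution_below_one_rejected(self):
        with pytest.raises(ParameterError):
            dst.generations_per_passage(0.5)


class TestFisherExact:
    def test_diauxie_contingency_reproduces_published_p(self):
        """48/0 vs 36/12 with/without diauxie: one-sided tail 1.12e-4."""
        table = dst.DiauxieContingency(("W", "Z"), (48, 36), (0, 12))
        res = dst.fisher_exact_one_sided(table)
        assert f"{res.p_one_sided:.3g}" == "0.000112"
        assert res.p_one_sided == pytest.approx(1.12e-4, rel=5e-3)

    def test_single_extreme_table_point_mass(self):
        """All successes in one group of a 5+5 balanced design:
        p = 1/C(10,5)."""
        res = dst.fisher_exact_one_sided([[5, 0], [0, 5]])
        assert res.p_one_sided == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_brute_force_enumeration_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            tab = [[a, b], [c, d]]
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                continue
            res = dst.fisher_exact_one_sided(tab)
            pg, pl = brute_force_fisher(tab)
            assert res.p_greater == pytest.approx(pg, rel=1e-9)
            assert res.p_less == pytest.approx(pl, rel=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_matches_scipy_directed_tails(self, cells):
        a, b, c, d = cells
        res = dst.fisher_exact_one_sided([[a, b], [c, d]])
        if res.degenerate:
            assert a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0
            return
        _, p_greater = sps.fisher_exact([[a, b], [c, d]],
                                        alternative="greater")
        _, p_less = sps.fisher_exact([[a, b], [c, d]], alternative="less")
        assert res.p_greater == pytest.approx(p_greater, rel=1e-7)
        assert res.p_less == pytest.approx(p_less, rel=1e-7)

    def test_zero_margin_degenerate(self):
        res = dst.fisher_exact_one_sided([[0, 0], [3, 4]])
        assert res.degenerate and res.p_one_sided == 1.0


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        res = dst.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        """Groups (1,2,3) and (2,3,4): SSB=1.5, SSW=4, F=1.5."""
        res = dst.one_way_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert res.f == pytest.approx(1.5)
        assert res.p == pytest.approx(float(sps.f.sf(1.5, 1, 4)))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            dst.one_way_anova([[2.0, 2.0], [2.0, 2.0]])

    def test_null_rejection_rate_near_alpha(self):
        """12 groups drawn from one normal: rejection at 5% stays within
        alpha +/- 2% over 1000 simulations."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(1000):
            groups = rng.normal(0.9, 0.1, size=(12, 4))
            rejections += dst.one_way_anova(list(groups)).p <= 0.05
        assert 30 <= rejections <= 70


class TestNestedAnova:
    @staticmethod
    def cohort(rng, n_groups=2, n_iso=4, n_rep=3, group_effect=0.0,
               iso_sd=0.1, rep_sd=0.05):
        rows = []
        for gi in range(n_groups):
            gmean = gi * group_effect
            for ii in range(n_iso):
                imean = gmean + rng.normal(0, iso_sd)
                for ri in range(n_rep):
                    rows.append({"population": f"g{gi}",
                                 "isolate": f"i{ii}",
                                 "value": imean + rng.normal(0, rep_sd)})
        return pd.DataFrame(rows)

    def test_matches_statsmodels_decomposition(self):
        """F for the group factor against the isolate stratum agrees with
        an independent statsmodels Type-I decomposition."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = self.cohort(np.random.default_rng(5), group_effect=0.15)
        mine = dst.nested_anova(df)
        fit = smf.ols("value ~ C(population) + C(population):C(isolate)",
                      data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        ms_group = tab.loc["C(population)", "sum_sq"] / \
            tab.loc["C(population)", "df"]
        ms_iso = tab.loc["C(population):C(isolate)", "sum_sq"] / \
            tab.loc["C(population):C(isolate)", "df"]
        f_ref = ms_group / ms_iso
        p_ref = float(sps.f.sf(f_ref, int(tab.loc["C(population)", "df"]),
                               int(tab.loc["C(population):C(isolate)",
                                           "df"])))
        assert mine.f == pytest.approx(f_ref, rel=1e-9)
        assert mine.p == pytest.approx(p_ref, rel=1e-9)

    def test_all_identical_values_degenerate_path(self):
        df = self.cohort(np.random.default_rng(0), iso_sd=0.0, rep_sd=0.0)
        res = dst.nested_anova(df)
        assert res.degenerate
        assert res.p == 1.0

    def test_power_with_injected_group_effect(self):
        """A one-isolate-sd group effect is detected in >= 80% of
        simulated balanced designs."""
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(200):
            df = self.cohort(rng, n_iso=6, group_effect=0.2, iso_sd=0.1)
            hits += dst.nested_anova(df).p <= 0.05
        assert hits >= 160

    def test_null_calibrated_despite_isolate_effect(self):
        """Strong isolate heterogeneity, zero group effect: the nesting
        absorbs isolate variance and rejects near alpha."""
        rng = np.random.default_rng(31)
        rejections = 0
        for _ in range(1000):
            df = self.cohort(rng, group_effect=0.0, iso_sd=0.3,
                             rep_sd=0.02)
            rejections += dst.nested_anova(df).p <= 0.05
        assert 30 <= rejections <= 70

    def test_single_isolate_group_rejected(self):
        df = pd.DataFrame({"population": ["a", "a", "b", "b"],
                           "isolate": ["i1", "i1", "i2", "i3"],
                           "value": [1.0, 1.1, 2.0, 2.1]})
        with pytest.raises(ParameterError):
            dst.nested_anova(df)


class TestCvAndCorrelation:
    def test_cv_simple_cases(self):
        assert dst.coefficient_of_variation([0.5, 1.0, 1.5]) == \
            pytest.approx(50.0)
        assert dst.coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_cv_recovery_on_synthetic_cohort(self):
        """A cohort generated at CV 23.4% is recovered within sampling
        error across seeds."""
        rng = np.random.default_rng(77)
        cvs = [dst.coefficient_of_variation(rng.normal(0.8, 0.8 * 0.234,
                                                       size=48))
               for _ in range(50)]
        assert np.mean(cvs) == pytest.approx(23.4, abs=2.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ParameterError):
            dst.coefficient_of_variation([-1.0, 1.0])

    def test_perfect_line_pearson(self):
        r, p = dst.correlate([1, 2, 3, 4], [2, 4, 6, 8], "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinear_rank_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp(x)
        rho, _ = dst.correlate(x, y, "spearman")
        r, _ = dst.correlate(x, y, "pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_small_n_spearman_matches_permutation_enumeration(self):
        """n=5 Spearman p equals the exhaustive permutation tail."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho_obs, p = dst.correlate(x, y, "spearman")
        rhos = []
        for perm in itertools.permutations(y):
            rhos.append(sps.spearmanr(x, perm).statistic)
        rhos = np.array(rhos)
        exact = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert p == pytest.approx(exact, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            dst.correlate([1, 1, 1], [1, 2, 3])


class TestFrequencyFromCounts:
    def test_fraction_and_flag(self):
        res = dst.frequency_from_counts(4500, 45000)
        assert res.fraction == pytest.approx(0.10)
        assert not res.low_counts
        assert dst.frequency_from_counts(10, 100).low_counts

    def test_zero_count_boundary(self):
        res = dst.frequency_from_counts(0, 45000)
        assert res.fraction == 0.0
        assert res.ci_low == 0.0
        assert res.ci_high > 0.0

    def test_wilson_interval_coverage(self):
        """Simulated counts at true fraction 0.12: the interval covers
        truth in >= 93 of 100 draws."""
        rng = np.random.default_rng(9)
        cover = 0
        for _ in range(100):
            k = rng.binomial(45000, 0.12)
            res = dst.frequency_from_counts(int(k), 45000)
            cover += res.ci_low <= 0.12 <= res.ci_high
        assert cover >= 93

    def test_focal_above_total_rejected(self):
        with pytest.raises(ParameterError):
            dst.frequency_from_counts(10, 5)


class TestCoexistenceCall:
    @staticmethod
    def traj(fractions, dilution=512.0):
        f = np.asarray(fractions, dtype=float)
        return dst.CompetitionTrajectory(
            passages=np.arange(1, len(f) + 1), focal_fraction=f,
            counts=None, dilution=dilution)

    def test_constant_half_is_coexistence(self):
        call = dst.coexistence_call(self.traj([0.5] * 6))
        assert call.verdict == "coexistence"
        assert call.level == pytest.approx(0.5)

    def test_collapse_to_zero_is_exclusion(self):
        call = dst.coexistence_call(self.traj([0.4, 0.1, 0.02, 0.005, 0.0]))
        assert call.verdict == "exclusion"

    def test_short_trajectory_undecided(self):
        call = dst.coexistence_call(self.traj([0.5, 0.5]), tail_passages=3)
        assert call.verdict == "undecided"

    def test_unsettled_tail_undecided(self):
        call = dst.coexistence_call(self.traj([0.9, 0.6, 0.4, 0.2]),
                                    band=0.1)
        assert call.verdict == "undecided"

    def test_relabeling_symmetry(self):
        """Mapping f -> 1-f maps coexistence to coexistence and exclusion
        of the focal to exclusion of the competitor."""
        f = np.array([0.12, 0.115, 0.118, 0.117])
        a = dst.coexistence_call(self.traj(f))
        b = dst.coexistence_call(self.traj(1 - f))
        assert a.verdict == b.verdict == "coexistence"
        assert a.level == pytest.approx(1 - b.level)
        lost = np.array([0.3, 0.05, 0.008, 0.001])
        assert dst.coexistence_call(self.traj(lost)).verdict == "exclusion"
        assert dst.coexistence_call(self.traj(1 - lost)).verdict == \
            "exclusion"
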