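import numpy as np
import pytest
from scipy import stats as sps

from dgephys import stats as st


class TestMeanSE:
    def test_constant_sample(self):
        r = st.mean_se([2.0, 2.0, 2.0])
        assert (r.n, r.mean, r.se) == (3, 2.0, 0.0)

    def test_hand_formula(self):
        # sd({1,2,3}) = 1, se = 1/sqrt(3) = 0.5774
        r = st.mean_se([1.0, 2.0, 3.0])
        assert r.mean == 2.0
        assert r.se == pytest.approx(0.57735, abs=1e-4)

    def test_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        a, b = st.mean_se(x), st.mean_se(3.5 * x)
        assert b.mean == pytest.approx(3.5 * a.mean)
        assert b.se == pytest.approx(3.5 * a.se)

    def test_single_observation_flagged(self):
        r = st.mean_se([4.0])
        assert r.se == 0.0 and "n1" in r.flags


class TestOneProportionZ:
    @pytest.mark.parametrize(
        "x,n,z,pmax",
        [
            (19, 27, 2.117, 0.019),   # type I majority in the wild-type cohort
            (18, 31, 0.898, 0.19),    # near-even split in the disease cohort
            (26, 37, 2.466, 0.007),
            (16, 24, 1.633, 0.052),
        ],
    )
    def test_reference_proportions(self, x, n, z, pmax):
        r = st.one_proportion_z(x, n)
        assert r.statistic == pytest.approx(z, abs=5e-4)
        assert r.p_value < pmax

    def test_even_split(self):
        r = st.one_proportion_z(10, 20)
        assert r.statistic == 0.0
        assert r.p_value == 0.5

    def test_antisymmetry(self):
        for x, n in [(3, 10), (7, 9), (0, 5)]:
            assert st.one_proportion_z(x, n).statistic == pytest.approx(
                -st.one_proportion_z(n - x, n).statistic
            )

    def test_two_sided_doubles(self):
        one = st.one_proportion_z(19, 27, sided="one")
        two = st.one_proportion_z(19, 27, sided="two")
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            st.one_proportion_z(5, 0)
        with pytest.raises(ValueError):
            st.one_proportion_z(5, 4)


class TestStudentT:
    def test_identical_samples(self):
        r = st.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_textbook_pair(self):
        # pooled sd = 1, t = -1/sqrt(2/3) = -1.2247, df = 4
        r = st.two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert r.df == (4,)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 2, 9)
        r = st.two_sample_t(a, b)
        ref = sps.ttest_ind(a, b)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_zero_variance(self):
        r = st.two_sample_t([5.0, 5.0], [5.0, 5.0])
        assert r.p_value == 1.0 and "degenerate" in r.flags


class TestAnova:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        r = st.one_way_anova([g, g, g])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_brute_force_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [5.0, 6.0, 7.0]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_expected = (ssb / 2) / (ssw / 6)
        r = st.one_way_anova(groups)
        assert r.statistic == pytest.approx(f_expected)
        assert r.df == (2, 6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        r1 = st.one_way_anova(groups)
        r2 = st.one_way_anova([2.5 * g - 7 for g in groups])
        assert r2.statistic == pytest.approx(r1.statistic)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, n) for n in (6, 11, 8)]
        r = st.one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


class TestKruskalWallis:
    def test_identical_constants(self):
        r = st.kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
        assert r.statistic == 0.0

    def test_brute_force_ranks(self):
        # groups occupy rank blocks {1,2},{3,4},{5,6}: H by the rank formula
        groups = [[0.1, 0.2], [1.1, 1.2], [2.1, 2.2]]
        n, N = 2, 6
        rbars = [1.5, 3.5, 5.5]
        h = 12 / (N * (N + 1)) * sum(n * (r - 3.5) ** 2 for r in rbars)
        r = st.kruskal_wallis(groups)
        assert r.statistic == pytest.approx(h)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i, 1, 7) for i in range(3)]
        r1 = st.kruskal_wallis(groups)
        r2 = st.kruskal_wallis([np.exp(g) for g in groups])
        assert r2.statistic == pytest.approx(r1.statistic)

    def test_matches_scipy_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 3.0], [2.0, 3.0, 4.0, 4.0], [5.0, 5.0, 6.0, 7.0]]
        r = st.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


class TestDunnett:
    def test_k2_reduces_to_pooled_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        ph = st.dunnett_posthoc([a, b], 0, n_mc=400_000, seed=1)
        ref = st.two_sample_t(b, a)
        assert ph.comparisons[0].statistic == pytest.approx(ref.statistic)
        assert ph.comparisons[0].p_adjusted == pytest.approx(ref.p_value, abs=0.005)

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(0, 1, 12)
        t1, t2 = rng.normal(0.5, 1, 9), rng.normal(-0.3, 1, 15)
        ph = st.dunnett_posthoc([ctrl, t1, t2], 0, n_mc=400_000, seed=2)
        ref = sps.dunnett(t1, t2, control=ctrl)
        for comp, t_ref, p_ref in zip(ph.comparisons, ref.statistic, ref.pvalue):
            assert comp.statistic == pytest.approx(t_ref, abs=1e-8)
            assert comp.p_adjusted == pytest.approx(p_ref, abs=0.01)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.0, -0.5)]
        ph = st.dunnett_posthoc(groups, 0, seed=3)
        for comp in ph.comparisons:
            assert comp.p_adjusted >= comp.p_unadjusted

    def test_critical_value_seed_stability(self):
        c1 = st.dunnett_critical_value([10, 10, 10], 0, 27, n_mc=1_000_000, seed=1)
        c2 = st.dunnett_critical_value([10, 10, 10], 0, 27, n_mc=1_000_000, seed=99)
        assert c1 == pytest.approx(c2, abs=2e-3)


class TestFisherLSD:
    def test_two_groups_equal_pooled_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        ph = st.fisher_lsd([a, b], 0)
        ref = st.two_sample_t(b, a)
        assert ph.comparisons[0].statistic == pytest.approx(ref.statistic)
        assert ph.comparisons[0].p_adjusted == pytest.approx(ref.p_value)

    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0]
        ph = st.fisher_lsd([g, g, g], 0)
        assert all(c.p_adjusted == pytest.approx(1.0) for c in ph.comparisons)

    def test_lsd_not_above_dunnett(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.7, -0.4)]
        lsd = st.fisher_lsd(groups, 0)
        dun = st.dunnett_posthoc(groups, 0, seed=4)
        for a, b in zip(lsd.comparisons, dun.comparisons):
            assert a.p_adjusted <= b.p_adjusted + 1e-12


class TestDunn:
    def test_equal_mean_ranks(self):
        r = st.dunn_posthoc([[1.0, 4.0], [2.0, 3.0]], 0)
        assert r.comparisons[0].statistic == pytest.approx(0.0)

    def test_brute_force_three_groups(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        # ranks 1..6, no ties: var_core = N(N+1)/12 = 3.5
        z12 = (3.5 - 1.5) / np.sqrt(3.5 * (1 / 2 + 1 / 2))
        z13 = (5.5 - 1.5) / np.sqrt(3.5)
        r = st.dunn_posthoc(groups, 0)
        assert r.comparisons[0].statistic == pytest.approx(z12)
        assert r.comparisons[1].statistic == pytest.approx(z13)

    def test_bonferroni_multiplies(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(m, 1, 9) for m in (0, 0.5, 1.5)]
        plain = st.dunn_posthoc(groups, 0, adjust="none")
        bonf = st.dunn_posthoc(groups, 0, adjust="bonferroni")
        for a, b in zip(plain.comparisons, bonf.comparisons):
            assert b.p_adjusted == pytest.approx(min(1.0, 2 * a.p_adjusted))

    def test_tie_correction_term(self):
        # with heavy ties the tie term must shrink the denominator
        tied = [[1.0, 1.0, 1.0], [1.0, 2.0, 2.0], [2.0, 3.0, 3.0]]
        free = [[1.0, 1.1, 1.2], [1.3, 2.0, 2.1], [2.2, 3.0, 3.1]]
        zt = st.dunn_posthoc(tied, 0).comparisons[1].statistic
        zf = st.dunn_posthoc(free, 0).comparisons[1].statistic
        assert abs(zt) > 0 and abs(zf) > 0  # both defined despite ties


class TestInputOrderInvariance:
    def test_group_order_only_relabels(self):
        rng = np.random.default_rng(12)
        a, b, c = (rng.normal(m, 1, 8) for m in (0, 1, 2))
        f1 = st.one_way_anova([a, b, c]).statistic
        f2 = st.one_way_anova([c, a, b]).statistic
        assert f1 == pytest.approx(f2)
        h1 = st.kruskal_wallis([a, b, c]).statistic
        h2 = st.kruskal_wallis([b, c, a]).statistic
        assert h1 == pytest.approx(h2)
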