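import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genefabric import (
    CorPair,
    GeneProfile,
    chi2_midinterval_factor,
    classify_pair,
    classify_pairs,
    compute_ave,
    compute_cor,
    compute_pooled_cv,
    compute_rev,
    coordination_score,
    cor_matrix,
)
from genefabric.expression import DegenerateInputError

from conftest import QUADRUPLES, brute_pearson


def profile(values, gene="g", condition="CO"):
    return GeneProfile(gene=gene, condition=condition, spot_ids=["s1"],
                       spot_values=np.asarray([values], dtype=float))


class TestAve:
    @pytest.mark.parametrize("gene", ["A", "B", "C", "D"])
    def test_quadruples_share_ave_100(self, toy_profiles, gene):
        assert compute_ave(toy_profiles[gene]) == pytest.approx(100.0)

    def test_mean_over_spots(self):
        p = GeneProfile("g", "CO", ["s1", "s2"],
                        np.array([[10.0] * 4, [30.0] * 4]))
        assert compute_ave(p) == pytest.approx(20.0)


class TestPooledCv:
    @pytest.mark.parametrize(
        "gene,cv", [("A", 0.0365), ("B", 0.1787), ("C", 0.0440), ("D", 0.0346)]
    )
    def test_quadruple_cvs(self, toy_profiles, gene, cv):
        assert compute_pooled_cv(toy_profiles[gene]) == pytest.approx(cv, abs=5e-5)

    def test_constant_profile_is_zero(self):
        assert compute_pooled_cv(profile([5, 5, 5, 5])) == 0.0

    def test_zero_mean_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_pooled_cv(profile([0, 0, 0, 0]))

    def test_pooled_over_two_spots(self):
        p = GeneProfile("g", "CO", ["s1", "s2"],
                        np.array([[96, 98, 102, 104], [87, 83, 110, 120]], float))
        cv1 = compute_pooled_cv(profile([96, 98, 102, 104]))
        cv2 = compute_pooled_cv(profile([87, 83, 110, 120]))
        assert compute_pooled_cv(p) == pytest.approx(math.sqrt((cv1**2 + cv2**2) / 2))


class TestChi2Factor:
    # chi-square quantiles for df=3 from an independent statistics table
    CHI2_3_HI, CHI2_3_LO = 9.3484, 0.21580

    def test_sqrt_variant_df3(self):
        expected = 0.5 * (math.sqrt(3 / self.CHI2_3_HI) + math.sqrt(3 / self.CHI2_3_LO))
        assert chi2_midinterval_factor(3) == pytest.approx(expected, rel=1e-4)
        assert chi2_midinterval_factor(3) == pytest.approx(2.148, abs=5e-3)

    def test_linear_variant_df3(self):
        expected = 0.5 * (3 / self.CHI2_3_HI + 3 / self.CHI2_3_LO)
        assert chi2_midinterval_factor(3, "linear") == pytest.approx(expected, rel=1e-4)
        assert chi2_midinterval_factor(3, "linear") == pytest.approx(7.11, abs=5e-3)

    def test_large_df_limit(self):
        assert 1.0 < chi2_midinterval_factor(1000) < 1.05

    def test_strictly_decreasing_in_df(self):
        vals = [chi2_midinterval_factor(r) for r in range(1, 60)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            chi2_midinterval_factor(0)


class TestRev:
    def test_gene_a(self, toy_profiles):
        # factor(df=3) ~ 2.148 times CV 3.65% ~ 7.84%
        assert compute_rev(toy_profiles["A"]) == pytest.approx(7.84, abs=0.01)

    def test_constant_profile(self):
        assert compute_rev(profile([5, 5, 5, 5])) == 0.0

    def test_scale_invariance(self, toy_profiles):
        p = toy_profiles["B"]
        doubled = GeneProfile(p.gene, p.condition, p.spot_ids, p.spot_values * 2)
        assert compute_rev(doubled) == pytest.approx(compute_rev(p))

    @settings(deadline=None)
    @given(st.floats(min_value=1.01, max_value=10))
    def test_inflating_deviations_increases_rev(self, c):
        base = np.array([96.0, 98.0, 102.0, 104.0])
        wider = 100 + c * (base - 100)
        assert compute_rev(profile(wider)) > compute_rev(profile(base))

    def test_redundant_spots_extend_degrees_of_freedom(self):
        one = profile([96, 98, 102, 104])
        two = GeneProfile("g", "CO", ["s1", "s2"],
                          np.array([[96, 98, 102, 104]] * 2, float))
        # same pooled CV, but df 7 instead of 3 gives a smaller correction
        assert compute_rev(two) < compute_rev(one)
        assert compute_rev(two) == pytest.approx(
            chi2_midinterval_factor(7) * compute_pooled_cv(two) * 100
        )


class TestCor:
    def test_quadruple_pairs(self, toy_profiles):
        ab = compute_cor(toy_profiles["A"], toy_profiles["B"], log2=False)
        ac = compute_cor(toy_profiles["A"], toy_profiles["C"], log2=False)
        ad = compute_cor(toy_profiles["A"], toy_profiles["D"], log2=False)
        assert ab == pytest.approx(0.95, abs=5e-3)
        assert ac == pytest.approx(-0.997, abs=5e-4)
        assert ad == pytest.approx(0.0, abs=1e-12)

    def test_self_correlation_is_one(self, toy_profiles):
        for g in QUADRUPLES:
            assert compute_cor(toy_profiles[g], toy_profiles[g]) == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = profile(rng.lognormal(0, 1, size=4))
            b = profile(rng.lognormal(0, 1, size=4))
            got = compute_cor(a, b, log2=False)
            want = brute_pearson(a.replicate_values, b.replicate_values)
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry(self, toy_profiles):
        for a in QUADRUPLES:
            for b in QUADRUPLES:
                assert compute_cor(toy_profiles[a], toy_profiles[b]) == pytest.approx(
                    compute_cor(toy_profiles[b], toy_profiles[a]), abs=1e-14
                )

    def test_constant_profile_is_undefined_not_zero(self, toy_profiles):
        c = compute_cor(profile([5, 5, 5, 5]), toy_profiles["A"])
        assert math.isnan(c)

    def test_pooled_spots_mode_stays_bounded(self):
        rng = np.random.default_rng(1)
        a = GeneProfile("a", "CO", ["s1", "s2", "s3"], rng.lognormal(0, 1, (3, 4)))
        b = GeneProfile("b", "CO", ["s1"], rng.lognormal(0, 1, (1, 4)))
        c = compute_cor(a, b, mode="pooled_spots")
        assert -1.0 <= c <= 1.0

    def test_cor_matrix_matches_pairwise(self, toy_profiles):
        m = cor_matrix(toy_profiles, log2=False)
        for a in QUADRUPLES:
            for b in QUADRUPLES:
                want = compute_cor(toy_profiles[a], toy_profiles[b], log2=False)
                assert m.loc[a, b] == pytest.approx(want, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "cor,klass",
        [
            (0.95, "synergistic"),     # boundary inclusive
            (0.9499, "not_significant"),
            (-0.997, "antagonistic"),
            (0.0, "independent"),
            (0.05, "independent"),     # boundary inclusive
            (0.5, "not_significant"),
            (float("nan"), "not_significant"),
        ],
    )
    def test_threshold_rule(self, cor, klass):
        assert classify_pair(cor) == klass

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            classify_pair(0.5, sig_threshold=0.05, ind_threshold=0.95)


class TestCoordination:
    def test_all_synergistic_scores_100(self):
        pairs = [CorPair("a", "b", "CO", 0.99, "synergistic")] * 4
        assert coordination_score("S", "CO", pairs).coord == pytest.approx(100.0)

    def test_percentage_arithmetic(self):
        mk = lambda k, n: [CorPair("a", "b", "CO", 0.5, k)] * n
        pairs = (mk("synergistic", 5) + mk("antagonistic", 1)
                 + mk("independent", 2) + mk("not_significant", 2))
        cs = coordination_score("S", "CO", pairs)
        assert (cs.syn_pct, cs.ant_pct, cs.ind_pct) == (50.0, 10.0, 20.0)
        assert cs.coord == pytest.approx(40.0)

    def test_quadruple_set_matches_brute_force(self, toy_profiles):
        pairs = classify_pairs(toy_profiles, "CO", log2=False)
        cs = coordination_score("toy", "CO", pairs)
        # independent check: brute-force Pearson + the threshold rule
        genes = list(QUADRUPLES)
        classes = []
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                r = brute_pearson(QUADRUPLES[a], QUADRUPLES[b])
                if abs(r) >= 0.95:
                    classes.append("syn" if r > 0 else "ant")
                elif abs(r) <= 0.05:
                    classes.append("ind")
                else:
                    classes.append("ns")
        n = len(classes)
        assert cs.n_pairs == n == 6
        assert cs.syn_pct == pytest.approx(100 * classes.count("syn") / n)
        assert cs.ant_pct == pytest.approx(100 * classes.count("ant") / n)
        assert cs.ind_pct == pytest.approx(100 * classes.count("ind") / n)
        assert cs.coord == pytest.approx(cs.syn_pct + cs.ant_pct - cs.ind_pct)

    def test_empty_pair_list_is_error(self):
        with pytest.raises(DegenerateInputError):
            coordination_score("S", "CO", [])
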