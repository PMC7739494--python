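"""The mixture cognitive model: heuristics, weighting, likelihood, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import beastmix as bm
from beastmix.cognitive_model import _discretized_normal_logpmf


def gaussian_product_oracle(means, variances, n_grid=400_001, span=12.0):
    """Mean/variance of a normalized product of Gaussian densities by
    numerical integration on a fine grid (independent of the
    precision-weighting formula).

    The product is at least as concentrated as its tightest factor and
    its mean lies within the span of the factor means, so the grid covers
    that span padded by a few tightest-factor widths.
    """
    means = np.asarray(means, float)
    sds = np.sqrt(np.asarray(variances, float))
    lo = means.min() - span * sds.min()
    hi = means.max() + span * sds.min()
    x = np.linspace(lo, hi, n_grid)
    logd = sum(
        -0.5 * ((x - m) / s) ** 2 - np.log(s) for m, s in zip(means, sds)
    )
    d = np.exp(logd - logd.max())
    z = np.trapezoid(d, x)
    mean = np.trapezoid(x * d, x) / z
    var = np.trapezoid((x - mean) ** 2 * d, x) / z
    return mean, var


class TestHeuristics:
    def test_nearest_peer_distance_relative_units(self):
        assert bm.nearest_peer_distance(100, [132, 140, 148]) == (0.32, 0)
        assert bm.nearest_peer_distance(100, [100, 140, 180]) == (0.0, 0)
        d, i = bm.nearest_peer_distance(100, [90, 110])
        assert d == pytest.approx(0.1) and i == 0  # tie -> lower index

    def test_keep_probability_logistic(self):
        p = bm.IndividualParams(keep_intercept=0.0, keep_slope=-5.0)
        assert bm.keep_probability(0.0, p) == pytest.approx(0.5)
        p = bm.IndividualParams(keep_intercept=1.0, keep_slope=-5.0)
        assert bm.keep_probability(0.32, p) == pytest.approx(
            float(expit(-0.6)), abs=1e-12
        )

    def test_keeping_declines_with_distance_for_negative_slope(self):
        p = bm.IndividualParams(keep_intercept=0.5, keep_slope=-4.0)
        d = np.linspace(0, 1, 20)
        probs = [bm.keep_probability(x, p) for x in d]
        assert np.all(np.diff(probs) < 0)

    def test_branch_probabilities_form_simplex(self):
        p = bm.IndividualParams(keep_intercept=2.0, keep_slope=-1.0,
                                adopt_intercept=1.0, adopt_slope=-2.0)
        for d in (0.0, 0.2, 1.0, 5.0):
            pk, pa, pc = bm.branch_probabilities(d, p, bm.ModelSpec())
            assert pk + pa + pc == pytest.approx(1.0, abs=1e-12)
            assert min(pk, pa, pc) >= 0

    def test_feature_gating_zeroes_heuristics(self):
        p = bm.IndividualParams(keep_intercept=3.0, adopt_intercept=3.0)
        off = bm.ModelSpec(use_keep=False, use_adopt=False)
        pk, pa, pc = bm.branch_probabilities(0.1, p, off)
        assert pk == 0.0 and pa == 0.0 and pc == 1.0
        assert bm.adopt_probability(0.0, p, bm.ModelSpec(use_adopt=False)) == 0.0

    @given(d=st.floats(0, 2), ki=st.floats(-3, 3), ks=st.floats(-10, 1),
           ai=st.floats(-3, 3), aslope=st.floats(-10, 1))
    @settings(max_examples=100, deadline=None)
    def test_simplex_property(self, d, ki, ks, ai, aslope):
        p = bm.IndividualParams(keep_intercept=ki, keep_slope=ks,
                                adopt_intercept=ai, adopt_slope=aslope)
        pk, pa, pc = bm.branch_probabilities(d, p, bm.ModelSpec())
        assert pk + pa + pc == pytest.approx(1.0, abs=1e-9)
        assert pk >= 0 and pa >= 0 and pc >= -1e-12


class TestPeerWeighting:
    def test_equal_variances_without_features(self):
        p = bm.IndividualParams(var_base=0.0, var_conf=2.0, var_prox=2.0)
        spec = bm.ModelSpec(use_confirmation=False, use_proximity=False)
        v = [bm.peer_variance(i, 100, [110, 150, 190], p, spec) for i in range(3)]
        assert v == pytest.approx([1.0, 1.0, 1.0])

    def test_confirmation_penalizes_distant_peers(self):
        p = bm.IndividualParams(var_base=0.0, var_conf=2.0)
        spec = bm.ModelSpec(use_proximity=False)
        v1 = bm.peer_variance(0, 100, [110, 150, 190], p, spec)
        v3 = bm.peer_variance(2, 100, [110, 150, 190], p, spec)
        assert v1 < v3
        assert bm.peer_variance(0, 100, [140, 150, 190], p, spec) == pytest.approx(
            math.exp(0.8), rel=1e-12
        )

    def test_proximity_penalizes_outliers(self):
        p = bm.IndividualParams(var_base=0.0, var_prox=1.0)
        spec = bm.ModelSpec(use_confirmation=False)
        # peers 0,1 cluster; peer 2 stands apart
        v = [bm.peer_variance(i, 100, [120, 122, 180], p, spec) for i in range(3)]
        assert v[0] < v[2] and v[1] < v[2]


class TestCompromisePosterior:
    def test_equal_weights_recover_arithmetic_mean(self):
        p = bm.IndividualParams(log_sigma_E=math.log(0.3), var_base=2 * math.log(0.3))
        spec = bm.ModelSpec(use_confirmation=False, use_proximity=False)
        E1, X = 100, [110, 130, 180]
        mu, var = bm.compromise_posterior(E1, X, p, spec)
        assert mu == pytest.approx(np.mean([E1, *X]), rel=1e-12)
        s = bm.compute_s(E1, mu, X)
        assert s == pytest.approx(0.75, rel=1e-12)

    def test_two_source_symmetry(self):
        p = bm.IndividualParams(log_sigma_E=0.0, var_base=0.0)
        spec = bm.ModelSpec(use_confirmation=False, use_proximity=False)
        mu, var = bm.compromise_posterior(10, [20], p, spec)
        assert mu == pytest.approx(15.0)

    def test_posterior_mean_bounded_by_sources(self):
        rng = np.random.default_rng(3)
        p = bm.IndividualParams(var_conf=1.5, var_prox=0.5)
        for _ in range(50):
            E1 = int(rng.integers(20, 150))
            X = sorted(int(rng.integers(1, 200)) for _ in range(3))
            mu, var = bm.compromise_posterior(E1, X, p, bm.ModelSpec())
            assert min(E1, *X) - 1e-9 <= mu <= max(E1, *X) + 1e-9
            assert var > 0

    def test_matches_gaussian_product_oracle(self):
        rng = np.random.default_rng(7)
        spec = bm.ModelSpec()
        for _ in range(25):
            p = bm.IndividualParams(
                log_sigma_E=rng.uniform(-2.5, -0.5),
                var_base=rng.uniform(-4, -1),
                var_conf=rng.uniform(0, 3),
                var_prox=rng.uniform(0, 2),
            )
            E1 = int(rng.integers(30, 150))
            X = [int(rng.integers(10, 200)) for _ in range(int(rng.integers(1, 4)))]
            mu, var = bm.compromise_posterior(E1, X, p, spec)
            variances = [math.exp(2 * p.log_sigma_E) * E1**2] + [
                bm.peer_variance(i, E1, X, p, spec) * E1**2 for i in range(len(X))
            ]
            m_ref, v_ref = gaussian_product_oracle([E1, *X], variances)
            assert mu == pytest.approx(m_ref, rel=1e-6)
            assert var == pytest.approx(v_ref, rel=1e-6)


class TestControlPosterior:
    def test_equal_weights_give_peer_mean(self):
        p = bm.IndividualParams(var_prox=0.0)
        mu, var = bm.control_posterior([80, 100, 120, 140], p, bm.ModelSpec())
        assert mu == pytest.approx(110.0)

    def test_proximity_pulls_towards_cluster(self):
        p = bm.IndividualParams(var_base=-3.0, var_prox=2.0)
        mu, _ = bm.control_posterior([10, 10, 20, 30], p, bm.ModelSpec())
        assert mu < 17.5

    def test_requires_four_peers(self):
        with pytest.raises(ValueError, match="4 peers"):
            bm.control_posterior([10, 20, 30], bm.IndividualParams(), bm.ModelSpec())


class TestResponseDistribution:
    def _trial(self, E2=None):
        return bm.Trial("p", 1, "HN", 150, 100, (112, 140, 168), E2)

    def test_pmf_sums_to_one_for_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = bm.IndividualParams(
                keep_intercept=rng.normal(0, 2), keep_slope=rng.normal(-3, 3),
                adopt_intercept=rng.normal(-1, 2), adopt_slope=rng.normal(-2, 2),
                log_sigma_E=rng.normal(-2, 0.7), var_base=rng.normal(-3, 1),
                var_conf=rng.normal(1, 1), var_prox=rng.normal(0.5, 0.7),
                log_sigma_resp=rng.normal(-3, 0.7),
            )
            pmf = bm.response_distribution(self._trial(), p, bm.ModelSpec())
            assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
            assert (pmf >= 0).all()

    def test_loglik_consistent_with_pmf(self):
        p = bm.IndividualParams(keep_intercept=0.5, keep_slope=-4, var_conf=1.5)
        pmf = bm.response_distribution(self._trial(), p, bm.ModelSpec())
        for e2 in (100, 112, 120, 140, 1, 200):
            ll = bm.trial_loglik(self._trial(E2=e2), p, bm.ModelSpec())
            assert ll == pytest.approx(math.log(pmf[e2 - 1]), abs=1e-9)

    def test_certain_keeper_scores_zero_loglik(self):
        p = bm.IndividualParams(keep_intercept=500.0, keep_slope=0.0)
        ll = bm.trial_loglik(self._trial(E2=100), p, bm.ModelSpec())
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_pure_compromise_mode_at_four_estimate_mean(self):
        p = bm.IndividualParams(log_sigma_E=math.log(0.2),
                                var_base=2 * math.log(0.2),
                                log_sigma_resp=-4.0)
        spec = bm.ModelSpec(use_keep=False, use_adopt=False,
                            use_confirmation=False, use_proximity=False)
        t = self._trial()
        pmf = bm.response_distribution(t, p, spec)
        target = np.mean([t.E1, *t.X])
        assert abs((np.argmax(pmf) + 1) - target) <= 0.5

    def test_off_grid_response_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            bm.trial_loglik(self._trial(E2=250), bm.IndividualParams(), bm.ModelSpec())


class TestSimulateResponse:
    def test_certain_keeper_always_keeps(self):
        p = bm.IndividualParams(keep_intercept=500.0)
        t = bm.Trial("p", 1, "LN", 150, 100, (132, 140, 148), None)
        rng = np.random.default_rng(0)
        assert all(
            bm.simulate_response(t, p, bm.ModelSpec(), rng) == 100 for _ in range(20)
        )

    def test_seeded_runs_reproduce(self):
        p = bm.IndividualParams(keep_intercept=0.3, keep_slope=-3, var_conf=1.0)
        t = bm.Trial("p", 1, "HC", 150, 100, (120, 120, 180), None)
        a = [bm.simulate_response(t, p, bm.ModelSpec(), np.random.default_rng(42))
             for _ in range(5)]
        assert len(set(a)) == 1

    def test_frequencies_match_likelihood(self):
        # simulation and likelihood share one code path: empirical
        # frequencies must match the pmf within binomial error
        p = bm.IndividualParams(keep_intercept=0.0, keep_slope=-3,
                                var_conf=1.0, var_prox=0.5,
                                log_sigma_resp=math.log(0.08))
        spec = bm.ModelSpec(use_adopt=False)
        t = bm.Trial("p", 1, "HN", 150, 100, (112, 140, 168), None)
        rng = np.random.default_rng(123)
        n = 40_000
        draws = np.array([bm.simulate_response(t, p, spec, rng) for _ in range(n)])
        pmf = bm.response_distribution(t, p, spec)
        counts = np.bincount(draws, minlength=201)[1:]
        expected = n * pmf
        se = np.sqrt(np.maximum(n * pmf * (1 - pmf), 1e-12))
        check = expected > 5
        assert np.all(np.abs(counts[check] - expected[check]) <= 4 * se[check] + 3)


class TestModelFamilyStructure:
    def test_active_params_follow_feature_flags(self):
        full = bm.ModelSpec()
        assert len(full.active_params()) == 9
        null = bm.ModelSpec(False, False, False, False)
        assert null.active_params() == (
            "log_sigma_E", "var_base", "log_sigma_resp"
        )
        no_adopt = bm.ModelSpec(use_adopt=False)
        assert "adopt_intercept" not in no_adopt.active_params()
        assert no_adopt.label == "keep+conf+prox"

    def test_group_params_sampling_respects_gating(self):
        g = bm.default_group_params()
        spec = bm.ModelSpec(use_adopt=False, use_proximity=False)
        theta = g.sample_individuals(50, spec, np.random.default_rng(0))
        names = list(bm.PARAM_NAMES)
        assert np.all(theta[:, names.index("adopt_intercept")] == 0)
        assert np.all(theta[:, names.index("var_prox")] == 0)
        assert theta[:, names.index("var_conf")].std() > 0


class TestQualitativeModelBehaviour:
    """Population-level signatures of confirmation-based weighting."""

    @staticmethod
    def _expected_s(condition, params, spec):
        lay = bm.make_condition_layout(condition)
        E1 = 100
        X = bm.realize_social_info(E1, lay, 1)
        pmf = bm.response_distribution(
            bm.Trial("p", 1, condition, 150, E1, X, None), params, spec
        )
        e2 = float((np.arange(1, 201) * pmf).sum())
        return (e2 - E1) / (np.mean(X) - E1)

    def test_confirmation_weighting_orders_skewed_conditions(self):
        # with confirmation on, the near-cluster layout (HC) draws larger
        # expected adjustments than the far-cluster layout (HF)
        p = bm.IndividualParams(keep_intercept=0.8, keep_slope=-7,
                                log_sigma_E=math.log(0.15), var_base=-3.5,
                                var_conf=2.0, var_prox=0.0)
        spec = bm.ModelSpec(use_adopt=False, use_proximity=False)
        assert self._expected_s("HC", p, spec) > self._expected_s("HF", p, spec)
        assert self._expected_s("LN", p, spec) > self._expected_s("HC", p, spec)

    def test_equal_weighting_gives_75_percent_everywhere(self):
        p = bm.IndividualParams(log_sigma_E=math.log(0.2),
                                var_base=2 * math.log(0.2),
                                log_sigma_resp=-5.0)
        spec = bm.ModelSpec(False, False, False, False)
        for c in bm.CONDITIONS:
            assert self._expected_s(c, p, spec) == pytest.approx(0.75, abs=0.01)

    def test_adjustment_peaks_at_intermediate_distance(self):
        # keep heuristic suppresses adjustment for close peers and
        # confirmation weighting for distant ones: the expected shift
        # rises then falls with a single peer's distance
        p = bm.IndividualParams(keep_intercept=1.0, keep_slope=-8,
                                log_sigma_E=math.log(0.15), var_base=-3.5,
                                var_conf=3.0, log_sigma_resp=math.log(0.05))
        spec = bm.ModelSpec(use_adopt=False, use_proximity=False)
        shifts = []
        for dist in np.arange(5, 90, 5):
            E1 = 100
            X = (E1 + int(dist),)
            t = bm.Trial("p", 1, "FILLER", 150, E1, (X[0],) * 3, None)
            pmf = bm.response_distribution(t, p, spec)
            e2 = float((np.arange(1, 201) * pmf).sum())
            shifts.append(e2 - E1)
        peak = int(np.argmax(shifts))
        assert 0 < peak < len(shifts) - 1
        assert shifts[peak] > shifts[0] and shifts[peak] > shifts[-1]
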