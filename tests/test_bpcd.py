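import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from drinkometer import (
    LogIntervalSample,
    aic_per_measurement,
    classify_intervals,
    component_intersection,
    derive_pc,
    fit_gmm,
    log_transform,
    make_interval_table,
    select_k,
)
from drinkometer.errors import (
    CriterionUndefinedError,
    DataError,
    DegenerateFitError,
    NoIntersectionError,
)


def grid_intersection(w1, m1, s1, w2, m2, s2, step=1e-6):
    """Brute-force oracle: densest grid point where the weighted densities meet."""
    x = np.arange(m1, m2, step)
    diff = w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    assert sign_change.size >= 1
    i = sign_change[0]
    return 0.5 * (x[i] + x[i + 1])


class TestLogTransform:
    def test_unit_interval_maps_to_zero(self):
        s = log_transform(make_interval_table("P", 1, [1.0, np.e]))
        np.testing.assert_allclose(s.values, [0.0, 1.0])

    def test_powers_of_e(self):
        s = log_transform(make_interval_table("P", 1, [np.e, np.e**2]))
        np.testing.assert_allclose(s.values, [1.0, 2.0])

    def test_exp_inverts_log(self):
        rng = np.random.default_rng(0)
        iv = np.exp(rng.normal(0, 1, 50))
        s = log_transform(make_interval_table("P", 1, iv))
        np.testing.assert_allclose(np.exp(s.values), iv, rtol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DataError):
            make_interval_table("P", 1, [1.0, -0.5])


class TestFitGMM:
    def test_k1_is_the_closed_form_gaussian_mle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1.5, 0.7, 200)
        fit = fit_gmm(LogIntervalSample(x), k=1)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-12)
        assert fit.sds[0] == pytest.approx(x.std(), abs=1e-12)

    def test_k1_two_point_sample_has_known_likelihood(self):
        fit = fit_gmm(LogIntervalSample(np.array([-1.0, 1.0])), k=1)
        # mean 0, sd 1: loglik = -ln(2*pi) - 1
        assert fit.loglik == pytest.approx(-np.log(2 * np.pi) - 1, abs=1e-12)
        assert fit.aic == pytest.approx(4 + 2 * np.log(2 * np.pi) + 2, abs=1e-9)

    def test_k2_recovers_well_separated_components(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [rng.normal(0, 0.25, 1000), rng.normal(2, 0.25, 1000)]
        )
        fit = fit_gmm(LogIntervalSample(x), k=2, restarts=10, seed=3)
        np.testing.assert_allclose(fit.means, [0.0, 2.0], atol=0.05)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.05)

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.5, 300), rng.normal(1.5, 0.5, 200)])
        fit = fit_gmm(LogIntervalSample(x), k=2, restarts=5, seed=4)
        assert np.all(np.diff(fit.loglik_history) >= -1e-10)

    def test_agrees_with_reference_em_implementation(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.4, 800), rng.normal(2, 0.5, 400)])
        ours = fit_gmm(LogIntervalSample(x), k=2, restarts=10, seed=5)
        ref = GaussianMixture(
            2, n_init=10, random_state=5, tol=1e-8, max_iter=500,
            covariance_type="full",
        ).fit(x[:, None])
        assert ours.loglik == pytest.approx(
            ref.score(x[:, None]) * x.size, rel=1e-4
        )
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.02)
        np.testing.assert_allclose(ours.weights, ref.weights_[order], atol=0.02)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 300)
        a = fit_gmm(LogIntervalSample(x), k=2, restarts=5, seed=42)
        b = fit_gmm(LogIntervalSample(x), k=2, restarts=5, seed=42)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.sds, b.sds)

    def test_weights_normalised_and_aic_identity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 200)
        for k in (1, 2, 3):
            fit = fit_gmm(LogIntervalSample(x), k=k, restarts=3, seed=7)
            assert abs(fit.weights.sum() - 1.0) < 1e-9
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.loglik, abs=1e-9
            )
            assert fit.n_params == 3 * k - 1 if k > 1 else 2

    def test_sd_floor_on_duplicated_values(self):
        x = np.array([0.0] * 10 + [2.0] * 10)
        fit = fit_gmm(LogIntervalSample(x), k=2, restarts=5, seed=8)
        assert np.all(fit.sds >= 1e-3)

    @pytest.mark.parametrize("bad", [np.zeros(5), np.arange(4)])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(DegenerateFitError):
            fit_gmm(LogIntervalSample(bad.astype(float)), k=2)


class TestSelectK:
    def test_bimodal_sample_selects_two_components(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.normal(-0.03, 0.3, 1400), rng.normal(1.15, 0.3, 600)]
        )
        fits, k = select_k(LogIntervalSample(x), k_max=5, restarts=5, seed=9)
        assert k == 2
        assert [f.k for f in fits] == [1, 2, 3, 4, 5]

    def test_single_gaussian_selects_one_component_in_majority_of_seeds(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0.5, 0.6, 2000)
            _, k = select_k(LogIntervalSample(x), k_max=3, restarts=3, seed=seed)
            wins += k == 1
        assert wins > 10

    def test_aic_formula_holds_for_every_k(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 300)
        fits, _ = select_k(LogIntervalSample(x), k_max=4, restarts=3, seed=10)
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik, abs=1e-9)


class TestComponentIntersection:
    def test_symmetric_equal_weight_crosses_at_midpoint(self):
        assert component_intersection(0.5, 0.0, 1.0, 0.5, 2.0, 1.0) == pytest.approx(1.0)

    def test_unequal_weights_equal_sds_closed_form(self):
        # w1 phi(x;0,1) = w2 phi(x;2,1)  =>  x = 1 + ln(w1/w2)/2
        got = component_intersection(0.75, 0.0, 1.0, 0.25, 2.0, 1.0)
        assert got == pytest.approx(1 + np.log(3) / 2, abs=1e-12)
        assert got == pytest.approx(
            grid_intersection(0.75, 0.0, 1.0, 0.25, 2.0, 1.0), abs=1e-5
        )

    def test_unequal_sds_match_grid_search(self):
        got = component_intersection(0.5, 0.0, 0.5, 0.5, 2.0, 1.0)
        assert got == pytest.approx(
            grid_intersection(0.5, 0.0, 0.5, 0.5, 2.0, 1.0), abs=1e-5
        )

    def test_overlapping_components_without_interior_root(self):
        # one density dominates everywhere between the means
        with pytest.raises(NoIntersectionError):
            component_intersection(0.999, 0.0, 1.0, 0.001, 0.2, 1.0)

    def test_means_must_be_ordered(self):
        with pytest.raises(NoIntersectionError):
            component_intersection(0.5, 2.0, 1.0, 0.5, 0.0, 1.0)


class TestDerivePC:
    def _fit(self, weights, means, sds):
        from drinkometer.bpcd import MixtureFit

        w = np.asarray(weights, float)
        return MixtureFit(
            k=len(w), weights=w, means=np.asarray(means, float),
            sds=np.asarray(sds, float), loglik=0.0, aic=0.0,
            n_params=3 * len(w) - 1, converged=True, n_restarts_used=1,
            seed=0, n_obs=100,
        )

    def test_symmetric_two_component_pc_is_e(self):
        pc = derive_pc(self._fit([0.5, 0.5], [0.0, 2.0], [1.0, 1.0]))
        assert pc.pc_log == pytest.approx(1.0)
        assert pc.pc_s == pytest.approx(np.e)
        assert pc.component_pair == (0, 1)

    def test_pc_back_transform_consistency(self):
        pc = derive_pc(self._fit([0.6, 0.4], [-0.0325, 1.1460], [0.45, 0.55]))
        assert pc.pc_s == pytest.approx(np.exp(pc.pc_log), rel=1e-12)
        assert -0.0325 < pc.pc_log < 1.1460

    def test_k3_trimodal_reports_two_candidates(self):
        fit = self._fit([0.4, 0.35, 0.25], [-1.0, 1.0, 3.0], [0.3, 0.3, 0.3])
        pc = derive_pc(fit)
        assert len(pc.candidates) == 2
        lows = [c["pc_log"] for c in pc.candidates]
        assert -1.0 < lows[0] < 1.0 < lows[1] < 3.0
        # the pc itself comes from the two heaviest components
        assert pc.component_pair == (0, 1)

    def test_peak_height_selection_switch(self):
        # middle component has low weight but very high peak density
        fit = self._fit([0.45, 0.1, 0.45], [-1.0, 0.5, 3.0], [0.5, 0.01, 0.5])
        assert derive_pc(fit, selection="weight").component_pair == (0, 2)
        assert 1 in derive_pc(fit, selection="peak").component_pair

    def test_k1_fit_has_no_criterion(self):
        with pytest.raises(CriterionUndefinedError):
            derive_pc(self._fit([1.0], [0.0], [1.0]))


class TestClassifyIntervals:
    def test_partition_against_printed_criterion(self):
        t = make_interval_table("P", 1, [0.5, 1.0, 2.0, 5.0])
        isi, ibi = classify_intervals(t, 1.34)
        assert isi["interval_s"].tolist() == [0.5, 1.0]
        assert ibi["interval_s"].tolist() == [2.0, 5.0]

    def test_boundary_interval_is_an_ibi(self):
        t = make_interval_table("P", 1, [1.34])
        isi, ibi = classify_intervals(t, 1.34)
        assert len(isi) == 0 and len(ibi) == 1

    def test_infinite_criterion_keeps_everything_as_isi(self):
        t = make_interval_table("P", 1, [0.5, 100.0])
        isi, ibi = classify_intervals(t, float("inf"))
        assert len(isi) == 2 and len(ibi) == 0

    def test_partition_is_exact(self):
        rng = np.random.default_rng(11)
        t = make_interval_table("P", 1, np.exp(rng.normal(0, 1, 200)))
        isi, ibi = classify_intervals(t, 1.5)
        assert len(isi) + len(ibi) == len(t)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(c=st.floats(min_value=0.05, max_value=20.0))
def test_pc_is_scale_equivariant(c):
    rng = np.random.default_rng(12)
    iv = np.exp(np.concatenate([rng.normal(0, 0.4, 400), rng.normal(1.5, 0.4, 200)]))
    base = derive_pc(fit_gmm(LogIntervalSample(np.log(iv)), 2, restarts=5, seed=12))
    scaled = derive_pc(
        fit_gmm(LogIntervalSample(np.log(iv * c)), 2, restarts=5, seed=12)
    )
    assert scaled.pc_log == pytest.approx(base.pc_log + np.log(c), abs=1e-6)
    assert scaled.pc_s == pytest.approx(base.pc_s * c, rel=1e-6)


class TestAICPerMeasurement:
    def test_two_decimal_rounding(self):
        assert aic_per_measurement(100.0, 3) == 33.33

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(DataError):
            aic_per_measurement(100.0, 0)
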