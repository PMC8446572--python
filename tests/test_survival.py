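"""Weibull curves, PH adjustment, cycle probabilities, and KM fitting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oncocea as oc

OS_CURVE = oc.WeibullCurve(scale=0.055227, shape=0.724424, endpoint="OS")
PFS_CURVE = oc.WeibullCurve(scale=0.119257, shape=0.701234, endpoint="PFS")

curve_st = st.builds(
    oc.WeibullCurve,
    scale=st.floats(1e-3, 0.5),
    shape=st.floats(0.3, 3.0),
)


class TestSurvivalAt:
    def test_starts_at_one(self):
        assert oc.survival_at(OS_CURVE, 0.0) == 1.0

    @pytest.mark.parametrize(
        "curve, t, expected",
        [(OS_CURVE, 12.0, 0.715934), (PFS_CURVE, 6.0, 0.657745)],
    )
    def test_published_curve_evaluations(self, curve, t, expected):
        assert oc.survival_at(curve, t) == pytest.approx(expected, abs=5e-5)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            oc.survival_at(OS_CURVE, -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            oc.WeibullCurve(scale=0.0, shape=1.0)
        with pytest.raises(ValueError):
            oc.WeibullCurve(scale=0.1, shape=-2.0)


class TestApplyHr:
    def test_unit_hr_is_identity(self):
        assert oc.apply_hr(OS_CURVE, 1.0) == OS_CURVE

    def test_half_hr_takes_square_root_of_survival(self):
        adjusted = oc.apply_hr(OS_CURVE, 0.5)
        t = 14.0
        assert adjusted.survival(t) == pytest.approx(np.sqrt(OS_CURVE.survival(t)), rel=1e-12)

    def test_exponential_special_case(self):
        curve = oc.WeibullCurve(scale=0.1, shape=1.0)
        assert oc.apply_hr(curve, 2.0).survival(5.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_non_positive_hr_rejected(self):
        with pytest.raises(ValueError):
            oc.apply_hr(OS_CURVE, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(curve=curve_st, hr=st.floats(0.1, 5.0), t=st.floats(0.0, 60.0))
    def test_power_identity_everywhere(self, curve, hr, t):
        """Proportional hazards on a common-shape Weibull: S'(t) = S(t)**hr."""
        assert oc.apply_hr(curve, hr).survival(t) == pytest.approx(
            curve.survival(t) ** hr, abs=1e-12
        )


class TestCycleTransitionProb:
    def test_exponential_is_memoryless(self):
        curve = oc.WeibullCurve(scale=0.1, shape=1.0)
        probs = {oc.cycle_transition_prob(curve, k, 1.0) for k in (0, 3, 10, 100)}
        assert all(p == pytest.approx(1 - np.exp(-0.1), rel=1e-12) for p in probs)

    def test_first_cycle_equals_one_minus_survival(self):
        delta = 0.69
        assert oc.cycle_transition_prob(PFS_CURVE, 0, delta) == pytest.approx(
            1 - PFS_CURVE.survival(delta), rel=1e-12
        )

    def test_tiny_scale_gives_vanishing_probability(self):
        curve = oc.WeibullCurve(scale=1e-12, shape=0.8)
        assert oc.cycle_transition_prob(curve, 5, 0.7) == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(curve=curve_st, n=st.integers(1, 40), delta=st.floats(0.1, 3.0))
    def test_chained_probabilities_recover_direct_survival(self, curve, n, delta):
        alive = 1.0
        for k in range(n):
            alive *= 1.0 - oc.cycle_transition_prob(curve, k, delta)
        assert alive == pytest.approx(curve.survival(n * delta), abs=1e-12)


class TestKMPoints:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            oc.KMPoints([1.0, 1.0], [0.9, 0.8])  # not strictly increasing
        with pytest.raises(ValueError):
            oc.KMPoints([1.0, 2.0], [0.8, 0.9])  # survival increases
        with pytest.raises(ValueError):
            oc.KMPoints([1.0, 2.0], [1.2, 0.9])  # above 1


class TestFitWeibull:
    def test_noiseless_points_recover_exactly(self):
        t = np.arange(1, 25, dtype=float)
        points = oc.KMPoints(t, OS_CURVE.survival(t))
        fit = oc.fit_weibull(points)
        assert fit.curve.scale == pytest.approx(OS_CURVE.scale, abs=1e-10)
        assert fit.curve.shape == pytest.approx(OS_CURVE.shape, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noisy_digitization_recovers_within_five_percent(self):
        points = oc.gen_km_points(OS_CURVE, n_points=200, noise_sd=0.005, seed=7)
        fit = oc.fit_weibull(points)
        assert fit.curve.scale == pytest.approx(OS_CURVE.scale, rel=0.05)
        assert fit.curve.shape == pytest.approx(OS_CURVE.shape, rel=0.05)

    def test_bias_shrinks_with_more_points(self):
        """Relative error of both parameters decreases from n=50 to n=800."""
        errs = {}
        for n in (50, 200, 800):
            rel = []
            for seed in range(10):
                pts = oc.gen_km_points(OS_CURVE, n_points=n, noise_sd=0.005, seed=seed)
                fit = oc.fit_weibull(pts)
                rel.append(
                    abs(fit.curve.scale / OS_CURVE.scale - 1)
                    + abs(fit.curve.shape / OS_CURVE.shape - 1)
                )
            errs[n] = np.mean(rel)
        assert errs[800] < errs[50]

    def test_too_few_usable_points_rejected(self):
        with pytest.raises(oc.FitError):
            oc.fit_weibull(oc.KMPoints([1.0, 2.0], [0.9, 0.8]))

    def test_saturated_points_excluded_with_warning(self):
        t = np.arange(0, 25, dtype=float)
        s = np.concatenate([[1.0], OS_CURVE.survival(t[1:])])
        with pytest.warns(UserWarning, match="survival == 1"):
            fit = oc.fit_weibull(oc.KMPoints(t, s))
        assert fit.n_used == 24  # t=0 and the S=1 point share the first row
        assert fit.curve.scale == pytest.approx(OS_CURVE.scale, abs=1e-10)


def test_cloglog_fit_agrees_with_mle_oracle(rng):
    """Independent route: lifelines' Weibull MLE on sampled event times.

    lifelines parameterises S(t) = exp(-(t/lambda_)**rho_); converting, both
    fits must sit near the truth on a large uncensored sample.
    """
    lifelines = pytest.importorskip("lifelines")
    true = oc.WeibullCurve(scale=0.09, shape=1.3)
    # inverse-CDF sampling from S(t) = exp(-scale * t**shape)
    u = rng.uniform(size=4000)
    times = (-np.log(u) / true.scale) ** (1.0 / true.shape)
    wf = lifelines.WeibullFitter().fit(times)
    mle_shape = wf.rho_
    mle_scale = (1.0 / wf.lambda_) ** wf.rho_
    grid = np.quantile(times, np.linspace(0.02, 0.98, 60))
    km = oc.KMPoints(grid, np.array([(times > t).mean() for t in grid]))
    ours = oc.fit_weibull(km)
    assert mle_scale == pytest.approx(true.scale, rel=0.08)
    assert mle_shape == pytest.approx(true.shape, rel=0.08)
    assert ours.curve.scale == pytest.approx(true.scale, rel=0.08)
    assert ours.curve.shape == pytest.approx(true.shape, rel=0.08)
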