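import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troopmove.direction import (
    InsufficientDataError,
    StepRecord,
    build_steps,
    compare_models,
    compute_waic,
    fit_full_model,
    fit_reduced_model,
    interpolate_position,
    unit_vector,
)
from troopmove.io import validate_observations
from troopmove.sampling import MCMCSettings
from troopmove.simulate import ObserverSchedule, SimConfig, degrade_observations, simulate_group

FAST = MCMCSettings(draws=400, warmup=300, chains=1)


class TestUnitVector:
    def test_three_four_five(self):
        v = unit_vector(np.array([0.0, 0.0]), np.array([3.0, 4.0]))
        assert v == pytest.approx([0.6, 0.8])

    def test_zero_displacement_is_none(self):
        assert unit_vector(np.array([1.0, 1.0]), np.array([1.0, 1.0])) is None

    @given(
        st.tuples(*[st.floats(-1e3, 1e3) for _ in range(4)]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_unit_norm(self, pts):
        a = np.array(pts[:2])
        b = np.array(pts[2:])
        v = unit_vector(a, b)
        if v is None:
            assert unit_vector(b, a) is None
        else:
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            assert unit_vector(b, a) == pytest.approx(-v)


class TestInterpolation:
    times = np.array([0.0, 10.0])
    xy = np.array([[0.0, 0.0], [10.0, 0.0]])

    def test_midpoint(self):
        assert interpolate_position(self.times, self.xy, 5.0, max_gap=60) == pytest.approx(
            [5.0, 0.0]
        )

    def test_exact_at_knots(self):
        assert interpolate_position(self.times, self.xy, 0.0, max_gap=60) == pytest.approx(
            [0.0, 0.0]
        )

    def test_never_extrapolates(self):
        assert interpolate_position(self.times, self.xy, 12.0, max_gap=60) is None
        assert interpolate_position(self.times, self.xy, -1.0, max_gap=60) is None

    def test_gap_limit(self):
        assert interpolate_position(self.times, self.xy, 5.0, max_gap=9.0) is None

    def test_unsorted_track_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            interpolate_position(np.array([10.0, 0.0]), self.xy, 5.0, max_gap=60)


def _line_obs(n_focal=3):
    """Focal walking a straight line; one neighbour densely sampled."""
    import pandas as pd

    rows = [("f", 600.0 * k, 100.0 * k, 0.0) for k in range(n_focal)]
    rows += [("n", 60.0 * k, 50.0, 100.0) for k in range(40)]
    return validate_observations(pd.DataFrame(rows, columns=["animal_id", "t", "x", "y"]))


class TestBuildSteps:
    def test_first_step_lacks_previous_heading(self):
        steps = build_steps(_line_obs(3), "f")
        assert len(steps) == 1  # three fixes, only the second step has v_prev

    def test_two_fixes_give_no_steps(self):
        assert build_steps(_line_obs(2), "f") == []

    def test_unknown_focal(self):
        with pytest.raises(KeyError):
            build_steps(_line_obs(), "ghost")

    def test_vectors_unit_norm_and_cm_consistent(self):
        steps = build_steps(_line_obs(4), "f")
        for s in steps:
            for v in [s.v_obs, s.v_prev, s.v_cm, *s.v_to.values()]:
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_follower_step_matches_direction_to_target(self):
        # simulator as oracle: pure follower's observed step direction equals
        # the stored unit vector toward its target at the step start
        W = np.zeros((2, 2))
        W[1, 0] = 1.0
        cfg = SimConfig(
            n_agents=2, duration_h=0.5, true_influence=W,
            w_cm=0.0, w_persist=0.0, heading_noise_sd=0.0, seed=4,
        )
        table, _ = simulate_group(cfg)
        steps = build_steps(table, "a01", min_step=1.0)
        assert len(steps) > 10
        for s in steps:
            assert s.v_obs == pytest.approx(s.v_to["a00"], abs=1e-9)


@pytest.fixture(scope="module")
def follower_steps():
    # a01 follows a00; a02 wanders independently (no planted link to a01)
    W = np.zeros((3, 3))
    W[1, 0] = 1.0
    cfg = SimConfig(
        n_agents=3, duration_h=30.0, true_influence=W,
        w_cm=0.2, heading_noise_sd=0.3, seed=11,
    )
    table, _ = simulate_group(cfg)
    obs = degrade_observations(table, ObserverSchedule(dwell=120.0), seed=12)
    return build_steps(obs, "a01")


class TestFitModels:
    def test_planted_influence_recovered_with_positive_interval(self, follower_steps):
        fit = fit_full_model(follower_steps, mcmc=FAST, seed=1)
        assert fit.beta["a00"].lo > 0

    def test_persistence_dominates_for_independent_walker(self):
        W = np.zeros((3, 3))
        cfg = SimConfig(
            n_agents=3, duration_h=30.0, true_influence=W,
            w_cm=0.0, w_persist=1.0, heading_noise_sd=0.15, seed=21,
        )
        table, _ = simulate_group(cfg)
        obs = degrade_observations(table, ObserverSchedule(dwell=120.0), seed=22)
        fit = fit_full_model(build_steps(obs, "a00"), mcmc=FAST, seed=2)
        assert fit.beta_prev.lo > 0
        mags = [abs(s.mean) for s in fit.beta.values()] + [abs(fit.beta_cm.mean)]
        assert abs(fit.beta_prev.mean) > max(mags)

    def test_pure_noise_targets_shrink_under_prior(self, follower_steps):
        rng = np.random.default_rng(0)
        noisy = []
        for s in follower_steps:
            theta = rng.uniform(0, 2 * np.pi)
            noisy.append(
                StepRecord(
                    focal=s.focal, t=s.t,
                    v_obs=np.array([np.cos(theta), np.sin(theta)]),
                    v_prev=s.v_prev, v_cm=s.v_cm, v_to=s.v_to,
                    step_dt=s.step_dt, step_len=s.step_len,
                )
            )
        fit = fit_full_model(noisy, prior_sd=0.1, mcmc=FAST, seed=3)
        for s in [*fit.beta.values(), fit.beta_cm, fit.beta_prev]:
            assert abs(s.mean) < 0.1

    def test_reduced_model_has_two_coefficients(self, follower_steps):
        fit = fit_reduced_model(follower_steps, mcmc=FAST, seed=4)
        assert fit.beta == {}
        assert fit.pointwise_loglik.shape[1] == 2 * fit.n_steps

    def test_seeded_determinism(self, follower_steps):
        a = fit_full_model(follower_steps, mcmc=FAST, seed=5)
        b = fit_full_model(follower_steps, mcmc=FAST, seed=5)
        assert a.beta["a00"].mean == b.beta["a00"].mean
        assert np.array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_insufficient_steps_error_names_focal(self, follower_steps):
        with pytest.raises(InsufficientDataError, match="a01"):
            fit_full_model(follower_steps[:10], mcmc=FAST, seed=6, n_min=50)

    def test_hpdi_brackets_mean(self, follower_steps):
        fit = fit_full_model(follower_steps, mcmc=FAST, seed=7)
        for s in [*fit.beta.values(), fit.beta_cm, fit.beta_prev]:
            assert s.lo <= s.mean <= s.hi


class TestWAIC:
    def test_zero_posterior_variance_closed_form(self):
        ll = np.tile(np.array([[-1.3, -0.7]]), (5, 1))
        waic, se = compute_waic(ll)
        assert waic == pytest.approx(-2 * (-1.3 - 0.7), abs=1e-12)

    def test_duplicating_observations_doubles_waic(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1, 0.1, size=(20, 6))
        w1, _ = compute_waic(ll)
        w2, _ = compute_waic(np.hstack([ll, ll]))
        assert w2 == pytest.approx(2 * w1, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            compute_waic(np.array([[0.0, -np.inf], [0.0, -1.0]]))

    def test_self_comparison_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-1, 0.3, size=(30, 8))

        class Fit:
            focal = "x"
            pointwise_loglik = ll

        cmp = compare_models(Fit(), Fit())
        assert cmp.dwaic == 0.0 and cmp.dse == 0.0

    def test_mismatched_observation_counts_rejected(self):
        class Fit:
            focal = "x"

            def __init__(self, n):
                self.pointwise_loglik = np.zeros((4, n))

        with pytest.raises(ValueError, match="same observation set"):
            compare_models(Fit(4), Fit(6))
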