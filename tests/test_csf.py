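import numpy as np
import pytest

from myovis.csf import (
    DEFAULT_FREQUENCIES,
    PsiGridConfig,
    PsiState,
    PsychometricParams,
    aulcsf,
    cutoff_sf,
    estimate_log_threshold,
    fit_trial_log,
    psi_init,
    psi_select,
    psi_update,
    psychometric,
    run_session,
)
from myovis.synthetic import ObserverSpec, SimulatedObserver


class TestPsychometric:
    def test_threshold_performance_is_80p3(self):
        # the Weibull 1 - 1/e point with gamma=0.5, lambda=0.02
        p = psychometric(0.02, PsychometricParams(threshold=0.02, slope=3))
        assert p == pytest.approx(0.5 + 0.48 * (1 - np.exp(-1)), abs=1e-12)
        assert p == pytest.approx(0.8034, abs=5e-5)

    def test_guessing_floor_and_lapse_ceiling(self):
        params = PsychometricParams(threshold=0.1, slope=3)
        assert psychometric(1e-9, params) == pytest.approx(0.5, abs=1e-6)
        assert psychometric(1.0, params) == pytest.approx(0.98, abs=1e-6)

    def test_monotone_in_contrast(self):
        params = PsychometricParams(threshold=0.05, slope=2.5)
        c = np.logspace(-3, 0, 40)
        p = psychometric(c, params)
        assert np.all(np.diff(p) >= 0)  # saturates at 1 - lambda in float
        assert np.all(np.diff(p[c < 0.2]) > 0)

    def test_nonpositive_contrast_rejected(self):
        with pytest.raises(ValueError):
            psychometric(0.0, PsychometricParams(threshold=0.1, slope=3))


def _entropy(p):
    p = p[p > 0]
    return -(p * np.log(p)).sum()


def _brute_force_select(state: PsiState):
    """Exhaustive expected-entropy enumeration (independent oracle)."""
    cfg = state.config
    tau, beta = state.grid_params()
    best, best_h = None, np.inf
    for c in state.candidates:
        pc = np.array([
            psychometric(c, PsychometricParams(threshold=t, slope=b,
                                               guess_rate=cfg.guess_rate,
                                               lapse_rate=cfg.lapse_rate))
            for t, b in zip(tau, beta)
        ])
        eh = 0.0
        for like in (pc, 1 - pc):
            post = state.posterior * like
            z = post.sum()
            if z > 0:
                eh += z * _entropy(post / z)
        if eh < best_h - 1e-12:
            best, best_h = c, eh
    return best


SMALL = PsiGridConfig(log_tau_min=-2.0, log_tau_max=-0.5, log_tau_step=0.5,
                      n_slopes=2, slope_min=2.0, slope_max=4.0)


class TestPsiSelect:
    def test_agrees_with_brute_force_enumeration(self):
        state = psi_init(SMALL)
        rng = np.random.default_rng(0)
        for trial in range(12):
            assert psi_select(state) == _brute_force_select(state)
            c = psi_select(state)
            state = psi_update(state, c, bool(rng.random() < 0.7))

    def test_point_mass_posterior_returns_nearest_candidate(self):
        state = psi_init(SMALL)
        post = np.zeros_like(state.posterior)
        tau, _ = state.grid_params()
        target = np.argmin(np.abs(np.log10(tau) + 1.0))  # log tau = -1
        post[target] = 1.0
        state = PsiState(config=SMALL, posterior=post)
        assert psi_select(state) == pytest.approx(0.1)

    def test_two_point_posterior_selects_between(self):
        state = psi_init(SMALL)
        tau, beta = state.grid_params()
        post = np.zeros_like(state.posterior)
        lo = np.argmin(np.abs(np.log10(tau) + 2.0) + (beta != beta[0]))
        hi = np.argmin(np.abs(np.log10(tau) + 0.5) + (beta != beta[0]))
        post[lo] = post[hi] = 0.5
        state = PsiState(config=SMALL, posterior=post)
        c = psi_select(state)
        assert 10 ** -2.0 < c < 10 ** -0.5

    def test_concentrates_near_true_threshold(self):
        true = PsychometricParams(threshold=0.02, slope=3)
        rng = np.random.default_rng(123)
        state = psi_init()
        placed = []
        for _ in range(45):
            c = psi_select(state)
            placed.append(np.log10(c))
            state = psi_update(state, c, bool(rng.random() < psychometric(c, true)))
        tail = np.asarray(placed[-20:])
        frac = np.mean(np.abs(tail - np.log10(0.02)) <= 0.3)
        assert frac >= 0.6


class TestPsiUpdate:
    def test_posterior_proportional_to_prior_times_likelihood(self):
        rng = np.random.default_rng(1)
        state = psi_init(SMALL)
        prior = rng.dirichlet(np.ones(len(state.posterior)))
        state = PsiState(config=SMALL, posterior=prior)
        c = 0.05
        tau, beta = state.grid_params()
        like = np.array([
            psychometric(c, PsychometricParams(threshold=t, slope=b,
                                               lapse_rate=SMALL.lapse_rate))
            for t, b in zip(tau, beta)
        ])
        new = psi_update(state, c, True)
        np.testing.assert_allclose(new.posterior, prior * like / (prior * like).sum(),
                                   atol=1e-12)

    def test_double_update_equals_squared_likelihood(self):
        state = psi_init(SMALL)
        twice = psi_update(psi_update(state, 0.05, True), 0.05, True)
        tau, beta = state.grid_params()
        like = np.array([
            psychometric(0.05, PsychometricParams(threshold=t, slope=b,
                                                  lapse_rate=SMALL.lapse_rate))
            for t, b in zip(tau, beta)
        ])
        direct = state.posterior * like**2
        np.testing.assert_allclose(twice.posterior, direct / direct.sum(), atol=1e-12)

    def test_posterior_stays_normalized(self):
        rng = np.random.default_rng(9)
        state = psi_init()
        for _ in range(60):
            c = psi_select(state)
            state = psi_update(state, c, bool(rng.random() < 0.7))
            assert abs(state.posterior.sum() - 1.0) < 1e-9


class TestRunSession:
    def test_session_records_270_trials(self):
        obs = SimulatedObserver(ObserverSpec())
        res = run_session(obs, rng=np.random.default_rng(0))
        assert len(res.trial_log) == 270
        assert res.trial_log.groupby("frequency_cpd").size().eq(45).all()
        assert res.spatial_frequencies == DEFAULT_FREQUENCIES

    def test_zero_trials_returns_prior_mean(self):
        obs = SimulatedObserver(ObserverSpec())
        cfg = PsiGridConfig()
        res = run_session(obs, n_trials_per_freq=0, config=cfg,
                          rng=np.random.default_rng(0))
        prior_mean = (cfg.log_tau_min + cfg.log_tau_max) / 2
        for t in res.thresholds:
            assert np.log10(t) == pytest.approx(prior_mean, abs=1e-9)

    def test_replay_from_trial_log_matches(self):
        obs = SimulatedObserver(ObserverSpec())
        res = run_session(obs, rng=np.random.default_rng(5))
        refit = fit_trial_log(res.trial_log)
        np.testing.assert_allclose(refit.thresholds, res.thresholds, rtol=1e-12)
        assert refit.aulcsf == pytest.approx(res.aulcsf, abs=1e-12)


class TestAulcsf:
    FREQS = np.array(DEFAULT_FREQUENCIES)

    def test_flat_unit_log_sensitivity(self):
        assert aulcsf(self.FREQS, np.ones(6)) == pytest.approx(
            np.log10(24 / 1.5), abs=1e-10)

    def test_zero_log_sensitivity(self):
        assert aulcsf(self.FREQS, np.zeros(6)) == 0.0

    def test_doubling_sensitivities_adds_log2_band(self):
        y = np.array([1.2, 1.5, 1.4, 1.0, 0.7, 0.4])
        a1 = aulcsf(self.FREQS, y)
        a2 = aulcsf(self.FREQS, y + np.log10(2))
        assert a2 - a1 == pytest.approx(np.log10(2) * np.log10(24 / 1.5), abs=1e-12)

    def test_matches_analytic_piecewise_linear_integral(self):
        # trapezoid of a positive piecewise-linear curve == sum of segment areas
        y = np.array([0.9, 1.4, 1.2, 0.8, 0.5, 0.2])
        x = np.log10(self.FREQS)
        manual = sum((y[i] + y[i + 1]) / 2 * (x[i + 1] - x[i]) for i in range(5))
        assert aulcsf(self.FREQS, y) == pytest.approx(manual, abs=1e-12)

    def test_negative_log_sensitivity_clipped(self):
        y = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0])
        assert aulcsf(self.FREQS, y) >= 0.0

    def test_unordered_frequencies_rejected(self):
        with pytest.raises(ValueError):
            aulcsf([3, 1.5, 6], [1, 1, 1])


class TestCutoffSF:
    def test_extrapolation_from_descending_tail(self):
        assert cutoff_sf([18, 24], [0.5, 0.25]) == pytest.approx(1.50515, abs=1e-4)

    def test_on_node_crossing(self):
        y = [1.5, 1.4, 1.0, 0.6, 0.3, 0.0]
        assert cutoff_sf(DEFAULT_FREQUENCIES, y) == pytest.approx(np.log10(24), abs=1e-9)

    def test_interior_crossing_at_node(self):
        y = [1.5, 1.4, 1.0, 0.6, 0.0, -0.3]
        assert cutoff_sf(DEFAULT_FREQUENCIES, y) == pytest.approx(np.log10(18), abs=1e-9)

    def test_interior_crossing_between_nodes(self):
        y = np.array([1.5, 1.4, 1.0, 0.4, -0.4, -0.8])
        x = np.log10(np.array(DEFAULT_FREQUENCIES))
        expect = x[3] + (0 - y[3]) * (x[4] - x[3]) / (y[4] - y[3])
        assert cutoff_sf(DEFAULT_FREQUENCIES, y) == pytest.approx(expect, abs=1e-12)

    def test_non_descending_tail_flagged_via_session_floor(self):
        with pytest.raises(ValueError):
            cutoff_sf(DEFAULT_FREQUENCIES, [1.0, 1.1, 1.2, 1.3, 1.4, 1.5])
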