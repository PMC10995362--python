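"""Bayesian adaptive contrast-threshold estimation (Psi method) and CSF summaries.

A 2AFC grating-orientation observer is modelled with a Weibull psychometric
function

    P(correct | c) = gamma + (1 - gamma - lambda) * (1 - exp(-(c/tau)^beta))

with guess rate gamma = 0.5 and lapse rate lambda = 0.02.  The contrast
threshold tau is defined at the Weibull ``1 - 1/e`` point, so performance at
threshold is 0.5 + 0.48*(1 - e^-1) = 80.34% correct — the criterion the
adaptive procedure targets.

The Psi method maintains a discrete posterior over (log10 threshold,
log10 slope) and, each trial, presents the candidate contrast that minimizes
the expected posterior entropy over the two possible responses.  After a
fixed number of trials the threshold estimate is the posterior mean of
log10 tau.

Per-frequency sensitivities S = 1/tau over the six tested spatial
frequencies (1.5, 3, 6, 12, 18, 24 cpd) are summarized by

* AULCSF — trapezoidal area under max(log10 S, 0) against log10 frequency
  over the measured range;
* cut-off SF — the log10 frequency where the high-frequency limb of the log
  CSF crosses log10 S = 0 (sensitivity 1), by linear inter/extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FREQUENCIES",
    "PsychometricParams",
    "PsiGridConfig",
    "PsiState",
    "psychometric",
    "psi_init",
    "psi_select",
    "psi_update",
    "estimate_log_threshold",
    "run_session",
    "fit_trial_log",
    "CSFResult",
    "aulcsf",
    "cutoff_sf",
]

DEFAULT_FREQUENCIES = (1.5, 3.0, 6.0, 12.0, 18.0, 24.0)  # cpd
TRIALS_PER_FREQUENCY = 45


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric parameters for a 2AFC task."""

    threshold: float  # Michelson contrast in (0, 1]
    slope: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must be in [0, 0.5)")


def psychometric(contrast, params: PsychometricParams):
    """Probability of a correct response at the given contrast(s)."""
    c = np.asarray(contrast, dtype=float)
    if np.any(c <= 0):
        raise ValueError("contrast must be positive")
    p = params.guess_rate + (1 - params.guess_rate - params.lapse_rate) * (
        1 - np.exp(-((c / params.threshold) ** params.slope))
    )
    return p if p.shape else float(p)


@dataclass(frozen=True)
class PsiGridConfig:
    """Parameter grid and candidate set for the Psi procedure (all log10)."""

    log_tau_min: float = -3.0
    log_tau_max: float = 0.0
    log_tau_step: float = 0.02
    # slope prior spans the empirical range of 2AFC contrast psychometric
    # slopes; hypotheses shallower than ~1.5 are not observed in practice and
    # including them biases the marginal threshold posterior low at 45 trials
    n_slopes: int = 10
    slope_min: float = 1.5
    slope_max: float = 8.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.02

    def log_tau_grid(self) -> np.ndarray:
        n = int(round((self.log_tau_max - self.log_tau_min) / self.log_tau_step)) + 1
        return self.log_tau_min + self.log_tau_step * np.arange(n)

    def slope_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.slope_min), np.log10(self.slope_max), self.n_slopes)


# (config) -> lookup tables shared across sessions with one config:
# candidates, grid taus/betas, pc[cand, grid], and the entropy helper
# matrices pc*log(pc) and (1-pc)*log(1-pc)
_TABLE_CACHE: dict[PsiGridConfig, tuple] = {}


def _tables(config: PsiGridConfig):
    cached = _TABLE_CACHE.get(config)
    if cached is not None:
        return cached
    log_tau = config.log_tau_grid()
    slopes = config.slope_grid()
    tt, bb = np.meshgrid(10.0 ** log_tau, slopes, indexing="ij")
    tau_flat, beta_flat = tt.ravel(), bb.ravel()
    candidates = 10.0 ** log_tau
    scale = 1 - config.guess_rate - config.lapse_rate
    pc = config.guess_rate + scale * (
        1 - np.exp(-((candidates[:, None] / tau_flat[None, :]) ** beta_flat[None, :]))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(pc > 0, pc * np.log(pc), 0.0)
        m0 = np.where(pc < 1, (1 - pc) * np.log1p(-pc), 0.0)
    out = (candidates, tau_flat, beta_flat, pc, m1, m0)
    _TABLE_CACHE[config] = out
    return out


@dataclass
class PsiState:
    """Posterior over (log10 tau, log10 slope) plus trial history."""

    config: PsiGridConfig
    posterior: np.ndarray
    history: list[tuple[float, bool]] = field(default_factory=list)

    @property
    def candidates(self) -> np.ndarray:
        return _tables(self.config)[0]

    def grid_params(self) -> tuple[np.ndarray, np.ndarray]:
        t = _tables(self.config)
        return t[1], t[2]


def psi_init(config: PsiGridConfig = PsiGridConfig()) -> PsiState:
    """Fresh Psi state with a uniform prior over the grid."""
    n = len(_tables(config)[1])
    return PsiState(config=config, posterior=np.full(n, 1.0 / n))


def psi_select(state: PsiState) -> float:
    """Next contrast: the candidate minimizing expected posterior entropy.

    Ties (within numerical tolerance) break toward the lower contrast.  A
    degenerate point-mass posterior carries no information to gain, in which
    case the candidate nearest the posterior-mean threshold is returned.
    """
    candidates, tau_flat, _, pc, m1, m0 = _tables(state.config)
    p = state.posterior
    # Expected entropy via H(q/Z) = log Z - (sum q log q)/Z with q the
    # unnormalized response posterior; everything reduces to matrix-vector
    # products against the cached tables.
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(p > 0, p * np.log(p), 0.0)
    u_sum = u.sum()
    p_corr = pc @ p  # P(correct at candidate) under the posterior
    pc_u = pc @ u
    s_c = m1 @ p + pc_u  # sum over grid of q log q, correct branch
    s_i = m0 @ p + (u_sum - pc_u)  # incorrect branch
    with np.errstate(divide="ignore", invalid="ignore"):
        t_c = np.where(p_corr > 0, p_corr * np.log(p_corr), 0.0)
        t_i = np.where(p_corr < 1, (1 - p_corr) * np.log1p(-p_corr), 0.0)
    expected_h = t_c + t_i - s_c - s_i

    if np.ptp(expected_h) < 1e-12:
        mean_log_tau = float(p @ np.log10(tau_flat))
        return float(candidates[np.argmin(np.abs(np.log10(candidates) - mean_log_tau))])
    # candidates ascend, argmin returns the first (= lowest-contrast) minimizer
    best = np.flatnonzero(expected_h <= expected_h.min() + 1e-12)[0]
    return float(candidates[best])


def psi_update(state: PsiState, contrast: float, response: bool) -> PsiState:
    """Bayes update of the posterior with one (contrast, correct?) trial."""
    tau_flat, beta_flat = state.grid_params()
    cfg = state.config
    scale = 1 - cfg.guess_rate - cfg.lapse_rate
    p_corr = cfg.guess_rate + scale * (1 - np.exp(-((contrast / tau_flat) ** beta_flat)))
    like = p_corr if response else 1 - p_corr
    post = state.posterior * like
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("zero total likelihood in Psi update")
    return PsiState(
        config=cfg,
        posterior=post / total,
        history=state.history + [(float(contrast), bool(response))],
    )


def estimate_log_threshold(state: PsiState) -> float:
    """Posterior mean of log10 threshold (marginal over slope)."""
    tau_flat, _ = state.grid_params()
    return float(state.posterior @ np.log10(tau_flat))


@dataclass(frozen=True)
class CSFResult:
    """Per-frequency thresholds and the two scalar CSF summaries."""

    spatial_frequencies: tuple[float, ...]
    thresholds: tuple[float, ...]
    log_sensitivities: tuple[float, ...]
    aulcsf: float
    cutoff_sf: float
    trial_log: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _summaries(freqs: np.ndarray, log_s: np.ndarray) -> tuple[float, float, dict]:
    a = aulcsf(freqs, log_s)
    meta: dict = {}
    try:
        cut = cutoff_sf(freqs, log_s)
    except _NonDescendingTail as e:
        cut = float(np.log10(freqs[-1]))
        meta["cutoff_flag"] = str(e)
    return a, cut, meta


def run_session(
    observer,
    n_trials_per_freq: int = TRIALS_PER_FREQUENCY,
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    config: PsiGridConfig = PsiGridConfig(),
    rng: np.random.Generator | int | None = None,
) -> CSFResult:
    """Run an independent Psi track at each spatial frequency.

    ``observer`` must expose ``respond(frequency_cpd, contrast, rng) -> bool``.
    The per-frequency threshold estimate is the posterior mean of log10 tau
    after ``n_trials_per_freq`` trials; the trial log records every
    (trial, frequency, contrast, response).
    """
    if n_trials_per_freq < 0:
        raise ValueError("n_trials_per_freq must be >= 0")
    rng = np.random.default_rng(rng)
    rows = []
    log_thr = []
    trial_no = 0
    for f in frequencies:
        state = psi_init(config)
        for _ in range(n_trials_per_freq):
            c = psi_select(state)
            resp = bool(observer.respond(f, c, rng))
            state = psi_update(state, c, resp)
            trial_no += 1
            rows.append(
                {"trial": trial_no, "frequency_cpd": f, "contrast": c, "response": int(resp)}
            )
        log_thr.append(estimate_log_threshold(state))
    freqs = np.asarray(frequencies, dtype=float)
    thresholds = 10.0 ** np.asarray(log_thr)
    log_s = -np.asarray(log_thr)  # log10 sensitivity = -log10 threshold
    a, cut, meta = _summaries(freqs, log_s)
    return CSFResult(
        spatial_frequencies=tuple(freqs),
        thresholds=tuple(thresholds),
        log_sensitivities=tuple(log_s),
        aulcsf=a,
        cutoff_sf=cut,
        trial_log=pd.DataFrame(rows, columns=["trial", "frequency_cpd", "contrast", "response"]),
        metadata=meta,
    )


def fit_trial_log(
    log: pd.DataFrame, config: PsiGridConfig = PsiGridConfig()
) -> CSFResult:
    """Re-estimate thresholds from a recorded trial log (offline Psi replay)."""
    req = {"frequency_cpd", "contrast", "response"}
    if not req.issubset(log.columns):
        raise ValueError(f"trial log must have columns {sorted(req)}")
    freqs = np.sort(log["frequency_cpd"].unique())
    log_thr = []
    for f in freqs:
        state = psi_init(config)
        sub = log[log["frequency_cpd"] == f]
        for _, row in sub.iterrows():
            state = psi_update(state, float(row["contrast"]), bool(row["response"]))
        log_thr.append(estimate_log_threshold(state))
    log_s = -np.asarray(log_thr)
    a, cut, meta = _summaries(freqs, log_s)
    return CSFResult(
        spatial_frequencies=tuple(freqs),
        thresholds=tuple(10.0 ** np.asarray(log_thr)),
        log_sensitivities=tuple(log_s),
        aulcsf=a,
        cutoff_sf=cut,
        trial_log=log,
        metadata=meta,
    )


def aulcsf(frequencies, log_sensitivities) -> float:
    """Area under max(log10 S, 0) vs log10 frequency over the measured range."""
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(log_sensitivities, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least two frequencies")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    return float(np.trapezoid(np.clip(y, 0, None), np.log10(f)))


class _NonDescendingTail(ValueError):
    pass


def cutoff_sf(frequencies, log_sensitivities) -> float:
    """Cut-off spatial frequency in log10 cpd.

    The high-frequency limb of the log CSF is extended linearly in
    (log10 f, log10 S) until it crosses log10 S = 0.  If the measured curve
    already crosses zero between nodes, the interior crossing is returned;
    if the tail does not descend, the highest measured frequency is returned
    as a floor (callers see the flag via run_session metadata).
    """
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(log_sensitivities, dtype=float)
    x = np.log10(f)
    # interior descending zero crossing
    for i in range(len(y) - 1, 0, -1):
        if y[i - 1] > 0 >= y[i]:
            if y[i] == 0:
                return float(x[i])
            return float(x[i - 1] + (0 - y[i - 1]) * (x[i] - x[i - 1]) / (y[i] - y[i - 1]))
    if y[0] <= 0:
        return float(x[0])
    if y[-1] >= y[-2]:
        raise _NonDescendingTail(
            "log CSF does not descend over the two highest frequencies; "
            "returning log10 of the highest frequency as a floor"
        )
    slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    return float(x[-1] - y[-1] / slope)
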