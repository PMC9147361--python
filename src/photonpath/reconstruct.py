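"""Photon-by-photon hidden-state reconstruction.

Each interphoton interval dt is scored under every candidate state n by
the exponential emission log-density log k_n - k_n*dt.  States form a
hidden Markov chain over intervals with a pinned, extremely small
transition rate r (default 1e-10 transitions/s): the per-interval
off-diagonal transition probability is r*dt, the self-transition its
complement.  The pinned rate makes state changes expensive, so the
Viterbi path only switches states where the photon statistics demand it
— a change-point detector at single-photon resolution.  The state count
rates are then refined by maximizing the Viterbi path likelihood over
log-rates with a deterministic simplex search; r itself is never
optimized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .config import AnalysisConfig
from .errors import CorruptInputError, InsufficientDataError, InvalidConfigError
from .interphoton import (
    InterphotonSeries,
    compute_interphoton_times,
    fit_exponential_mixture,
    histogram_interphoton,
    select_model,
)
from .simulate import PhotonTrajectory

__all__ = [
    "HiddenStateModel",
    "StatePath",
    "RateOptimizationResult",
    "viterbi_path",
    "optimize_rates",
    "reconstruct",
]

log = logging.getLogger(__name__)

DEFAULT_TRANSITION_RATE = 1e-10
_LOG_FLOOR = -690.0  # ~ log(1e-300)


@dataclass(frozen=True)
class HiddenStateModel:
    """Per-state count rates (ascending; state 0 = background) plus the
    pinned transition rate and initial state distribution."""

    state_rates: np.ndarray
    transition_rate: float = DEFAULT_TRANSITION_RATE
    initial_probs: np.ndarray | None = None

    def __post_init__(self):
        rates = np.asarray(self.state_rates, dtype=float)
        object.__setattr__(self, "state_rates", rates)
        if not 2 <= rates.size <= 3:
            raise InvalidConfigError(f"need 2-3 states, got {rates.size}")
        if np.any(rates <= 0):
            raise InvalidConfigError("state rates must be positive")
        if np.any(np.diff(rates) <= 0):
            raise InvalidConfigError("state rates must be strictly ascending")
        if not self.transition_rate > 0:
            raise InvalidConfigError("transition_rate must be positive")
        if self.initial_probs is None:
            object.__setattr__(self, "initial_probs", np.full(rates.size, 1.0 / rates.size))
        else:
            p = np.asarray(self.initial_probs, dtype=float)
            if p.size != rates.size or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise InvalidConfigError("initial_probs must be a distribution over the states")
            object.__setattr__(self, "initial_probs", p)

    @property
    def n_states(self) -> int:
        return self.state_rates.size


@dataclass(frozen=True)
class StatePath:
    """Most likely per-interval state assignment with its joint
    log-likelihood and the contiguous segments it induces
    (start time, end time, state index)."""

    states: np.ndarray
    log_likelihood: float
    segments: tuple[tuple[float, float, int], ...]

    def __len__(self) -> int:
        return self.states.size

    def occupancy(self, n_states: int) -> np.ndarray:
        return np.bincount(self.states, minlength=n_states)


@dataclass(frozen=True)
class RateOptimizationResult:
    rates: np.ndarray
    log_likelihood: float
    initial_log_likelihood: float
    n_evaluations: int
    converged: bool
    trace: tuple = ()


@njit(cache=True)
def _viterbi_core(dt, rates, log_init, trans_rate):
    N = dt.size
    S = rates.size
    logk = np.log(rates)
    delta = np.empty(S)
    work = np.empty(S)
    psi = np.empty((N, S), dtype=np.int64)
    for s in range(S):
        delta[s] = log_init[s] + logk[s] - rates[s] * dt[0]
        psi[0, s] = -1
    for i in range(1, N):
        d = dt[i]
        p_off = trans_rate * d
        if p_off * (S - 1) >= 1.0:
            p_off = 1.0 / S
        log_off = np.log(p_off) if p_off > 1e-300 else _LOG_FLOOR
        p_stay = 1.0 - (S - 1) * p_off
        log_stay = np.log(p_stay) if p_stay > 1e-300 else _LOG_FLOOR
        for s in range(S):
            best_j = 0
            best = delta[0] + (log_stay if s == 0 else log_off)
            for j in range(1, S):
                v = delta[j] + (log_stay if s == j else log_off)
                if v > best:  # strict: ties break toward the lower index
                    best = v
                    best_j = j
            work[s] = best + logk[s] - rates[s] * d
            psi[i, s] = best_j
        for s in range(S):
            delta[s] = work[s]
    best_s = 0
    best_ll = delta[0]
    for s in range(1, S):
        if delta[s] > best_ll:
            best_ll = delta[s]
            best_s = s
    path = np.empty(N, dtype=np.int64)
    path[N - 1] = best_s
    for i in range(N - 1, 0, -1):
        path[i - 1] = psi[i, path[i]]
    return path, best_ll


def _segments_from_path(path: np.ndarray, times: np.ndarray):
    """Collapse the per-interval assignment into contiguous (start, end,
    state) runs; interval i spans (times[i], times[i+1])."""
    segs = []
    start = 0
    for i in range(1, path.size):
        if path[i] != path[start]:
            segs.append((float(times[start]), float(times[i]), int(path[start])))
            start = i
    segs.append((float(times[start]), float(times[-1]), int(path[start])))
    return tuple(segs)


def viterbi_path(model: HiddenStateModel, series: InterphotonSeries) -> StatePath:
    """Globally most likely state assignment for every interphoton interval."""
    if len(series) == 0:
        raise InsufficientDataError("empty interphoton series")
    dt = series.dt
    if np.any(dt <= 0):
        raise CorruptInputError("interphoton series contains dt <= 0")
    log_init = np.log(model.initial_probs + 1e-300)
    path, ll = _viterbi_core(dt, model.state_rates, log_init, model.transition_rate)
    times = series.arrival_times()
    return StatePath(states=path, log_likelihood=float(ll), segments=_segments_from_path(path, times))


def optimize_rates(
    series: InterphotonSeries,
    init_rates,
    model_config: AnalysisConfig | None = None,
) -> RateOptimizationResult:
    """Refine state rates by maximizing the Viterbi path log-likelihood.

    Derivative-free Nelder-Mead search in log-rate space, deterministic
    given its inputs; the returned likelihood never falls below the
    initialization's.
    """
    cfg = model_config or AnalysisConfig()
    k0 = np.sort(np.asarray(init_rates, dtype=float))
    if np.any(k0 <= 0):
        raise InvalidConfigError("initial rates must be positive")
    if np.any(np.diff(k0) == 0):
        raise InvalidConfigError("initial rates must be distinct")

    r = cfg.transition_rate

    def neg_ll(log_k: np.ndarray) -> float:
        k = np.sort(np.exp(log_k))
        if np.any(np.diff(k) <= 0):  # collided rates: reject
            return np.inf
        model = HiddenStateModel(state_rates=k, transition_rate=r)
        return -viterbi_path(model, series).log_likelihood

    x0 = np.log(k0)
    f0 = neg_ll(x0)
    res = minimize(
        neg_ll,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": cfg.optimizer_maxiter,
            "fatol": cfg.likelihood_rtol * max(1.0, abs(f0)),
            "xatol": 1e-6,
        },
    )
    if res.fun <= f0:
        rates = np.sort(np.exp(res.x))
        ll = -float(res.fun)
    else:  # simplex cannot regress, but guard anyway
        rates, ll = k0, -f0
    return RateOptimizationResult(
        rates=rates,
        log_likelihood=ll,
        initial_log_likelihood=-f0,
        n_evaluations=int(res.nfev),
        converged=bool(res.success),
    )


def reconstruct(
    traj: PhotonTrajectory,
    n_states: int | str = "auto",
    config: AnalysisConfig | None = None,
):
    """Full per-molecule pipeline: interphoton times -> histogram ->
    2- and 3-term mixture fits -> model selection -> rate refinement ->
    Viterbi path.

    Returns ``(StatePath, HiddenStateModel)`` with the refined rates.
    """
    cfg = config or AnalysisConfig()
    if len(traj) < cfg.min_photons:
        raise InsufficientDataError(
            f"{traj.molecule_id}: {len(traj)} photons < floor of {cfg.min_photons}"
        )
    series = compute_interphoton_times(traj)
    hist = histogram_interphoton(series, n_bins=cfg.n_bins, binning=cfg.binning)
    if n_states == "auto":
        fit2 = fit_exponential_mixture(hist, 2)
        try:
            fit3 = fit_exponential_mixture(hist, 3)
            chosen = select_model(fit2, fit3, cfg.improvement_factor)
        except Exception as exc:  # 3-term fit unavailable: fall back to 2
            log.info("%s: 3-term fit unavailable (%s); using 2 states", traj.molecule_id, exc)
            fit3, chosen = None, 2
        fit = fit3 if chosen == 3 else fit2
    elif n_states in (2, 3):
        fit = fit_exponential_mixture(hist, n_states)
        chosen = n_states
    else:
        raise InvalidConfigError(f"n_states must be 'auto', 2 or 3, got {n_states!r}")
    log.info(
        "%s: %d states, mixture rates %s, redchi %.3g",
        traj.molecule_id,
        chosen,
        np.round(fit.rates, 1),
        fit.reduced_chi_square,
    )
    opt = optimize_rates(series, fit.rates, cfg)
    model = HiddenStateModel(state_rates=opt.rates, transition_rate=cfg.transition_rate)
    path = viterbi_path(model, series)
    occ = path.occupancy(model.n_states)
    if np.any(occ == 0):
        log.warning("%s: states %s unoccupied in the Viterbi path", traj.molecule_id, np.flatnonzero(occ == 0))
    return path, model
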