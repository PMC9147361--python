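"""Interphoton-time statistics and multi-exponential mixture fitting.

Within one emitting state, interphoton times dt are exponential at the
state's count rate, so a trajectory visiting S states yields a mixture

    y(dt) = A1 exp(-k1 dt) + A2 exp(-k2 dt) [+ A3 exp(-k3 dt)]

whose decay rates k_n approximate the per-state emission rates.  The
histogram of dt is fit by weighted least squares (Poisson bin variance)
to the two- and three-term models, and the number of molecular states is
chosen from the reduced chi-square of the two fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import CorruptInputError, FitFailureError, InsufficientDataError, InvalidConfigError
from .simulate import PhotonTrajectory

__all__ = [
    "InterphotonSeries",
    "InterphotonHistogram",
    "ExponentialMixtureFit",
    "compute_interphoton_times",
    "histogram_interphoton",
    "fit_exponential_mixture",
    "select_model",
]

log = logging.getLogger(__name__)

#: fits whose adjacent rates differ by less than this fraction are flagged
RATE_COLLISION_TOL = 0.05


@dataclass(frozen=True)
class InterphotonSeries:
    """Ordered interphoton times for one molecule.

    ``t_start`` is the first photon's arrival time, kept so absolute
    segment times can be reconstructed downstream.
    """

    dt: np.ndarray
    molecule_id: str = "anonymous"
    t_start: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "dt", np.asarray(self.dt, dtype=float))

    def __len__(self) -> int:
        return self.dt.size

    def arrival_times(self) -> np.ndarray:
        """Absolute photon arrival times implied by t_start and the gaps."""
        return self.t_start + np.concatenate(([0.0], np.cumsum(self.dt)))


@dataclass(frozen=True)
class InterphotonHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    densities: np.ndarray
    n_total: int

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers (the natural choice for log-spaced bins)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class ExponentialMixtureFit:
    """Result of fitting the exponential-mixture model to a dt histogram."""

    n_terms: int
    amplitudes: np.ndarray
    rates: np.ndarray
    reduced_chi_square: float
    chi_square: float
    n_occupied_bins: int
    covariance: np.ndarray | None
    degenerate: bool

    def evaluate(self, dt: np.ndarray) -> np.ndarray:
        dt = np.asarray(dt, dtype=float)
        return np.sum(self.amplitudes[:, None] * np.exp(-np.outer(self.rates, dt)), axis=0)


def compute_interphoton_times(traj: PhotonTrajectory) -> InterphotonSeries:
    """Difference the photon arrival times, preserving stream order."""
    t = traj.arrival_times
    if t.size < 3:
        raise InsufficientDataError(f"{traj.molecule_id}: need >= 3 photons, got {t.size}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise CorruptInputError(
            f"{traj.molecule_id}: non-increasing timestamps at photon {i + 1} "
            f"(t={t[i]!r} -> {t[i + 1]!r})"
        )
    return InterphotonSeries(dt=dt, molecule_id=traj.molecule_id, t_start=float(t[0]))


def histogram_interphoton(
    series: InterphotonSeries, n_bins: int = 50, binning: str = "log"
) -> InterphotonHistogram:
    """Histogram the interphoton times; densities estimate the dt pdf."""
    if n_bins < 4:
        raise InvalidConfigError(f"n_bins must be >= 4, got {n_bins}")
    if binning not in ("log", "linear"):
        raise InvalidConfigError(f"binning must be 'log' or 'linear', got {binning!r}")
    if len(series) == 0:
        raise InsufficientDataError("empty interphoton series")
    lo, hi = float(series.dt.min()), float(series.dt.max())
    if lo == hi:  # degenerate: widen so one bin holds everything
        lo, hi = lo * 0.5, hi * 2.0
    if binning == "log":
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(series.dt, bins=edges)
    n = len(series)
    densities = counts / (n * np.diff(edges))
    return InterphotonHistogram(bin_edges=edges, counts=counts, densities=densities, n_total=n)


def _weighted_quantiles(hist: InterphotonHistogram, qs) -> np.ndarray:
    """Approximate dt quantiles from the histogram's cumulative counts."""
    cum = np.cumsum(hist.counts)
    targets = np.asarray(qs) * cum[-1]
    idx = np.searchsorted(cum, targets)
    idx = np.clip(idx, 0, hist.centers.size - 1)
    return hist.centers[idx]


def _candidate_inits(hist: InterphotonHistogram, n_terms: int, init_rates) -> list[np.ndarray]:
    """Deterministic starting rates: user-supplied, else dt-quantile
    reciprocals plus a log-spaced spread over the observed dt range
    (a cheap multi-start guard against local minima)."""
    if init_rates is not None:
        k0 = np.sort(np.asarray(init_rates, dtype=float))
        if k0.size != n_terms:
            raise InvalidConfigError(f"init_rates must have {n_terms} entries")
        return [k0]
    qs = (0.30, 0.85) if n_terms == 2 else (0.30, 0.70, 0.95)
    quantile_init = np.sort(1.0 / _weighted_quantiles(hist, qs))
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    spread_init = np.sort(1.0 / np.geomspace(hi, lo, n_terms + 2)[1:-1])
    return [quantile_init, spread_init]


def _make_params(k0: np.ndarray, n_terms: int) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for i, k in enumerate(k0):
        # the densities estimate a pdf, so a mixture weight 1/n_terms per
        # component gives amplitude k/n_terms
        params.add(f"A{i}", value=k / n_terms, min=0.0)
        params.add(f"k{i}", value=k, min=1e-9)
    return params


def _mixture_bin_means(params: lmfit.Parameters, edges: np.ndarray, n_terms: int) -> np.ndarray:
    """Model density averaged over each bin: the exact expectation of the
    histogram density estimator, avoiding the bias of point evaluation on
    wide logarithmic bins."""
    widths = np.diff(edges)
    y = np.zeros(widths.size)
    for i in range(n_terms):
        a, k = params[f"A{i}"].value, params[f"k{i}"].value
        y += a / k * (np.exp(-k * edges[:-1]) - np.exp(-k * edges[1:])) / widths
    return y


def fit_exponential_mixture(
    hist: InterphotonHistogram, n_terms: int, init_rates=None
) -> ExponentialMixtureFit:
    """Weighted least-squares fit of the n-term exponential mixture.

    Weights are 1/sigma with Poisson bin variance sigma^2 =
    max(counts, 1) / (n_total * width)^2, so empty bins still constrain
    the fit.  Reduced chi-square uses occupied bins minus the 2*n_terms
    parameters as the degrees of freedom.  Rates come back sorted
    ascending; near-coincident rates are flagged ``degenerate``.
    """
    if n_terms not in (2, 3):
        raise InvalidConfigError(f"n_terms must be 2 or 3, got {n_terms}")
    n_par = 2 * n_terms
    if hist.n_occupied < n_par + 1:
        raise InsufficientDataError(
            f"{hist.n_occupied} occupied bins < {n_par + 1} needed for a {n_terms}-term fit"
        )
    edges = hist.bin_edges
    sigma = np.sqrt(np.maximum(hist.counts, 1)) / (hist.n_total * hist.widths)

    def residual(p):
        return (_mixture_bin_means(p, edges, n_terms) - hist.densities) / sigma

    result = None
    failures = []
    for k0 in _candidate_inits(hist, n_terms, init_rates):
        res = lmfit.minimize(residual, _make_params(k0, n_terms), method="leastsq")
        if not res.success:
            failures.append(res.message)
            continue
        if result is None or res.chisqr < result.chisqr:
            result = res
    if result is None:
        raise FitFailureError(
            f"{n_terms}-term mixture fit failed: {failures}",
            diagnostics={"lmfit_messages": failures},
        )
    amps = np.array([result.params[f"A{i}"].value for i in range(n_terms)])
    rates = np.array([result.params[f"k{i}"].value for i in range(n_terms)])
    order = np.argsort(rates)
    amps, rates = amps[order], rates[order]
    chisq = float(np.sum(residual(result.params) ** 2))
    dof = hist.n_occupied - n_par
    redchi = chisq / dof if dof > 0 else np.inf
    degenerate = bool(np.any(np.abs(rates[1:] / rates[:-1] - 1.0) < RATE_COLLISION_TOL))
    if degenerate:
        log.warning("%d-term fit has nearly coincident rates: %s", n_terms, rates)
    return ExponentialMixtureFit(
        n_terms=n_terms,
        amplitudes=amps,
        rates=rates,
        reduced_chi_square=redchi,
        chi_square=chisq,
        n_occupied_bins=hist.n_occupied,
        covariance=result.covar,
        degenerate=degenerate,
    )


def select_model(
    fit2: ExponentialMixtureFit,
    fit3: ExponentialMixtureFit,
    improvement_factor: float = 0.8,
) -> int:
    """Pick 2 or 3 exponential terms from the reduced chi-square.

    Three terms win only if their reduced chi-square is below
    ``improvement_factor`` times the two-term value; otherwise the simpler
    model stands.
    """
    choice = 3 if fit3.reduced_chi_square < improvement_factor * fit2.reduced_chi_square else 2
    log.info(
        "model selection: redchi2=%.4g redchi3=%.4g factor=%.2f -> %d terms",
        fit2.reduced_chi_square,
        fit3.reduced_chi_square,
        improvement_factor,
        choice,
    )
    return choice
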