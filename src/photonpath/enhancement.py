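"""Per-state count rates, intensities and substrate enhancement factors.

The reconstructed state path collects the interphoton intervals of each
molecular state; the reciprocal of their mean is the state's count rate
k_n'.  Fluorescence intensity is the difference between count rates of
adjacent states (I1 = k1' - k0' is emission above background, I2 = k2' -
k1' the second emitting state above the first).  Cohort-level statistics
group intensities into four distributions — two-state I1, all I1,
three-state I2, and all I1 and I2 pooled — and the enhancement factor is
the ratio of ZMW to glass mean intensity per distribution, optionally
after excluding anomalously bright glass molecules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import CorruptInputError, InsufficientStatesError, MissingGroupError
from .interphoton import InterphotonSeries
from .reconstruct import StatePath
from .simulate import PhotonTrajectory

__all__ = [
    "StateSummary",
    "IntensityResult",
    "GroupStats",
    "EnhancementResult",
    "BinnedTrajectory",
    "summarize_states",
    "compute_intensities",
    "aggregate_enhancement",
    "enhancement_from_means",
    "enhancement_factor",
    "round_half_up",
    "bin_trajectory",
    "GROUPS",
]

log = logging.getLogger(__name__)

#: default glass-side outlier cut, photons/s
DEFAULT_OUTLIER_THRESHOLD = 16_000.0

#: the four cohort distributions, in reporting order
GROUPS = ("two_state_I1", "all_I1", "three_state_I2", "pooled_I1_I2")


@dataclass(frozen=True)
class StateSummary:
    """Occupation statistics of one model state along the Viterbi path."""

    state: int
    n_intervals: int
    total_time: float
    mean_interphoton_time: float | None
    count_rate: float | None  # k_n' = 1 / mean interphoton time


@dataclass(frozen=True)
class IntensityResult:
    """Adjacent-state count-rate differences for one molecule.

    ``intensities[n]`` holds I_n = k_n' - k_{n-1}' for each emitting state
    n whose lower neighbour is also occupied.  Negative values are kept
    but flagged (they indicate a state-ordering violation upstream).
    """

    molecule_id: str
    substrate: str
    n_states: int
    intensities: dict[int, float]
    flagged_negative: bool = False


@dataclass(frozen=True)
class GroupStats:
    mean: float
    std_error: float
    n: int
    values: tuple[float, ...] = ()


@dataclass(frozen=True)
class EnhancementResult:
    """Per-distribution glass/ZMW statistics and enhancement factors."""

    glass: dict[str, GroupStats]
    zmw: dict[str, GroupStats]
    ef: dict[str, float]          # raw mean ratios
    ef_rounded: dict[str, float]  # half-up to one decimal
    outlier_threshold: float | None
    excluded_ids: tuple[str, ...]


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def enhancement_factor(glass_mean: float, zmw_mean: float) -> tuple[float, float]:
    """Raw and one-decimal-rounded ZMW/glass mean-intensity ratio."""
    if glass_mean <= 0:
        raise MissingGroupError(f"glass mean must be positive, got {glass_mean}")
    raw = zmw_mean / glass_mean
    return raw, round_half_up(raw, 1)


def summarize_states(path: StatePath, series: InterphotonSeries, n_states: int | None = None) -> list[StateSummary]:
    """Per-state mean interphoton time and count rate along the path.

    Unoccupied states get a null summary (``None`` mean and rate).
    """
    if len(path) != len(series):
        raise CorruptInputError(
            f"path has {len(path)} intervals but series has {len(series)}"
        )
    S = n_states if n_states is not None else int(path.states.max()) + 1
    out = []
    for s in range(S):
        mask = path.states == s
        n = int(mask.sum())
        if n == 0:
            out.append(StateSummary(s, 0, 0.0, None, None))
            continue
        total = float(series.dt[mask].sum())
        mean_dt = total / n
        out.append(StateSummary(s, n, total, mean_dt, 1.0 / mean_dt))
    return out


def compute_intensities(
    summaries: list[StateSummary],
    molecule_id: str = "anonymous",
    substrate: str = "synthetic",
) -> IntensityResult:
    """Adjacent-state count-rate differences I_n = k_n' - k_{n-1}'."""
    occupied = [s for s in summaries if s.n_intervals > 0]
    if len(occupied) < 2:
        raise InsufficientStatesError(
            f"{molecule_id}: only {len(occupied)} occupied state(s); intensities undefined"
        )
    by_state = {s.state: s for s in summaries}
    intensities: dict[int, float] = {}
    flagged = False
    for n in sorted(by_state):
        if n == 0:
            continue
        lower = by_state.get(n - 1)
        cur = by_state[n]
        if cur.n_intervals == 0 or lower is None or lower.n_intervals == 0:
            continue
        val = cur.count_rate - lower.count_rate
        if val < 0:
            flagged = True
            log.warning("%s: negative intensity I%d = %.1f (state ordering violated)", molecule_id, n, val)
        intensities[n] = val
    return IntensityResult(
        molecule_id=molecule_id,
        substrate=substrate,
        n_states=len(summaries),
        intensities=intensities,
        flagged_negative=flagged,
    )


def _group_values(results: list[IntensityResult], group: str) -> tuple[list[float], list[str]]:
    vals, ids = [], []
    for r in results:
        if group == "two_state_I1":
            picked = [r.intensities[1]] if r.n_states == 2 and 1 in r.intensities else []
        elif group == "all_I1":
            picked = [r.intensities[1]] if 1 in r.intensities else []
        elif group == "three_state_I2":
            picked = [r.intensities[2]] if r.n_states == 3 and 2 in r.intensities else []
        else:  # pooled_I1_I2
            picked = [r.intensities[n] for n in sorted(r.intensities)]
        vals.extend(picked)
        ids.extend([r.molecule_id] * len(picked))
    return vals, ids


def _stats(values: list[float]) -> GroupStats:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return GroupStats(mean=float(arr.mean()), std_error=se, n=arr.size, values=tuple(values))


def aggregate_enhancement(
    results: list[IntensityResult],
    outlier_threshold: float | None = None,
    strict: bool = True,
) -> EnhancementResult:
    """Cohort statistics and ZMW/glass enhancement factors.

    When ``outlier_threshold`` is set, glass intensity values above it are
    excluded from every distribution and the molecules logged.  A
    distribution populated on one substrate only cannot be ratioed: with
    ``strict`` it raises :class:`MissingGroupError`, otherwise it is
    omitted with a warning.  Distributions empty on both substrates are
    always omitted.
    """
    excluded: set[str] = set()
    glass_stats: dict[str, GroupStats] = {}
    zmw_stats: dict[str, GroupStats] = {}
    ef: dict[str, float] = {}
    ef_rounded: dict[str, float] = {}
    for group in GROUPS:
        per_sub = {}
        for substrate in ("glass", "ZMW"):
            sub_results = [r for r in results if r.substrate == substrate]
            vals, ids = _group_values(sub_results, group)
            if substrate == "glass" and outlier_threshold is not None:
                kept = [(v, i) for v, i in zip(vals, ids) if v <= outlier_threshold]
                dropped = [i for v, i in zip(vals, ids) if v > outlier_threshold]
                if dropped:
                    log.info("outlier exclusion (> %.0f photons/s) in %s: %s", outlier_threshold, group, dropped)
                    excluded.update(dropped)
                vals = [v for v, _ in kept]
            per_sub[substrate] = vals
        if not per_sub["glass"] and not per_sub["ZMW"]:
            continue  # distribution absent from this cohort (e.g. no 3-state molecules)
        one_sided = [sub for sub in ("glass", "ZMW") if not per_sub[sub]]
        if one_sided:
            if strict:
                raise MissingGroupError(
                    f"no {one_sided[0]} intensities in distribution {group!r}"
                )
            log.warning("distribution %r has no %s intensities; omitted", group, one_sided[0])
            continue
        for substrate in ("glass", "ZMW"):
            per_sub[substrate] = _stats(per_sub[substrate])
        glass_stats[group] = per_sub["glass"]
        zmw_stats[group] = per_sub["ZMW"]
        ef[group], ef_rounded[group] = enhancement_factor(
            per_sub["glass"].mean, per_sub["ZMW"].mean
        )
    return EnhancementResult(
        glass=glass_stats,
        zmw=zmw_stats,
        ef=ef,
        ef_rounded=ef_rounded,
        outlier_threshold=outlier_threshold,
        excluded_ids=tuple(sorted(excluded)),
    )


def enhancement_from_means(means: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    """Enhancement factors from per-distribution (glass mean, ZMW mean)
    pairs — e.g. published summary tables — via the same ratio-and-round
    arithmetic as :func:`aggregate_enhancement`."""
    return {g: enhancement_factor(gm, zm) for g, (gm, zm) in means.items()}


@dataclass(frozen=True)
class BinnedTrajectory:
    """Display-style fixed-width binning of a photon stream with an
    optional state-path overlay scaled to the per-state count rates."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    overlay: np.ndarray | None = None  # expected counts/bin of the majority state


def bin_trajectory(
    traj: PhotonTrajectory,
    path: StatePath | None = None,
    bin_width: float = 0.1,
) -> BinnedTrajectory:
    """Bin photon arrivals into fixed-width time bins (default 100 ms).

    With a state path, each bin gets an overlay value: the count rate of
    the state occupying the majority of the bin, scaled to expected
    counts per bin, with the rate of each state estimated from its mean
    interphoton time along the path.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = traj.arrival_times
    if t.size == 0:
        return BinnedTrajectory(bin_width, np.array([0.0]), np.empty(0, dtype=int))
    n_bins = max(int(math.ceil(t[-1] / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] <= t[-1]:  # last photon exactly on the edge
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(t, bins=edges)
    overlay = None
    if path is not None:
        # per-state count rate = interval count / total occupied time
        rates = {}
        for s in {seg[2] for seg in path.segments}:
            dur = sum(e - b for b, e, st in path.segments if st == s)
            n_int = int(np.sum(path.states == s))
            rates[s] = n_int / dur if dur > 0 else 0.0
        overlay = np.zeros(counts.size)
        for i in range(counts.size):
            lo, hi = edges[i], edges[i + 1]
            best_s, best_t = None, 0.0
            for b, e, s in path.segments:
                ov = min(hi, e) - max(lo, b)
                if ov > best_t:
                    best_t, best_s = ov, s
            overlay[i] = rates.get(best_s, 0.0) * bin_width if best_s is not None else 0.0
    return BinnedTrajectory(bin_width, edges, counts, overlay)
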