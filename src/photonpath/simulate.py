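"""Synthetic photon-stream generation.

Emission is modeled as a Markov-modulated Poisson process: a molecule
occupies one hidden state at a time, each state emits photons as a
homogeneous Poisson process at its total count rate (background photons
included, so state rates are directly comparable to the per-state count
rates k_n' estimated downstream), and the state switches according to a
small kinetic scheme.  Supported schemes:

``two_state_bleach``
    one emitting state that photobleaches irreversibly to background
    (glass-like single-step bleach).
``three_state_bleach``
    two emitting states bleaching sequentially 2 -> 1 -> 0 (the
    double-step traces attributed to two dyes in one confocal spot).
``three_state_blink``
    reversible alternation between two emitting states atop background
    (ZMW-like blinking), optionally terminated by an independent
    photobleach clock to state 0.
``constant``
    a single state held for the whole duration (calibration aid).

Dwell times are exponential.  Photon arrivals inside each dwell segment
are generated as exponential gaps restarted at every segment boundary,
which by memorylessness is exactly the competing-clocks event simulation
with no time discretization.  Timestamps are then quantized to the timing
resolution of the emulated counting hardware and colliding photons are
dropped (later one loses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "EmissionState",
    "KineticScheme",
    "SimulationConfig",
    "PhotonTrajectory",
    "GroundTruthPath",
    "simulate_trajectory",
    "simulate_cohort",
]

#: TCSPC-like timestamp quantum, seconds.
DEFAULT_TIMING_RESOLUTION = 4e-12

MODES = ("two_state_bleach", "three_state_bleach", "three_state_blink", "constant")


@dataclass(frozen=True)
class EmissionState:
    """One hidden molecular state: ``index`` (0 = background) and its total
    photon count rate in photons/s."""

    index: int
    rate: float

    def __post_init__(self):
        if not self.rate > 0:
            raise InvalidConfigError(f"state {self.index}: rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class KineticScheme:
    """States plus switching kinetics.

    ``dwell_means[i]`` is the mean dwell (s) of state ``i``; it is ignored
    for absorbing states (the bleach target).  ``blink_bleach_mean`` is the
    mean of the optional independent photobleach clock active in
    ``three_state_blink`` mode (``None`` disables terminal bleaching).
    """

    states: tuple[EmissionState, ...]
    dwell_means: tuple[float, ...]
    mode: str
    bleach_target: int = 0
    blink_bleach_mean: float | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise InvalidConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        idx = [s.index for s in self.states]
        if len(set(idx)) != len(idx):
            raise InvalidConfigError("state indices must be unique")
        rates = [s.rate for s in self.states]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise InvalidConfigError("states must be ordered ascending by rate")
        if len(self.dwell_means) != len(self.states):
            raise InvalidConfigError("need one dwell mean per state")
        if any(m <= 0 for m in self.dwell_means):
            raise InvalidConfigError("dwell means must be positive")
        n = len(self.states)
        if self.mode == "two_state_bleach" and n != 2:
            raise InvalidConfigError("two_state_bleach needs exactly 2 states")
        if self.mode in ("three_state_bleach", "three_state_blink") and n != 3:
            raise InvalidConfigError(f"{self.mode} needs exactly 3 states")
        if self.blink_bleach_mean is not None and self.blink_bleach_mean <= 0:
            raise InvalidConfigError("blink_bleach_mean must be positive")

    @property
    def rates(self) -> np.ndarray:
        return np.array([s.rate for s in self.states], dtype=float)


@dataclass(frozen=True)
class SimulationConfig:
    scheme: KineticScheme
    duration: float
    seed: int
    timing_resolution: float = DEFAULT_TIMING_RESOLUTION

    def __post_init__(self):
        if not self.duration > 0:
            raise InvalidConfigError(f"duration must be > 0, got {self.duration}")
        if not self.timing_resolution > 0:
            raise InvalidConfigError("timing_resolution must be > 0")
        if self.timing_resolution >= 1.0 / max(s.rate for s in self.scheme.states):
            raise InvalidConfigError("timing_resolution must be far below the mean interphoton time")


@dataclass(frozen=True)
class PhotonTrajectory:
    """Strictly increasing photon arrival times (s) for one molecule."""

    arrival_times: np.ndarray
    substrate: str = "synthetic"
    molecule_id: str = "anonymous"

    def __post_init__(self):
        t = np.asarray(self.arrival_times, dtype=float)
        object.__setattr__(self, "arrival_times", t)

    def __len__(self) -> int:
        return self.arrival_times.size


@dataclass(frozen=True)
class GroundTruthPath:
    """True state segments tiling [0, duration]: (start, end, state_index)."""

    segments: tuple[tuple[float, float, int], ...]

    @property
    def duration(self) -> float:
        return self.segments[-1][1]

    def state_at(self, t: float) -> int:
        for start, end, s in self.segments:
            if start <= t < end:
                return s
        return self.segments[-1][2]

    def boundaries(self) -> list[float]:
        return [seg[0] for seg in self.segments[1:]]


def _draw_segments(scheme: KineticScheme, duration: float, rng: np.random.Generator):
    """Realize the hidden state sequence as (start, end, state_index) tuples."""
    segs: list[tuple[float, float, int]] = []
    t = 0.0
    by_index = {s.index: s for s in scheme.states}

    def dwell(state_index: int) -> float:
        pos = [s.index for s in scheme.states].index(state_index)
        return rng.exponential(scheme.dwell_means[pos])

    if scheme.mode == "constant":
        state = scheme.states[-1].index if len(scheme.states) > 1 else scheme.states[0].index
        segs.append((0.0, duration, state))
        return segs

    if scheme.mode == "two_state_bleach":
        order = [by_index[1].index, scheme.bleach_target]
    elif scheme.mode == "three_state_bleach":
        order = [by_index[2].index, by_index[1].index, scheme.bleach_target]
    else:  # three_state_blink
        bleach_at = (
            rng.exponential(scheme.blink_bleach_mean)
            if scheme.blink_bleach_mean is not None
            else math.inf
        )
        state = by_index[2].index  # start in the brighter emitting state
        while t < duration and t < bleach_at:
            end = min(t + dwell(state), duration, bleach_at)
            segs.append((t, end, state))
            t = end
            state = 3 - state  # toggle 1 <-> 2
        if t < duration:  # photobleached: background for the remainder
            segs.append((t, duration, scheme.bleach_target))
        return segs

    # sequential bleach cascade; the final (background) state is absorbing
    for state in order[:-1]:
        if t >= duration:
            break
        end = min(t + dwell(state), duration)
        segs.append((t, end, state))
        t = end
    if t < duration:
        segs.append((t, duration, order[-1]))
    return segs


def _poisson_arrivals(t0: float, t1: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson arrivals in [t0, t1) via exponential gaps."""
    span = t1 - t0
    if span <= 0:
        return np.empty(0)
    out = []
    t = 0.0
    mean_n = rate * span
    chunk = max(int(mean_n + 6.0 * math.sqrt(mean_n + 1.0)) + 16, 16)
    while True:
        gaps = rng.exponential(1.0 / rate, size=chunk)
        times = t + np.cumsum(gaps)
        inside = times[times < span]
        out.append(inside)
        if inside.size < times.size:
            break
        t = times[-1]
    return t0 + np.concatenate(out)


def simulate_trajectory(config: SimulationConfig) -> tuple[PhotonTrajectory, GroundTruthPath]:
    """Simulate one photon stream and its ground-truth state path.

    Within each ground-truth segment of state ``n`` the interphoton times
    are exponential at rate ``k_n``; dwell times are exponential with the
    configured means; identical seeds reproduce identical output
    bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    segs = _draw_segments(config.scheme, config.duration, rng)
    by_index = {s.index: s.rate for s in config.scheme.states}
    parts = [_poisson_arrivals(a, b, by_index[s], rng) for a, b, s in segs]
    times = np.concatenate(parts) if parts else np.empty(0)
    # quantize to the timing resolution; drop the later photon on collision
    q = np.round(times / config.timing_resolution) * config.timing_resolution
    keep = np.ones(q.size, dtype=bool)
    keep[1:] = np.diff(q) > 0
    q = q[keep]
    traj = PhotonTrajectory(arrival_times=q, substrate="synthetic", molecule_id=f"sim_{config.seed}")
    return traj, GroundTruthPath(segments=tuple(segs))


@dataclass(frozen=True)
class CohortSpec:
    """A simulation recipe replicated ``count`` times within one cohort arm."""

    scheme: KineticScheme
    duration: float
    count: int
    timing_resolution: float = DEFAULT_TIMING_RESOLUTION

    def __post_init__(self):
        if self.count < 1:
            raise InvalidConfigError("count must be >= 1")


def simulate_cohort(
    glass_specs: list[CohortSpec],
    zmw_specs: list[CohortSpec],
    seed: int,
) -> list[tuple[PhotonTrajectory, GroundTruthPath]]:
    """Simulate a two-substrate cohort.

    Per-molecule seeds are ``seed + ordinal`` so the cohort is reproducible
    while streams stay independent.  Molecule IDs encode substrate and
    ordinal (``glass_000``, ``zmw_017`` ...).
    """
    if not glass_specs and not zmw_specs:
        raise InvalidConfigError("cohort needs at least one spec")
    out: list[tuple[PhotonTrajectory, GroundTruthPath]] = []
    ordinal = 0
    for substrate, specs in (("glass", glass_specs), ("ZMW", zmw_specs)):
        counter = 0
        for spec in specs:
            for _ in range(spec.count):
                cfg = SimulationConfig(
                    scheme=spec.scheme,
                    duration=spec.duration,
                    seed=seed + ordinal,
                    timing_resolution=spec.timing_resolution,
                )
                traj, truth = simulate_trajectory(cfg)
                traj = PhotonTrajectory(
                    arrival_times=traj.arrival_times,
                    substrate=substrate,
                    molecule_id=f"{substrate.lower()}_{counter:03d}",
                )
                out.append((traj, truth))
                ordinal += 1
                counter += 1
    return out


def two_state_bleach_scheme(
    background_rate: float = 649.0,
    emitting_rate: float = 1625.0,
    bleach_mean: float = 6.0,
) -> KineticScheme:
    """Glass-like single-step photobleach scheme (defaults mirror a typical
    Atto647-on-glass trace: ~650 photons/s background, ~1600 photons/s on)."""
    return KineticScheme(
        states=(EmissionState(0, background_rate), EmissionState(1, emitting_rate)),
        dwell_means=(1e9, bleach_mean),
        mode="two_state_bleach",
    )


def three_state_blink_scheme(
    background_rate: float = 650.0,
    rate1: float = 2500.0,
    rate2: float = 6000.0,
    dwell1: float = 0.5,
    dwell2: float = 0.5,
    bleach_mean: float | None = 6.0,
) -> KineticScheme:
    """ZMW-like blinking between two emitting states with terminal bleach.

    The bleach clock default keeps the emulated acquisition protocol:
    recordings continue until a photobleach step and the background count
    rate are observed, so background occupancy appears in nearly every
    trace."""
    return KineticScheme(
        states=(
            EmissionState(0, background_rate),
            EmissionState(1, rate1),
            EmissionState(2, rate2),
        ),
        dwell_means=(1e9, dwell1, dwell2),
        mode="three_state_blink",
        blink_bleach_mean=bleach_mean,
    )


def three_state_bleach_scheme(
    background_rate: float = 650.0,
    rate1: float = 2500.0,
    rate2: float = 6000.0,
    dwell1: float = 4.0,
    dwell2: float = 4.0,
) -> KineticScheme:
    """Double-step photobleach (two dyes in one spot, glass-like)."""
    return KineticScheme(
        states=(
            EmissionState(0, background_rate),
            EmissionState(1, rate1),
            EmissionState(2, rate2),
        ),
        dwell_means=(1e9, dwell1, dwell2),
        mode="three_state_bleach",
    )
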