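"""Analysis configuration with YAML round-tripping.

Defaults pin the physically meaningful values the analysis relies on: a
transition rate of 1e-10 transitions/s for the Viterbi chain and 100 ms
bins for display-style trajectory binning.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import InvalidConfigError

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    #: interphoton histogram bins and scale
    n_bins: int = 50
    binning: str = "log"
    #: 3-term model wins if redchi3 < improvement_factor * redchi2
    improvement_factor: float = 0.8
    #: pinned Viterbi transition rate, transitions/s
    transition_rate: float = 1e-10
    #: rate-refinement simplex budget and relative likelihood tolerance
    optimizer_maxiter: int = 500
    likelihood_rtol: float = 1e-8
    #: display binning width, seconds
    bin_width: float = 0.1
    #: glass-side intensity outlier cut, photons/s (None = keep everything)
    outlier_threshold: float | None = None
    #: minimum photons per trajectory for reconstruction
    min_photons: int = 100
    #: cohort / pipeline seed
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 4:
            raise InvalidConfigError("n_bins must be >= 4")
        if self.binning not in ("log", "linear"):
            raise InvalidConfigError("binning must be 'log' or 'linear'")
        for name in ("improvement_factor", "transition_rate", "likelihood_rtol", "bin_width"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.outlier_threshold is not None and self.outlier_threshold <= 0:
            raise InvalidConfigError("outlier_threshold must be positive when set")
        if self.min_photons < 3:
            raise InvalidConfigError("min_photons must be >= 3")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
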