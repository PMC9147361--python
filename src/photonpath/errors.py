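"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: InvalidConfigError -> 2,
CorruptInputError -> 3, FitFailureError -> 4.
"""


class PhotonPathError(Exception):
    """Base class for all photonpath errors."""


class InvalidConfigError(PhotonPathError):
    """A configuration value violates its physical or structural constraints."""


class CorruptInputError(PhotonPathError):
    """Input data violates an invariant (non-monotone timestamps, dt <= 0, ...)."""


class InsufficientDataError(PhotonPathError):
    """Not enough photons / occupied bins to run the requested operation."""


class FitFailureError(PhotonPathError):
    """The exponential-mixture fit did not converge.

    Carries optimizer diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientStatesError(PhotonPathError):
    """Fewer than two occupied states; no intensity difference is defined."""


class MissingGroupError(PhotonPathError):
    """An enhancement distribution has no molecules on one substrate."""


class ConsistencyError(PhotonPathError):
    """Cross-artifact molecule IDs or lengths disagree."""
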