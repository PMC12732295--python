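"""Exception hierarchy for the automaton package."""


class RDAError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RDAError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class NoAdmissibleState(RDAError):
    """The requested state violates an admissibility condition.

    The ``reason`` attribute names the first condition that failed, e.g.
    ``"n <= 0 branch"`` or ``"x2 <= x0"``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        msg = f"no stationary state: {reason}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class NonStationaryWarning(UserWarning):
    """Simulated time series shows no stationary plateau."""
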