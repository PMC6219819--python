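"""Exception hierarchy for hiddenpaths.

All errors derive from :class:`HiddenPathsError` so callers can catch the
package's failures with one clause; the stability errors additionally carry
enough state (iteration traces, offending frequency) to let ensemble
pipelines skip unstable draws rather than abort.
"""

from __future__ import annotations


class HiddenPathsError(Exception):
    """Base class for all hiddenpaths errors."""


class InvalidKernelError(HiddenPathsError, ValueError):
    """Raised for non-positive kernel rate parameters or unknown families."""


class InvalidPartitionError(HiddenPathsError, ValueError):
    """Raised when recorded/hidden index sets overlap or do not cover the network."""


class InvalidConfigError(HiddenPathsError, ValueError):
    """Raised for inconsistent generator or run configurations."""


class UnsupportedNonlinearityError(HiddenPathsError, ValueError):
    """Raised when an operation requires a specific rate nonlinearity."""


class HiddenNetworkUnstableError(HiddenPathsError, RuntimeError):
    """Hidden-subnetwork mean-field iteration diverged or failed to converge.

    Catchable so that ensemble pipelines can skip-and-count unstable random
    draws (excitation-dominated hidden subsets under an unbounded
    nonlinearity have no steady state).
    """

    def __init__(self, message: str, iterations: int = 0, trace=None):
        super().__init__(message)
        self.iterations = iterations
        #: residual history of the fixed-point iteration (last few entries)
        self.trace = list(trace) if trace is not None else []


class LinearResponseSingularError(HiddenPathsError, RuntimeError):
    """[I - V(omega)] was singular at some frequency; names the frequency."""

    def __init__(self, omega: float):
        super().__init__(
            f"linear response singular: [I - V(omega)] not invertible at omega={omega!r}"
        )
        self.omega = omega


class UnstableFixtureError(HiddenPathsError, ValueError):
    """Circuit fixture parameters violate the closed-form convergence condition."""


class SimulationUnstableError(HiddenPathsError, RuntimeError):
    """Spike probability per bin persistently exceeded 1; carries onset time."""

    def __init__(self, message: str, t_onset: float):
        super().__init__(message)
        self.t_onset = t_onset


class SpecParseError(HiddenPathsError, ValueError):
    """Network-spec JSON violated the schema; names the offending field."""

    def __init__(self, field: str, message: str | None = None):
        super().__init__(message or f"invalid or missing field {field!r} in network spec")
        self.field = field
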