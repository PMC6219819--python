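"""Domain types for nonlinear Hawkes networks.

A network is a collection of ``N`` point-process neurons whose instantaneous
rate is ``lambda_i(t) = lambda0 * phi(mu_i + sum_j (J_ij * g_j) convolved with
spikes_j)``.  Couplings factor into a time-integrated synaptic weight ``J_ij``
(row = postsynaptic ``i``, column = presynaptic ``j``; units of time) and a
normalized temporal waveform ``g(t)`` with ``integral_0^inf g = 1``.  Diagonal
entries model self-history effects (refractoriness when negative), not
autapses.

The module provides closed-form time- and frequency-domain kernel evaluation
under the transform convention ``ghat(omega) = int dt exp(-i omega t) g(t)``,
the supported rate nonlinearities with analytic derivatives, and the
recorded/hidden block decomposition of the weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import InvalidKernelError, InvalidPartitionError

__all__ = [
    "Kernel",
    "Nonlinearity",
    "KernelAssignment",
    "NetworkSpec",
    "Partition",
    "kernel_time",
    "kernel_freq",
    "apply_nonlinearity",
    "nonlinearity_deriv",
    "block_weights",
]

_KERNEL_FAMILIES = ("alpha", "single_exp", "delta")
_NL_KINDS = ("exponential", "rectified_linear", "sigmoid")


@dataclass(frozen=True)
class Kernel:
    """Normalized causal synaptic waveform.

    family
        ``"alpha"``: g(t) = alpha^2 t exp(-alpha t);
        ``"single_exp"``: g(t) = beta exp(-beta t);
        ``"delta"``: g(t) = delta(t), a zero-frequency-only device that lets
        computations at omega=0 bypass temporal structure entirely.
    rate_param
        alpha (alpha family) or beta (single_exp), in units of inverse time;
        ignored by the delta family.
    """

    family: str
    rate_param: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _KERNEL_FAMILIES:
            raise InvalidKernelError(f"unknown kernel family {self.family!r}")
        if self.family != "delta":
            if self.rate_param is None or not np.isfinite(self.rate_param) or self.rate_param <= 0:
                raise InvalidKernelError(
                    f"kernel family {self.family!r} requires a positive rate parameter, "
                    f"got {self.rate_param!r}"
                )

    def waveform(self, tau):
        """g(tau); zero for tau < 0 (causality)."""
        tau = np.asarray(tau, dtype=float)
        if self.family == "delta":
            raise InvalidKernelError("delta kernels have no pointwise time-domain waveform")
        a = self.rate_param
        pos = tau >= 0
        if self.family == "alpha":
            out = np.where(pos, a * a * tau * np.exp(-a * np.where(pos, tau, 0.0)), 0.0)
        else:  # single_exp
            out = np.where(pos, a * np.exp(-a * np.where(pos, tau, 0.0)), 0.0)
        return out if out.ndim else float(out)

    def freq(self, omega):
        """ghat(omega), closed form; ghat(0) = 1 exactly for every family."""
        omega = np.asarray(omega, dtype=float)
        if self.family == "alpha":
            a = self.rate_param
            out = a**2 / (a + 1j * omega) ** 2
        elif self.family == "single_exp":
            b = self.rate_param
            out = b / (b + 1j * omega)
        else:  # delta
            out = np.ones_like(omega, dtype=complex)
        return out if out.ndim else complex(out)


def kernel_time(kernel: Kernel, weight: float, tau):
    """Interaction value J * g(tau): the time-domain coupling filter."""
    return weight * kernel.waveform(tau)


def kernel_freq(kernel: Kernel, weight: float, omega):
    """Closed-form transform J * ghat(omega)."""
    return weight * kernel.freq(omega)


@dataclass(frozen=True)
class Nonlinearity:
    """Rate nonlinearity phi(x) >= 0 with an analytic derivative.

    ``ceiling`` is the saturation level c of the sigmoid c / (1 + exp(-x));
    it is ignored by the unbounded kinds.  The rectified-linear derivative is
    the Heaviside step with Theta(0) = 1 (the max(x, 0) subgradient choice).
    """

    kind: str
    ceiling: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _NL_KINDS:
            raise InvalidKernelError(f"unknown nonlinearity kind {self.kind!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "exponential":
            out = np.exp(x)
        elif self.kind == "rectified_linear":
            out = np.maximum(x, 0.0)
        else:
            out = self.ceiling / (1.0 + np.exp(-x))
        return out if out.ndim else float(out)

    def deriv(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "exponential":
            out = np.exp(x)
        elif self.kind == "rectified_linear":
            out = np.heaviside(x, 1.0)
        else:
            s = 1.0 / (1.0 + np.exp(-x))
            out = self.ceiling * s * (1.0 - s)
        return out if out.ndim else float(out)

    @property
    def bounded(self) -> bool:
        return self.kind == "sigmoid"


def apply_nonlinearity(nl: Nonlinearity, x):
    """phi(x), the nonnegative rate factor."""
    return nl(x)


def nonlinearity_deriv(nl: Nonlinearity, x):
    """phi'(x), analytic."""
    return nl.deriv(x)


@dataclass(frozen=True)
class KernelAssignment:
    """Resolves every ordered pair (post, pre) to a Kernel.

    Precedence: per-pair > self-override (post == pre) > per-presynaptic
    neuron > global default.  The separate self slot mirrors the common setup
    of alpha inter-neuron filters combined with exponential self-history
    filters without per-pair enumeration.
    """

    default: Kernel = field(default_factory=lambda: Kernel("alpha", 1.0))
    per_neuron: Mapping[int, Kernel] = field(default_factory=dict)
    per_pair: Mapping[tuple[int, int], Kernel] = field(default_factory=dict)
    self_kernel: Kernel | None = None

    def resolve(self, post: int, pre: int) -> Kernel:
        k = self.per_pair.get((post, pre))
        if k is not None:
            return k
        if post == pre and self.self_kernel is not None:
            return self.self_kernel
        k = self.per_neuron.get(pre)
        if k is not None:
            return k
        return self.default

    def groups(self, n: int) -> Iterator[tuple[Kernel, np.ndarray]]:
        """Yield (kernel, boolean NxN mask) partitioning all ordered pairs.

        The fast path (no per-pair/per-neuron entries) avoids the O(N^2)
        resolution loop.
        """
        if not self.per_pair and not self.per_neuron:
            full = np.ones((n, n), dtype=bool)
            if self.self_kernel is not None and self.self_kernel != self.default:
                eye = np.eye(n, dtype=bool)
                yield self.default, full & ~eye
                yield self.self_kernel, eye
            else:
                yield self.default, full
            return
        keys: dict[Kernel, np.ndarray] = {}
        for i in range(n):
            for j in range(n):
                k = self.resolve(i, j)
                mask = keys.get(k)
                if mask is None:
                    mask = np.zeros((n, n), dtype=bool)
                    keys[k] = mask
                mask[i, j] = True
        yield from keys.items()


@dataclass
class NetworkSpec:
    """Fully specified ground-truth network.

    weights[i, j] is the time-integrated synaptic weight from presynaptic
    neuron j to postsynaptic neuron i (units of time via the rate scale
    lambda0; time is measured in units of 1/lambda0 throughout).
    """

    n_neurons: int
    rate_scale: float
    baselines: np.ndarray
    weights: np.ndarray
    kernels: KernelAssignment = field(default_factory=KernelAssignment)
    nonlinearity: Nonlinearity = field(default_factory=lambda: Nonlinearity("exponential"))

    def __post_init__(self) -> None:
        self.baselines = np.asarray(self.baselines, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.n_neurons
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights matrix must be square of dimension {n}, got shape {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.baselines.shape != (n,):
            raise ValueError(f"baselines must have shape ({n},), got {self.baselines.shape}")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be nonnegative")
        self._kernel_groups: list[tuple[Kernel, np.ndarray]] | None = None

    # -- frequency-domain coupling blocks -------------------------------
    def _groups(self) -> list[tuple[Kernel, np.ndarray]]:
        if self._kernel_groups is None:
            self._kernel_groups = list(self.kernels.groups(self.n_neurons))
        return self._kernel_groups

    def coupling_freq(self, omega, rows=None, cols=None) -> np.ndarray:
        """Jhat(omega) block: matrix of closed-form kernel transforms x weights.

        omega may be a scalar (returns ``(len(rows), len(cols))``) or a 1-D
        array (returns ``(n_omega, len(rows), len(cols))``).
        """
        rows = np.arange(self.n_neurons) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_neurons) if cols is None else np.asarray(cols)
        omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
        out = np.zeros((omega_arr.size, rows.size, cols.size), dtype=complex)
        for kern, mask in self._groups():
            w = np.where(mask, self.weights, 0.0)[np.ix_(rows, cols)]
            if not np.any(w):
                continue
            out += kern.freq(omega_arr)[:, None, None] * w[None, :, :]
        if np.isscalar(omega) or np.asarray(omega).ndim == 0:
            return out[0]
        return out

    def alpha_max(self) -> float:
        """Fastest kernel rate in use; sets the default time resolution."""
        rates = [k.rate_param for k, m in self._groups() if k.family != "delta" and m.any()]
        return max(rates) if rates else 10.0 * self.rate_scale


@dataclass(frozen=True)
class Partition:
    """Ordered recorded/hidden index sets.

    Both sets preserve a deterministic ordering so the block matrices
    J_RR, J_RH, J_HR, J_HH are reproducible.
    """

    recorded: tuple[int, ...]
    hidden: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "recorded", tuple(int(i) for i in self.recorded))
        object.__setattr__(self, "hidden", tuple(int(i) for i in self.hidden))
        if set(self.recorded) & set(self.hidden):
            raise InvalidPartitionError("recorded and hidden index sets overlap")
        both = list(self.recorded) + list(self.hidden)
        if len(set(both)) != len(both):
            raise InvalidPartitionError("duplicate indices in partition")

    @classmethod
    def from_recorded(cls, n_neurons: int, recorded) -> "Partition":
        recorded = tuple(int(i) for i in recorded)
        hidden = tuple(i for i in range(n_neurons) if i not in set(recorded))
        return cls(recorded, hidden)

    def validate_for(self, n_neurons: int) -> None:
        union = set(self.recorded) | set(self.hidden)
        if union != set(range(n_neurons)):
            raise InvalidPartitionError(
                f"partition covers {len(union)} of {n_neurons} neurons "
                "(recorded and hidden must partition the full index set)"
            )

    @property
    def n_recorded(self) -> int:
        return len(self.recorded)

    @property
    def n_hidden(self) -> int:
        return len(self.hidden)


def block_weights(spec: NetworkSpec, part: Partition):
    """Split the weight matrix into (J_RR, J_RH, J_HR, J_HH) in partition order."""
    part.validate_for(spec.n_neurons)
    r = np.asarray(part.recorded, dtype=int)
    h = np.asarray(part.hidden, dtype=int)
    J = spec.weights
    return (
        J[np.ix_(r, r)],
        J[np.ix_(r, h)],
        J[np.ix_(h, r)],
        J[np.ix_(h, h)],
    )
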