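"""Mean-field steady state of the hidden subnetwork.

With the recorded neurons removed, the hidden rates solve the self-consistent
system ``nu_h = lambda0 * phi(mu_h + sum_h' J_hh' nu_h')`` (zero-frequency
weights enter because a stationary rate convolved with a normalized kernel is
itself).  The gain ``gamma_h = lambda0 * phi'(same argument)`` is the node
factor of the linear-response path expansion; for the exponential
nonlinearity ``gamma_h == nu_h`` exactly.

The solver is a damped fixed-point iteration
``nu <- (1 - eta) nu + eta lambda0 phi(mu + J_HH nu)`` initialized at the
zero-coupling rates ``lambda0 phi(mu_h)`` (the leading term of the small-rate
series).  Multiple fixed points, if any, are not searched for: the state
reached from this initialization is the one reported.

A perturbative series for the rates is available for the exponential
nonlinearity: with homogeneous baselines ``mu_0`` and ``eps = exp(mu_0)``,
``nu_h = lambda0 eps sum_l a_h^(l) (lambda0 eps)^l`` whose coefficients are
polynomial contractions of the hidden weight matrix (orders 0..3 implemented,
giving rates accurate to O(eps^4); the heterogeneous variant is implemented
to second order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import HiddenNetworkUnstableError, UnsupportedNonlinearityError
from .network_model import NetworkSpec, Partition, block_weights

__all__ = [
    "SolverConfig",
    "MeanFieldState",
    "SeriesRates",
    "solve_hidden_rates",
    "series_rates",
    "effective_baselines",
]


@dataclass(frozen=True)
class SolverConfig:
    tolerance: float = 1e-10
    damping: float = 0.5
    max_iterations: int = 10_000
    divergence_cap: float = 1e6  # in units of lambda0


@dataclass
class MeanFieldState:
    """Steady hidden rates nu_h and gains gamma_h (partition's hidden order)."""

    rates: np.ndarray
    gains: np.ndarray
    converged: bool
    iterations: int
    residual: float

    @property
    def n_hidden(self) -> int:
        return self.rates.size


def solve_hidden_rates(
    spec: NetworkSpec, part: Partition, config: SolverConfig | None = None
) -> MeanFieldState:
    """Solve the hidden-subnetwork fixed point in the absence of recorded neurons.

    Raises
    ------
    HiddenNetworkUnstableError
        If rates exceed the divergence cap or the iteration fails to reach
        tolerance; catchable so ensemble pipelines can skip unstable draws.
    """
    config = config or SolverConfig()
    part.validate_for(spec.n_neurons)
    h = np.asarray(part.hidden, dtype=int)
    if h.size == 0:
        return MeanFieldState(np.zeros(0), np.zeros(0), True, 0, 0.0)
    lam0 = spec.rate_scale
    phi = spec.nonlinearity
    mu = spec.baselines[h]
    J_hh = block_weights(spec, part)[3]
    cap = config.divergence_cap * max(lam0, 1.0)

    nu = lam0 * phi(mu)
    eta = config.damping
    trace: list[float] = []
    for it in range(1, config.max_iterations + 1):
        target = lam0 * phi(mu + J_hh @ nu)
        residual = float(np.max(np.abs(target - nu)))
        trace.append(residual)
        if not np.all(np.isfinite(target)) or np.max(target) > cap:
            raise HiddenNetworkUnstableError(
                f"hidden mean-field rates diverged after {it} iterations "
                f"(cap {cap:g})",
                iterations=it,
                trace=trace[-20:],
            )
        nu = (1.0 - eta) * nu + eta * target
        if residual < config.tolerance:
            arg = mu + J_hh @ nu
            gains = lam0 * phi.deriv(arg)
            return MeanFieldState(lam0 * phi(arg), gains, True, it, residual)
    raise HiddenNetworkUnstableError(
        f"hidden mean-field iteration did not converge within "
        f"{config.max_iterations} iterations (residual {trace[-1]:.3e})",
        iterations=config.max_iterations,
        trace=trace[-20:],
    )


@dataclass
class SeriesRates:
    """Perturbative hidden rates: coefficients (homogeneous case) and values."""

    rates: np.ndarray
    coefficients: np.ndarray | None  # shape (n_hidden, order + 1); None if heterogeneous
    order: int
    epsilon: np.ndarray  # exp(mu_h), per hidden neuron


def series_rates(spec: NetworkSpec, part: Partition, order: int) -> SeriesRates:
    """Small-``exp(mu)`` series for the hidden rates (exponential nonlinearity).

    Homogeneous baselines support ``order <= 3`` (rates to O(eps^4));
    heterogeneous baselines support ``order <= 2``.
    """
    if spec.nonlinearity.kind != "exponential":
        raise UnsupportedNonlinearityError(
            "rate series requires the exponential nonlinearity"
        )
    part.validate_for(spec.n_neurons)
    h = np.asarray(part.hidden, dtype=int)
    lam0 = spec.rate_scale
    mu = spec.baselines[h]
    J = block_weights(spec, part)[3]
    eps = np.exp(mu)
    ones = np.ones(h.size)
    homogeneous = bool(np.all(mu == mu[0])) if h.size else True

    if order < 0:
        raise ValueError("order must be nonnegative")
    if homogeneous:
        if order > 3:
            raise ValueError("homogeneous series implemented through order 3")
        a = np.zeros((h.size, order + 1))
        a[:, 0] = 1.0
        J1 = J @ ones  # row sums
        if order >= 1:
            a[:, 1] = J1
        if order >= 2:
            a[:, 2] = J @ J1 + 0.5 * J1**2
        if order >= 3:
            JJ1 = J @ J1
            a[:, 3] = J @ JJ1 + 0.5 * (J @ (J1**2)) + J1 * JJ1 + J1**3 / 6.0
        le = lam0 * eps  # homogeneous: scalar value broadcast per neuron
        rates = le * sum(a[:, l] * le**l for l in range(order + 1))
        return SeriesRates(rates=rates, coefficients=a, order=order, epsilon=eps)

    if order > 2:
        raise ValueError("heterogeneous series implemented through order 2")
    le = lam0 * eps
    rates = le.copy()
    if order >= 1:
        rates = le * (1.0 + J @ le)
    if order >= 2:
        # sum_{h1,h2} { J_{h,h1} J_{h1,h2} + 1/2 J_{h,h1} J_{h,h2} } eps_h1 eps_h2
        quad = J @ (le * (J @ le)) + 0.5 * (J @ le) ** 2
        rates = le * (1.0 + J @ le + quad)
    return SeriesRates(rates=rates, coefficients=None, order=order, epsilon=eps)


def effective_baselines(spec: NetworkSpec, part: Partition, mf: MeanFieldState) -> np.ndarray:
    """mu_r^eff = mu_r + sum_h J_rh nu_h: tonic modulation by mean hidden input."""
    if not mf.converged:
        raise ValueError("mean-field state not converged")
    r = np.asarray(part.recorded, dtype=int)
    if mf.n_hidden != part.n_hidden:
        raise ValueError("mean-field state does not match partition")
    J_rh = block_weights(spec, part)[1]
    return spec.baselines[r] + J_rh @ mf.rates
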