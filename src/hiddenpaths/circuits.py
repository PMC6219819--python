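"""Worked small-circuit fixtures with analytic effective interactions.

Two classic motifs, both recording neurons 1 and 2 (0-based indices 0, 1):

* a 3-neuron feedforward-inhibition circuit — excitatory neuron 1 drives
  neuron 2 directly (alpha filter) and through a hidden inhibitory neuron 3
  that carries an exponential self-history (refractory) filter.  The hidden
  disynaptic branch narrows the window in which neuron 2 is likely to fire,
  and the self-history loop generates an emergent decay rate
  ``beta_33 (1 - gamma_3 J_33)`` present in no true kernel;

* a 4-neuron circuit in which the refractory self-loop is replaced by a
  second hidden inhibitory neuron (3 <-> 4 mutual inhibition, all alpha
  filters).  It is tuned to produce a near-identical effective interaction —
  a worked example of hidden-network degeneracy.

Both use the rectified-linear nonlinearity (gain = lambda0 exactly, no loop
corrections), so the effective interaction is independent of the hidden
baselines as long as the fixed-point argument stays positive.

Closed forms are obtained by exact partial-fraction (residue) inversion of
the rational frequency-domain path expressions; they are analytic in time
and fully independent of the FFT pipeline, which makes them a true oracle
for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Mapping

import numpy as np

from .errors import UnstableFixtureError
from .network_model import (
    Kernel,
    KernelAssignment,
    NetworkSpec,
    Nonlinearity,
    Partition,
)

__all__ = [
    "CircuitFixture",
    "SimilarityResult",
    "ffi_circuit",
    "four_neuron_circuit",
    "fixture_similarity",
]


def _merge_poles(poles) -> list[tuple[complex, int]]:
    merged: list[tuple[complex, int]] = []
    for p, m in poles:
        for idx, (p0, m0) in enumerate(merged):
            if abs(p - p0) < 1e-12 * (1.0 + abs(p0)):
                merged[idx] = (p0, m0 + m)
                break
        else:
            merged.append((complex(p), int(m)))
    return merged


def _partial_fractions_known_poles(num, poles):
    """Partial fractions of N(s) / prod_k (s - p_k)^{m_k} with the poles given.

    ``num`` are polynomial coefficients (highest power first) and ``poles``
    a list of (pole, multiplicity).  The expansion coefficients are obtained
    from exact truncated Taylor series at each pole (polynomial shifts for
    the numerator, binomial series for the other pole factors), which stays
    stable for high-multiplicity poles where numerical root-finding breaks.
    Returns terms (coef, pole, power) with power >= 1 meaning
    ``coef / (s - pole)^power``.
    """
    poles = _merge_poles(poles)
    num = np.atleast_1d(np.asarray(num, dtype=complex))
    deg_den = sum(m for _, m in poles)
    if num.size - 1 >= deg_den:
        raise ValueError("rational function must be strictly proper")
    terms: list[tuple[complex, complex, int]] = []
    for k, (pk, mk) in enumerate(poles):
        # Taylor coefficients (orders 0..mk-1) of h(s) = N(s) / prod_{l != k} (s-p_l)^{m_l}
        # in the local variable u = s - pk.
        series = _shift_poly(num, pk, mk)
        for l, (pl, ml) in enumerate(poles):
            if l == k:
                continue
            series = _mul_trunc(series, _inv_power_series(pk - pl, ml, mk), mk)
        coeffs = series
        for j in range(mk):
            coef = coeffs[j]
            power = mk - j
            if coef != 0:
                terms.append((coef, pk, power))
    return terms


def _shift_poly(coeffs_high_first, p, n_terms) -> np.ndarray:
    """Series of N(p + u) in u, truncated to n_terms (ascending powers)."""
    c = np.asarray(coeffs_high_first, dtype=complex)[::-1]  # ascending
    out = np.zeros(n_terms, dtype=complex)
    from math import comb

    for i, ci in enumerate(c):  # ci * (p + u)^i
        for j in range(min(i, n_terms - 1) + 1):
            out[j] += ci * comb(i, j) * p ** (i - j)
    return out


def _inv_power_series(delta: complex, m: int, n_terms: int) -> np.ndarray:
    """Series of 1/(delta + u)^m in u, truncated (ascending powers)."""
    from math import comb

    out = np.zeros(n_terms, dtype=complex)
    for i in range(n_terms):
        out[i] = comb(m + i - 1, i) * (-1.0) ** i / delta ** (m + i)
    return out


def _mul_trunc(a: np.ndarray, b: np.ndarray, n_terms: int) -> np.ndarray:
    return np.convolve(a, b)[:n_terms]


def _rational_time_fn(num, poles) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Inverse transform of a strictly proper rational function of s = i omega.

    ``poles`` is the analytically known pole list [(pole, multiplicity), ...]
    of the *monic* denominator.  Returns ``(f, pole_array)`` with
    ``f(tau) = sum coef tau^{power-1} e^{pole tau} / (power-1)!`` for tau >= 0
    and 0 otherwise (causality).
    """
    terms = _partial_fractions_known_poles(num, poles)

    def f(tau):
        tau = np.asarray(tau, dtype=float)
        pos = tau >= 0
        t = np.where(pos, tau, 0.0)
        out = np.zeros(t.shape, dtype=complex)
        for coef, pole, power in terms:
            out += coef * t ** (power - 1) * np.exp(pole * t) / factorial(power - 1)
        res = np.where(pos, out.real, 0.0)
        return res if res.ndim else float(res)

    pole_array = np.array([p for p, _ in _merge_poles(poles)])
    return f, pole_array


def _sum_fns(fns):
    def total(tau):
        return sum(f(tau) for f in fns)

    return total


@dataclass
class CircuitFixture:
    """A small circuit plus its analytic effective interaction 1 -> 2.

    ``closed_form(tau)`` evaluates J^eff_21(tau); ``components`` maps path
    labels to callables whose sum equals the closed form pointwise.
    ``poles`` collects the decay/oscillation rates (s-plane poles) of the
    indirect part, exposing emergent timescales.
    """

    spec: NetworkSpec
    partition: Partition
    closed_form: Callable[[np.ndarray], np.ndarray]
    components: Mapping[str, Callable[[np.ndarray], np.ndarray]]
    params: dict[str, float]
    poles: np.ndarray


def ffi_circuit(mu3: float = 0.95, **overrides) -> CircuitFixture:
    """3-neuron feedforward-inhibition fixture.

    Defaults (units of 1/lambda0): J21=1.0, J23=-2.0, J31=2.0, J33=-0.9,
    alpha21=alpha23=beta33=1.0, alpha31=1.8, lambda0=1.0.  ``mu3`` is the
    hidden baseline; it must keep the rectified-linear fixed-point argument
    positive, and the effective interaction does not depend on it.
    """
    p = dict(
        lam0=1.0,
        J21=1.0,
        J23=-2.0,
        J31=2.0,
        J33=-0.9,
        alpha21=1.0,
        alpha23=1.0,
        alpha31=1.8,
        beta33=1.0,
    )
    unknown = set(overrides) - set(p)
    if unknown:
        raise TypeError(f"unknown circuit parameters: {sorted(unknown)}")
    p.update(overrides)
    lam0 = p["lam0"]
    margin = 1.0 - lam0 * p["J33"]
    if margin <= 0:
        raise UnstableFixtureError(
            f"feedforward-inhibition fixture requires 1 - lambda0*J33 > 0, got {margin}"
        )
    nu3 = lam0 * mu3 / margin
    if mu3 <= 0 or mu3 + p["J33"] * nu3 <= 0:
        raise UnstableFixtureError(
            "mu3 must keep the rectified-linear argument of the hidden neuron positive"
        )

    weights = np.zeros((3, 3))
    weights[1, 0] = p["J21"]
    weights[1, 2] = p["J23"]
    weights[2, 0] = p["J31"]
    weights[2, 2] = p["J33"]
    kernels = KernelAssignment(
        default=Kernel("alpha", p["alpha21"]),
        per_pair={
            (1, 0): Kernel("alpha", p["alpha21"]),
            (1, 2): Kernel("alpha", p["alpha23"]),
            (2, 0): Kernel("alpha", p["alpha31"]),
            (2, 2): Kernel("single_exp", p["beta33"]),
        },
        self_kernel=Kernel("single_exp", p["beta33"]),
    )
    spec = NetworkSpec(
        n_neurons=3,
        rate_scale=lam0,
        baselines=np.array([0.0, 0.0, mu3]),
        weights=weights,
        kernels=kernels,
        nonlinearity=Nonlinearity("rectified_linear"),
    )
    part = Partition(recorded=(0, 1), hidden=(2,))

    gamma3 = lam0  # Theta(positive argument)
    a21, a23, a31, b33 = p["alpha21"], p["alpha23"], p["alpha31"], p["beta33"]
    b = b33 * (1.0 - gamma3 * p["J33"])

    def direct(tau):
        tau = np.asarray(tau, dtype=float)
        t = np.where(tau >= 0, tau, 0.0)
        out = np.where(tau >= 0, p["J21"] * a21**2 * t * np.exp(-a21 * t), 0.0)
        return out if out.ndim else float(out)

    # indirect branch: Jhat23 * gamma3/(1 - gamma3 Jhat33) * Jhat31
    #   = J23 J31 a23^2 a31^2 gamma3 (s + b33) / ((s+a23)^2 (s+a31)^2 (s + b))
    c = p["J23"] * p["J31"] * a23**2 * a31**2 * gamma3
    indirect, poles = _rational_time_fn(
        [c, c * b33], [(-a23, 2), (-a31, 2), (-b, 1)]
    )

    components = {"direct": direct, "via_3": indirect}
    return CircuitFixture(
        spec=spec,
        partition=part,
        closed_form=_sum_fns([direct, indirect]),
        components=components,
        params={**p, "mu3": mu3, "emergent_rate": b},
        poles=poles,
    )


def four_neuron_circuit(mu_hidden: float = 0.95, **overrides) -> CircuitFixture:
    """4-neuron degenerate fixture (hidden 3 <-> 4 inhibitory loop).

    Defaults: J21=J31=J41=1.0, J23=-3.0, J34=J43=-0.9, alpha21=1.0,
    alpha=1.294 for every other filter, lambda0=1.0.  Requires
    |J34||J43| < 1 for the loop resummation to converge.
    """
    p = dict(
        lam0=1.0,
        J21=1.0,
        J31=1.0,
        J41=1.0,
        J23=-3.0,
        J34=-0.9,
        J43=-0.9,
        alpha21=1.0,
        alpha=1.294,
    )
    unknown = set(overrides) - set(p)
    if unknown:
        raise TypeError(f"unknown circuit parameters: {sorted(unknown)}")
    p.update(overrides)
    lam0 = p["lam0"]
    q = lam0**2 * p["J34"] * p["J43"]
    if abs(p["J34"] * p["J43"]) >= 1.0:
        raise UnstableFixtureError(
            f"4-neuron fixture requires |J34||J43| < 1, got {abs(p['J34'] * p['J43'])}"
        )
    # hidden mutual inhibition: symmetric relu fixed point must stay positive
    nu = lam0 * mu_hidden / (1.0 - lam0 * min(p["J34"], p["J43"]))
    if mu_hidden <= 0 or nu <= 0:
        raise UnstableFixtureError("mu_hidden must keep hidden relu arguments positive")

    weights = np.zeros((4, 4))
    weights[1, 0] = p["J21"]
    weights[2, 0] = p["J31"]
    weights[3, 0] = p["J41"]
    weights[1, 2] = p["J23"]
    weights[2, 3] = p["J34"]
    weights[3, 2] = p["J43"]
    kernels = KernelAssignment(
        default=Kernel("alpha", p["alpha"]),
        per_pair={(1, 0): Kernel("alpha", p["alpha21"])},
    )
    spec = NetworkSpec(
        n_neurons=4,
        rate_scale=lam0,
        baselines=np.array([0.0, 0.0, mu_hidden, mu_hidden]),
        weights=weights,
        kernels=kernels,
        nonlinearity=Nonlinearity("rectified_linear"),
    )
    part = Partition(recorded=(0, 1), hidden=(2, 3))

    a21, a = p["alpha21"], p["alpha"]
    g = lam0  # relu gains
    # loop resummation poles: (s + a)^4 = q a^4  =>  s = -a + a q^{1/4} zeta, zeta^4 = 1
    r = (q + 0j) ** 0.25
    loop_poles = [(-a + a * r * z, 1) for z in (1, 1j, -1, -1j)]

    def direct(tau):
        tau = np.asarray(tau, dtype=float)
        t = np.where(tau >= 0, tau, 0.0)
        out = np.where(tau >= 0, p["J21"] * a21**2 * t * np.exp(-a21 * t), 0.0)
        return out if out.ndim else float(out)

    # path 2<-3<-1, bare (loop m=0): J23 g J31 a^4/(s+a)^4
    c_231 = p["J23"] * g * p["J31"] * a**4
    f_231, _ = _rational_time_fn([c_231], [(-a, 4)])
    # path 2<-3<-4<-1, bare: J23 g J34 g J41 a^6/(s+a)^6
    c_2341 = p["J23"] * g * p["J34"] * g * p["J41"] * a**6
    f_2341, _ = _rational_time_fn([c_2341], [(-a, 6)])
    # loop dressings (m >= 1): multiply the bare paths by q a^4/((s+a)^4 - q a^4)
    f_loop_231, poles_loop = _rational_time_fn(
        [c_231 * q * a**4], [(-a, 4)] + loop_poles
    )
    f_loop_2341, _ = _rational_time_fn(
        [c_2341 * q * a**4], [(-a, 6)] + loop_poles
    )

    components = {
        "direct": direct,
        "2<-3<-1": f_231,
        "2<-3<-4<-1": f_2341,
        "2<-3<>4<-3<-1": f_loop_231,
        "2<-3<>4<-1": f_loop_2341,
    }
    return CircuitFixture(
        spec=spec,
        partition=part,
        closed_form=_sum_fns(list(components.values())),
        components=components,
        params={**p, "mu_hidden": mu_hidden, "loop_gain": abs(q)},
        poles=poles_loop,
    )


@dataclass
class SimilarityResult:
    max_abs: float
    integrated_abs: float


def fixture_similarity(
    a: CircuitFixture,
    b: CircuitFixture,
    tau_max: float = 10.0,
    n_tau: int = 2001,
) -> SimilarityResult:
    """Max-absolute and integrated-absolute discrepancy of two closed forms."""
    tau = np.linspace(0.0, tau_max, n_tau)
    diff = np.abs(np.asarray(a.closed_form(tau)) - np.asarray(b.closed_form(tau)))
    return SimilarityResult(
        max_abs=float(diff.max()),
        integrated_abs=float(np.trapezoid(diff, tau)),
    )
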