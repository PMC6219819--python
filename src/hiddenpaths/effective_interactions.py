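"""Effective coupling filters between recorded neurons.

The central relationship: in the frequency domain the measured (effective)
filter between recorded neurons is the true filter plus corrections from
every directed path through hidden neurons,

    Jhat^eff(omega) = Jhat_RR(omega) + Jhat_RH(omega) Gammahat(omega) Jhat_HR(omega),

with ``Gammahat`` the hidden-network linear response.  The zero-frequency
component defines the effective synaptic weights, which also equal the time
integral of the effective filters; they depend only on the time-integrated
weights (every normalized kernel has ``ghat(0) = 1``), so they are computed by
a single real linear solve without any grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import LinearResponseSingularError
from .grids import FrequencyGrid
from .meanfield import (
    MeanFieldState,
    SolverConfig,
    effective_baselines,
    solve_hidden_rates,
)
from .linear_response import TransferOperator, transfer_operator
from .network_model import NetworkSpec, Partition, block_weights

__all__ = [
    "FrequencyGrid",
    "EffectiveModel",
    "effective_coupling_freq",
    "effective_weights",
    "to_time_domain",
    "build_effective_model",
]


def effective_coupling_freq(
    spec: NetworkSpec,
    part: Partition,
    mf: MeanFieldState,
    gammas: TransferOperator,
    grid: FrequencyGrid,
) -> np.ndarray:
    """Jhat^eff(omega) on every grid frequency; shape (n_fft, R, R)."""
    if not mf.converged:
        raise ValueError("mean-field state not converged")
    if gammas.grid != grid:
        raise ValueError("transfer operator was computed on a different grid")
    if tuple(gammas.hidden) != tuple(part.hidden):
        raise ValueError("transfer operator hidden ordering does not match partition")
    r = np.asarray(part.recorded, dtype=int)
    h = np.asarray(part.hidden, dtype=int)
    J_rr = spec.coupling_freq(grid.omegas, rows=r, cols=r)
    if h.size == 0:
        return J_rr
    J_rh = spec.coupling_freq(grid.omegas, rows=r, cols=h)
    J_hr = spec.coupling_freq(grid.omegas, rows=h, cols=r)
    return J_rr + J_rh @ gammas.gamma_matrices @ J_hr


def effective_weights(
    spec: NetworkSpec, part: Partition, mf: MeanFieldState
) -> np.ndarray:
    """Zero-frequency effective weights by one real linear solve.

    J^eff = J_RR + J_RH [I - V(0)]^{-1} diag(gamma) J_HR with
    V(0) = diag(gamma) J_HH; kernel shapes never enter.
    """
    if not mf.converged:
        raise ValueError("mean-field state not converged")
    J_rr, J_rh, J_hr, J_hh = block_weights(spec, part)
    if part.n_hidden == 0:
        return J_rr.copy()
    gamma = mf.gains
    A = np.eye(part.n_hidden) - gamma[:, None] * J_hh
    try:
        X = np.linalg.solve(A, gamma[:, None] * J_hr)
    except np.linalg.LinAlgError:
        raise LinearResponseSingularError(0.0) from None
    return J_rr + J_rh @ X


def to_time_domain(filters_freq: np.ndarray, grid: FrequencyGrid) -> np.ndarray:
    """Inverse-transform frequency-domain filters onto the grid's time bins.

    Linear in its input; warns and symmetrizes if the input is not
    Hermitian-consistent (a real time-domain filter requires
    ``fhat(-omega) = conj(fhat(omega))``), and warns if the imaginary residue
    of the inverse transform is unexpectedly large.
    """
    filters_freq = np.asarray(filters_freq, dtype=complex)
    scale = float(np.max(np.abs(filters_freq))) if filters_freq.size else 0.0
    defect = grid.hermitian_defect(filters_freq)
    if scale > 0 and defect > 1e-9 * scale:
        warnings.warn(
            f"filters_freq violates Hermitian symmetry (defect {defect:.2e}); "
            "symmetrizing before inverse transform",
            RuntimeWarning,
            stacklevel=2,
        )
        filters_freq = grid.symmetrize(filters_freq)
    ft = grid.inverse_transform(filters_freq)
    real = ft.real
    amp = float(np.max(np.abs(real))) if real.size else 0.0
    resid = float(np.max(np.abs(ft.imag))) if ft.size else 0.0
    if amp > 0 and resid > 1e-8 * amp:
        warnings.warn(
            f"imaginary residue {resid:.2e} exceeds 1e-8 of filter amplitude",
            RuntimeWarning,
            stacklevel=2,
        )
    return real


@dataclass
class EffectiveModel:
    """Effective description of the recorded subnetwork.

    filters_time has shape (n_time, R, R); weights_eff is the exact
    zero-frequency matrix (equal to the time-bin sum of filters_time times dt
    when the grid is not oversampled).  diagnostics records the imaginary
    residue of the inverse transform and the relative filter amplitude in the
    last 5% of the time window (wrap-around / truncation leakage).
    """

    partition: Partition
    baselines_eff: np.ndarray
    filters_freq: np.ndarray
    filters_time: np.ndarray
    weights_eff: np.ndarray
    grid: FrequencyGrid
    meanfield: MeanFieldState
    diagnostics: dict[str, float] = field(default_factory=dict)


def default_grid(spec: NetworkSpec, n_time: int = 4096, oversample: int = 1) -> FrequencyGrid:
    """Time step 0.1 / (fastest kernel rate): resolves the sharpest filter."""
    return FrequencyGrid(dt=0.1 / spec.alpha_max(), n_time=n_time, oversample=oversample)


def build_effective_model(
    spec: NetworkSpec,
    part: Partition,
    grid: FrequencyGrid | None = None,
    solver: SolverConfig | None = None,
) -> EffectiveModel:
    """One-call pipeline: mean field -> linear response -> effective filters.

    Deterministic: identical inputs give bit-identical results.  Propagates
    HiddenNetworkUnstableError and LinearResponseSingularError.
    """
    part.validate_for(spec.n_neurons)
    grid = grid or default_grid(spec)
    mf = solve_hidden_rates(spec, part, solver)
    if part.n_hidden == 0:
        r = np.asarray(part.recorded, dtype=int)
        filters_freq = spec.coupling_freq(grid.omegas, rows=r, cols=r)
        baselines = spec.baselines[r].copy()
        weights = block_weights(spec, part)[0].copy()
    else:
        gammas = transfer_operator(spec, part, mf, grid)
        filters_freq = effective_coupling_freq(spec, part, mf, gammas, grid)
        baselines = effective_baselines(spec, part, mf)
        weights = effective_weights(spec, part, mf)
    ft_complex = grid.inverse_transform(filters_freq)
    filters_time = ft_complex.real
    amp = float(np.max(np.abs(filters_time))) if filters_time.size else 0.0
    tail = max(1, grid.n_time // 20)
    diagnostics = {
        "imag_residue": float(np.max(np.abs(ft_complex.imag))) if ft_complex.size else 0.0,
        "tail_amplitude_ratio": (
            float(np.max(np.abs(filters_time[-tail:])) / amp) if amp > 0 else 0.0
        ),
    }
    return EffectiveModel(
        partition=part,
        baselines_eff=baselines,
        filters_freq=filters_freq,
        filters_time=filters_time,
        weights_eff=weights,
        grid=grid,
        meanfield=mf,
        diagnostics=diagnostics,
    )
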