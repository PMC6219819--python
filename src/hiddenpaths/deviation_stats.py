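"""Ensemble statistics of effective-minus-true synaptic weights.

The central question: when a random network is subsampled, how large are the
hidden-path corrections to the measured (zero-frequency) synaptic weights?
The measure is the off-diagonal sample standard deviation of
``J^eff - J`` normalized by that of the true weights, as a function of the
recorded fraction ``f = N_rec / N`` and the coupling scale ``J0``.  Diagonal
entries are excluded from all sample statistics (true self-couplings are
pinned to zero, so their statistics differ).

The two-level averaging protocol: for each independent network draw, many
random recorded subsets are sampled and the per-subset statistics averaged;
the subset means are then averaged across network draws, and the quoted
standard error is the across-subset standard error averaged across draws.
Hidden subsets whose mean field diverges (possible under Dale's law with an
unbounded nonlinearity) are skipped and counted.

Analytic companions, for the ER mixed ensemble with exponential
nonlinearity and ``eps = exp(mu0)``:

* strong coupling (a = 1/2), paths up to length 3:
  ``sigma[J^eff - J]/sigma[J] ~ lambda0 J0 eps sqrt(1-f) (1 + 3/2 (lambda0 J0 eps)^2 (1-f))``
* variance ratio at any scaling:
  ``var[J^eff]/var[J] = 1 + N_hid var[J] [(lambda0 eps)^2 + (lambda0 eps)^4 (3 - 3/N_hid) N_hid var[J]]``
  with ``var[J] = p J0^2/(pN)^{2a}``, reducing at a = 1/2, N -> inf to
  ``1 + (lambda0 J0 eps)^2 (1-f) + 3 (lambda0 J0 eps)^4 (1-f)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .effective_interactions import effective_weights
from .errors import HiddenNetworkUnstableError
from .meanfield import SolverConfig, solve_hidden_rates
from .netgen import EnsembleConfig, generate_network, sample_partition
from .network_model import NetworkSpec, Partition, block_weights

__all__ = [
    "DeviationSummary",
    "sample_stats",
    "deviation_experiment",
    "analytic_ratio_strong",
    "analytic_var_ratio",
]


def sample_stats(eff_weights: np.ndarray, true_weights: np.ndarray):
    """Off-diagonal sample mean and variance of (eff - true).

    Denominators follow the sample-statistics convention for n = R(R-1)
    off-diagonal entries: mean over n, variance over n - 1.
    """
    eff = np.asarray(eff_weights, dtype=float)
    true = np.asarray(true_weights, dtype=float)
    if eff.shape != true.shape or eff.ndim != 2 or eff.shape[0] != eff.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = eff.shape[0]
    if n < 2:
        raise ValueError("need dimension >= 2 for off-diagonal statistics")
    off = ~np.eye(n, dtype=bool)
    d = (eff - true)[off]
    mean = float(d.mean())
    var = float(np.sum((d - mean) ** 2) / (d.size - 1))
    return mean, var


def _offdiag_var(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    off = ~np.eye(n, dtype=bool)
    v = matrix[off]
    m = v.mean()
    return float(np.sum((v - m) ** 2) / (v.size - 1))


@dataclass
class DrawResult:
    ratio: float
    var_excess: float  # var[J^eff - J] / var[J]
    mean_dev: float


@dataclass
class DeviationSummary:
    """Ratio sigma[J^eff - J]/sigma[J] vs recorded fraction for one ensemble."""

    architecture: str
    scaling_exponent: float
    j0: float
    n_neurons: int
    recorded_counts: list[int]
    recorded_fractions: np.ndarray
    ratio: np.ndarray
    ratio_se: np.ndarray
    mean_dev: np.ndarray
    mean_dev_se: np.ndarray
    var_excess: np.ndarray
    var_excess_se: np.ndarray
    n_subsets: int
    n_networks: int
    n_used: np.ndarray
    skipped_draws: np.ndarray
    draws: dict[int, list[DrawResult]] = field(default_factory=dict, repr=False)


def deviation_ratio_for_partition(
    spec: NetworkSpec, part: Partition, solver: SolverConfig | None = None
) -> DrawResult:
    """Ratio statistics for one (network, subset) draw.

    Raises HiddenNetworkUnstableError for unstable hidden subsets; callers
    skip-and-count.
    """
    mf = solve_hidden_rates(spec, part, solver)
    eff = effective_weights(spec, part, mf)
    true = block_weights(spec, part)[0]
    mean_dev, var_dev = sample_stats(eff, true)
    var_true = _offdiag_var(true)
    if var_true == 0.0:
        raise HiddenNetworkUnstableError("degenerate draw: zero true weight variance")
    return DrawResult(
        ratio=float(np.sqrt(var_dev / var_true)),
        var_excess=float(var_dev / var_true),
        mean_dev=mean_dev,
    )


def deviation_experiment(
    config: EnsembleConfig,
    recorded_counts,
    n_subsets: int = 100,
    n_networks: int = 10,
    seed: int = 0,
    solver: SolverConfig | None = None,
) -> DeviationSummary:
    """Two-level-averaged deviation statistics over an ensemble.

    For every network draw and recorded count, ``n_subsets`` random recorded
    subsets are evaluated; subset means are averaged across the
    ``n_networks`` draws.  A (J0, f) cell whose draws were all unstable is
    reported as NaN with the skip count, not raised.
    """
    recorded_counts = [int(c) for c in recorded_counts]
    n = config.n_neurons
    for c in recorded_counts:
        if not (1 <= c <= n - 1):
            raise ValueError(f"recorded counts must lie in [1, {n - 1}], got {c}")
    ss = np.random.SeedSequence(seed)
    net_seeds = ss.spawn(n_networks)
    per_count: dict[int, list[list[DrawResult]]] = {c: [] for c in recorded_counts}
    skipped = {c: 0 for c in recorded_counts}
    draws_flat: dict[int, list[DrawResult]] = {c: [] for c in recorded_counts}
    for net_ss in net_seeds:
        rng = np.random.default_rng(net_ss)
        spec = generate_network(config, rng)
        for c in recorded_counts:
            results: list[DrawResult] = []
            for _ in range(n_subsets):
                part = sample_partition(n, c, rng)
                try:
                    res = deviation_ratio_for_partition(spec, part, solver)
                except HiddenNetworkUnstableError:
                    skipped[c] += 1
                    continue
                results.append(res)
            per_count[c].append(results)
            draws_flat[c].extend(results)

    def aggregate(extract):
        means, ses = [], []
        for c in recorded_counts:
            net_means, net_ses = [], []
            for results in per_count[c]:
                vals = np.array([extract(r) for r in results])
                if vals.size == 0:
                    continue
                net_means.append(vals.mean())
                net_ses.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
            if net_means:
                means.append(float(np.mean(net_means)))
                ses.append(float(np.mean(net_ses)))
            else:
                means.append(float("nan"))
                ses.append(float("nan"))
        return np.array(means), np.array(ses)

    ratio, ratio_se = aggregate(lambda r: r.ratio)
    mean_dev, mean_dev_se = aggregate(lambda r: r.mean_dev)
    var_excess, var_excess_se = aggregate(lambda r: r.var_excess)
    return DeviationSummary(
        architecture=config.architecture,
        scaling_exponent=config.scaling_exponent,
        j0=config.coupling_scale,
        n_neurons=n,
        recorded_counts=recorded_counts,
        recorded_fractions=np.array([c / n for c in recorded_counts]),
        ratio=ratio,
        ratio_se=ratio_se,
        mean_dev=mean_dev,
        mean_dev_se=mean_dev_se,
        var_excess=var_excess,
        var_excess_se=var_excess_se,
        n_subsets=n_subsets,
        n_networks=n_networks,
        n_used=np.array(
            [sum(len(r) for r in per_count[c]) for c in recorded_counts]
        ),
        skipped_draws=np.array([skipped[c] for c in recorded_counts]),
        draws=draws_flat,
    )


def analytic_ratio_strong(j0: float, f, mu0: float = -1.0, lambda0: float = 1.0):
    """Length-<=3 hidden-path prediction of sigma[J^eff - J]/sigma[J] (a = 1/2)."""
    f = np.asarray(f, dtype=float)
    x = lambda0 * j0 * np.exp(mu0)
    out = x * np.sqrt(1.0 - f) * (1.0 + 1.5 * x**2 * (1.0 - f))
    return out if out.ndim else float(out)


def analytic_var_ratio(
    j0: float,
    f,
    p: float,
    n_neurons: int,
    a: float,
    mu0: float = -1.0,
    lambda0: float = 1.0,
):
    """Fourth-order prediction of var[J^eff]/var[J] at finite N and either scaling."""
    f = np.asarray(f, dtype=float)
    eps = np.exp(mu0)
    var_j = p * j0**2 / (p * n_neurons) ** (2.0 * a)
    n_hid = (1.0 - f) * n_neurons
    le2 = (lambda0 * eps) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = le2 + le2**2 * (3.0 - 3.0 / n_hid) * n_hid * var_j
    out = np.where(n_hid > 0, 1.0 + n_hid * var_j * np.where(n_hid > 0, bracket, 0.0), 1.0)
    return out if out.ndim else float(out)
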