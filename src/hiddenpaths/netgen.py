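"""Seeded generators for the random network ensembles.

Three architectures share a common weight law: sparsity ``p`` (a fraction
``p`` of ordered pairs connected) and nonzero weights of zero mean and
standard deviation ``J0 / (pN)^a``, so the overall (zeros included) standard
deviation is ``sqrt(p) J0 / (pN)^a``.  The scaling exponent ``a`` selects the
coupling regime: ``a = 1/2`` is the strong (balanced, 1/sqrt(N)) regime where
hidden-path corrections stay O(1) as N grows, ``a = 1`` the weak (classical
1/N) regime where they vanish.  Self-couplings are zero throughout.

* ``er_mixed``  — Erdos-Renyi connectivity, "mixed synapses" (no Dale's law):
  every nonzero weight an independent normal draw.
* ``er_dale``   — Erdos-Renyi with Dale's law: neurons labelled E or I
  (independently, probability 1/2 each), magnitudes half-normal with the
  same scale, signs fixed by the presynaptic label (column-wise).
* ``watts_strogatz`` — small-world topology: a (pN)-nearest-neighbour ring
  with a fraction ``beta`` of edges rewired (networkx implementation), each
  undirected edge expanded to two directed edges with independent
  mixed-synapse weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidConfigError
from .network_model import (
    Kernel,
    KernelAssignment,
    NetworkSpec,
    Nonlinearity,
    Partition,
)

__all__ = [
    "EnsembleConfig",
    "er_mixed",
    "er_dale",
    "watts_strogatz",
    "generate_network",
    "sample_partition",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Parameters of a random-network draw.

    coupling_scale is J0; scaling_exponent a is 1/2 (strong) or 1 (weak);
    rewiring beta applies to the Watts-Strogatz architecture only.  The
    kernel is a global alpha filter with rate ``kernel_alpha`` (zero
    self-weights make the self kernel irrelevant).
    """

    n_neurons: int = 1000
    sparsity: float = 0.2
    coupling_scale: float = 1.0
    scaling_exponent: float = 0.5
    architecture: str = "er_mixed"
    rewiring: float = 0.3
    baseline: float = -1.0
    rate_scale: float = 1.0
    nonlinearity: str = "exponential"
    kernel_alpha: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sparsity <= 1.0):
            raise InvalidConfigError(f"sparsity must lie in [0, 1], got {self.sparsity}")
        if self.n_neurons < 2:
            raise InvalidConfigError("need at least 2 neurons")
        if self.architecture not in ("er_mixed", "er_dale", "watts_strogatz"):
            raise InvalidConfigError(f"unknown architecture {self.architecture!r}")
        if not (0.0 <= self.rewiring <= 1.0):
            raise InvalidConfigError("rewiring fraction must lie in [0, 1]")
        if self.scaling_exponent not in (0.5, 1.0):
            raise InvalidConfigError("scaling exponent must be 1/2 (strong) or 1 (weak)")

    @property
    def weight_std(self) -> float:
        """Nonzero-weight standard deviation J0 / (pN)^a (0 for an empty graph)."""
        if self.sparsity == 0.0:
            return 0.0
        return self.coupling_scale / (self.sparsity * self.n_neurons) ** self.scaling_exponent


def _spec_from_weights(config: EnsembleConfig, weights: np.ndarray) -> NetworkSpec:
    n = config.n_neurons
    return NetworkSpec(
        n_neurons=n,
        rate_scale=config.rate_scale,
        baselines=np.full(n, config.baseline),
        weights=weights,
        kernels=KernelAssignment(default=Kernel("alpha", config.kernel_alpha)),
        nonlinearity=Nonlinearity(config.nonlinearity),
    )


def er_mixed(config: EnsembleConfig, rng=None) -> NetworkSpec:
    """Erdos-Renyi mixed-synapse network; reproducible from config.seed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p = config.n_neurons, config.sparsity
    mask = rng.random((n, n)) < p
    weights = np.where(mask, rng.normal(0.0, config.weight_std, (n, n)), 0.0)
    np.fill_diagonal(weights, 0.0)
    return _spec_from_weights(config, weights)


def er_dale(config: EnsembleConfig, rng=None, labels=None):
    """Erdos-Renyi network obeying Dale's law.

    Returns ``(spec, labels)`` with labels +1 (excitatory) / -1 (inhibitory)
    per neuron.  ``labels`` may be supplied explicitly (test hook).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p = config.n_neurons, config.sparsity
    if labels is None:
        labels = np.where(rng.random(n) < 0.5, 1, -1)
    else:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (n,) or not np.all(np.isin(labels, (-1, 1))):
            raise InvalidConfigError("labels must be +/-1 per neuron")
    mask = rng.random((n, n)) < p
    magnitudes = np.abs(rng.normal(0.0, config.weight_std, (n, n)))
    weights = np.where(mask, magnitudes * labels[None, :], 0.0)
    np.fill_diagonal(weights, 0.0)
    return _spec_from_weights(config, weights), labels


def watts_strogatz(config: EnsembleConfig, rng=None) -> NetworkSpec:
    """Small-world mixed-synapse network.

    Requires k = pN to be an even integer (k/2 ring neighbours per side).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p = config.n_neurons, config.sparsity
    k_float = p * n
    k = int(round(k_float))
    if abs(k - k_float) > 1e-9 or k < 2 or k % 2 != 0:
        raise InvalidConfigError(
            f"Watts-Strogatz requires p*N to be an even integer >= 2 (got {k_float}); "
            "choose p and N so each node has p*N/2 ring neighbours per side"
        )
    graph_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.watts_strogatz_graph(n, k, config.rewiring, seed=graph_seed)
    adj = nx.to_numpy_array(g, nodelist=range(n), dtype=bool)
    weights = np.where(adj, rng.normal(0.0, config.weight_std, (n, n)), 0.0)
    np.fill_diagonal(weights, 0.0)
    return _spec_from_weights(config, weights)


_GENERATORS = {
    "er_mixed": er_mixed,
    "er_dale": lambda config, rng=None: er_dale(config, rng)[0],
    "watts_strogatz": watts_strogatz,
}


def generate_network(config: EnsembleConfig, rng=None) -> NetworkSpec:
    """Dispatch on config.architecture."""
    return _GENERATORS[config.architecture](config, rng)


def sample_partition(n_neurons: int, n_recorded: int, seed) -> Partition:
    """Uniform random recorded subset: permute indices, record the last n_rec.

    ``seed`` may be an integer or a numpy Generator.
    """
    if not (0 <= n_recorded <= n_neurons):
        raise ValueError(
            f"n_recorded must lie in [0, {n_neurons}], got {n_recorded}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_neurons)
    split = n_neurons - n_recorded
    return Partition(recorded=tuple(perm[split:]), hidden=tuple(perm[:split]))
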