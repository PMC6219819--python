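import numpy as np
import pytest

from hiddenpaths import (
    EnsembleConfig,
    Kernel,
    KernelAssignment,
    NetworkSpec,
    Nonlinearity,
    Partition,
    solve_hidden_rates,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_stable_hidden_spec(rng, n_hidden, n_recorded=2, radius=0.6, kernel=None):
    """Random spec whose hidden block has spectral radius of V(0) below ``radius``.

    Hidden weights are rescaled so that diag(gamma) J_HH at the exponential
    mean-field point stays inside the requested disc; verified by solving.
    """
    n = n_hidden + n_recorded
    weights = rng.normal(0.0, 1.0, (n, n))
    np.fill_diagonal(weights, 0.0)
    hid = np.arange(n_recorded, n)
    block = weights[np.ix_(hid, hid)]
    eig = np.max(np.abs(np.linalg.eigvals(block))) if n_hidden else 0.0
    if eig > 0:
        weights = weights * min(radius / (np.exp(-1.0) * eig), 1.0)
    part = Partition(recorded=tuple(range(n_recorded)), hidden=tuple(hid))

    def build(w):
        return NetworkSpec(
            n_neurons=n,
            rate_scale=1.0,
            baselines=np.full(n, -1.0),
            weights=w,
            kernels=KernelAssignment(default=kernel or Kernel("alpha", 2.0)),
            nonlinearity=Nonlinearity("exponential"),
        )

    for _ in range(20):
        spec = build(weights)
        try:
            mf = solve_hidden_rates(spec, part)
        except Exception:
            weights = weights * 0.7
            continue
        if n_hidden == 0:
            return spec, part
        V0 = mf.gains[:, None] * weights[np.ix_(hid, hid)]
        if np.max(np.abs(np.linalg.eigvals(V0))) <= radius + 0.05:
            return spec, part
        weights = weights * 0.7
    raise RuntimeError("could not build a stable random hidden spec")


@pytest.fixture
def small_er_config():
    return EnsembleConfig(
        n_neurons=200,
        sparsity=0.2,
        coupling_scale=0.5,
        scaling_exponent=0.5,
        seed=7,
    )
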