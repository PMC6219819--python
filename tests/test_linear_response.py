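"""Hidden-network linear response: inversion, path expansion, stability."""

import numpy as np
import pytest

import networkx as nx
from hiddenpaths import (
    FrequencyGrid,
    Kernel,
    KernelAssignment,
    NetworkSpec,
    Nonlinearity,
    Partition,
    ffi_circuit,
    four_neuron_circuit,
    path_series,
    solve_hidden_rates,
    stability_report,
    transfer_operator,
)
from conftest import random_stable_hidden_spec

GRID = FrequencyGrid(dt=0.05, n_time=128)


def _mf(spec, part):
    return solve_hidden_rates(spec, part)


class TestTransferOperator:
    def test_uncoupled_hidden_gives_diag_gains(self, rng):
        n = 5
        spec = NetworkSpec(n, 1.0, np.full(n, -1.0), np.zeros((n, n)))
        part = Partition(recorded=(0,), hidden=(1, 2, 3, 4))
        op = transfer_operator(spec, part, _mf(spec, part), GRID)
        expected = np.diag(np.full(4, np.exp(-1.0)))
        assert np.allclose(op.gamma_matrices, expected[None, :, :])
        assert op.spectral_radius_zero == 0.0

    def test_single_self_coupled_node_factor(self):
        """One hidden neuron: Gammahat = gamma / (1 - gamma Jhat_self)."""
        w = np.zeros((2, 2))
        w[1, 1] = -0.9
        spec = NetworkSpec(
            2,
            1.0,
            np.array([0.0, 0.95]),
            w,
            kernels=KernelAssignment(self_kernel=Kernel("single_exp", 1.0)),
            nonlinearity=Nonlinearity("rectified_linear"),
        )
        part = Partition(recorded=(0,), hidden=(1,))
        mf = _mf(spec, part)
        op = transfer_operator(spec, part, mf, GRID)
        jhat = Kernel("single_exp", 1.0).freq(GRID.omegas) * (-0.9)
        expected = 1.0 / (1.0 - 1.0 * jhat)
        assert np.allclose(op.gamma_matrices[:, 0, 0], expected)

    def test_feedforward_pair_triangular_solve(self):
        # hidden h1 -> h2 with weight w and delta kernels, omega arbitrary
        w = 0.7
        weights = np.zeros((3, 3))
        weights[2, 1] = w  # h2 <- h1 (hidden order: (1, 2))
        spec = NetworkSpec(
            3,
            1.0,
            np.full(3, -1.0),
            weights,
            kernels=KernelAssignment(default=Kernel("delta")),
        )
        part = Partition(recorded=(0,), hidden=(1, 2))
        mf = _mf(spec, part)
        op = transfer_operator(spec, part, mf, GRID)
        g1 = np.exp(-1.0)
        g2 = np.exp(-1.0 + w * g1)  # downstream neuron feels the upstream rate
        k0 = int(np.argmin(np.abs(GRID.omegas)))
        G0 = op.gamma_matrices[k0]
        assert G0[1, 0] == pytest.approx(g2 * w * g1)
        assert G0[1, 1] == pytest.approx(g2)
        assert G0[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_resolvent_identity_and_hermitian_symmetry(self, rng):
        spec, part = random_stable_hidden_spec(rng, 6)
        mf = _mf(spec, part)
        op = transfer_operator(spec, part, mf, GRID)
        nH = part.n_hidden
        lhs = (np.eye(nH)[None] - op.v_matrices) @ op.gamma_matrices
        assert np.max(np.abs(lhs - np.diag(mf.gains)[None])) < 1e-8
        assert GRID.hermitian_defect(op.gamma_matrices) < 1e-10


class TestPathSeries:
    def test_no_edges_single_node_paths_only(self, rng):
        n = 4
        spec = NetworkSpec(n, 1.0, np.full(n, -1.0), np.zeros((n, n)))
        part = Partition(recorded=(0,), hidden=(1, 2, 3))
        mf = _mf(spec, part)
        res = path_series(spec, part, mf, GRID, max_length=1)
        assert sorted(p.nodes for p in res.paths) == [(0,), (1,), (2,)]
        assert np.allclose(res.gamma_truncated, np.diag(mf.gains)[None])

    def test_enumeration_matches_matrix_partial_sum(self, rng):
        """Summed path contributions equal the factored matrix partial sums."""
        spec, part = random_stable_hidden_spec(rng, 4)
        mf = _mf(spec, part)
        res = path_series(spec, part, mf, GRID, max_length=3)
        nH = part.n_hidden
        total = np.zeros((GRID.n_fft, nH, nH), dtype=complex)
        for p in res.paths:
            total[:, p.nodes[-1], p.nodes[0]] += p.contribution(GRID.omegas)
        assert np.max(np.abs(total - res.gamma_truncated)) < 1e-10

    def test_partial_sums_converge_geometrically(self, rng):
        spec, part = random_stable_hidden_spec(rng, 5, radius=0.5)
        mf = _mf(spec, part)
        op = transfer_operator(spec, part, mf, GRID)
        k0 = int(np.argmin(np.abs(GRID.omegas)))
        errs = []
        for L in (4, 8, 12):
            res = path_series(spec, part, mf, GRID, max_length=L, collect_paths=False)
            errs.append(
                np.max(np.abs(res.gamma_truncated[k0] - op.gamma_matrices[k0]))
            )
        rho = op.spectral_radius_zero
        ratio1, ratio2 = errs[1] / errs[0], errs[2] / errs[1]
        # successive truncation errors shrink like rho^4
        assert ratio1 < 1.0 and ratio2 < 1.0
        assert ratio1 == pytest.approx(rho**4, rel=2.0)

    def test_four_neuron_loop_factor_resums(self):
        """The 3<->4 loop sums to 1/(1 - gamma3 Jhat34 gamma4 Jhat43)."""
        fx = four_neuron_circuit()
        mf = _mf(fx.spec, fx.partition)
        op = transfer_operator(fx.spec, fx.partition, mf, GRID)
        jhat34 = fx.spec.coupling_freq(GRID.omegas, rows=[2], cols=[3])[:, 0, 0]
        jhat43 = fx.spec.coupling_freq(GRID.omegas, rows=[3], cols=[2])[:, 0, 0]
        loop = 1.0 / (1.0 - jhat34 * jhat43)  # gains are 1
        assert np.allclose(op.gamma_matrices[:, 0, 0], loop)

    def test_zero_paths_give_zero_gamma_entries(self, rng):
        """No directed hidden path r' -> r means the Gamma entry is exactly 0."""
        for trial in range(5):
            n_hid = 6
            dag = nx.gnp_random_graph(
                n_hid, 0.4, seed=int(rng.integers(2**31)), directed=True
            )
            dag = nx.DiGraph((u, v) for u, v in dag.edges() if u < v)
            dag.add_nodes_from(range(n_hid))
            weights = np.zeros((n_hid + 1, n_hid + 1))
            for u, v in dag.edges():
                weights[v + 1, u + 1] = rng.normal(0.0, 0.3)
            spec = NetworkSpec(n_hid + 1, 1.0, np.full(n_hid + 1, -1.0), weights)
            part = Partition(recorded=(0,), hidden=tuple(range(1, n_hid + 1)))
            mf = _mf(spec, part)
            op = transfer_operator(spec, part, mf, GRID)
            for a in range(n_hid):
                for b in range(n_hid):
                    if a != b and not nx.has_path(dag, a, b):
                        assert np.all(op.gamma_matrices[:, b, a] == 0.0)

    def test_invalid_max_length(self, rng):
        spec, part = random_stable_hidden_spec(rng, 3)
        mf = _mf(spec, part)
        with pytest.raises(ValueError):
            path_series(spec, part, mf, GRID, max_length=0)

    def test_path_cap_warns_and_flags(self, rng):
        spec, part = random_stable_hidden_spec(rng, 6)
        mf = _mf(spec, part)
        with pytest.warns(RuntimeWarning, match="cap"):
            res = path_series(spec, part, mf, GRID, max_length=10, path_cap=50)
        assert res.truncated_enumeration

    def test_permutation_equivariance_of_gamma(self, rng):
        spec, part = random_stable_hidden_spec(rng, 5)
        mf = _mf(spec, part)
        op = transfer_operator(spec, part, mf, GRID)
        perm = [4, 2, 0, 3, 1]
        part2 = Partition(part.recorded, tuple(np.asarray(part.hidden)[perm]))
        op2 = transfer_operator(spec, part2, _mf(spec, part2), GRID)
        assert np.allclose(
            op2.gamma_matrices, op.gamma_matrices[:, perm][:, :, perm], atol=1e-9
        )


class TestStabilityReport:
    def test_ffi_circuit_margin(self):
        fx = ffi_circuit()
        mf = _mf(fx.spec, fx.partition)
        rep = stability_report(fx.spec, fx.partition, mf)
        assert rep.conditions["one_minus_gamma_j_self"] == pytest.approx(1.9)
        assert rep.series_converges

    def test_four_neuron_loop_gain(self):
        fx = four_neuron_circuit()
        mf = _mf(fx.spec, fx.partition)
        rep = stability_report(fx.spec, fx.partition, mf)
        assert rep.conditions["loop_gain"] == pytest.approx(0.81)
        assert rep.series_converges

    def test_uncoupled_radius_zero(self):
        spec = NetworkSpec(3, 1.0, np.full(3, -1.0), np.zeros((3, 3)))
        part = Partition(recorded=(0,), hidden=(1, 2))
        rep = stability_report(spec, part, _mf(spec, part))
        assert rep.spectral_radius_zero == 0.0
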