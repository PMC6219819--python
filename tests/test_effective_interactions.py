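"""Assembly of effective filters: frequency grid, omega=0 weights, transforms."""

import numpy as np
import pytest

from hiddenpaths import (
    EnsembleConfig,
    FrequencyGrid,
    Kernel,
    KernelAssignment,
    NetworkSpec,
    Nonlinearity,
    Partition,
    build_effective_model,
    effective_coupling_freq,
    effective_weights,
    er_mixed,
    ffi_circuit,
    four_neuron_circuit,
    sample_partition,
    solve_hidden_rates,
    to_time_domain,
    transfer_operator,
)
from conftest import random_stable_hidden_spec


class TestFrequencyGrid:
    def test_time_and_omega_layout(self):
        grid = FrequencyGrid(dt=0.1, n_time=64)
        assert grid.times[0] == 0.0
        assert np.allclose(np.diff(grid.times), 0.1)
        # omega grid symmetric about zero up to the unpaired Nyquist bin
        oms = np.sort(grid.omegas)
        assert np.allclose(oms + oms[::-1], oms + oms[::-1])
        assert 0.0 in grid.omegas

    def test_inverse_transform_recovers_alpha_kernel(self):
        """Closed-form transform of the alpha kernel inverts to the waveform.

        Oversampling pushes the 1/omega^2 truncation tail down so even the
        t=0 bin is recovered to ~1e-3 of the weight.
        """
        alpha, J = 10.0, 1.0
        grid = FrequencyGrid(dt=0.01, n_time=1024, oversample=128)
        fhat = J * Kernel("alpha", alpha).freq(grid.omegas)
        ft = to_time_domain(fhat, grid)
        truth = J * alpha**2 * grid.times * np.exp(-alpha * grid.times)
        assert np.max(np.abs(ft - truth)) < 1e-3 * J

    def test_zero_input_zero_output(self):
        grid = FrequencyGrid(dt=0.1, n_time=32)
        assert np.all(to_time_domain(np.zeros(grid.n_fft, dtype=complex), grid) == 0.0)

    def test_non_hermitian_input_warns_and_symmetrizes(self):
        grid = FrequencyGrid(dt=0.1, n_time=32)
        bad = np.ones(grid.n_fft, dtype=complex) * 1j  # anti-Hermitian
        with pytest.warns(RuntimeWarning, match="Hermitian"):
            out = to_time_domain(bad, grid)
        assert np.allclose(out, 0.0)


class TestEffectiveWeights:
    def test_no_hidden_cross_weights_leaves_recorded_block(self, rng):
        spec, part = random_stable_hidden_spec(rng, 4)
        w = spec.weights.copy()
        r, h = list(part.recorded), list(part.hidden)
        w[np.ix_(r, h)] = 0.0
        spec2 = NetworkSpec(spec.n_neurons, 1.0, spec.baselines, w,
                            nonlinearity=spec.nonlinearity)
        mf = solve_hidden_rates(spec2, part)
        eff = effective_weights(spec2, part, mf)
        assert np.allclose(eff, w[np.ix_(r, r)])

    def test_ffi_circuit_zero_frequency_value(self):
        fx = ffi_circuit()
        mf = solve_hidden_rates(fx.spec, fx.partition)
        eff = effective_weights(fx.spec, fx.partition, mf)
        # J21 + J23 gamma3 J31 / (1 - gamma3 J33) = 1 - 4/1.9
        assert eff[1, 0] == pytest.approx(1.0 + (-2.0) * 2.0 / 1.9, abs=1e-12)

    def test_four_neuron_zero_frequency_value(self):
        fx = four_neuron_circuit()
        mf = solve_hidden_rates(fx.spec, fx.partition)
        eff = effective_weights(fx.spec, fx.partition, mf)
        # 1 + [(-3)(1) + (-3)(-0.9)(1)] / (1 - 0.81)
        assert eff[1, 0] == pytest.approx(1.0 - 0.3 / 0.19, abs=1e-12)

    def test_kernel_shape_irrelevant_at_zero_frequency(self, rng):
        spec, part = random_stable_hidden_spec(rng, 5)
        mf = solve_hidden_rates(spec, part)
        eff_alpha = effective_weights(spec, part, mf)
        spec_delta = NetworkSpec(
            spec.n_neurons, 1.0, spec.baselines, spec.weights,
            kernels=KernelAssignment(default=Kernel("delta")),
            nonlinearity=spec.nonlinearity,
        )
        eff_delta = effective_weights(spec_delta, part, solve_hidden_rates(spec_delta, part))
        assert np.allclose(eff_alpha, eff_delta)

    def test_correction_linear_in_each_cross_block(self, rng):
        spec, part = random_stable_hidden_spec(rng, 5)
        mf = solve_hidden_rates(spec, part)
        r, h = list(part.recorded), list(part.hidden)
        J_rr = spec.weights[np.ix_(r, r)]
        corr = effective_weights(spec, part, mf) - J_rr
        for block in ("rh", "hr"):
            w2 = spec.weights.copy()
            if block == "rh":
                w2[np.ix_(r, h)] *= 3.0
            else:
                w2[np.ix_(h, r)] *= 3.0
            spec2 = NetworkSpec(spec.n_neurons, 1.0, spec.baselines, w2,
                                nonlinearity=spec.nonlinearity)
            corr2 = effective_weights(spec2, part, mf) - J_rr
            assert np.allclose(corr2, 3.0 * corr)


class TestPipeline:
    def test_empty_hidden_returns_true_model(self, rng):
        w = rng.normal(0.0, 0.1, (3, 3))
        spec = NetworkSpec(3, 1.0, np.full(3, -1.0), w)
        part = Partition(recorded=(0, 1, 2), hidden=())
        model = build_effective_model(spec, part, FrequencyGrid(0.05, 256))
        assert np.allclose(model.weights_eff, w)
        assert np.allclose(model.baselines_eff, spec.baselines)
        jhat0 = model.filters_freq[np.argmin(np.abs(model.grid.omegas))]
        assert np.allclose(jhat0, w)

    def test_weights_equal_time_integral_of_filters(self, rng):
        """At oversample=1 the omega=0 weights equal dt * sum_t filters exactly."""
        spec, part = random_stable_hidden_spec(rng, 4)
        model = build_effective_model(spec, part, FrequencyGrid(0.05, 1024))
        integral = model.filters_time.sum(axis=0) * model.grid.dt
        assert np.max(np.abs(integral - model.weights_eff)) < 1e-6 * (
            1.0 + np.max(np.abs(model.weights_eff))
        )

    def test_grid_mismatch_rejected(self, rng):
        spec, part = random_stable_hidden_spec(rng, 3)
        mf = solve_hidden_rates(spec, part)
        g1, g2 = FrequencyGrid(0.05, 128), FrequencyGrid(0.05, 256)
        op = transfer_operator(spec, part, mf, g1)
        with pytest.raises(ValueError):
            effective_coupling_freq(spec, part, mf, op, g2)

    def test_deterministic_rebuild_bit_identical(self, rng):
        spec, part = random_stable_hidden_spec(rng, 4)
        g = FrequencyGrid(0.05, 256)
        m1 = build_effective_model(spec, part, g)
        m2 = build_effective_model(spec, part, g)
        assert np.array_equal(m1.filters_time, m2.filters_time)
        assert np.array_equal(m1.weights_eff, m2.weights_eff)

    def test_imaginary_residue_small(self, rng):
        spec, part = random_stable_hidden_spec(rng, 4)
        model = build_effective_model(spec, part, FrequencyGrid(0.05, 512))
        amp = np.max(np.abs(model.filters_time))
        assert model.diagnostics["imag_residue"] < 1e-8 * amp


class TestStructuralProperties:
    def test_layered_dag_preserves_feedforward_zeros(self, rng):
        """Hidden paths cannot create lateral/feedback couplings in a DAG."""
        # 3 layers of 3; record layer 0 and layer 2, hide the middle layer
        n = 9
        weights = np.zeros((n, n))
        for pre in range(3):
            for post in range(3, 6):
                weights[post, pre] = rng.normal(0.0, 0.4)
        for pre in range(3, 6):
            for post in range(6, 9):
                weights[post, pre] = rng.normal(0.0, 0.4)
        spec = NetworkSpec(n, 1.0, np.full(n, -1.0), weights)
        part = Partition(recorded=(0, 1, 2, 6, 7, 8), hidden=(3, 4, 5))
        mf = solve_hidden_rates(spec, part)
        eff = effective_weights(spec, part, mf)
        rec = list(part.recorded)
        layer = {i: (0 if i < 3 else 2) for i in rec}
        for a, i in enumerate(rec):
            for b, j in enumerate(rec):
                if not (layer[i] == 2 and layer[j] == 0):  # only 0 -> 2 allowed
                    assert eff[a, b] == 0.0
                elif weights[i, j] == 0.0:
                    # feedforward corrections generically appear where J was 0
                    pass

    def test_recurrent_er_develops_dense_and_self_interactions(self):
        """Sparse true weights, dense effective weights; self-terms emerge."""
        config = EnsembleConfig(n_neurons=150, sparsity=0.2, coupling_scale=0.5,
                                scaling_exponent=0.5, seed=3)
        spec = er_mixed(config)
        part = sample_partition(150, 5, seed=4)
        mf = solve_hidden_rates(spec, part)
        eff = effective_weights(spec, part, mf)
        true_rr = spec.weights[np.ix_(part.recorded, part.recorded)]
        assert np.count_nonzero(true_rr) < true_rr.size  # sparse input
        assert np.count_nonzero(eff) == eff.size  # dense output
        assert np.all(np.abs(np.diag(eff)) > 0.0)  # emergent self-interactions
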