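"""Unit tests for the spiking vector-representation core."""

import numpy as np
import pytest

from neurocog.core import (Ensemble, Network, NeuronParams, Simulator,
                           compute_current, default_regularization,
                           filter_signal, lif_rate, merge_weights,
                           sample_eval_points, simulate, solve_decoders,
                           solve_gain_bias, step_neurons)


class TestLifRate:
    def test_subthreshold_is_silent(self):
        assert lif_rate(0.9) == 0.0
        assert lif_rate(1.0) == 0.0

    def test_closed_form_value(self):
        # 1 / (tau_ref + tau_rc * ln(J/(J-1))) at J=2
        assert lif_rate(2.0) == pytest.approx(63.0, abs=0.1)

    def test_refractory_limited_asymptote(self):
        p = NeuronParams()
        assert lif_rate(1e9, p) == pytest.approx(1.0 / p.tau_ref, rel=1e-3)

    def test_nonfinite_current_rejected(self):
        with pytest.raises(ValueError):
            lif_rate(np.nan)


class TestGainBias:
    @pytest.mark.parametrize("intercept,max_rate",
                             [(0.0, 100.0), (-0.5, 250.0), (0.99, 150.0)])
    def test_inversion_round_trip(self, intercept, max_rate):
        gain, bias = solve_gain_bias(max_rate, intercept)
        assert np.isfinite(gain) and gain > 0
        # just at threshold at the intercept (0+ up to float rounding in
        # the log divergence), max_rate at unit projection
        assert lif_rate(gain * intercept + bias) < 2.0
        assert lif_rate(gain * 1.0 + bias) == pytest.approx(max_rate,
                                                            abs=0.5)

    def test_unreachable_rate_rejected(self):
        p = NeuronParams()
        with pytest.raises(ValueError):
            solve_gain_bias(1.0 / p.tau_ref, 0.0, p)


class TestCurrent:
    def test_zero_input_gives_bias(self, rng):
        net = Network(seed=0)
        ens = net.ensemble("e", 5, 3)
        J = compute_current(np.zeros(3), ens)
        assert np.allclose(J, ens.biases)

    def test_preferred_direction(self):
        net = Network(seed=1)
        ens = net.ensemble("e", 4, 3)
        k = 2
        J = compute_current(ens.encoders[k], ens)
        assert J[k] == pytest.approx(ens.gains[k] + ens.biases[k])

    def test_matches_hand_evaluation(self, rng):
        net = Network(seed=2)
        ens = net.ensemble("e", 5, 4)
        x = rng.standard_normal(4)
        expected = ens.gains * (ens.encoders @ x) + ens.biases
        assert np.allclose(compute_current(x, ens), expected)

    def test_dimension_mismatch(self):
        net = Network(seed=3)
        ens = net.ensemble("e", 5, 4)
        with pytest.raises(ValueError):
            compute_current(np.zeros(3), ens)


class TestStepNeurons:
    @pytest.mark.parametrize("J", [1.5, 2.0, 5.0, 20.0, 100.0])
    def test_simulated_rate_matches_analytic(self, J):
        state = {"voltage": np.zeros(1), "refractory": np.zeros(1)}
        p = NeuronParams()
        count = sum(step_neurons(state, np.array([J]), p, 0.001)[0]
                    for _ in range(2000)) / 2.0
        assert count == pytest.approx(lif_rate(J, p), rel=0.05)

    def test_subthreshold_never_spikes(self):
        state = {"voltage": np.zeros(1), "refractory": np.zeros(1)}
        total = sum(step_neurons(state, np.array([0.5]), NeuronParams(),
                                 0.001)[0] for _ in range(1000))
        assert total == 0

    def test_adaptive_isi_non_decreasing(self):
        p = NeuronParams(model_kind="adaptive_lif", adaptation_tau=0.1,
                        adaptation_increment=0.22)
        state = {"voltage": np.zeros(1), "refractory": np.zeros(1),
                 "adaptation": np.zeros(1)}
        spikes = [k for k in range(1500)
                  if step_neurons(state, np.array([3.0]), p, 0.001)[0]]
        isis = np.diff(spikes)
        # adaptation slows the train; allow 1-step jitter from discreteness
        assert np.all(np.diff(isis) >= -1)
        assert isis[-1] > isis[0]


class TestDecoders:
    def test_normal_equations_residual(self, rng):
        net = Network(seed=4)
        ens = net.ensemble("e", 30, 1)
        pts = np.linspace(-1, 1, 120)[:, None]
        A = ens.rates(pts)
        lam = default_regularization(A)
        d = solve_decoders(A, pts, lam)
        lhs = (A.T @ A + lam * np.eye(30)) @ d
        rhs = A.T @ pts
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_identity_decode_accuracy(self):
        net = Network(seed=5)
        ens = net.ensemble("e", 100, 1)
        pts = np.linspace(-1, 1, 200)[:, None]
        A = ens.rates(pts)
        d = solve_decoders(A, pts, default_regularization(A))
        grid = np.linspace(-0.9, 0.9, 50)[:, None]
        err = ens.rates(grid) @ d - grid
        assert np.sqrt((err ** 2).mean()) < 0.05

    def test_ridge_limit_shrinks_to_zero(self):
        net = Network(seed=6)
        ens = net.ensemble("e", 20, 1)
        pts = np.linspace(-1, 1, 60)[:, None]
        A = ens.rates(pts)
        d = solve_decoders(A, pts, 1e12)
        assert np.abs(d).max() < 1e-4

    def test_silent_ensemble_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            solve_decoders(np.zeros((10, 5)), np.zeros((10, 1)), 0.1)

    def test_nonnegative_solution(self):
        net = Network(seed=7)
        ens = net.ensemble("e", 25, 1, encoders=np.ones((25, 1)),
                           intercepts=np.linspace(0.0, 0.8, 25),
                           max_rates=np.linspace(200, 350, 25))
        s = np.linspace(-0.2, 1.2, 80)[:, None]
        A = ens.rates(s)
        target = np.clip(s - 0.2, 0, None)
        d = solve_decoders(A, target, default_regularization(A),
                           nonnegative=True)
        assert np.all(d >= 0)


class TestWeights:
    def test_zero_decoders_zero_weights(self):
        net = Network(seed=8)
        post = net.ensemble("p", 3, 2)
        w = merge_weights(np.zeros((4, 2)), post.encoders, post.gains)
        assert np.all(w == 0)

    def test_outer_product_by_hand(self):
        net = Network(seed=9)
        post = net.ensemble("p", 2, 1, encoders=np.array([[1.0], [-1.0]]))
        d = np.array([[0.5], [2.0]])
        w = merge_weights(d, post.encoders, post.gains)
        expected = post.gains[:, None] * (post.encoders @ d.T)
        assert np.allclose(w, expected)
        assert w.shape == (2, 2)

    def test_factored_and_merged_simulations_identical(self):
        def run(merged):
            net = Network(seed=10)
            inp = net.node("in", np.array([0.4]))
            pre = net.ensemble("pre", 50, 1)
            post = net.ensemble("post", 50, 1)
            net.connect(inp, pre, synapse_tau=0.005)
            net.connect(pre, post, synapse_tau=0.005, merged=merged)
            probe = net.probe(post, "spikes")
            sim = Simulator(net)
            sim.run(0.2)
            return sim.data(probe)
        assert np.array_equal(run(False), run(True))


class TestFilter:
    def test_zero_input_zero_output(self):
        out = filter_signal(np.zeros(100), 0.01, 0.001)
        assert np.all(out == 0)

    def test_spike_impulse_response(self):
        dt, tau = 0.001, 0.02
        x = np.zeros(200)
        x[0] = 1.0 / dt  # unit-area impulse
        out = filter_signal(x, tau, dt)
        t = np.arange(1, 150)
        ratio = out[t] / out[1]
        expected = np.exp(-(t - 1) * dt / tau)
        assert np.allclose(ratio, expected, rtol=1e-6)
        assert out[0] == pytest.approx(1.0 / tau, rel=0.05)

    def test_dc_gain_is_one(self):
        out = filter_signal(np.full(2000, 37.0), 0.005, 0.001)
        assert out[-1] == pytest.approx(37.0, rel=1e-3)


class TestSimulator:
    def test_empty_network_advances_time(self):
        net = Network(seed=11)
        sim = simulate(net, 0.1)
        assert sim.t == pytest.approx(0.1)
        assert sim.probe_data == {}

    def test_communication_channel(self):
        net = Network(seed=12)
        inp = net.node("in", np.array([0.5]))
        ens = net.ensemble("e", 100, 1)
        out = net.node("out", lambda t, x: x, size_in=1, size_out=1)
        net.connect(inp, ens, synapse_tau=0.005)
        net.connect(ens, out, synapse_tau=0.005)
        probe = net.probe(out, "output", synapse_tau=0.01)
        sim = simulate(net, 0.2)
        assert sim.data(probe)[-20:].mean() == pytest.approx(0.5, abs=0.05)

    def test_closed_gate_blocks_transmission(self):
        net = Network(seed=13)
        inp = net.node("in", np.array([0.7]))
        ens = net.ensemble("e", 80, 1)
        net.gate("g", 0.0)
        net.connect(inp, ens, synapse_tau=0.005)
        out = net.node("out", lambda t, x: x, size_in=1, size_out=1)
        net.connect(ens, out, synapse_tau=0.005, gate="g")
        probe = net.probe(out, "output", synapse_tau=0.01)
        sim = simulate(net, 0.3)
        assert abs(sim.data(probe)[-10:].mean()) < 0.05

    def test_unknown_endpoint_rejected(self):
        net = Network(seed=14)
        other = Network(seed=15)
        foreign = other.ensemble("f", 10, 1)
        inp = net.node("in", np.array([0.0]))
        with pytest.raises(ValueError, match="unknown ensemble"):
            net.connect(inp, foreign)

    def test_identical_seeds_identical_rasters(self):
        def run():
            net = Network(seed=16)
            inp = net.node("in", np.array([0.3]))
            ens = net.ensemble("e", 40, 1)
            net.connect(inp, ens, synapse_tau=0.005)
            probe = net.probe(ens, "spikes")
            sim = simulate(net, 0.15)
            return sim.data(probe)
        assert np.array_equal(run(), run())

    def test_representation_fidelity_one_dim(self):
        net = Network(seed=17)
        ens = net.ensemble("e", 100, 1)
        pts = np.linspace(-0.9, 0.9, 37)[:, None]
        A = ens.rates(pts)
        d = solve_decoders(A, pts, default_regularization(A))
        err = A @ d - pts
        assert np.sqrt((err ** 2).mean()) < 0.05
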