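"""Plasticity rules: PES, Voja± and BCM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocog.core import Network, Simulator
from neurocog.learning import (BCM, PES, BcmState, VojaPmState, bcm_update,
                               pes_update, pes_train_rate_mode,
                               voja_pm_update)


class TestPesUpdate:
    def test_zero_error_no_change(self):
        d = np.ones((5, 2))
        delta = pes_update(d, np.ones(5) * 10, np.zeros(2), 1e-4, 1.0)
        assert np.all(delta == 0)

    def test_silent_neuron_unchanged(self):
        delta = pes_update(np.zeros((3, 2)), np.array([0.0, 5.0, 0.0]),
                           np.array([1.0, 1.0]), 1e-4, 1.0)
        assert np.all(delta[0] == 0) and np.all(delta[2] == 0)
        assert np.any(delta[1] != 0)

    def test_direct_evaluation(self):
        # kappa * r * a per unit time
        delta = pes_update(np.zeros((1, 2)), np.array([10.0]),
                           np.array([0.5, -0.2]), 1e-4, 1.0)
        assert np.allclose(delta[0], [5e-4, -2e-4])

    def test_rate_mode_convergence_monotone(self):
        net = Network(seed=1)
        ens = net.ensemble("e", 100, 2)
        x = np.array([0.6, -0.3])
        d, errs = pes_train_rate_mode(ens, x, x, kappa=1e-4, duration=1.0)
        assert np.all(np.diff(errs) <= 1e-9)
        assert errs[-1] < 0.1 * errs[0]


class TestVojaUpdate:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        e = rng.standard_normal((20, 8))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        x = rng.standard_normal(8)
        x /= np.linalg.norm(x)
        return e, x

    def test_silent_neurons_do_not_move(self):
        e, x = self._setup()
        state = VojaPmState(eta=0.1, sigma=100.0)
        delta = voja_pm_update(e, x, np.zeros(20), state, 0.001)
        assert np.all(delta == 0)

    @pytest.mark.parametrize("form", ["ratio", "product"])
    @pytest.mark.parametrize("a_val,expect_sign", [(150.0, 1), (50.0, -1)])
    def test_sign_property(self, form, a_val, expect_sign):
        # attraction above sigma, repulsion below, in both rule forms
        e, x = self._setup(3)
        eta = 0.1 if form == "ratio" else 1e-5
        state = VojaPmState(eta=eta, sigma=100.0, form=form)
        a = np.full(20, a_val)
        delta = voja_pm_update(e, x, a, state, 0.001)
        cos_before = e @ x
        e2 = e + delta
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        cos_after = e2 @ x
        moved = np.abs(cos_after - cos_before) > 1e-12
        assert np.all(np.sign(cos_after - cos_before)[moved] == expect_sign)

    @given(a=st.floats(1.0, 400.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_sign_property_everywhere(self, a):
        e, x = self._setup(4)
        state = VojaPmState(eta=0.05, sigma=120.0)
        delta = voja_pm_update(e, x, np.full(20, a), state, 0.001)
        e2 = e + delta
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
        dcos = e2 @ x - e @ x
        moved = np.abs(dcos) > 1e-13
        if a == state.sigma:
            return  # clamped at max_step; direction is attraction-capped
        assert np.all(np.sign(dcos[moved]) == np.sign(a - state.sigma))

    def test_magnitude_strongest_near_threshold(self):
        e, x = self._setup(5)
        state = VojaPmState(eta=0.001, sigma=100.0, max_step=10.0)
        d_near = voja_pm_update(e, x, np.full(20, 110.0), state, 0.001)
        d_far = voja_pm_update(e, x, np.full(20, 300.0), state, 0.001)
        assert np.linalg.norm(d_near) > np.linalg.norm(d_far)

    def test_update_clamped_at_threshold(self):
        e, x = self._setup(6)
        state = VojaPmState(eta=0.1, sigma=100.0, max_step=0.01)
        delta = voja_pm_update(e, x, np.full(20, 100.0), state, 0.001)
        mags = np.linalg.norm(delta, axis=1)
        assert np.all(mags <= 0.01 + 1e-12)
        assert np.all(np.isfinite(delta))

    def test_frequency_gives_weaker_response(self):
        """Repeated presentation of one input leaves it driving less summed
        activity than a rarely presented input (net repulsion dominates)."""
        net = Network(seed=7)
        rng = np.random.default_rng(8)
        from scipy.stats import norm as norm_dist
        p = rng.uniform(0.05, 0.2, 200)
        intercepts = norm_dist.ppf(1 - p) / np.sqrt(16)
        ens = net.ensemble("e", 200, 16, intercepts=intercepts)
        freq = rng.standard_normal(16)
        freq /= np.linalg.norm(freq)
        rare = rng.standard_normal(16)
        rare /= np.linalg.norm(rare)
        state = VojaPmState(eta=0.03, sigma=240.0)
        e = ens.encoders.copy()
        pre_active = {}
        for name, x in (("freq", freq), ("rare", rare)):
            r = (ens.gains * (e @ x) + ens.biases)
            pre_active[name] = r
        # frequent input presented 10x, rare once, interleaved
        sched = ["freq"] * 10 + ["rare"]
        rng.shuffle(sched)
        for item in sched:
            x = freq if item == "freq" else rare
            for _ in range(10):  # 10 sub-updates per presentation
                from neurocog.core import lif_rate
                a = lif_rate(ens.gains * (e @ x) + ens.biases)
                e = e + voja_pm_update(e, x, a, state, 0.05)
                e /= np.linalg.norm(e, axis=1, keepdims=True)
        from neurocog.core import lif_rate
        sum_freq = lif_rate(ens.gains * (e @ freq) + ens.biases).sum()
        sum_rare = lif_rate(ens.gains * (e @ rare) + ens.biases).sum()
        n_freq = (lif_rate(ens.gains * (e @ freq) + ens.biases) > 0).sum()
        n_pre = (lif_rate(ens.gains * (ens.encoders @ freq)
                          + ens.biases) > 0).sum()
        assert n_freq <= n_pre          # active set shrinks or stays flat
        assert sum_freq < sum_rare      # frequent ends weaker than rare


class TestBcmUpdate:
    def test_at_threshold_no_change(self):
        w = np.zeros((3, 3))
        a = np.array([5.0, 5.0, 5.0])
        theta = a.copy()
        delta = bcm_update(w, a, a, theta, BcmState(kappa=1e-5), 1.0)
        assert np.allclose(delta, 0)

    def test_silent_pre_no_change(self):
        delta = bcm_update(np.zeros((2, 2)), np.zeros(2),
                           np.array([10.0, 10.0]), np.array([5.0, 5.0]),
                           BcmState(kappa=1e-5), 1.0)
        assert np.all(delta == 0)

    def test_direct_evaluation_potentiation(self):
        # kappa * a_i * a_j * (a_j - theta) per unit time
        delta = bcm_update(np.zeros((1, 1)), np.array([5.0]),
                           np.array([10.0]), np.array([8.0]),
                           BcmState(kappa=1e-5), 1.0)
        assert delta[0, 0] == pytest.approx(1e-3)
        assert delta[0, 0] > 0

    def test_weights_bounded_in_simulation(self):
        net = Network(seed=9)
        inp = net.node("in", np.array([0.8]))
        ens = net.ensemble("e", 50, 1)
        net.connect(inp, ens, synapse_tau=0.005)
        bcm = BCM(kappa=1e-8, w_limit=1e-3)
        rec = net.connect(ens, ens.neurons, weights=np.zeros((50, 50)),
                          synapse_tau=0.005, learning=bcm)
        sim = Simulator(net)
        sim.run(0.8)
        w = sim.conn_map[id(rec)].weights
        assert np.abs(w).max() <= 1e-3 + 1e-15
        assert np.any(w != 0)


class TestVojaPatternSeparation:
    def test_active_set_overlap_decreases(self):
        """Interleaved training on 8 random inputs lowers the mean pairwise
        Jaccard overlap of active-neuron sets."""
        from scipy.stats import norm as norm_dist
        from neurocog.core import lif_rate
        rng = np.random.default_rng(11)
        net = Network(seed=11)
        p = rng.uniform(0.05, 0.25, 300)
        intercepts = norm_dist.ppf(1 - p) / np.sqrt(16)
        ens = net.ensemble("e", 300, 16, intercepts=intercepts)
        X = rng.standard_normal((8, 16))
        X /= np.linalg.norm(X, axis=1, keepdims=True)

        def overlap(e):
            rates = lif_rate(ens.gains[None, :] * (X @ e.T) + ens.biases)
            act = rates > 0.1 * rates.max()
            vals = []
            for i in range(8):
                for j in range(i + 1, 8):
                    union = (act[i] | act[j]).sum()
                    vals.append((act[i] & act[j]).sum() / union
                                if union else 0.0)
            return np.mean(vals)

        state = VojaPmState(eta=0.05, sigma=200.0)
        e = ens.encoders.copy()
        before = overlap(e)
        for rep in range(6):
            for k in rng.permutation(8):
                for _ in range(8):
                    a = lif_rate(ens.gains * (e @ X[k]) + ens.biases)
                    e = e + voja_pm_update(e, X[k], a, state, 0.05)
                    e /= np.linalg.norm(e, axis=1, keepdims=True)
        assert overlap(e) < before
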