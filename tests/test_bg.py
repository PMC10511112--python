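"""Basal-ganglia action selection and the pulse controller."""

import numpy as np
import pytest

from neurocog.core import Network, Simulator
from neurocog.bg import (ActionRule, BasalGanglia, Effect, PulseController,
                         TaskGraph, TaskGraphTimeout, Thalamus,
                         compute_utilities, gurney_rate_model, rate_select)
from neurocog.spa import Vocabulary


class TestRateOracle:
    def test_clear_winner_disinhibited(self):
        gpi = gurney_rate_model([0.9, 0.1, 0.1])["gpi"]
        assert gpi[0] < 0.1
        assert np.all(gpi[1:] > 0.3)
        assert rate_select([0.9, 0.1, 0.1]) == 0

    def test_all_zero_keeps_tonic_inhibition(self):
        gpi = gurney_rate_model([0.0, 0.0, 0.0])["gpi"]
        assert np.all(gpi > 0.1)
        assert rate_select([0.0, 0.0, 0.0]) is None


@pytest.fixture(scope="module")
def bg_sim():
    net = Network(seed=7)
    holder = {"u": np.zeros(3)}
    u = net.node("u", lambda t: holder["u"], size_out=3)
    bg = BasalGanglia(net, u, 3)
    thal = Thalamus(net, bg)
    p_thal = net.probe(thal.output, "output", synapse_tau=0.01)
    sim = Simulator(net)
    sim.run(0.15)  # settle to tonic state
    return holder, bg, sim, p_thal


class TestSpikingSelection:
    def test_matches_oracle_on_margin_utilities(self, bg_sim):
        """Spiking winner agrees with the rate-model oracle on >= 95% of
        random utility vectors with a 0.1 margin."""
        holder, bg, sim, p_thal = bg_sim
        rng = np.random.default_rng(0)
        agree, n_tests = 0, 50
        for _ in range(n_tests):
            u = rng.uniform(0.0, 0.6, 3)
            k = rng.integers(0, 3)
            u[k] = u.max() + rng.uniform(0.1, 0.4)
            u = np.clip(u, 0, 1.0)
            holder["u"][:] = u
            sim.run(0.1)
            out = sim.data(p_thal)[-1]
            oracle = rate_select(u)
            spiking = int(np.argmax(out)) if out.max() > 0.5 else None
            agree += spiking == oracle
        assert agree >= int(0.95 * n_tests)

    def test_dale_sign_constraints(self, bg_sim):
        holder, bg, sim, _ = bg_sim
        W = bg.weight_matrices(sim)
        for name in ("strD1_gpi", "strD2_gpe", "gpe_gpi", "gpe_stn"):
            assert W[name].max() <= 0, f"{name} must be inhibitory"
        for name in ("stn_gpi", "stn_gpe"):
            assert W[name].min() >= 0, f"{name} must be excitatory"


class TestComputeUtilities:
    def test_matching_pointer_dominates(self):
        vocab = Vocabulary(64, rng_seed=1)
        vocab.make_orthogonal(["s1", "s2", "s3"])
        rules = [ActionRule(f"r{i}", condition_pointer=f"s{i+1}")
                 for i in range(3)]
        u = compute_utilities(vocab["s1"].v, {}, rules, vocab)
        assert u[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(u[1:] < 0.3)

    def test_zero_state_zero_utilities(self):
        vocab = Vocabulary(32, rng_seed=2)
        vocab.make_orthogonal(["s1", "s2"])
        rules = [ActionRule("r1", condition_pointer="s1"),
                 ActionRule("r2", condition_pointer="s2")]
        u = compute_utilities(np.zeros(32), {}, rules, vocab)
        assert np.allclose(u, 0)

    def test_linearity_in_state(self):
        vocab = Vocabulary(32, rng_seed=3)
        vocab.make_orthogonal(["s1", "s2"])
        rules = [ActionRule("r1", condition_pointer="s1")]
        u_full = compute_utilities(vocab["s1"].v, {}, rules, vocab)
        u_half = compute_utilities(0.5 * vocab["s1"].v, {}, rules, vocab)
        assert u_half[0] == pytest.approx(0.5 * u_full[0], abs=1e-9)

    def test_signal_terms(self):
        vocab = Vocabulary(32, rng_seed=4)
        vocab.make_orthogonal(["s1"])
        rules = [ActionRule("r", condition_pointer="s1",
                            condition_signals={"go": 0.7}, bias=-0.8)]
        low = compute_utilities(vocab["s1"].v, {"go": 0.0}, rules, vocab)
        high = compute_utilities(vocab["s1"].v, {"go": 1.0}, rules, vocab)
        assert low[0] < 0.3 < high[0]


class TestPulseController:
    def _rules(self):
        return [ActionRule("p", condition_pointer="a", mode="pulse_initiator",
                           effects=[Effect("pulse_gate", "g1",
                                           duration=0.05)]),
                ActionRule("m", condition_pointer="b", mode="maintainer",
                           effects=[Effect("open_gate", "g2")])]

    def test_pulse_opens_then_closes(self):
        pc = PulseController(self._rules())
        gates = pc.step(0.0, np.array([1.0, 0.0]))
        assert gates.get("g1") == 1.0
        gates = pc.step(0.04, np.array([0.0, 0.0]))
        assert gates.get("g1") == 1.0
        gates = pc.step(0.06, np.array([0.0, 0.0]))
        assert gates.get("g1") == 0.0

    def test_continuous_mode_keeps_pulse_gates_open(self):
        pc = PulseController(self._rules(), mode="continuous")
        pc.step(0.0, np.array([1.0, 0.0]))
        gates = pc.step(0.5, np.array([0.0, 0.0]))
        assert gates.get("g1") == 1.0

    def test_maintainer_holds_and_releases(self):
        pc = PulseController(self._rules())
        gates = pc.step(0.0, np.array([0.0, 1.0]))
        assert gates.get("g2") == 1.0
        gates = pc.step(0.1, np.array([0.0, 1.0]))
        assert gates.get("g2") == 1.0
        gates = pc.step(0.2, np.array([0.0, 0.0]))
        assert gates.get("g2") == 0.0

    def test_refractory_blocks_refire(self):
        pc = PulseController(self._rules())
        pc.step(0.0, np.array([1.0, 0.0]))
        pc.step(0.1, np.array([0.0, 0.0]))
        pc.step(0.15, np.array([1.0, 0.0]))  # within 0.3 s refractory
        assert len([f for f in pc.firings if f[1] == "p"]) == 1


class TestTaskGraph:
    @staticmethod
    def _vocab():
        vocab = Vocabulary(32, rng_seed=5)
        vocab.make_orthogonal(["start", "work", "done"])
        return vocab

    def test_empty_rule_set_rejected(self):
        with pytest.raises(ValueError):
            TaskGraph([], self._vocab())

    def test_sequence_executes_in_order(self):
        vocab = self._vocab()
        rules = [
            ActionRule("begin", condition_pointer="start",
                       effects=[Effect("set_state", "step", "work")]),
            ActionRule("finish", condition_pointer="work",
                       condition_signals={"go": 0.7}, bias=-0.8,
                       effects=[Effect("set_state", "step", "done")]),
        ]
        tg = TaskGraph(rules, vocab, seed=6)
        tg.set_state("start")
        t0 = tg.sim.t
        while tg.sim.t - t0 < 1.5 and tg._current_state_name != "done":
            tg.signals["go"] = 1.0 if tg.sim.t - t0 > 0.3 else 0.0
            tg.step()
        names = [n for _, n, _ in tg.controller.firings]
        assert names == ["begin", "finish"]
        assert tg._current_state_name == "done"

    def test_watchdog_timeout_names_state(self):
        vocab = self._vocab()
        rules = [ActionRule("never", condition_pointer="work",
                            condition_signals={"no": 1.0}, bias=-1.0)]
        tg = TaskGraph(rules, vocab, seed=7, watchdog=0.3)
        tg.set_state("start")
        with pytest.raises(TaskGraphTimeout) as exc:
            tg.run(1.0)
        assert "start" in str(exc.value)
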