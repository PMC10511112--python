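"""Cortex -> basal ganglia -> thalamus action selection.

The basal ganglia implement winner-take-all selection over action utilities
using the classic Gurney-style box model: striatal D1/D2 channels, the
subthalamic nucleus (STN), globus pallidus externus (GPe) and internus
(GPi).  Each internal quantity is approximated by a small group of spiking
neurons per action channel; connection signs respect the known excitatory /
inhibitory neurochemistry (striatal and pallidal projections inhibitory,
STN diffusely excitatory), enforced by solving non-negative decoders so the
sign of the merged weights is the sign of the anatomical transform.

GPi output is tonically active and inhibits the thalamus; the *selected*
channel's GPi output is suppressed, disinhibiting its thalamic relay.  On
top of the selection loop sits the pulse controller: each long cognitive
action is implemented as a pair of rules — a *pulse initiator* that briefly
(default 50 ms) changes cortical gating, and a *maintainer* that keeps the
process marked as ongoing until a new striatal state is reached.  A
continuous-gating mode (the behaviour of the framework this model departs
from) is retained for A/B comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (Network, Simulator, Ensemble, lif_rate, solve_decoders,
                   solve_gain_bias, NeuronParams)

__all__ = [
    "GURNEY", "gurney_rate_model", "rate_select",
    "BasalGanglia", "Thalamus",
    "ActionRule", "Effect", "PulseController", "compute_utilities",
    "TaskGraph", "TaskGraphTimeout",
]

# Standard parameter set of the Gurney box model as used by the framework
# family this package follows.
GURNEY = dict(
    mm=1.0, mp=1.0, me=1.0, mg=1.0,
    ws=1.0, wt=1.0, wm=1.0, wg=1.0, wp=0.9, we=0.3,
    e=0.2, ep=-0.25, ee=-0.2, eg=-0.2,
    le=0.2, lg=0.2,
)


def _ramp(x, threshold, slope):
    x = np.asarray(x, dtype=float)
    return np.where(x < threshold, 0.0, slope * (x - threshold))


def gurney_rate_model(utilities: np.ndarray, n_iter: int = 200,
                      relax: float = 0.5) -> dict:
    """Non-spiking fixed-point oracle of the selection circuit.

    Returns the steady-state nucleus outputs for a constant utility vector.
    """
    u = np.asarray(utilities, dtype=float)
    g = GURNEY
    strD1 = _ramp(g["ws"] * (1 + g["lg"]) * u, g["e"], g["mm"])
    strD2 = _ramp(g["ws"] * (1 - g["le"]) * u, g["e"], g["mm"])
    stn = np.zeros_like(u)
    gpe = np.zeros_like(u)
    gpi = np.zeros_like(u)
    for _ in range(n_iter):
        stn_new = _ramp(g["wt"] * u - g["wg"] * gpe, g["ep"], g["mp"])
        ex = g["wp"] * stn_new.sum()
        gpe_new = _ramp(ex - g["wm"] * strD2, g["ee"], g["me"])
        gpi_new = _ramp(ex - g["wm"] * strD1 - g["we"] * gpe_new,
                        g["eg"], g["mg"])
        stn = relax * stn + (1 - relax) * stn_new
        gpe = relax * gpe + (1 - relax) * gpe_new
        gpi = relax * gpi + (1 - relax) * gpi_new
    return {"strD1": strD1, "strD2": strD2, "stn": stn,
            "gpe": gpe, "gpi": gpi}


def rate_select(utilities: np.ndarray, threshold: float = 0.1,
                min_utility: float = 0.3) -> Optional[int]:
    """Winner according to the rate-model oracle.

    A channel counts as selected when its GPi output is suppressed below
    ``threshold``, or suppressed to well under the runner-up's level (for
    low-utility winners the absolute GPi floor scales with the drive, but
    the *relative* disinhibition is unambiguous).  None when nothing is
    selected — e.g. all-zero utilities leave every channel tonically
    active at the same level.
    """
    u = np.asarray(utilities, dtype=float)
    if u.max() < min_utility:
        return None
    gpi = gurney_rate_model(u)["gpi"]
    k = int(np.argmin(gpi))
    others = np.delete(gpi, k)
    if gpi[k] < threshold or (others.size and gpi[k] <= 0.55 * others.min()):
        return k
    return None


# ---------------------------------------------------------------------------
# Spiking basal ganglia
# ---------------------------------------------------------------------------

def _channel_ensemble(net: Network, name: str, n_actions: int,
                      n_per_channel: int, intercept_low: float) -> Ensemble:
    """One ensemble holding all channels of a nucleus: block one-hot
    encoders, intercepts above the nucleus threshold."""
    n = n_actions * n_per_channel
    enc = np.zeros((n, n_actions))
    for c in range(n_actions):
        enc[c * n_per_channel:(c + 1) * n_per_channel, c] = 1.0
    intercepts = net.rng.uniform(intercept_low, 1.0, size=n)
    max_rates = net.rng.uniform(200, 400, size=n)
    return net.ensemble(name, n, n_actions, encoders=enc,
                        intercepts=intercepts, max_rates=max_rates)


def _channel_decoders(ens: Ensemble, n_actions: int, n_per_channel: int,
                      threshold: float, slope: float) -> np.ndarray:
    """Block decoders approximating the rectified-linear nucleus output
    per channel, solved channel-wise with non-negative least squares."""
    s = np.linspace(-0.3, 1.4, 120)
    target = _ramp(s, threshold, slope)
    dec = np.zeros((ens.n_neurons, n_actions))
    for c in range(n_actions):
        sl = slice(c * n_per_channel, (c + 1) * n_per_channel)
        A = lif_rate(ens.gains[sl][None, :] * s[:, None]
                     + ens.biases[sl][None, :], ens.neuron_params)
        lam = (0.1 * max(A.max(), 1e-3)) ** 2 * len(s)
        dec[sl, c] = solve_decoders(A, target, lam, nonnegative=True)[:, 0]
    return dec


class BasalGanglia:
    """Spiking winner-take-all selector over ``n_actions`` utilities.

    Wires five nucleus ensembles into ``net`` and exposes ``output`` (a node
    carrying the per-channel GPi activity; low output = selected).
    ``utilities_source`` is a node with one output per action.
    """

    TAU_AMPA = 0.002
    TAU_GABA = 0.008

    def __init__(self, net: Network, utilities_source, n_actions: int,
                 n_per_channel: int = 50, prefix: str = "bg") -> None:
        g = GURNEY
        self.n_actions = n_actions
        k, npc = n_actions, n_per_channel
        mk = lambda nm, thr: _channel_ensemble(
            net, f"{prefix}_{nm}", k, npc, thr)
        self.strD1 = mk("strD1", g["e"])
        self.strD2 = mk("strD2", g["e"])
        self.stn = mk("stn", g["ep"])
        self.gpe = mk("gpe", g["ee"])
        self.gpi = mk("gpi", g["eg"])

        I = np.eye(k)
        conn = net.connect
        conn(utilities_source, self.strD1,
             transform=g["ws"] * (1 + g["lg"]) * I, synapse_tau=self.TAU_AMPA)
        conn(utilities_source, self.strD2,
             transform=g["ws"] * (1 - g["le"]) * I, synapse_tau=self.TAU_AMPA)
        conn(utilities_source, self.stn,
             transform=g["wt"] * I, synapse_tau=self.TAU_AMPA)

        def dec(ens, thr, slope):
            return _channel_decoders(ens, k, npc, thr, slope)

        def link(pre, d, post, transform, tau, sign):
            c = conn(pre, post, transform=transform, synapse_tau=tau,
                     weight_sign=sign, merged=True)
            c._fixed_decoders = d
            return c

        d_str1 = dec(self.strD1, g["e"], g["mm"])
        d_str2 = dec(self.strD2, g["e"], g["mm"])
        d_stn = dec(self.stn, g["ep"], g["mp"])
        d_gpe = dec(self.gpe, g["ee"], g["me"])
        self.d_gpi = dec(self.gpi, g["eg"], g["mg"])

        self.conn_strD1_gpi = link(self.strD1, d_str1, self.gpi,
                                   -g["wm"] * I, self.TAU_GABA, -1)
        self.conn_strD2_gpe = link(self.strD2, d_str2, self.gpe,
                                   -g["wm"] * I, self.TAU_GABA, -1)
        self.conn_stn_gpi = link(self.stn, d_stn, self.gpi,
                                 g["wp"] * np.ones((k, k)), self.TAU_AMPA, +1)
        self.conn_stn_gpe = link(self.stn, d_stn, self.gpe,
                                 g["wp"] * np.ones((k, k)), self.TAU_AMPA, +1)
        self.conn_gpe_gpi = link(self.gpe, d_gpe, self.gpi,
                                 -g["we"] * I, self.TAU_GABA, -1)
        self.conn_gpe_stn = link(self.gpe, d_gpe, self.stn,
                                 -g["wg"] * I, self.TAU_GABA, -1)

        self.output = net.node(f"{prefix}_output", lambda t, x: x,
                               size_in=k, size_out=k)
        c_out = conn(self.gpi, self.output, synapse_tau=self.TAU_GABA)
        c_out._fixed_decoders = self.d_gpi

    def weight_matrices(self, sim: Simulator) -> dict:
        """Merged weight matrices of the internal pathways (for inspecting
        the excitatory/inhibitory sign constraints)."""
        out = {}
        for nm in ("strD1_gpi", "strD2_gpe", "stn_gpi", "stn_gpe",
                   "gpe_gpi", "gpe_stn"):
            conn = getattr(self, f"conn_{nm}")
            out[nm] = sim.conn_map[id(conn)].weights
        return out


class Thalamus:
    """Tonically active relays inhibited by GPi; a relay's activation in
    [0, 1] rises when its channel is disinhibited."""

    def __init__(self, net: Network, bg: BasalGanglia,
                 n_per_channel: int = 40, prefix: str = "thal") -> None:
        k = bg.n_actions
        self.n_actions = k
        self.ens = _channel_ensemble(net, f"{prefix}_ens", k, n_per_channel,
                                     0.2)
        bias = net.node(f"{prefix}_bias", np.ones(k))
        net.connect(bias, self.ens, synapse_tau=0.005)
        # tonic GPi (~0.17 for idle channels) must keep relays well below
        # the activation threshold; only a suppressed channel (~0) passes
        net.connect(bg.output, self.ens, transform=-4.5 * np.eye(k),
                    synapse_tau=0.008)
        npc = n_per_channel
        dec = np.zeros((self.ens.n_neurons, k))
        s = np.linspace(-0.3, 1.4, 120)
        target = np.clip(s, 0, 1)
        for c in range(k):
            sl = slice(c * npc, (c + 1) * npc)
            A = lif_rate(self.ens.gains[sl][None, :] * s[:, None]
                         + self.ens.biases[sl][None, :],
                         self.ens.neuron_params)
            lam = (0.1 * A.max()) ** 2 * len(s)
            dec[sl, c] = solve_decoders(A, target, lam,
                                        nonnegative=True)[:, 0]
        self.output = net.node(f"{prefix}_output",
                               lambda t, x: np.clip(x, 0.0, 1.0),
                               size_in=k, size_out=k)
        c_out = net.connect(self.ens, self.output, synapse_tau=0.005)
        c_out._fixed_decoders = dec


# ---------------------------------------------------------------------------
# Action rules and the pulse controller
# ---------------------------------------------------------------------------

@dataclass
class Effect:
    kind: str                  # pulse_gate | open_gate | close_gate | set_state
    target: str                # gate name or state-slot name
    value: object = None       # pointer name for set_state
    duration: float = 0.05     # pulse length (s)

    def __post_init__(self) -> None:
        if self.kind not in ("pulse_gate", "open_gate", "close_gate",
                             "set_state"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass
class ActionRule:
    """A striatal condition plus thalamic effects.

    Utility is a linear functional on the cortical state: the similarity of
    the control-state buffer to ``condition_pointer`` plus weighted scalar
    signals plus a constant.  ``mode`` distinguishes rules that fire a brief
    pulse from rules that simply maintain processing.
    """

    name: str
    effects: list = field(default_factory=list)
    condition_pointer: Optional[str] = None
    condition_signals: dict = field(default_factory=dict)
    bias: float = 0.0
    mode: str = "pulse_initiator"   # or "maintainer"
    refractory: float = 0.3         # re-fire guard for pulse rules (s)

    def __post_init__(self) -> None:
        if self.mode not in ("pulse_initiator", "maintainer"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


def compute_utilities(state_vector: np.ndarray, signals: dict,
                      rules: Sequence[ActionRule], vocab) -> np.ndarray:
    """utility_k = cond_k . state + sum_i w_i * signal_i + bias_k.

    The pointer part is the dot product with the rule's condition pointer
    (solved connection weights compute exactly this in the spiking model).
    """
    if not rules:
        raise ValueError("no rules")
    out = np.zeros(len(rules))
    for k, rule in enumerate(rules):
        u = rule.bias
        if rule.condition_pointer is not None:
            u += float(np.dot(vocab[rule.condition_pointer].v,
                              np.asarray(state_vector)))
        for sig, w in rule.condition_signals.items():
            u += w * float(signals.get(sig, 0.0))
        out[k] = u
    return np.clip(out, 0.0, 1.2)


class PulseController:
    """Turns thalamic channel activations into gate commands.

    Pulse-initiator rules trigger once per condition epoch: their
    ``pulse_gate`` effects open a gate for a fixed duration, their
    ``set_state`` effects request a control-state overwrite.  Maintainer
    rules hold their gates open for as long as they stay selected.  In
    ``continuous`` mode pulse gates behave like maintained gates (the
    default-framework behaviour, kept for A/B comparison).
    """

    def __init__(self, rules: Sequence[ActionRule], *,
                 activation_threshold: float = 0.5,
                 mode: str = "pulse") -> None:
        if mode not in ("pulse", "continuous"):
            raise ValueError(f"unknown gating mode {mode!r}")
        self.rules = list(rules)
        self.threshold = activation_threshold
        self.mode = mode
        self._gate_until: dict[str, float] = {}
        self._last_fire: dict[str, float] = {}
        self._prev_active = np.zeros(len(self.rules), dtype=bool)
        self.firings: list = []          # (t, rule name, mode)
        self.state_requests: list = []   # (t, slot, pointer name)

    def step(self, t: float, activations: np.ndarray) -> dict:
        """Returns {gate_name: 0/1} commands for this instant."""
        act = np.asarray(activations) > self.threshold
        gates: dict[str, float] = {}
        for k, rule in enumerate(self.rules):
            rising = act[k] and not self._prev_active[k]
            if rule.mode == "pulse_initiator":
                if rising and (t - self._last_fire.get(rule.name, -1e9)
                               >= rule.refractory):
                    self._last_fire[rule.name] = t
                    self.firings.append((t, rule.name, rule.mode))
                    for eff in rule.effects:
                        if eff.kind == "pulse_gate":
                            until = (np.inf if self.mode == "continuous"
                                     else t + eff.duration)
                            self._gate_until[eff.target] = until
                        elif eff.kind == "open_gate":
                            self._gate_until[eff.target] = np.inf
                        elif eff.kind == "close_gate":
                            self._gate_until[eff.target] = -np.inf
                        elif eff.kind == "set_state":
                            self.state_requests.append(
                                (t, eff.target, eff.value))
            else:  # maintainer: hold gates open while selected
                if act[k]:
                    if rising:
                        self.firings.append((t, rule.name, rule.mode))
                    for eff in rule.effects:
                        if eff.kind in ("pulse_gate", "open_gate"):
                            gates[eff.target] = 1.0
                elif self._prev_active[k]:
                    # falling edge: release the maintained gates
                    for eff in rule.effects:
                        if eff.kind in ("pulse_gate", "open_gate"):
                            gates.setdefault(eff.target, 0.0)
        self._prev_active = act
        for gate, until in list(self._gate_until.items()):
            if until == -np.inf:
                gates[gate] = 0.0
                del self._gate_until[gate]
            elif t <= until:
                gates[gate] = 1.0
            else:
                gates.setdefault(gate, 0.0)
                del self._gate_until[gate]
        return gates


class TaskGraphTimeout(RuntimeError):
    def __init__(self, last_state: str, t: float) -> None:
        super().__init__(f"no rule fired for watchdog interval; "
                         f"last state {last_state!r} at t={t:.3f}s")
        self.last_state = last_state


class TaskGraph:
    """Spiking control loop: state buffer -> utilities -> BG -> thalamus ->
    pulse controller -> gates/state updates.

    The cortical control state is held in a spiking buffer; ``signals`` is a
    dict of named scalars (e.g. accumulator bound detectors) that rules may
    reference.  ``run`` executes until a rule sets the step state to
    ``done`` or the watchdog expires.
    """

    def __init__(self, rules: Sequence[ActionRule], vocab,
                 *, seed: int = 0, gating_mode: str = "pulse",
                 state_neurons: int = 600, watchdog: float = 3.0,
                 dt: float = 0.001, net: Optional[Network] = None,
                 warmup: float = 0.2) -> None:
        if not rules:
            raise ValueError("empty rule set")
        self.rules = list(rules)
        self.vocab = vocab
        self.watchdog = watchdog
        d = vocab.dimensions
        if net is None:
            net = Network(seed=seed, dt=dt)
        else:
            dt = net.dt
        self.net = net
        self.signals: dict[str, float] = {}
        self._state_override: Optional[np.ndarray] = None
        self._override_until = -1.0
        self._current_state_name = "start"

        self.state = net.ensemble("ctrl_state", state_neurons, d,
                                  radius=1.2)
        self.state_in = net.node("ctrl_state_in",
                                 lambda t: self._state_input(t), size_out=d)
        self._state_in_conn = net.connect(self.state_in, self.state,
                                          synapse_tau=0.005)
        self._state_rec_conn = net.connect(self.state, self.state,
                                           synapse_tau=0.1)
        # transition wipe: brief inhibition clears the old state pointer so
        # utilities do not fire on stale mixtures
        self._reset_until = -1.0
        net.gate("ctrl_state_reset", 0.0)
        wipe = net.node("ctrl_state_wipe", np.full(state_neurons, -4.0))
        net.connect(wipe, self.state.neurons, synapse_tau=0.003,
                    gate="ctrl_state_reset")

        # channels: one per rule plus a tonic "do nothing" channel at the
        # utility threshold, so nothing fires when no condition matches
        n_rules = len(self.rules)
        self.utility_threshold = 0.3
        M = np.vstack([
            np.array([vocab[r.condition_pointer].v
                      if r.condition_pointer else np.zeros(d)
                      for r in self.rules]),
            np.zeros((1, d)),
        ])
        # the pointer-match part is clipped to 1 so that transients while
        # a new state pointer is being driven in cannot fire signal rules
        self.utilities = net.node(
            "utilities",
            lambda t, x: np.clip(np.clip(x, 0.0, 1.0)
                                 + self._signal_part_now(), 0.0, 1.2),
            size_in=n_rules + 1, size_out=n_rules + 1)
        net.connect(self.state, self.utilities, transform=M,
                    synapse_tau=0.01)
        self.bg = BasalGanglia(net, self.utilities, n_rules + 1)
        self.thalamus = Thalamus(net, self.bg)
        self.controller = PulseController(self.rules, mode=gating_mode)
        self.gate_log: list = []
        self.sim = Simulator(self.net)
        # let GPi reach its tonic firing level before any rule can fire,
        # otherwise the transiently disinhibited thalamus triggers rules
        for _ in range(int(round(warmup / dt))):
            self.sim.step()
        self.controller._prev_active = np.ones(len(self.rules), dtype=bool)

    def _signal_part_now(self) -> np.ndarray:
        out = np.zeros(len(self.rules) + 1)
        for k, rule in enumerate(self.rules):
            out[k] = rule.bias + sum(
                w * self.signals.get(sig, 0.0)
                for sig, w in rule.condition_signals.items())
        out[-1] = self.utility_threshold
        return out

    def _state_input(self, t: float) -> np.ndarray:
        if t <= self._reset_until:
            return np.zeros(self.vocab.dimensions)
        if self._state_override is not None and t <= self._override_until:
            return self._state_override
        return np.zeros(self.vocab.dimensions)

    def set_state(self, pointer_name: str, t: Optional[float] = None,
                  strength: float = 1.5, hold: float = 0.1,
                  wipe: float = 0.03) -> None:
        """Wipe the state buffer briefly, then drive it toward a control
        pointer for ``hold`` seconds.

        The wipe also clears the recurrent connection's synaptic trace —
        its time constant (100 ms) would otherwise outlive the inhibitory
        pulse and reload the old state."""
        t = self.sim.t if t is None else t
        self._reset_until = t + wipe
        self._state_override = strength * self.vocab[pointer_name].v
        self._override_until = t + wipe + hold
        self._current_state_name = pointer_name
        for conn in (self._state_rec_conn, self._state_in_conn):
            cs = self.sim.conn_map.get(id(conn))
            if cs is not None:
                cs.filter.state[...] = 0.0
                cs.value = np.zeros_like(np.atleast_1d(cs.value))

    def step(self) -> None:
        sim = self.sim
        sim.set_gate("ctrl_state_reset",
                     1.0 if sim.t <= self._reset_until else 0.0)
        sim.step()
        thal = sim._node_outputs["thal_output"]
        gates = self.controller.step(sim.t, thal[:-1])
        for req_t, slot, pointer in self.controller.state_requests:
            self.set_state(pointer)
        self.controller.state_requests.clear()
        for gname, gval in gates.items():
            if gname in self.net.gates:
                sim.set_gate(gname, gval)
        if gates:
            self.gate_log.append((sim.t, dict(gates)))
        self._gates_now = gates

    def run(self, max_time: float, *,
            stop_state: str = "done") -> list:
        """Run until the ``stop_state`` pointer is set or watchdog expiry.
        Returns the ordered list of rule firings (t, name, mode)."""
        start = self.sim.t
        last_fire = self.sim.t
        n_fired = 0
        while self.sim.t - start < max_time:
            self.step()
            if len(self.controller.firings) > n_fired:
                n_fired = len(self.controller.firings)
                last_fire = self.sim.t
            if self._current_state_name == stop_state:
                break
            if self.sim.t - last_fire > self.watchdog:
                raise TaskGraphTimeout(self._current_state_name, self.sim.t)
        return list(self.controller.firings)
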