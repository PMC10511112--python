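"""Spiking-neuron vector representation and time-stepped simulation.

This module implements the Neural Engineering Framework (NEF) primitives the
rest of the package is built on: leaky integrate-and-fire (LIF) tuning curves,
gain/bias inversion, ridge-regression decoder solving, factored and merged
connection weights, first-order synaptic filtering, and a small deterministic
simulator for networks of ensembles, nodes, gates and probes.

Conventions (normalized LIF): membrane resistance R = 1, firing threshold 1,
reset voltage 0.  A represented vector ``x`` drives neuron ``i`` with current

    J_i = alpha_i * (e_i . x) / radius + J_bias_i

where ``e_i`` is the neuron's unit-length preferred-direction vector (encoder),
``alpha_i`` its gain and ``J_bias_i`` its background current.  Decoders ``d``
are solved by regularized least squares so that ``sum_i d_i (a_i * h)(t)``
approximates a target function of ``x``, with ``h`` a first-order low-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = [
    "NeuronParams",
    "lif_rate",
    "solve_gain_bias",
    "compute_current",
    "step_neurons",
    "solve_decoders",
    "merge_weights",
    "filter_signal",
    "Ensemble",
    "Node",
    "Gate",
    "Connection",
    "Probe",
    "Network",
    "Simulator",
    "simulate",
    "sample_eval_points",
    "default_regularization",
]


# ---------------------------------------------------------------------------
# Neuron model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """LIF / adaptive-LIF parameters.

    tau_rc : membrane time constant (s)
    tau_ref : absolute refractory period (s)
    model_kind : "lif" or "adaptive_lif"
    adaptation_tau : decay time constant of the adaptation current (s)
    adaptation_increment : adaptation current added per spike (dimensionless)
    """

    tau_rc: float = 0.02
    tau_ref: float = 0.002
    model_kind: str = "lif"
    adaptation_tau: Optional[float] = None
    adaptation_increment: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_rc <= 0:
            raise ValueError("tau_rc must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.model_kind not in ("lif", "adaptive_lif"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "adaptive_lif":
            if self.adaptation_tau is None or self.adaptation_increment is None:
                raise ValueError("adaptive_lif requires adaptation_tau and "
                                 "adaptation_increment")
        else:
            if self.adaptation_tau is not None or self.adaptation_increment is not None:
                raise ValueError("adaptation fields only valid for adaptive_lif")


def lif_rate(J, params: NeuronParams = NeuronParams()):
    """Steady-state LIF firing rate (Hz) for input current ``J``.

    rate = 0 for J <= 1, else 1 / (tau_ref + tau_rc * ln(J / (J - 1))).
    """
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite input current")
    out = np.zeros_like(J)
    above = J > 1.0
    Ja = J[above] if J.ndim else (J if above else None)
    if J.ndim == 0:
        if above:
            return float(1.0 / (params.tau_ref
                                + params.tau_rc * np.log1p(1.0 / (J - 1.0))))
        return 0.0
    out[above] = 1.0 / (params.tau_ref
                        + params.tau_rc * np.log1p(1.0 / (Ja - 1.0)))
    return out


def solve_gain_bias(max_rate, intercept, params: NeuronParams = NeuronParams()):
    """Invert the LIF tuning curve: find (gain, bias) so that the neuron is
    silent at projection = intercept and fires at ``max_rate`` at projection 1.

    Vectorized over max_rate / intercept.  Raises for rates at or above the
    refractory-limited asymptote 1/tau_ref.
    """
    max_rate = np.asarray(max_rate, dtype=float)
    intercept = np.asarray(intercept, dtype=float)
    if np.any(max_rate <= 0):
        raise ValueError("max_rate must be positive")
    if np.any((intercept < -1) | (intercept >= 1)):
        raise ValueError("intercept must lie in [-1, 1)")
    inv_t = 1.0 / max_rate - params.tau_ref
    if np.any(inv_t <= 0):
        raise ValueError("max_rate unreachable: at or above 1/tau_ref")
    # current at projection 1 giving max_rate
    J_max = 1.0 / (1.0 - np.exp(-inv_t / params.tau_rc))
    gain = (J_max - 1.0) / (1.0 - intercept)
    bias = 1.0 - gain * intercept
    return gain, bias


def step_neurons(state: dict, J, params: NeuronParams, dt: float):
    """Advance LIF (or adaptive LIF) neurons by one step of length ``dt``.

    ``state`` holds "voltage", "refractory" (time remaining, s) and, for
    adaptive neurons, "adaptation".  Returns a binary spike array.  Spike
    times are interpolated within the step so that the refractory clock
    carries fractional periods, keeping simulated rates close to analytic
    rates even for periods of only a few ``dt``.
    """
    V = state["voltage"]
    ref = state["refractory"]
    J = np.asarray(J, dtype=float)
    if params.model_kind == "adaptive_lif":
        J = J - state["adaptation"]

    ref -= dt
    delta_t = dt - ref
    np.clip(delta_t, 0.0, dt, out=delta_t)
    V[...] = J + (V - J) * np.exp(delta_t * (-1.0 / params.tau_rc))

    spiked = V > 1.0
    spikes = spiked.astype(float)
    if np.any(spiked):
        # interpolate the in-step crossing time so that the refractory clock
        # carries the fractional period into the next step
        Js = J[spiked]
        t_left = -params.tau_rc * np.log1p(-(V[spiked] - 1.0) / (Js - 1.0))
        ref[spiked] = params.tau_ref + dt - t_left
        V[spiked] = 0.0
    np.maximum(ref, 0.0, out=ref)
    np.maximum(V, 0.0, out=V)

    if params.model_kind == "adaptive_lif":
        n = state["adaptation"]
        n *= np.exp(-dt / params.adaptation_tau)
        n += params.adaptation_increment * spikes
    return spikes


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def _unit_rows(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length encoder")
    return v / norms


class Ensemble:
    """A population of spiking neurons representing a real-valued vector."""

    def __init__(
        self,
        name: str,
        n_neurons: int,
        dimensions: int,
        rng: np.random.Generator,
        *,
        encoders: Optional[np.ndarray] = None,
        intercepts: Optional[np.ndarray] = None,
        max_rates: Optional[np.ndarray] = None,
        neuron_params: NeuronParams = NeuronParams(),
        radius: float = 1.0,
        intercept_range: tuple = (-1.0, 0.9),
        max_rate_range: tuple = (200.0, 400.0),
    ) -> None:
        self.name = name
        self.n_neurons = int(n_neurons)
        self.dimensions = int(dimensions)
        self.neuron_params = neuron_params
        self.radius = float(radius)
        if encoders is None:
            encoders = rng.standard_normal((self.n_neurons, self.dimensions))
        self.encoders = _unit_rows(np.asarray(encoders, dtype=float))
        if intercepts is None:
            intercepts = rng.uniform(*intercept_range, size=self.n_neurons)
        if max_rates is None:
            max_rates = rng.uniform(*max_rate_range, size=self.n_neurons)
        self.intercepts = np.asarray(intercepts, dtype=float)
        self.max_rates = np.asarray(max_rates, dtype=float)
        self.gains, self.biases = solve_gain_bias(
            self.max_rates, self.intercepts, neuron_params)

    # -- analytic (rate-mode) helpers used for decoder solving ------------
    def current(self, x: np.ndarray) -> np.ndarray:
        """Per-neuron currents for represented value(s) ``x``.

        ``x`` has shape (dimensions,) or (n_points, dimensions); the result
        has shape (n_neurons,) or (n_points, n_neurons).
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.dimensions:
            raise ValueError(
                f"dimension mismatch: x has {x.shape[-1]}, "
                f"ensemble {self.name!r} has {self.dimensions}")
        proj = x @ self.encoders.T / self.radius
        return self.gains * proj + self.biases

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Analytic steady-state firing rates at represented value(s) ``x``."""
        return lif_rate(self.current(x), self.neuron_params)

    @property
    def neurons(self) -> "_Neurons":
        return _Neurons(self)


class _Neurons:
    """Addressing handle for direct per-neuron current injection."""

    def __init__(self, ensemble: Ensemble) -> None:
        self.ensemble = ensemble


def compute_current(x, ens: Ensemble) -> np.ndarray:
    """J_i = alpha_i * (e_i . x) / radius + J_bias_i (module-level alias)."""
    return ens.current(x)


# ---------------------------------------------------------------------------
# Decoder solving & weights
# ---------------------------------------------------------------------------

def solve_decoders(activities: np.ndarray, targets: np.ndarray,
                   regularization: float = 0.0, *,
                   nonnegative: bool = False) -> np.ndarray:
    """Ridge-regression decoders: minimize ||A d - Y||^2 + lam ||d||^2.

    ``activities`` is (n_points, n_neurons), ``targets`` (n_points, d_out).
    With ``nonnegative`` the solution is constrained to d >= 0 (used for
    sign-constrained pathways such as the basal ganglia).
    """
    A = np.asarray(activities, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    if not np.any(A):
        raise ValueError("silent ensemble: all-zero activities")
    if nonnegative:
        lam = np.sqrt(regularization)
        n = A.shape[1]
        A_aug = np.vstack([A, lam * np.eye(n)]) if lam > 0 else A
        d = np.empty((n, Y.shape[1]))
        for k in range(Y.shape[1]):
            y_aug = (np.concatenate([Y[:, k], np.zeros(n)])
                     if lam > 0 else Y[:, k])
            d[:, k] = scipy.optimize.nnls(A_aug, y_aug)[0]
        return d
    G = A.T @ A + regularization * np.eye(A.shape[1])
    return scipy.linalg.solve(G, A.T @ Y, assume_a="pos")


def merge_weights(decoders: np.ndarray, post_encoders: np.ndarray,
                  post_gains: np.ndarray, *, post_radius: float = 1.0,
                  transform: Optional[np.ndarray] = None) -> np.ndarray:
    """Fold decode-then-encode into a full weight matrix.

    omega[j, i] = alpha_j * (e_j . T d_i) / radius, so that the current into
    post neuron j is ``omega @ filtered_pre_activity`` (bias added separately).
    """
    d = np.asarray(decoders, dtype=float)  # (n_pre, d_out)
    if transform is not None:
        d = d @ np.asarray(transform, dtype=float).T
    if d.shape[1] != post_encoders.shape[1]:
        raise ValueError("decoder output dim != post ensemble dim")
    return (post_gains[:, None] * (post_encoders @ d.T)) / post_radius


def filter_signal(signal: np.ndarray, synapse_tau: float, dt: float,
                  axis: int = 0) -> np.ndarray:
    """First-order low-pass filter along ``axis`` with DC gain 1.

    For spike trains, pass impulses of amplitude 1/dt so that a single spike
    carries unit area and a constant rate r maps to steady state r.
    """
    if synapse_tau <= 0:
        raise ValueError("synapse_tau must be positive")
    x = np.moveaxis(np.asarray(signal, dtype=float), axis, 0)
    a = np.exp(-dt / synapse_tau)
    out = np.empty_like(x)
    acc = np.zeros(x.shape[1:])
    for k in range(x.shape[0]):
        acc = a * acc + (1 - a) * x[k]
        out[k] = acc
    return np.moveaxis(out, 0, axis)


class Lowpass:
    """Stateful one-pole low-pass used inside the simulator."""

    __slots__ = ("a", "state")

    def __init__(self, tau: Optional[float], dt: float, shape) -> None:
        self.a = np.exp(-dt / tau) if tau else 0.0
        self.state = np.zeros(shape)

    def step(self, x: np.ndarray) -> np.ndarray:
        if self.a == 0.0:
            self.state = np.asarray(x, dtype=float).copy()
        else:
            self.state *= self.a
            self.state += (1.0 - self.a) * x
        return self.state


# ---------------------------------------------------------------------------
# Network description
# ---------------------------------------------------------------------------

class Node:
    """External signal or arbitrary per-step callback.

    ``output`` may be a constant array or a callable ``f(t, x) -> array``
    where ``x`` is the summed (gated, filtered) input to the node.
    """

    def __init__(self, name: str, output, size_in: int = 0,
                 size_out: Optional[int] = None) -> None:
        self.name = name
        self.size_in = int(size_in)
        if callable(output):
            if size_out is None:
                raise ValueError("callable node needs explicit size_out")
            self.output = output
            self.size_out = int(size_out)
        else:
            arr = np.atleast_1d(np.asarray(output, dtype=float))
            self.output = arr
            self.size_out = arr.size


class Gate:
    """A named multiplicative gate in [0, 1] applied to connections.

    ``source`` is None (manual control via ``Simulator.set_gate``) or a node
    name whose (scalar) output drives the gate each step.
    """

    def __init__(self, name: str, value: float = 1.0,
                 source: Optional[str] = None) -> None:
        self.name = name
        self.value = float(value)
        self.source = source


@dataclass
class Connection:
    """A weighted, synapse-filtered link between network members.

    pre/post are Ensemble, Node or ``ensemble.neurons`` handles.  Exactly one
    of the factored (decoders) or full-weight form is active; ``weights`` may
    be given explicitly, or requested via ``merged=True`` to fold solved
    decoders into a weight matrix at build time.
    """

    pre: object
    post: object
    function: Optional[Callable] = None
    transform: Optional[np.ndarray] = None
    synapse_tau: Optional[float] = 0.005
    gate: Optional[str] = None
    weights: Optional[np.ndarray] = None
    merged: bool = False
    learning: Optional[object] = None
    solver: str = "ridge"
    reg_scale: float = 1.0
    eval_points: Optional[np.ndarray] = None
    sample_domain: str = "ball"
    weight_sign: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.synapse_tau is not None and self.synapse_tau <= 0:
            raise ValueError("synapse_tau must be positive")
        if self.weights is not None and self.function is not None:
            raise ValueError("full-weight and decoded forms are exclusive")


class Probe:
    """Records a signal every dt: decoded value, spikes, or node output."""

    def __init__(self, target: object, attr: str = "decoded",
                 synapse_tau: Optional[float] = 0.01,
                 label: Optional[str] = None) -> None:
        if attr not in ("decoded", "spikes", "output", "input"):
            raise ValueError(f"unknown probe attr {attr!r}")
        self.target = target
        self.attr = attr
        self.synapse_tau = synapse_tau
        self.label = label or f"{getattr(target, 'name', target)}.{attr}"


class Network:
    """Container for ensembles, nodes, gates, connections and probes."""

    def __init__(self, seed: int = 0, dt: float = 0.001) -> None:
        self.seed = int(seed)
        self.dt = float(dt)
        self.rng = np.random.default_rng(self.seed)
        self.ensembles: dict[str, Ensemble] = {}
        self.nodes: dict[str, Node] = {}
        self.gates: dict[str, Gate] = {}
        self.connections: list[Connection] = []
        self.probes: list[Probe] = []

    # -- builders ---------------------------------------------------------
    def ensemble(self, name: str, n_neurons: int, dimensions: int,
                 **kwargs) -> Ensemble:
        if name in self.ensembles:
            raise ValueError(f"duplicate ensemble {name!r}")
        ens = Ensemble(name, n_neurons, dimensions, self.rng, **kwargs)
        self.ensembles[name] = ens
        return ens

    def node(self, name: str, output, size_in: int = 0,
             size_out: Optional[int] = None) -> Node:
        if name in self.nodes:
            raise ValueError(f"duplicate node {name!r}")
        node = Node(name, output, size_in, size_out)
        self.nodes[name] = node
        return node

    def gate(self, name: str, value: float = 1.0,
             source: Optional[str] = None) -> Gate:
        g = Gate(name, value, source)
        self.gates[name] = g
        return g

    def connect(self, pre, post, **kwargs) -> Connection:
        conn = Connection(pre, post, **kwargs)
        self._check_endpoint(conn.pre, conn)
        self._check_endpoint(conn.post, conn)
        self.connections.append(conn)
        return conn

    def probe(self, target, attr: str = "decoded", **kwargs) -> Probe:
        p = Probe(target, attr, **kwargs)
        self.probes.append(p)
        return p

    def _check_endpoint(self, obj, conn) -> None:
        if isinstance(obj, _Neurons):
            obj = obj.ensemble
        if isinstance(obj, Ensemble):
            if self.ensembles.get(obj.name) is not obj:
                raise ValueError(
                    f"connection {conn.label!r}: unknown ensemble {obj.name!r}")
        elif isinstance(obj, Node):
            if self.nodes.get(obj.name) is not obj:
                raise ValueError(
                    f"connection {conn.label!r}: unknown node {obj.name!r}")
        else:
            raise TypeError(f"connection {conn.label!r}: bad endpoint {obj!r}")


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

def sample_eval_points(rng: np.random.Generator, n_points: int, dims: int,
                       radius: float = 1.0, domain: str = "ball") -> np.ndarray:
    """Evaluation points for decoder solving: uniform in the ball or cube."""
    if domain == "cube":
        return rng.uniform(-radius, radius, size=(n_points, dims))
    x = rng.standard_normal((n_points, dims))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    r = rng.uniform(0, 1, size=(n_points, 1)) ** (1.0 / dims)
    return radius * x * r


def default_regularization(A: np.ndarray) -> float:
    """lam = (0.1 * max activity)^2 * n_points (standard ridge heuristic)."""
    return (0.1 * A.max()) ** 2 * A.shape[0]


class _ConnState:
    __slots__ = ("conn", "decoders", "weights", "filter", "value",
                 "pre_kind", "post_kind", "pre", "post", "theta")

    def __init__(self) -> None:
        self.decoders = None
        self.weights = None
        self.theta = None


class Simulator:
    """Deterministic time-stepped executor for a :class:`Network`.

    All signals propagate with a one-step delay; gates multiply a
    connection's contribution at read time, so closing a gate suppresses
    transmission immediately.
    """

    def __init__(self, network: Network, *, n_eval_points: int = 500,
                 progress: bool = False) -> None:
        self.net = network
        self.dt = network.dt
        self.t = 0.0
        self.n_eval_points = n_eval_points
        self._build()

    # -- build ------------------------------------------------------------
    def _endpoint(self, obj):
        if isinstance(obj, _Neurons):
            return "neurons", obj.ensemble
        if isinstance(obj, Ensemble):
            return "ensemble", obj
        return "node", obj

    def _build(self) -> None:
        net = self.net
        rng = np.random.default_rng(net.seed + 7919)
        self.states: dict[str, dict] = {}
        for ens in net.ensembles.values():
            st = {
                "voltage": rng.uniform(0, 1, ens.n_neurons),
                "refractory": np.zeros(ens.n_neurons),
                "spikes": np.zeros(ens.n_neurons),
            }
            if ens.neuron_params.model_kind == "adaptive_lif":
                st["adaptation"] = np.zeros(ens.n_neurons)
            self.states[ens.name] = st

        self.conn_states: list[_ConnState] = []
        self.conn_map: dict[int, _ConnState] = {}
        for conn in net.connections:
            cs = _ConnState()
            cs.conn = conn
            cs.pre_kind, cs.pre = self._endpoint(conn.pre)
            cs.post_kind, cs.post = self._endpoint(conn.post)
            if cs.pre_kind == "ensemble" and conn.weights is None:
                cs.decoders = self._solve(conn, cs.pre, rng)
                out_dim = cs.decoders.shape[1]
                if conn.transform is not None and np.ndim(conn.transform) == 2:
                    out_dim = np.asarray(conn.transform).shape[0]
                if conn.merged or cs.post_kind == "neurons" \
                        or conn.weight_sign is not None:
                    if cs.post_kind == "node":
                        raise ValueError("merged weights need ensemble post")
                    post = cs.post
                    cs.weights = merge_weights(
                        cs.decoders, post.encoders, post.gains,
                        post_radius=post.radius,
                        transform=conn.transform)
                    if conn.weight_sign is not None:
                        if conn.weight_sign > 0:
                            np.clip(cs.weights, 0.0, None, out=cs.weights)
                        else:
                            np.clip(cs.weights, None, 0.0, out=cs.weights)
                    cs.decoders = None
                    out_dim = post.n_neurons
            elif conn.weights is not None:
                cs.weights = np.asarray(conn.weights, dtype=float)
                out_dim = cs.weights.shape[0]
            else:  # node pre
                out_dim = cs.pre.size_out
                if conn.transform is not None and np.ndim(conn.transform) == 2:
                    out_dim = np.asarray(conn.transform).shape[0]
            if cs.weights is not None and cs.pre_kind == "ensemble":
                sig_dim = cs.pre.n_neurons if cs.decoders is None \
                    and conn.weights is None else cs.weights.shape[0]
                # weights applied to filtered spikes: filter pre activity
                cs.filter = Lowpass(conn.synapse_tau, self.dt,
                                    cs.pre.n_neurons)
                cs.value = np.zeros(cs.weights.shape[0])
            else:
                cs.filter = Lowpass(conn.synapse_tau, self.dt, out_dim)
                cs.value = np.zeros(out_dim)
            if conn.learning is not None:
                conn.learning.attach(cs, net, self.dt)
            self.conn_states.append(cs)
            self.conn_map[id(conn)] = cs

        self.probe_data: dict[str, list] = {}
        self._probe_states = []
        for p in net.probes:
            kind, obj = self._endpoint(p.target)
            dec = None
            flt = None
            if p.attr == "decoded":
                if kind != "ensemble":
                    raise ValueError("decoded probe needs an ensemble")
                pts = sample_eval_points(rng, self.n_eval_points,
                                         obj.dimensions, obj.radius)
                A = obj.rates(pts)
                dec = solve_decoders(A, pts, default_regularization(A))
                flt = Lowpass(p.synapse_tau, self.dt, obj.dimensions)
            elif p.attr in ("output", "input"):
                flt = Lowpass(p.synapse_tau, self.dt, obj.size_out
                              if p.attr == "output" else obj.size_in) \
                    if p.synapse_tau else None
            self._probe_states.append((p, kind, obj, dec, flt))
            self.probe_data[p.label] = []

        self._node_inputs = {name: np.zeros(n.size_in)
                             for name, n in net.nodes.items() if n.size_in}
        self._node_outputs = {}
        for name, n in net.nodes.items():
            if callable(n.output):
                self._node_outputs[name] = np.zeros(n.size_out)
            else:
                self._node_outputs[name] = np.array(n.output, dtype=float)

    def _solve(self, conn: Connection, pre: Ensemble,
               rng: np.random.Generator) -> np.ndarray:
        fixed = getattr(conn, "_fixed_decoders", None)
        if fixed is not None:
            return np.asarray(fixed, dtype=float)
        pts = conn.eval_points
        if pts is None:
            pts = sample_eval_points(rng, self.n_eval_points, pre.dimensions,
                                     pre.radius, conn.sample_domain)
        A = pre.rates(pts)
        if conn.function is not None:
            Y = np.array([np.atleast_1d(conn.function(x)) for x in pts],
                         dtype=float)
        else:
            Y = pts
        lam = default_regularization(A) * conn.reg_scale
        return solve_decoders(A, Y, lam,
                              nonnegative=(conn.solver == "nnls"))

    # -- gate control -----------------------------------------------------
    def set_gate(self, name: str, value: float) -> None:
        self.net.gates[name].value = float(np.clip(value, 0.0, 1.0))

    def _gate_value(self, gate_name: Optional[str]) -> float:
        if gate_name is None:
            return 1.0
        g = self.net.gates[gate_name]
        if g.source is not None:
            v = float(np.atleast_1d(self._node_outputs[g.source])[0])
            return float(np.clip(v, 0.0, 1.0))
        return g.value

    # -- step -------------------------------------------------------------
    def step(self) -> None:
        net, dt = self.net, self.dt

        # 1. accumulate inputs from connection values (previous step)
        if not hasattr(self, "_ens_x"):
            self._ens_x = {name: np.zeros(e.dimensions)
                           for name, e in net.ensembles.items()}
            self._ens_J = {name: np.zeros(e.n_neurons)
                           for name, e in net.ensembles.items()}
        ens_x, ens_J = self._ens_x, self._ens_J
        for arr in ens_x.values():
            arr[...] = 0.0
        for arr in ens_J.values():
            arr[...] = 0.0
        for arr in self._node_inputs.values():
            arr[...] = 0.0
        for cs in self.conn_states:
            g = self._gate_value(cs.conn.gate)
            if g == 0.0:
                continue
            v = cs.value if g == 1.0 else g * cs.value
            if cs.post_kind == "neurons" or (
                    cs.weights is not None and cs.post_kind == "ensemble"):
                # full-weight or direct-current connection: inject current
                ens_J[cs.post.name] += v
            elif cs.post_kind == "ensemble":
                ens_x[cs.post.name] += v
            else:
                if cs.post.size_in:
                    self._node_inputs[cs.post.name] += v

        # 2. node outputs
        for name, node in net.nodes.items():
            if callable(node.output):
                x = self._node_inputs.get(name)
                self._node_outputs[name] = np.atleast_1d(np.asarray(
                    node.output(self.t, x) if node.size_in
                    else node.output(self.t), dtype=float))

        # 3. neuron updates
        for name, ens in net.ensembles.items():
            st = self.states[name]
            J = ens.gains * (ens.encoders @ ens_x[name]) / ens.radius \
                + ens.biases + ens_J[name]
            st["spikes"] = step_neurons(st, J, ens.neuron_params, dt)
            st["x_in"] = ens_x[name]

        # 4. connection filters / learning
        for cs in self.conn_states:
            conn = cs.conn
            if cs.pre_kind == "ensemble":
                spikes = self.states[cs.pre.name]["spikes"]
                if cs.weights is not None:
                    act = cs.filter.step(spikes / dt)
                    cs.value = cs.weights @ act
                else:
                    dec = spikes @ cs.decoders / dt
                    if conn.transform is not None:
                        dec = np.atleast_2d(conn.transform) @ dec \
                            if np.ndim(conn.transform) else conn.transform * dec
                    cs.value = cs.filter.step(dec)
            else:
                out = self._node_outputs[cs.pre.name]
                if conn.transform is not None:
                    T = conn.transform
                    out = (np.atleast_2d(T) @ out
                           if np.ndim(T) > 0 else T * out)
                cs.value = cs.filter.step(out)
            if conn.learning is not None:
                conn.learning.step(cs, self, dt)

        # 5. probes
        for (p, kind, obj, dec, flt) in self._probe_states:
            if p.attr == "spikes":
                self.probe_data[p.label].append(
                    self.states[obj.name]["spikes"].copy())
            elif p.attr == "decoded":
                val = self.states[obj.name]["spikes"] @ dec / dt
                self.probe_data[p.label].append(flt.step(val).copy())
            elif p.attr == "output":
                v = self._node_outputs[obj.name]
                self.probe_data[p.label].append(
                    (flt.step(v) if flt else v).copy())
            else:  # input
                v = self._node_inputs[obj.name]
                self.probe_data[p.label].append(
                    (flt.step(v) if flt else v).copy())

        self.t += dt

    def run(self, duration: float) -> None:
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.step()

    def data(self, probe: Union[Probe, str]) -> np.ndarray:
        label = probe.label if isinstance(probe, Probe) else probe
        rows = self.probe_data[label]
        return np.array(rows) if rows else np.empty((0,))

    def trange(self, probe: Union[Probe, str]) -> np.ndarray:
        label = probe.label if isinstance(probe, Probe) else probe
        n = len(self.probe_data[label])
        return (np.arange(n) + 1) * self.dt


def simulate(network: Network, duration: float, *,
             n_eval_points: int = 500) -> Simulator:
    """Build and run ``network`` for ``duration`` seconds; returns the sim."""
    sim = Simulator(network, n_eval_points=n_eval_points)
    sim.run(duration)
    return sim
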