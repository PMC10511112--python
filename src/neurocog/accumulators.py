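"""Drift-to-bound evidence accumulation with spiking integrators.

Each accumulator is a recurrently connected neural population trained to
approximate the identity function, so that its represented scalar integrates
its input.  Signed evidence is scaled asymmetrically — positive evidence by
``drift_pos``, negative evidence by ``drift_neg`` — and the integrator state
is compared against an upper and a lower bound.  Crossing the upper bound is
a positive decision (e.g. "familiar", "retrieved", "match"); crossing the
lower bound a negative one; reaching ``max_time`` without a crossing is a
timeout.

Drift rates are dimensionless; ``evidence_gain`` converts them to
accumulated units per second.  Bound magnitudes may differ per side, which
is how decisions from an absence of evidence (new foils, mismatches) can
terminate on a lower criterion than evidence-driven positive decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .core import Network, Simulator

__all__ = ["AccumulatorParams", "AccumulatorOutcome", "Accumulator",
           "build_accumulator", "accumulate", "attach_integrator"]


@dataclass
class AccumulatorParams:
    drift_pos: float = 1.14
    drift_neg: float = -0.10
    upper_bound: float = 1.0
    lower_bound: float = -1.0
    evidence_gain: float = 1.0
    n_neurons: int = 150
    synapse_tau: float = 0.1    # recurrent/integration synapse (s)
    readout_tau: float = 0.01

    def __post_init__(self) -> None:
        if not (self.upper_bound > 0 > self.lower_bound):
            raise ValueError("bounds must straddle 0")
        if self.drift_pos <= 0:
            raise ValueError("drift_pos must be positive")
        if self.drift_neg > 0:
            raise ValueError("drift_neg must be <= 0")


@dataclass
class AccumulatorOutcome:
    decision: str               # "positive" | "negative" | "timeout"
    crossing_time: float        # s (== max_time for timeout)
    trajectory: np.ndarray      # decoded integrator state per dt


def drift_rate(evidence: float, params: AccumulatorParams) -> float:
    """Signed accumulation rate for a momentary evidence value."""
    e = float(evidence)
    return params.evidence_gain * (params.drift_pos * max(e, 0.0)
                                   + params.drift_neg * max(-e, 0.0))


def attach_integrator(net: Network, name: str, params: AccumulatorParams,
                      evidence: Callable[[float], float]):
    """Wire a spiking integrator into ``net``.

    ``evidence`` is a callable t -> scalar; the input connection is scaled
    by the recurrent synapse time constant so the represented value
    integrates drift_rate(evidence) per second.  Returns (ensemble, probe,
    drive node, gate name): the gate zeroes the input drive, and a separate
    reset gate name can inhibit the population between trials.
    """
    radius = 1.2 * max(params.upper_bound, -params.lower_bound)
    ens = net.ensemble(name, params.n_neurons, 1, radius=radius)
    drive = net.node(f"{name}_drive",
                     lambda t: np.array([drift_rate(evidence(t), params)]),
                     size_out=1)
    net.gate(f"{name}_gate", 1.0)
    net.connect(drive, ens, transform=params.synapse_tau,
                synapse_tau=params.synapse_tau, gate=f"{name}_gate")
    rec = net.connect(ens, ens, synapse_tau=params.synapse_tau)
    # inhibitory reset: strong negative current to every neuron
    net.gate(f"{name}_reset", 0.0)
    reset = net.node(f"{name}_reset_drive",
                     np.full(params.n_neurons, -12.0))
    net.connect(reset, ens.neurons, synapse_tau=0.005,
                gate=f"{name}_reset")
    probe = net.probe(ens, "decoded", synapse_tau=params.readout_tau)
    return ens, probe, rec


class Accumulator:
    """Standalone accumulate-to-bound module with its own network."""

    def __init__(self, params: AccumulatorParams, seed: int = 0,
                 dt: float = 0.001) -> None:
        self.params = params
        self._evidence_value = 0.0
        self.net = Network(seed=seed, dt=dt)
        self.ens, self.probe, self._rec = attach_integrator(
            self.net, "acc", params, lambda t: self._evidence_value)
        self.sim = Simulator(self.net)

    def run(self, evidence, max_time: float = 3.0) -> AccumulatorOutcome:
        """Integrate ``evidence`` (callable t -> scalar, array at dt, or
        constant) until a bound crossing or ``max_time``."""
        p = self.params
        dt = self.net.dt
        if callable(evidence):
            ev = evidence
        elif np.isscalar(evidence):
            ev = lambda t: float(evidence)
        else:
            arr = np.asarray(evidence, dtype=float)
            ev = lambda t: float(arr[min(int(t / dt), arr.size - 1)])
        start = self.sim.t
        traj = []
        decision, crossing = "timeout", max_time
        n_steps = int(round(max_time / dt))
        for _ in range(n_steps):
            self._evidence_value = ev(self.sim.t - start)
            self.sim.step()
            x = float(self.sim.probe_data[self.probe.label][-1][0])
            traj.append(x)
            t_rel = self.sim.t - start
            if x >= p.upper_bound:
                decision, crossing = "positive", t_rel
                break
            if x <= p.lower_bound:
                decision, crossing = "negative", t_rel
                break
        return AccumulatorOutcome(decision, crossing, np.array(traj))

    def reset(self, duration: float = 0.15) -> None:
        """Inhibit the integrator back to zero between trials."""
        self._evidence_value = 0.0
        cs = self.sim.conn_map[id(self._rec)]
        cs.filter.state[...] = 0.0
        cs.value = np.zeros_like(np.atleast_1d(cs.value))
        self.sim.set_gate("acc_gate", 0.0)
        self.sim.set_gate("acc_reset", 1.0)
        for _ in range(int(round(duration / self.net.dt))):
            self.sim.step()
        self.sim.set_gate("acc_reset", 0.0)
        self.sim.set_gate("acc_gate", 1.0)


def build_accumulator(params: AccumulatorParams, seed: int = 0,
                      dt: float = 0.001) -> Accumulator:
    """Spiking integrator population with bound detectors."""
    return Accumulator(params, seed=seed, dt=dt)


def accumulate(evidence, params: AccumulatorParams, max_time: float = 3.0,
               seed: int = 0, dt: float = 0.001) -> AccumulatorOutcome:
    """One-shot accumulation of an evidence stream (see Accumulator.run)."""
    return Accumulator(params, seed=seed, dt=dt).run(evidence, max_time)
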