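"""Synaptic plasticity rules: PES, Voja± and BCM.

Three rules drive the memory system:

* **PES** (prescribed error sensitivity) — locally supervised decoder
  learning: ``delta d_i = kappa * r * a_i`` with error vector ``r`` and
  filtered presynaptic activity ``a_i``.
* **Voja±** — unsupervised encoder adaptation with an activity threshold
  ``sigma``: encoders of neurons firing above threshold are attracted to the
  current input vector, encoders of neurons below it are repelled, and the
  effect strengthens as the activity approaches the threshold (ratio form
  ``eta * a * (x - e) / (a - sigma)``, clamped per step).  Because more
  neurons end up repelled than attracted, frequently seen inputs come to
  drive *less* total activity — the mechanism behind the fan-2 < fan-1
  response paradox.
* **BCM** — unsupervised Hebbian learning on a recurrent weight matrix with a
  sliding modification threshold and a hard weight limit:
  ``delta w_ij = kappa * a_i * a_j * (a_j - theta_j)``.

Activities in all rules are synapse-filtered rates, not raw spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PesState", "VojaPmState", "BcmState",
    "pes_update", "voja_pm_update", "bcm_update",
    "PES", "VojaPM", "BCM",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PesState:
    kappa: float = 1e-4

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class VojaPmState:
    eta: float = 1e-4
    sigma: float = 100.0        # activity threshold, filtered-rate units (Hz)
    max_step: float = 0.01      # per-update magnitude clamp on |delta e|
    form: str = "ratio"         # "ratio" (default) or "product"

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.form not in ("ratio", "product"):
            raise ValueError(f"unknown Voja± form {self.form!r}")


@dataclass
class BcmState:
    kappa: float = 1e-9
    theta_tau: float = 1.0      # sliding-threshold filter time constant (s)
    w_limit: float = 1e-3       # absolute weight cap
    theta_ref: float = 100.0    # reference rate (Hz) normalizing theta's
    #                             low-passed a^2 back onto the rate scale

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.w_limit <= 0:
            raise ValueError("w_limit must be positive")


# ---------------------------------------------------------------------------
# Pure update functions (unit-time deltas scaled by dt)
# ---------------------------------------------------------------------------

def pes_update(d: np.ndarray, a: np.ndarray, r: np.ndarray,
               kappa: float, dt: float) -> np.ndarray:
    """delta d_i = kappa * r * a_i, scaled by dt.

    ``d`` is (n_neurons, d_out), ``a`` (n_neurons,) filtered pre activity,
    ``r`` (d_out,) the error vector (desired minus actual).
    """
    a = np.asarray(a, dtype=float)
    r = np.asarray(r, dtype=float)
    return kappa * dt * a[:, None] * r[None, :]


def voja_pm_update(e: np.ndarray, x: np.ndarray, a: np.ndarray,
                   state: VojaPmState, dt: float) -> np.ndarray:
    """Signed encoder update along (x - e): attraction for a > sigma,
    repulsion for 0 < a < sigma, nothing for silent neurons.

    Ratio form: eta * a * (x - e) / (a - sigma); the magnitude is clamped to
    ``max_step`` per update, which also defines the behaviour at a == sigma.
    Product form: eta * a * (x - e) * (a - sigma).  Returns delta e (the
    caller renormalizes encoders to unit length after applying it).
    """
    e = np.asarray(e, dtype=float)
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("activities must be non-negative")
    delta = np.zeros_like(e)
    act = a > 0.0
    if not np.any(act):
        return delta
    # silent neurons never move; restrict the update to the active subset
    aa = a[act]
    diff = x[None, :] - e[act]
    if state.form == "ratio":
        denom = aa - state.sigma
        # clamp the 1/(a - sigma) divergence; a == sigma caps at max_step
        with np.errstate(divide="ignore", invalid="ignore"):
            coeff = np.where(denom == 0.0, np.inf, aa / denom)
        coeff = coeff * state.eta * dt
    else:
        coeff = state.eta * dt * aa * (aa - state.sigma)
    d_act = coeff[:, None] * diff
    # per-neuron magnitude clamp (also handles the a == sigma divergence)
    mag2 = np.einsum("ij,ij->i", d_act, d_act)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        mag = np.sqrt(mag2)
        scale = np.where(mag > state.max_step, state.max_step / mag, 1.0)
    finite = np.isfinite(mag)
    scale = np.where(finite, scale, 0.0)
    with np.errstate(invalid="ignore"):
        d_act = d_act * scale[:, None]
    d_act[~finite] = 0.0
    if not np.all(finite):
        rows = ~finite
        dn = np.linalg.norm(diff[rows], axis=1, keepdims=True)
        dn[dn == 0] = 1.0
        d_act[rows] = state.max_step * diff[rows] / dn
    delta[act] = d_act
    return delta


def bcm_update(w: np.ndarray, a_pre: np.ndarray, a_post: np.ndarray,
               theta: np.ndarray, state: BcmState, dt: float) -> np.ndarray:
    """delta w_ij = kappa * a_i * a_j * (a_j - theta_j), scaled by dt.

    ``w`` is (n_post, n_pre) with post index j on rows; returns the delta
    (the caller applies the +/- w_limit clamp).
    """
    a_pre = np.asarray(a_pre, dtype=float)
    a_post = np.asarray(a_post, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return kappa_outer(state.kappa * dt, a_post * (a_post - theta), a_pre)


def kappa_outer(k: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return k * np.outer(u, v)


def pes_train_rate_mode(ensemble, x: np.ndarray, target: np.ndarray,
                        kappa: float = 1e-4, dt: float = 1e-3,
                        duration: float = 1.0,
                        decoders: Optional[np.ndarray] = None):
    """Noiseless rate-mode PES: iterate the decoder update against analytic
    tuning-curve activities for a fixed input/target pair.

    Returns (decoders, error_norm_trajectory).  Useful as a convergence
    oracle: without spike noise or synaptic lag the error norm decreases
    monotonically whenever kappa * ||a||^2 * dt < 2.
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    a = ensemble.rates(x)
    d = (np.zeros((ensemble.n_neurons, target.size))
         if decoders is None else np.array(decoders, dtype=float))
    errs = []
    for _ in range(int(round(duration / dt))):
        y = a @ d
        r = target - y
        errs.append(float(np.linalg.norm(r)))
        d += pes_update(d, a, r, kappa, dt)
    return d, np.array(errs)


# ---------------------------------------------------------------------------
# Simulator attachments
# ---------------------------------------------------------------------------

class _Attachment:
    """Base class hooking a rule into a Connection inside the Simulator."""

    enabled: bool = True

    def attach(self, conn_state, net, dt) -> None:  # pragma: no cover
        pass

    def step(self, conn_state, sim, dt) -> None:  # pragma: no cover
        pass


class PES(_Attachment):
    """Decoder learning on a factored connection.

    ``error`` is a callable ``() -> vector`` or a Node whose current output
    is read each step (desired minus actual, in the decoded space).
    """

    def __init__(self, error, kappa: float = 1e-4, period: int = 1) -> None:
        self.params = PesState(kappa)
        self.error = error
        self.period = int(period)
        self._count = 0

    def attach(self, conn_state, net, dt) -> None:
        if conn_state.decoders is None:
            raise ValueError("PES needs a factored (decoded) connection")
        self._act = None

    def step(self, conn_state, sim, dt) -> None:
        if not self.enabled:
            return
        spikes = sim.states[conn_state.pre.name]["spikes"]
        if self._act is None:
            self._act = np.zeros_like(spikes)
        a = np.exp(-dt / 0.005)
        self._act = a * self._act + (1 - a) * spikes / dt
        self._count += 1
        if self._count % self.period:
            return
        if callable(self.error):
            r = np.asarray(self.error(), dtype=float)
        else:
            r = np.asarray(sim._node_outputs[self.error.name], dtype=float)
        conn_state.decoders += pes_update(
            conn_state.decoders, self._act, r,
            self.params.kappa, dt * self.period)


class VojaPM(_Attachment):
    """Encoder learning on the post ensemble of an input connection.

    The input vector ``x`` is the filtered decoded value carried by the
    connection; activities are the post population's filtered rates.
    Encoders are renormalized to unit length after every update.
    """

    def __init__(self, eta: float = 1e-4, sigma: float = 100.0,
                 max_step: float = 0.01, form: str = "ratio",
                 period: int = 1) -> None:
        self.params = VojaPmState(eta, sigma, max_step, form)
        self.period = int(period)
        self._count = 0

    def attach(self, conn_state, net, dt) -> None:
        if conn_state.post_kind != "ensemble":
            raise ValueError("Voja± needs an ensemble post")
        self._act = None

    def step(self, conn_state, sim, dt) -> None:
        if not self.enabled:
            return
        post = conn_state.post
        spikes = sim.states[post.name]["spikes"]
        if self._act is None:
            self._act = np.zeros_like(spikes)
        a = np.exp(-dt / 0.005)
        self._act = a * self._act + (1 - a) * spikes / dt
        self._count += 1
        if self._count % self.period:
            return
        x = conn_state.value  # filtered decoded input on this connection
        delta = voja_pm_update(post.encoders, x, self._act, self.params,
                               dt * self.period)
        post.encoders += delta
        norms = np.linalg.norm(post.encoders, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        post.encoders /= norms


class BCM(_Attachment):
    """Weight learning on a full-weight (recurrent) connection."""

    def __init__(self, kappa: float = 1e-9, theta_tau: float = 1.0,
                 w_limit: float = 1e-3, period: int = 1,
                 theta_ref: float = 100.0) -> None:
        self.params = BcmState(kappa, theta_tau, w_limit, theta_ref)
        self.period = int(period)
        self._count = 0

    def attach(self, conn_state, net, dt) -> None:
        if conn_state.weights is None:
            raise ValueError("BCM needs a full-weight connection")
        self._theta = np.zeros(conn_state.weights.shape[0])
        self._act_pre = None
        self._act_post = None

    def step(self, conn_state, sim, dt) -> None:
        if not self.enabled:
            return
        pre_spk = sim.states[conn_state.pre.name]["spikes"]
        post_spk = sim.states[conn_state.post.name]["spikes"]
        if self._act_pre is None:
            self._act_pre = np.zeros_like(pre_spk)
            self._act_post = np.zeros_like(post_spk)
        a = np.exp(-dt / 0.005)
        self._act_pre = a * self._act_pre + (1 - a) * pre_spk / dt
        self._act_post = a * self._act_post + (1 - a) * post_spk / dt
        self._count += 1
        if self._count % self.period:
            return
        # sliding threshold tracks a_post^2, normalized to the rate scale
        b = np.exp(-dt * self.period / self.params.theta_tau)
        self._theta = (b * self._theta
                       + (1 - b) * self._act_post ** 2 / self.params.theta_ref)
        conn_state.weights += bcm_update(
            conn_state.weights, self._act_pre, self._act_post,
            self._theta, self.params, dt * self.period)
        np.clip(conn_state.weights, -self.params.w_limit,
                self.params.w_limit, out=conn_state.weights)

    @property
    def theta(self) -> np.ndarray:
        return self._theta
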