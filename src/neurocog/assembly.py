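"""Full-model assembly: visual system, memories, comparison, motor, control.

Wires the seven-module architecture into one spiking network and runs
trials end to end.  A trial proceeds through five stages, sequenced by the
basal-ganglia / thalamus pulse controller:

1. **encode** — the two word images are attended in turn, parsed by a
   Gabor-tuned adaptive-LIF population, mapped to word pointers, and bound
   into the pair ITEM1 (*) word1 + ITEM2 (*) word2 held in the visual
   buffer.
2. **familiarity** — the word concepts drive the familiarity memory; a
   spiking population represents the input/output similarity, thresholded
   into signed evidence for a drift accumulator.  Crossing the lower bound
   short-circuits to a "no" response (new foils); the upper bound opens the
   retrieval stage.
3. **retrieve** — the declarative memory completes the probe pair; the
   norm of its output (clarity) drives the retrieval accumulator; when the
   retrieved representation is clear enough, it has been loaded into the
   prefrontal representation buffer.
4. **compare** — both buffers are unbound word-by-word (circular
   convolution with the fixed role inverses is linear, hence a connection
   transform), cleaned up over the studied vocabulary, and compared;
   matches accumulate positive evidence at a higher rate than mismatches
   accumulate negative evidence.
5. **respond** — the decision routes to the block's response hand: index
   finger for "yes", middle finger for "no"; both fingers are slightly
   pre-activated during the decision, and the simulated key press occurs
   when the selected finger population crosses its press threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Network, Simulator, NeuronParams, merge_weights
from .spa import Vocabulary, circular_convolution, circulant_matrix, \
    approx_inverse, SpikingCleanup
from .accumulators import AccumulatorParams, drift_rate
from .bg import ActionRule, Effect, TaskGraph
from .design import Trial, WordPair, render_word_image, \
    IMAGE_WIDTH, IMAGE_HEIGHT
from .memory import MemoryScaleConfig

__all__ = ["ModelConfig", "TrialRecord", "AssembledModel", "assemble_model",
           "gabor_encoders", "run_participant"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Scale and parameter configuration for the assembled model.

    The ``full`` preset is the full-fidelity model (512-D pointers,
    384-D visual representation, 2,000 adaptive-LIF parser neurons, 30k
    main memory populations with 50 neurons per output dimension); the
    ``desk`` preset keeps the same architecture at sizes one CPU handles.
    Accumulator drift rates default to the mean fitted values.
    """

    scale: str = "desk"
    vocab_dim: int = 64
    ctrl_dim: int = 32
    visual_rep_dim: int = 96
    parser_n: int = 300
    buffer_per_dim: int = 8
    finger_n: int = 50
    memory: MemoryScaleConfig = field(default_factory=MemoryScaleConfig)
    fam_acc: AccumulatorParams = field(default_factory=lambda:
        AccumulatorParams(drift_pos=1.14, drift_neg=-0.10,
                          upper_bound=0.25, lower_bound=-0.06))
    retr_acc: AccumulatorParams = field(default_factory=lambda:
        AccumulatorParams(drift_pos=0.0057, drift_neg=-0.0001,
                          upper_bound=0.6, lower_bound=-1.0,
                          evidence_gain=1000.0))
    cmp_acc: AccumulatorParams = field(default_factory=lambda:
        AccumulatorParams(drift_pos=2.5, drift_neg=-0.11,
                          upper_bound=0.89, lower_bound=-0.25,
                          evidence_gain=2.5))
    familiarity_threshold: float = 0.5
    retrieval_floor: float = 0.40   # clarity below this drives no evidence
    cleanup_threshold: float = 0.25
    match_threshold: float = 0.55
    gating_mode: str = "pulse"      # or "continuous"
    pulse_duration: float = 0.05
    attend_duration: float = 0.15   # per-word visual attention window (s)
    motor_latency: float = 0.06     # press transduction latency (s)
    press_threshold: float = 0.7
    preactivation: float = 0.3      # finger pre-activation during decision
    watchdog: float = 3.5
    reset_duration: float = 0.2     # inter-trial inhibitory reset (s)
    dt: float = 0.001
    seed: int = 0

    @classmethod
    def full(cls) -> "ModelConfig":
        return cls(scale="full", vocab_dim=512, ctrl_dim=64,
                   visual_rep_dim=384, parser_n=2000, buffer_per_dim=50,
                   memory=MemoryScaleConfig.full())

    def validate(self) -> None:
        if self.vocab_dim < 1:
            raise ValueError("vocab_dim must be positive")
        if self.scale == "full":
            expected = dict(vocab_dim=512, visual_rep_dim=384, parser_n=2000)
            for key, val in expected.items():
                if getattr(self, key) != val:
                    raise ValueError(f"full scale requires {key}={val}")


@dataclass
class TrialRecord:
    trial: Trial
    response: str               # "yes" | "no" | "none"
    rt: float                   # ms from probe onset to key press
    correct: bool
    stage_times: dict           # stage -> s from probe onset
    finger: Optional[str] = None

    @property
    def timed_out(self) -> bool:
        return self.response == "none"


# ---------------------------------------------------------------------------
# Visual front end
# ---------------------------------------------------------------------------

def gabor_encoders(n: int, rng: np.random.Generator,
                   width: int = IMAGE_WIDTH, height: int = IMAGE_HEIGHT,
                   patch: int = 9) -> np.ndarray:
    """Random 9x9 Gabor patches embedded at random image positions,
    flattened and unit-normalized: the parser's preferred stimuli."""
    enc = np.zeros((n, width * height))
    yy, xx = np.mgrid[0:patch, 0:patch] - (patch - 1) / 2.0
    for i in range(n):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(0.1, 0.35)       # cycles per pixel
        phase = rng.uniform(0, 2 * np.pi)
        sigma = rng.uniform(1.5, 3.0)
        xr = xx * np.cos(theta) + yy * np.sin(theta)
        g = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2)) \
            * np.cos(2 * np.pi * freq * xr + phase)
        x0 = rng.integers(0, width - patch + 1)
        y0 = rng.integers(0, height - patch + 1)
        canvas = np.zeros((height, width))
        canvas[y0:y0 + patch, x0:x0 + patch] = g
        flat = canvas.ravel()
        enc[i] = flat / np.linalg.norm(flat)
    return enc


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------

class AssembledModel:
    """The runnable network plus its trial-execution machinery."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary,
                 ctrl_vocab: Vocabulary,
                 familiarity_state: dict, declarative_state: dict,
                 word_list: Sequence[str], studied_words: Sequence[str],
                 ) -> None:
        config.validate()
        for need, state, kind in (("familiarity", familiarity_state,
                                   "familiarity"),
                                  ("declarative", declarative_state,
                                   "declarative")):
            if state is None:
                raise ValueError(f"missing trained {need} memory")
            if state.get("kind") != kind:
                raise ValueError(f"{need} state has kind {state.get('kind')!r}")
        self.config = config
        self.vocab = vocab
        self.ctrl_vocab = ctrl_vocab
        self._fam_state = familiarity_state
        self._dec_state = declarative_state
        self.word_list = list(word_list)
        self.studied_words = list(studied_words)
        self._trial_state: dict = {}
        self.events: list = []
        d = vocab.dimensions

        net = Network(seed=config.seed, dt=config.dt)
        self.net = net

        # ---------------- visual system ----------------
        self._image = np.zeros(IMAGE_WIDTH * IMAGE_HEIGHT)
        self.stim = net.node("stimulus", lambda t: self._image,
                             size_out=IMAGE_WIDTH * IMAGE_HEIGHT)
        enc = gabor_encoders(config.parser_n, net.rng)
        adaptive = NeuronParams(model_kind="adaptive_lif",
                                adaptation_tau=0.1,
                                adaptation_increment=0.22)
        self.parser = net.ensemble(
            "visual", config.parser_n, IMAGE_WIDTH * IMAGE_HEIGHT,
            encoders=enc, intercepts=net.rng.uniform(0.05, 0.5,
                                                     config.parser_n),
            max_rates=net.rng.uniform(100, 200, config.parser_n),
            neuron_params=adaptive, radius=2.0)
        net.connect(self.stim, self.parser, synapse_tau=0.005)
        # weak recurrence: total-activity feedback producing the long tail
        self._parser_fb = net.node("visual_fb", lambda t, x: x,
                                   size_in=1, size_out=1)
        cfb = net.connect(self.parser, self._parser_fb,
                          function=lambda x: np.array([x.sum()]),
                          synapse_tau=0.05)
        net.connect(self._parser_fb, self.parser.neurons,
                    transform=np.full((config.parser_n, 1), 0.002),
                    synapse_tau=0.05)

        # visual representation: random projection of pixel space, decoded
        # from parser activity.  The decoders are solved on the actual word
        # images (a trained read-out of the visual hierarchy), not on
        # arbitrary pixel vectors — the parser only ever sees words.
        proj_rng = np.random.default_rng(config.seed + 101)
        P = proj_rng.standard_normal(
            (config.visual_rep_dim, IMAGE_WIDTH * IMAGE_HEIGHT))
        P /= np.linalg.norm(P, axis=1, keepdims=True)
        self._P = P
        images = np.array([render_word_image(w).ravel()
                           for w in self.word_list])
        protos = images @ P.T
        protos /= np.linalg.norm(protos, axis=1, keepdims=True) + 1e-12
        self._protos = protos
        self.rep_node = net.node("visual_rep", lambda t, x: x,
                                 size_in=config.visual_rep_dim,
                                 size_out=config.visual_rep_dim)
        from .core import solve_decoders, default_regularization
        A_img = self.parser.rates(
            np.vstack([images, np.zeros((1, images.shape[1]))]))
        Y_img = np.vstack([protos, np.zeros((1, protos.shape[1]))])
        rep_conn = net.connect(self.parser, self.rep_node,
                               synapse_tau=0.005)
        rep_conn._fixed_decoders = solve_decoders(
            A_img, Y_img, default_regularization(A_img))
        self._pointers = np.array([vocab[w].v for w in self.word_list])
        self.concept = net.node("concept", self._concept_fn,
                                size_in=config.visual_rep_dim, size_out=d)
        net.connect(self.rep_node, self.concept, synapse_tau=0.005)

        # binding: latch the two attended word concepts into the pair
        self._latch = [None, None]
        self._enc_start: Optional[float] = None
        self.pair_node = net.node("pair_in", lambda t: self._pair_value(t),
                                  size_out=d)
        self.words_node = net.node("words_in",
                                   lambda t: self._words_value(t),
                                   size_out=d)

        # ---------------- visual buffer ----------------
        # Buffers only ever hold role-bound pair vectors, so identity
        # decoders are solved on that manifold (random word pairs at
        # varied clarity), not on arbitrary vectors — identity decoding of
        # a 64-D ball from a few hundred neurons would otherwise shrink
        # the feedback gain well below 1 and the buffers would leak.
        man_rng = np.random.default_rng(config.seed + 303)
        n_man = 260
        wa = man_rng.integers(0, len(self.word_list), n_man)
        wb = man_rng.integers(0, len(self.word_list), n_man)
        scales = man_rng.uniform(0.3, 1.1, n_man)[:, None]
        I1v, I2v = vocab["ITEM1"].v, vocab["ITEM2"].v
        self._pair_manifold = scales * np.array([
            circular_convolution(I1v, self._pointers[a])
            + circular_convolution(I2v, self._pointers[b])
            for a, b in zip(wa, wb)])
        nbuf = config.buffer_per_dim * d
        self.visual_buffer = net.ensemble("visual_buffer", nbuf, d,
                                          radius=1.6)
        net.gate("g_vis_load", 0.0)
        # difference-gated loading: drive toward the target pair rather
        # than adding to the held state, so the buffer converges to the
        # pair instead of integrating it into saturation
        self._vis_read_val = np.zeros(d)
        vis_read = net.node("vis_read", self._store("_vis_read_val"),
                            size_in=d, size_out=d)
        self._vis_read_conn = net.connect(
            self.visual_buffer, vis_read, synapse_tau=0.01,
            eval_points=self._pair_manifold, reg_scale=0.01)
        vis_drive = net.node(
            "vis_drive",
            lambda t: 1.5 * (self._pair_value(t) - self._vis_read_val),
            size_out=d)
        net.connect(vis_drive, self.visual_buffer, synapse_tau=0.005,
                    gate="g_vis_load")
        # near-unity effective feedback: identity decoders on the pair
        # manifold with light regularization, times a small latch margin
        self._vb_rec = net.connect(self.visual_buffer, self.visual_buffer,
                    synapse_tau=0.1, transform=1.0, reg_scale=0.01,
                    eval_points=self._pair_manifold)
        self._add_reset(self.visual_buffer, "r_visbuf")

        # ---------------- memories (trained, cloned in) ----------------
        self.fam_main, self.fam_out, self._fam_conns = self._clone_memory(
            "familiarity", familiarity_state)
        self.dec_main, self.dec_out, self._dec_conns = self._clone_memory(
            "declarative", declarative_state)

        # familiarity input: the word concepts (structural + gated boost)
        net.gate("g_fam", 0.0)
        net.connect(self.words_node, self.fam_main, transform=0.2,
                    synapse_tau=0.005)
        net.connect(self.words_node, self.fam_main, transform=0.8,
                    synapse_tau=0.005, gate="g_fam")
        # declarative input: the encoded pair from the visual buffer
        net.gate("g_mem", 0.0)
        net.connect(self.visual_buffer, self.dec_main, transform=0.2,
                    synapse_tau=0.005, eval_points=self._pair_manifold,
                    reg_scale=0.1)
        net.connect(self.visual_buffer, self.dec_main, transform=0.8,
                    synapse_tau=0.005, gate="g_mem",
                    eval_points=self._pair_manifold, reg_scale=0.1)

        # familiarity index: spiking population representing input/output
        # similarity of the familiarity memory
        self._fam_in_val = np.zeros(d)
        self._fam_out_val = np.zeros(d)
        fam_in_read = net.node("fam_in_read", self._store("_fam_in_val"),
                               size_in=d, size_out=d)
        fam_out_read = net.node("fam_out_read", self._store("_fam_out_val"),
                                size_in=d, size_out=d)
        net.connect(self.words_node, fam_in_read, synapse_tau=0.01)
        net.connect(self.fam_out, fam_out_read, synapse_tau=0.01)
        self.fam_index_drive = net.node(
            "fam_index_drive",
            lambda t: np.array([np.dot(self._fam_in_val,
                                       self._fam_out_val)]),
            size_out=1)
        self.fam_index = net.ensemble("fam_index", 60, 1, radius=1.5)
        net.connect(self.fam_index_drive, self.fam_index, synapse_tau=0.005)
        self.fam_index_read = net.node("fam_index_read",
                                       self._store_scalar("_fam_index"),
                                       size_in=1, size_out=1)
        self._fam_index = 0.0
        net.connect(self.fam_index, self.fam_index_read, synapse_tau=0.01)

        # ---------------- representation buffer ----------------
        self.representation = net.ensemble("representation", nbuf, d,
                                           radius=1.6)
        self._rep_read_val = np.zeros(d)
        rep_read = net.node("rep_read", self._store("_rep_read_val"),
                            size_in=d, size_out=d)
        self._rep_read_conn = net.connect(
            self.representation, rep_read, synapse_tau=0.01,
            eval_points=self._pair_manifold, reg_scale=0.01)
        def _rep_target():
            # re-express the retrieved content at working strength, but
            # only once the retrieval accumulator confirms there is real
            # clarity evidence — otherwise the structural pathway's
            # residual would be amplified into a spurious "retrieval"
            if getattr(self, "_acc_retr_val", 0.0) \
                    < 0.1 * self.config.retr_acc.upper_bound:
                return np.zeros(d)
            v = np.asarray(self._dec_out_val)
            nv = float(np.linalg.norm(v))
            if nv < 0.2:
                return np.zeros(d)
            return v * min(1.15 / nv, 2.0)

        rep_drive = net.node(
            "rep_drive",
            lambda t: 1.5 * (_rep_target() - self._rep_read_val),
            size_out=d)
        net.connect(rep_drive, self.representation, synapse_tau=0.005,
                    gate="g_mem")
        net.connect(self.dec_out, self.representation, transform=0.1,
                    synapse_tau=0.01)
        # mildly supralinear recurrence: the representation should latch
        # and clean the retrieved pair rather than passively hold it
        self._rep_rec = net.connect(self.representation, self.representation,
                    synapse_tau=0.1, transform=1.0, reg_scale=0.01,
                    eval_points=self._pair_manifold)
        self._add_reset(self.representation, "r_rep")
        self._dec_out_val = np.zeros(d)
        dec_read = net.node("dec_out_read", self._store("_dec_out_val"),
                            size_in=d, size_out=d)
        net.connect(self.dec_out, dec_read, synapse_tau=0.01)

        # ---------------- accumulators ----------------
        self.fam_acc = self._add_accumulator("acc_fam", config.fam_acc,
                                             self._fam_evidence)
        self.retr_acc = self._add_accumulator("acc_retr", config.retr_acc,
                                              self._retr_evidence)
        self.cmp_acc = self._add_accumulator("acc_cmp", config.cmp_acc,
                                             self._cmp_evidence)

        # ---------------- comparison ----------------
        inv1 = circulant_matrix(approx_inverse(vocab["ITEM1"].v))
        inv2 = circulant_matrix(approx_inverse(vocab["ITEM2"].v))
        self.cleanups = {}
        for src_name, src, inv, slot in (
                ("vis", self.visual_buffer, inv1, "w1"),
                ("vis", self.visual_buffer, inv2, "w2"),
                ("rep", self.representation, inv1, "w1"),
                ("rep", self.representation, inv2, "w2")):
            cname = f"cleanup_{src_name}_{slot}"
            cl = SpikingCleanup(cname, vocab, self.studied_words, net,
                                neurons_per_item=12,
                                threshold=config.cleanup_threshold)
            net.connect(src, cl.ensemble, transform=inv, synapse_tau=0.01,
                        eval_points=self._pair_manifold, reg_scale=0.1)
            setattr(self, f"_{cname}_val", np.zeros(d))
            read = net.node(f"{cname}_read",
                            self._store(f"_{cname}_val"),
                            size_in=d, size_out=d)
            cl.output_connection(net, read, synapse_tau=0.01)
            self.cleanups[(src_name, slot)] = cl

        # ---------------- motor ----------------
        self.fingers = {}
        for hand in ("left", "right"):
            for finger in ("index", "middle"):
                name = f"{hand}_{finger}"
                ens = net.ensemble(f"finger_{name}", config.finger_n, 1)
                self.fingers[name] = ens
                setattr(self, f"_press_{name}", 0.0)
                read = net.node(f"finger_{name}_read",
                                self._store_scalar(f"_press_{name}"),
                                size_in=1, size_out=1)
                net.connect(ens, read, synapse_tau=0.02)
        self.motor_drive = net.node("motor_drive", lambda t:
                                    self._motor_value(t), size_out=4)
        order = ["left_index", "left_middle", "right_index", "right_middle"]
        self._finger_order = order
        for i, name in enumerate(order):
            tr = np.zeros((1, 4))
            tr[0, i] = 1.0
            net.connect(self.motor_drive, self.fingers[name], transform=tr,
                        synapse_tau=0.01)

        # ---------------- control ----------------
        ctrl_vocab.make_orthogonal(
            [s for s in ("start", "encode", "familiar", "retrieve",
                         "compare", "respond_yes", "respond_no", "done")
             if s not in ctrl_vocab])
        self.rules = self._build_rules()
        self.tg = TaskGraph(self.rules, ctrl_vocab, net=net,
                            gating_mode=config.gating_mode,
                            watchdog=config.watchdog)
        self.sim = self.tg.sim

        # recorders for the forward models
        self._record_pops = ["visual", "familiarity_main", "declarative_main",
                             "representation", "visual_buffer"] + \
            [f"finger_{n}" for n in order]
        self.activity_log = {p: [] for p in self._record_pops}
        self.usage_coeffs = self._usage_coefficients()
        self._usage_filters = {m: {} for m in self.usage_coeffs}
        self.usage_log = {m: [] for m in self.usage_coeffs}

    # -- helpers ----------------------------------------------------------
    def _store(self, attr):
        def f(t, x, _attr=attr, _self=self):
            setattr(_self, _attr, np.array(x))
            return x
        return f

    def _store_scalar(self, attr):
        def f(t, x, _attr=attr, _self=self):
            setattr(_self, _attr, float(x[0]))
            return x
        return f

    def _add_reset(self, ens, gate_name, strength=-12.0):
        self.net.gate(gate_name, 0.0)
        node = self.net.node(f"{gate_name}_drive",
                             np.full(ens.n_neurons, strength))
        self.net.connect(node, ens.neurons, synapse_tau=0.003,
                         gate=gate_name)

    def _clone_memory(self, prefix: str, state: dict):
        net = self.net
        n = state["encoders"].shape[0]
        d = self.vocab.dimensions
        main = net.ensemble(f"{prefix}_main", n, d,
                            encoders=state["encoders"],
                            intercepts=state["intercepts"],
                            max_rates=state["max_rates"],
                            radius=state["radius"])
        main.gains = state["gains"].copy()
        main.biases = state["biases"].copy()
        nout = self.config.memory.output_per_dim * d
        out = net.ensemble(f"{prefix}_output", nout, d,
                           radius=state["radius"])
        conn = net.connect(main, out, synapse_tau=0.005)
        conn._fixed_decoders = state["decoders"]
        conns = [conn]
        if "recurrent_weights" in state:
            conns.append(net.connect(main, main.neurons,
                                     weights=state["recurrent_weights"],
                                     synapse_tau=0.005))
        self._add_reset(main, f"r_{prefix}")
        return main, out, conns

    def _add_accumulator(self, name, params, evidence_fn):
        net = self.net
        radius = 1.2 * max(params.upper_bound, -params.lower_bound)
        ens = net.ensemble(name, 120, 1, radius=radius)
        drive = net.node(f"{name}_drive",
                         lambda t: np.array([drift_rate(evidence_fn(),
                                                        params)]),
                         size_out=1)
        net.gate(f"g_{name}", 0.0)
        net.connect(drive, ens, transform=params.synapse_tau,
                    synapse_tau=params.synapse_tau, gate=f"g_{name}")
        rec = net.connect(ens, ens, synapse_tau=params.synapse_tau)
        self._acc_recs = getattr(self, "_acc_recs", []) + [rec]
        self._add_reset(ens, f"r_{name}", strength=-5.0)
        setattr(self, f"_{name}_val", 0.0)
        read = net.node(f"{name}_read", self._store_scalar(f"_{name}_val"),
                        size_in=1, size_out=1)
        net.connect(ens, read, synapse_tau=0.01)
        return ens

    # -- node callbacks ---------------------------------------------------
    def _concept_fn(self, t, x):
        v = np.asarray(x)
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            return np.zeros(self.vocab.dimensions)
        sims = self._protos @ (v / nv)
        k = int(np.argmax(sims))
        if sims[k] < 0.4:
            return np.zeros(self.vocab.dimensions)
        return self._pointers[k] * min(1.0, float(sims[k]) / 0.8)

    def _pair_value(self, t):
        v = self.vocab
        out = np.zeros(self.vocab.dimensions)
        if self._latch[0] is not None:
            out = out + circular_convolution(v["ITEM1"].v, self._latch[0])
        if self._latch[1] is not None:
            out = out + circular_convolution(v["ITEM2"].v, self._latch[1])
        return out

    def _words_value(self, t):
        # attend the two word concepts in turn: the sparse memory responds
        # to single trained words, not to their mixture direction
        w1, w2 = self._latch
        if w1 is None and w2 is None:
            return np.zeros(self.vocab.dimensions)
        if w2 is None:
            return np.asarray(w1)
        k = int(t / 0.15) % 2
        return np.asarray(w1 if k == 0 else w2)

    def _fam_evidence(self):
        if not self._trial_state.get("fam_on", False):
            return 0.0
        return 1.0 if self._fam_index > self.config.familiarity_threshold \
            else -1.0

    def _retr_evidence(self):
        if not self._trial_state.get("retr_on", False):
            return 0.0
        clarity = float(np.linalg.norm(self._dec_out_val))
        return max(clarity - self.config.retrieval_floor, 0.0)

    def _cmp_evidence(self):
        """Word-by-word match signal.

        +1 when both cleaned word slots agree between the encoded and the
        retrieved pair; -1 when any slot disagrees — including when a word
        was encoded but nothing was retrieved to match it (the
        recall-to-reject signal); 0 only when there is nothing to compare.
        """
        if not self._trial_state.get("cmp_on", False):
            return 0.0
        thr = self.config.match_threshold
        m = []
        for slot in ("w1", "w2"):
            a = getattr(self, f"_cleanup_vis_{slot}_val")
            b = getattr(self, f"_cleanup_rep_{slot}_val")
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na < 0.2 and nb < 0.2:
                m.append(None)
            elif na >= 0.2 and nb >= 0.2:
                m.append(float(np.dot(a, b) / (na * nb)))
            else:
                m.append(-1.0)  # one side present, the other missing
        present = [x for x in m if x is not None]
        if not present:
            return 0.0
        if len(present) == 2 and min(present) > thr:
            return 1.0
        if any(x <= thr for x in present):
            return -1.0
        return 0.0

    def _motor_value(self, t):
        ts = self._trial_state
        out = np.zeros(4)
        hand = ts.get("hand")
        if hand is None:
            return out
        idx = {"left": (0, 1), "right": (2, 3)}[hand]
        stage = self.tg._current_state_name
        if stage == "compare":
            out[idx[0]] = out[idx[1]] = self.config.preactivation
        elif stage == "respond_yes":
            out[idx[0]] = 1.0
        elif stage == "respond_no":
            out[idx[1]] = 1.0
        return out

    # -- action rules -----------------------------------------------------
    def _build_rules(self):
        """Two gating regimes for the same task graph.

        Pulse mode: each transition rule fires briefly; its effects toggle
        the stage's gates, which then *stay* switched (sustained adjusted
        connectivity after a brief thalamic pulse) until the next
        transition closes them.  No channel stays disinhibited during a
        stage, so integrated thalamic output is small.

        Continuous mode (the default-framework behaviour, for A/B
        comparison): transition rules only switch the control state; a
        maintainer rule per long stage stays selected throughout and holds
        the stage's gates open through sustained thalamic output.
        """
        pulse = self.config.gating_mode == "pulse"

        def stage_effects(opens, closes):
            if not pulse:
                return []
            return ([Effect("open_gate", g) for g in opens]
                    + [Effect("close_gate", g) for g in closes])

        rules = [
            ActionRule("begin_encode", condition_pointer="start",
                       effects=[Effect("open_gate", "g_vis_load"),
                                Effect("set_state", "step", "encode")]),
            ActionRule("encode_to_familiarity", condition_pointer="encode",
                       condition_signals={"enc_done": 0.7}, bias=-0.8,
                       effects=stage_effects(["g_fam", "g_acc_fam"], [])
                       + [Effect("set_state", "step", "familiar")]),
            ActionRule("familiar_to_retrieve", condition_pointer="familiar",
                       condition_signals={"fam_pos": 0.7}, bias=-0.8,
                       effects=stage_effects(["g_mem", "g_acc_retr"],
                                             ["g_fam", "g_acc_fam",
                                              "g_vis_load"])
                       + [Effect("set_state", "step", "retrieve")]),
            ActionRule("familiar_to_no", condition_pointer="familiar",
                       condition_signals={"fam_neg": 0.7}, bias=-0.8,
                       effects=stage_effects([], ["g_fam", "g_acc_fam",
                                                  "g_vis_load"])
                       + [Effect("set_state", "step", "respond_no")]),
            ActionRule("retrieve_to_compare", condition_pointer="retrieve",
                       condition_signals={"retr_done": 0.7}, bias=-0.8,
                       effects=stage_effects(["g_acc_cmp"], ["g_acc_retr"])
                       + [Effect("set_state", "step", "compare")]),
            ActionRule("compare_to_yes", condition_pointer="compare",
                       condition_signals={"cmp_pos": 0.7}, bias=-0.8,
                       effects=stage_effects([], ["g_acc_cmp", "g_mem"])
                       + [Effect("set_state", "step", "respond_yes")]),
            ActionRule("compare_to_no", condition_pointer="compare",
                       condition_signals={"cmp_neg": 0.7}, bias=-0.8,
                       effects=stage_effects([], ["g_acc_cmp", "g_mem"])
                       + [Effect("set_state", "step", "respond_no")]),
        ]
        if not pulse:
            rules += [
                # maintainers sit just below the transition utilities so
                # a satisfied transition condition always wins the channel
                ActionRule("familiarity_maintain",
                           condition_pointer="familiar", mode="maintainer",
                           bias=-0.15,
                           effects=[Effect("open_gate", "g_fam"),
                                    Effect("open_gate", "g_acc_fam")]),
                ActionRule("retrieve_maintain",
                           condition_pointer="retrieve", mode="maintainer",
                           bias=-0.15,
                           effects=[Effect("open_gate", "g_mem"),
                                    Effect("open_gate", "g_acc_retr")]),
                ActionRule("compare_maintain",
                           condition_pointer="compare", mode="maintainer",
                           bias=-0.15,
                           effects=[Effect("open_gate", "g_acc_cmp")]),
            ]
        return rules

    # -- forward-model bookkeeping ---------------------------------------
    def _usage_coefficients(self):
        """module -> [(pre population, per-pre-neuron sum_j |w_ij|)]."""
        coeffs = {}
        for cs in self.sim.conn_states:
            if cs.pre_kind != "ensemble":
                continue
            post_name = getattr(cs.post, "name", None)
            if post_name is None or cs.post_kind == "node":
                continue
            if cs.weights is not None:
                W = cs.weights
            elif cs.decoders is not None and cs.post_kind == "ensemble":
                tr = cs.conn.transform
                W = merge_weights(cs.decoders, cs.post.encoders,
                                  cs.post.gains, post_radius=cs.post.radius,
                                  transform=(np.eye(cs.decoders.shape[1])
                                             * tr if np.ndim(tr) == 0
                                             and tr is not None else tr))
            else:
                continue
            module = post_name.split("_")[0]
            coeffs.setdefault(post_name, []).append(
                (cs.pre.name, np.abs(W).sum(axis=0)))
        keep = {"familiarity_main", "declarative_main", "representation",
                "visual_buffer"}
        return {k: v for k, v in coeffs.items() if k in keep}

    def _record_step(self):
        dt = self.net.dt
        for p in self._record_pops:
            self.activity_log[p].append(
                float(self.sim.states[p]["spikes"].sum()))
        a = np.exp(-dt / 0.005)
        for module, incoming in self.usage_coeffs.items():
            total = 0.0
            filt = self._usage_filters[module]
            for pre_name, coeff in incoming:
                spikes = self.sim.states[pre_name]["spikes"]
                prev = filt.get(pre_name)
                cur = (a * prev + (1 - a) * spikes / dt) if prev is not None \
                    else (1 - a) * spikes / dt
                filt[pre_name] = cur
                total += float(cur @ coeff)
            self.usage_log[module].append(total)

    # -- trial execution --------------------------------------------------
    def _reset_trial(self):
        sim = self.sim
        # clear the recurrent synaptic traces: their time constants would
        # otherwise carry the previous trial's content through the reset
        for conn in [self._vb_rec, self._rep_rec] + self._acc_recs:
            cs = sim.conn_map[id(conn)]
            cs.filter.state[...] = 0.0
            cs.value = np.zeros_like(np.atleast_1d(cs.value))
        # wipe the control state for the whole reset window so no stale
        # stage pointer can fire a rule against residual signals
        self.tg._reset_until = sim.t + self.config.reset_duration
        self.tg._state_override = None
        self.tg._current_state_name = "idle"
        for conn in (self.tg._state_rec_conn, self.tg._state_in_conn):
            cs = sim.conn_map[id(conn)]
            cs.filter.state[...] = 0.0
            cs.value = np.zeros_like(np.atleast_1d(cs.value))
        ts = {"fam_on": False, "retr_on": False, "cmp_on": False}
        self._trial_state = ts
        self._latch = [None, None]
        self._enc_start = None
        self._image = np.zeros(IMAGE_WIDTH * IMAGE_HEIGHT)
        for g in ("g_vis_load", "g_fam", "g_mem", "g_acc_fam", "g_acc_retr",
                  "g_acc_cmp"):
            sim.set_gate(g, 0.0)
        for g in ("r_visbuf", "r_rep", "r_familiarity", "r_declarative",
                  "r_acc_fam", "r_acc_retr", "r_acc_cmp"):
            sim.set_gate(g, 1.0)
        for _ in range(int(round(self.config.reset_duration / self.net.dt))):
            self.sim.step()
            self._record_step()
        for g in ("r_visbuf", "r_rep", "r_familiarity", "r_declarative",
                  "r_acc_fam", "r_acc_retr", "r_acc_cmp"):
            sim.set_gate(g, 0.0)
        self.tg.signals.clear()
        self.tg.controller._gate_until.clear()
        self.tg.controller._last_fire.clear()

    def run_trial(self, trial: Trial, images: Optional[tuple] = None
                  ) -> TrialRecord:
        cfg = self.config
        sim = self.sim
        self._reset_trial()
        if images is None:
            images = (render_word_image(trial.pair.word1).ravel(),
                      render_word_image(trial.pair.word2).ravel())
        self._trial_state["hand"] = trial.hand
        t0 = sim.t
        n_fire0 = len(self.tg.controller.firings)
        self.tg.set_state("start")
        stage_times: dict = {}
        clarity_sum, clarity_n = 0.0, 0
        response, finger, press_t = "none", None, None
        attend = cfg.attend_duration
        max_steps = int(round(cfg.watchdog / self.net.dt))
        for _ in range(max_steps):
            t_rel = sim.t - t0
            # attention schedule during encoding
            stage = self.tg._current_state_name
            if stage == "encode" and self._enc_start is None:
                self._enc_start = sim.t
            if self._enc_start is not None:
                # attend word1, latch, saccade gap, attend word2, latch —
                # the gap lets the parser's activity tail die out so the
                # second word's representation is not a mixture
                gap = 0.05
                te = sim.t - self._enc_start
                if te < attend:
                    self._image = images[0]
                elif te < attend + gap:
                    if self._latch[0] is None:
                        self._latch[0] = self._concept_now()
                    self._image = np.zeros(IMAGE_WIDTH * IMAGE_HEIGHT)
                elif te < 2 * attend + gap:
                    self._image = images[1]
                else:
                    if self._latch[1] is None:
                        self._latch[1] = self._concept_now()
                    self._image = np.zeros(IMAGE_WIDTH * IMAGE_HEIGHT)
            sigs = self.tg.signals
            sigs["enc_done"] = 1.0 if self._latch[1] is not None else 0.0
            self._trial_state["fam_on"] = \
                self.net.gates["g_acc_fam"].value > 0
            self._trial_state["retr_on"] = \
                self.net.gates["g_acc_retr"].value > 0
            self._trial_state["cmp_on"] = \
                self.net.gates["g_acc_cmp"].value > 0
            fam = self._acc_fam_val
            sigs["fam_pos"] = 1.0 if fam >= cfg.fam_acc.upper_bound else 0.0
            sigs["fam_neg"] = 1.0 if fam <= cfg.fam_acc.lower_bound else 0.0
            retr = self._acc_retr_val
            sigs["retr_done"] = 1.0 if retr >= cfg.retr_acc.upper_bound \
                else 0.0
            cmp_v = self._acc_cmp_val
            sigs["cmp_pos"] = 1.0 if cmp_v >= cfg.cmp_acc.upper_bound else 0.0
            sigs["cmp_neg"] = 1.0 if cmp_v <= cfg.cmp_acc.lower_bound else 0.0

            # the representation only starts integrating at retrieval;
            # before that it is held at reset so its recurrence cannot
            # latch onto pre-retrieval noise from the structural pathway
            if stage in ("start", "encode", "familiar"):
                sim.set_gate("r_rep", 1.0)
            elif self.net.gates["r_rep"].value and stage == "retrieve" \
                    and self._acc_retr_val > 0.1 * \
                    self.config.retr_acc.upper_bound:
                # release once real clarity evidence has accumulated, so
                # the buffer cannot latch the memory's gating transient
                sim.set_gate("r_rep", 0.0)

            self.tg.step()
            self._record_step()
            if stage == "retrieve":
                clarity_sum += float(np.linalg.norm(self._dec_out_val))
                clarity_n += 1

            for ft, fname, fmode in \
                    self.tg.controller.firings[n_fire0:]:
                key = {"encode_to_familiarity": "familiarity_start",
                       "familiar_to_retrieve": "familiarity_crossing",
                       "familiar_to_no": "familiarity_negative",
                       "retrieve_to_compare": "retrieval_crossing",
                       "compare_to_yes": "decision_crossing",
                       "compare_to_no": "decision_crossing"}.get(fname)
                if key and key not in stage_times:
                    stage_times[key] = ft - t0
            n_fire0 = len(self.tg.controller.firings)

            stage = self.tg._current_state_name
            if stage in ("respond_yes", "respond_no"):
                hand = trial.hand
                fngr = "index" if stage == "respond_yes" else "middle"
                name = f"{hand}_{fngr}"
                if getattr(self, f"_press_{name}") >= cfg.press_threshold:
                    response = "yes" if stage == "respond_yes" else "no"
                    finger = name
                    press_t = sim.t - t0
                    break
        if clarity_n:
            stage_times["retrieve_clarity"] = clarity_sum / clarity_n
        rt = (press_t + cfg.motor_latency) * 1000.0 if press_t else 0.0
        correct = (response == trial.correct_response)
        rec = TrialRecord(trial, response, rt, correct, stage_times, finger)
        self.events.append(dict(
            condition=f"{trial.probe}_fan{trial.pair.fan}",
            correct=correct, stimulus_time=t0,
            response_time=(t0 + press_t) if press_t else None,
            probe=trial.probe, fan=trial.pair.fan, hand=trial.hand))
        # let the motor response finish before the next trial
        self._image = np.zeros(IMAGE_WIDTH * IMAGE_HEIGHT)
        for _ in range(int(round(0.05 / self.net.dt))):
            self.sim.step()
            self._record_step()
        return rec

    def _concept_now(self):
        v = np.asarray(self._node_output("concept"))
        nv = np.linalg.norm(v)
        if nv < 0.2:
            return None
        return v / nv

    def _node_output(self, name):
        return self.sim._node_outputs[name]

    def activity_series(self) -> dict:
        """Summed-spike-count time series per recorded population."""
        return {("familiarity" if k == "familiarity_main" else
                 "declarative" if k == "declarative_main" else k):
                np.array(v) for k, v in self.activity_log.items()}


def assemble_model(config: ModelConfig, vocab: Vocabulary,
                   familiarity: MemoryModule, declarative: MemoryModule,
                   word_list: Sequence[str], studied_words: Sequence[str],
                   ctrl_vocab: Optional[Vocabulary] = None) -> AssembledModel:
    """Wire the full architecture from trained memory modules."""
    if ctrl_vocab is None:
        ctrl_vocab = Vocabulary(config.ctrl_dim, rng_seed=config.seed + 77)
    return AssembledModel(config, vocab, ctrl_vocab,
                          familiarity.trained_state() if familiarity
                          is not None else None,
                          declarative.trained_state() if declarative
                          is not None else None,
                          word_list, studied_words)


def run_participant(model: AssembledModel, trials: Sequence[Trial],
                    max_trials: Optional[int] = None) -> list:
    """Run test trials end to end; returns TrialRecords.

    Buffers and accumulators reset between trials; learned weights do not.
    Deterministic given the model's seeds and the trial sequence.
    """
    records = []
    for k, tr in enumerate(trials):
        if max_trials is not None and k >= max_trials:
            break
        records.append(model.run_trial(tr))
    return records
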