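"""End-to-end orchestration: study list -> trained memories -> trials.

The full experiment (32 studied pairs, 1,120 test trials) is what the
design module generates; simulations at desk scale run a reduced version
of the same structure — a mini study list with the same fan-2 word-sharing
cycles and balanced mini test blocks — so that one CPU can train and test
a participant in minutes.  The reduction factors live here, in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import AssembledModel, ModelConfig, TrialRecord, \
    assemble_model, run_participant
from .config import RunConfig
from .design import StudyList, Trial, WordPair, generate_words, \
    generate_study_list, make_repaired_foil, _fan2_cycle
from .memory import MemoryModule, build_memory, make_training_schedule, \
    train_memory
from .spa import Vocabulary, bind_pair

__all__ = ["mini_study_list", "sample_trials", "build_vocab_for_words",
           "train_memories_for_design", "simulate_participant",
           "ParticipantResult", "records_to_frame", "pair_name"]


def pair_name(pair: WordPair) -> str:
    return f"{pair.word1}__{pair.word2}"


def mini_study_list(seed: int, n_fan1: int = 4, n_fan2: int = 8) -> StudyList:
    """Reduced study list preserving the design structure: fan-1 pairs with
    unique words, fan-2 pairs in 4-cycles (every fan-2 word in two pairs),
    split over short/long length classes.  At least two fan-2 cycles are
    required, because within one cycle every recombination is itself a
    studied pair and no re-paired foil exists."""
    if n_fan2 % 4:
        raise ValueError("n_fan2 must be a multiple of 4 (word cycles)")
    rng = np.random.default_rng(seed)
    used: set = set()
    pairs = []
    for i in range(n_fan1):
        lc = "short" if i % 2 == 0 else "long"
        w = generate_words(rng, 2, lc, used)
        pairs.append(WordPair(w[0], w[1], 1, lc))
    for c in range(n_fan2 // 4):
        lc = "short" if c % 2 == 0 else "long"
        fw = generate_words(rng, 4, lc, used)
        pairs.extend(_fan2_cycle(fw[0:2], fw[2:4], lc))
    return StudyList(pairs, seed)


def sample_trials(study: StudyList, seed: int, n_trials: int,
                  hand_blocks: int = 2) -> list:
    """Balanced mini test set with the 2:2:1 target/re-paired/new-foil
    composition of the full blocks, split into alternating-hand blocks."""
    rng = np.random.default_rng(seed)
    used = set(study.words)
    per_unit = 5  # 2 targets + 2 re-paired + 1 new foil
    n_units = max(1, n_trials // per_unit)
    trials = []
    targets = [p for p in study.pairs]
    fans = [1, 2]
    for u in range(n_units):
        for fan in fans:
            cand = [p for p in targets if p.fan == fan]
            trials.append(("target", cand[rng.integers(len(cand))]))
            trials.append(("repaired_foil",
                           make_repaired_foil(study, rng, fan)))
        lc = "short" if u % 2 == 0 else "long"
        w1, w2 = generate_words(rng, 2, lc, used)
        trials.append(("new_foil", WordPair(w1, w2, 1, lc)))
    rng.shuffle(trials)
    out = []
    block_len = max(1, len(trials) // hand_blocks)
    for i, (probe, pair) in enumerate(trials[:n_trials]):
        block = min(i // block_len, hand_blocks - 1)
        hand = "left" if block % 2 == 0 else "right"
        out.append(Trial(probe, pair, hand, block,
                         float(rng.uniform(400, 600))))
    return out


def build_vocab_for_words(words: Sequence[str], dims: int,
                          seed: int) -> Vocabulary:
    vocab = Vocabulary(dims, rng_seed=seed)
    vocab.make_pointer("ITEM1")
    vocab.make_pointer("ITEM2")
    for w in words:
        vocab.make_pointer(w)
    return vocab


def train_memories_for_design(study: StudyList, model_cfg: ModelConfig,
                              seed: int = 0,
                              vocab: Optional[Vocabulary] = None):
    """Pre-train familiarity (on words) and declarative (on bound pairs).

    Declarative training follows the human exposure statistics (5 vs 11
    presentations, fan-2 at half duration); familiarity memory, which has
    no Voja±/BCM, gets a compressed schedule with the same 2x frequency
    ratio — it only needs the PES decoders to learn the studied words.
    """
    if vocab is None:
        vocab = build_vocab_for_words(sorted(study.words),
                                      model_cfg.vocab_dim, seed + 13)
    f1_words = sorted({w for p in study.pairs if p.fan == 1
                       for w in p.words})
    f2_words = sorted({w for p in study.pairs if p.fan == 2
                       for w in p.words})

    from dataclasses import replace as _replace
    fam = build_memory("familiarity",
                       vocab, _replace(model_cfg.memory, pes_kappa=5e-6),
                       seed=seed + 1)
    fam_sched = make_training_schedule(
        vocab, f1_words, f2_words, seed=seed + 2,
        fan1_duration=0.5, fan1_reps=3, fan2_reps=6)
    train_memory(fam, fam_sched)

    pair_vectors = {pair_name(p): bind_pair(p.word1, p.word2, vocab).v
                    for p in study.pairs}
    f1_names = [pair_name(p) for p in study.pairs if p.fan == 1]
    f2_names = [pair_name(p) for p in study.pairs if p.fan == 2]
    dec = build_memory("declarative", vocab, model_cfg.memory,
                       seed=seed + 3)
    dec_sched = make_training_schedule(
        vocab, f1_names, f2_names, seed=seed + 4,
        vectors=pair_vectors)
    train_memory(dec, dec_sched)
    return vocab, fam, dec, pair_vectors


@dataclass
class ParticipantResult:
    records: list
    trials: pd.DataFrame
    model: AssembledModel
    vocab: Vocabulary
    study: StudyList


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(dict(
            probe=r.trial.probe, fan=r.trial.pair.fan,
            word1=r.trial.pair.word1, word2=r.trial.pair.word2,
            length_class=r.trial.pair.length_class, hand=r.trial.hand,
            block=r.trial.block, response=r.response, rt_ms=r.rt,
            correct=r.correct, finger=r.finger,
            **{f"t_{k}": v for k, v in r.stage_times.items()}))
    return pd.DataFrame(rows)


def simulate_participant(cfg: RunConfig, seed: int = 0,
                         study: Optional[StudyList] = None,
                         trials: Optional[list] = None) -> ParticipantResult:
    """Train the memory system and run one simulated participant.

    Desk scale uses a reduced study list (4 fan-1 + 8 fan-2 pairs) and a
    balanced subset of test trials; full scale uses the complete design.
    """
    model_cfg = cfg.model
    if study is None:
        if model_cfg.scale == "full":
            study = generate_study_list(cfg.design_seed + seed)
        else:
            study = mini_study_list(cfg.design_seed + seed)
    n_trials = cfg.n_trials if cfg.n_trials is not None else 25
    if trials is None:
        trials = sample_trials(study, cfg.design_seed + seed + 500,
                               n_trials)
    vocab, fam, dec, _ = train_memories_for_design(
        study, model_cfg, seed=cfg.training_seed + seed)
    new_words = sorted({w for t in trials for w in t.pair.words
                        if w not in study.words})
    for w in new_words:
        vocab.make_pointer(w)
    model_cfg.seed = cfg.network_seed + seed
    model = assemble_model(model_cfg, vocab, fam, dec,
                           word_list=sorted(study.words) + new_words,
                           studied_words=sorted(study.words))
    records = run_participant(model, trials)
    return ParticipantResult(records, records_to_frame(records), model,
                             vocab, study)
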