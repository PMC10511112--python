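"""Associative-recognition experiment structure.

Study phase: 32 word pairs — 16 fan-1 (each word unique to one pair) and 16
fan-2 (each word shared by exactly two pairs), half short (4-5 letters) and
half long (7-8 letters) within each fan level.  Test phase: 14 blocks, each
with 32 targets, 32 re-paired foils (recombinations of studied words that
never co-occurred at study, preserving fan and length class) and 16 new
foils built from words never seen elsewhere; response hand fixed per block,
seven left- and seven right-hand blocks.

Words are synthetic pronounceable consonant-vowel strings; only their
length class matters to the model.  Word images are deterministic 90x14
binary rasterizations — longer words carry more ink pixels, the premise of
the word-length effect in visual cortex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WordPair", "Trial", "StudyList", "generate_words",
    "generate_study_list", "make_repaired_foil", "generate_test_blocks",
    "render_word_image", "design_to_frame",
    "N_STUDY_PAIRS", "N_BLOCKS", "TARGETS_PER_BLOCK",
    "REPAIRED_PER_BLOCK", "NEW_FOILS_PER_BLOCK", "trials_per_participant",
]

N_STUDY_PAIRS = 32
N_BLOCKS = 14
TARGETS_PER_BLOCK = 32
REPAIRED_PER_BLOCK = 32
NEW_FOILS_PER_BLOCK = 16


def trials_per_participant() -> int:
    """Total test trials for one simulated participant."""
    return N_BLOCKS * (TARGETS_PER_BLOCK + REPAIRED_PER_BLOCK
                       + NEW_FOILS_PER_BLOCK)


@dataclass(frozen=True)
class WordPair:
    word1: str
    word2: str
    fan: int                    # 1 or 2
    length_class: str           # "short" | "long"

    def __post_init__(self) -> None:
        if self.fan not in (1, 2):
            raise ValueError("fan must be 1 or 2")
        if self.length_class not in ("short", "long"):
            raise ValueError("length_class must be short or long")

    @property
    def words(self):
        return (self.word1, self.word2)


@dataclass
class Trial:
    probe: str                  # "target" | "repaired_foil" | "new_foil"
    pair: WordPair
    hand: str                   # "left" | "right"
    block: int
    fixation_ms: float          # drawn uniformly in [400, 600]

    @property
    def correct_response(self) -> str:
        return "yes" if self.probe == "target" else "no"


@dataclass
class StudyList:
    pairs: list
    seed: int

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    @property
    def words(self) -> set:
        return {w for p in self.pairs for w in p.words}


_CONS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def generate_words(rng: np.random.Generator, n: int, length_class: str,
                   used: set) -> list:
    """Fresh pronounceable CV strings of the requested length class."""
    lengths = (4, 5) if length_class == "short" else (7, 8)
    out = []
    while len(out) < n:
        ln = int(rng.choice(lengths))
        chars = []
        for i in range(ln):
            pool = _CONS if i % 2 == 0 else _VOWELS
            chars.append(pool[rng.integers(len(pool))])
        w = "".join(chars)
        if w not in used:
            used.add(w)
            out.append(w)
    return out


def _fan2_cycle(words1: Sequence[str], words2: Sequence[str],
                length_class: str) -> list:
    """Four pairs over 2+2 words in a cycle, giving every word fan 2:
    (a,x), (b,x), (b,y), (a,y)."""
    a, b = words1
    x, y = words2
    return [WordPair(a, x, 2, length_class), WordPair(b, x, 2, length_class),
            WordPair(b, y, 2, length_class), WordPair(a, y, 2, length_class)]


def generate_study_list(seed: int) -> StudyList:
    """16 fan-1 + 16 fan-2 pairs, half short / half long per fan level.

    Fan-2 pairs are organized as word-sharing cycles so that every fan-2
    word appears in exactly two pairs; fan-1 words appear in exactly one.
    """
    rng = np.random.default_rng(seed)
    used: set = set()
    pairs: list = []
    for length_class in ("short", "long"):
        w = generate_words(rng, 16, length_class, used)
        pairs.extend(WordPair(w[2 * i], w[2 * i + 1], 1, length_class)
                     for i in range(8))
        # 8 fan-2 pairs per length class = two 4-cycles over 4+4 words
        fw = generate_words(rng, 8, length_class, used)
        pairs.extend(_fan2_cycle(fw[0:2], fw[2:4], length_class))
        pairs.extend(_fan2_cycle(fw[4:6], fw[6:8], length_class))
    assert len(pairs) == N_STUDY_PAIRS
    return StudyList(pairs, seed)


def make_repaired_foil(study_list: StudyList, rng: np.random.Generator,
                       fan: Optional[int] = None,
                       length_class: Optional[str] = None,
                       max_tries: int = 200) -> WordPair:
    """Recombine word1 of one studied pair with word2 of another of the
    same fan and length class; the result is never itself a studied pair."""
    studied = {(p.word1, p.word2) for p in study_list}
    cands = [p for p in study_list
             if (fan is None or p.fan == fan)
             and (length_class is None or p.length_class == length_class)]
    if len(cands) < 2:
        raise ValueError("need >= 2 studied pairs of matching fan/length")
    for _ in range(max_tries):
        a, b = rng.choice(len(cands), size=2, replace=False)
        pa, pb = cands[a], cands[b]
        foil = (pa.word1, pb.word2)
        if foil not in studied:
            return WordPair(foil[0], foil[1], pa.fan, pa.length_class)
    raise ValueError("no legal recombination found under the constraints")


def generate_test_blocks(study_list: StudyList, seed: int) -> list:
    """14 blocks of 32 targets + 32 re-paired foils + 16 new foils each.

    Foils are balanced over fan x length cells; new-foil words are unique
    across the whole experiment; hands alternate over blocks with seven
    left and seven right in seeded order; trial order is shuffled within
    each block.
    """
    rng = np.random.default_rng(seed)
    used = {w for p in study_list for w in p.words}
    hands = ["left"] * (N_BLOCKS // 2) + ["right"] * (N_BLOCKS // 2)
    rng.shuffle(hands)
    blocks = []
    for b in range(N_BLOCKS):
        trials = []
        for pair in study_list:
            trials.append(Trial("target", pair, hands[b], b,
                                float(rng.uniform(400, 600))))
        # 8 re-paired foils per fan x length cell
        for fan in (1, 2):
            for lc in ("short", "long"):
                for _ in range(REPAIRED_PER_BLOCK // 4):
                    foil = make_repaired_foil(study_list, rng, fan, lc)
                    trials.append(Trial("repaired_foil", foil, hands[b], b,
                                        float(rng.uniform(400, 600))))
        # 16 new foils, balanced over length only
        for lc in ("short", "long"):
            for _ in range(NEW_FOILS_PER_BLOCK // 2):
                w1, w2 = generate_words(rng, 2, lc, used)
                trials.append(Trial("new_foil", WordPair(w1, w2, 1, lc),
                                    hands[b], b,
                                    float(rng.uniform(400, 600))))
        order = rng.permutation(len(trials))
        blocks.append([trials[i] for i in order])
    return blocks


# ---------------------------------------------------------------------------
# Word images
# ---------------------------------------------------------------------------

IMAGE_WIDTH = 90
IMAGE_HEIGHT = 14


def render_word_image(word: str) -> np.ndarray:
    """Deterministic 90x14 binary rasterization of a word.

    Uses the fixed-width PIL bitmap font; raises if the word does not fit.
    """
    from PIL import Image, ImageDraw

    img = Image.new("1", (IMAGE_WIDTH, IMAGE_HEIGHT), 0)
    if word:
        draw = ImageDraw.Draw(img)
        x0, y0, x1, y1 = draw.textbbox((0, 0), word)
        if x1 - x0 > IMAGE_WIDTH:
            raise ValueError(f"word {word!r} too wide for "
                             f"{IMAGE_WIDTH}px raster")
        draw.text(((IMAGE_WIDTH - (x1 - x0)) // 2,
                   (IMAGE_HEIGHT - (y1 - y0)) // 2 - y0), word, fill=1)
    return np.asarray(img, dtype=float)


def design_to_frame(blocks: list):
    """Flatten test blocks to a pandas DataFrame (one row per trial)."""
    import pandas as pd

    rows = []
    for block in blocks:
        for tr in block:
            rows.append(dict(block=tr.block, probe=tr.probe,
                             word1=tr.pair.word1, word2=tr.pair.word2,
                             fan=tr.pair.fan,
                             length_class=tr.pair.length_class,
                             hand=tr.hand, fixation_ms=tr.fixation_ms))
    return pd.DataFrame(rows)
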