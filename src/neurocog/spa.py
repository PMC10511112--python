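"""Semantic-pointer algebra: vocabularies, binding, unbinding, cleanup.

Words, word pairs and control states are named high-dimensional unit vectors
("semantic pointers").  Direction encodes content; vector length encodes the
clarity of a representation and is deliberately *not* renormalized after
algebraic operations.  Pairs are role-filler structures built with circular
convolution: ``ITEM1 (*) word1 + ITEM2 (*) word2``.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np

from .core import Ensemble, Network, solve_decoders, lif_rate

__all__ = [
    "SemanticPointer",
    "Vocabulary",
    "circular_convolution",
    "circulant_matrix",
    "approx_inverse",
    "bind_pair",
    "cleanup",
    "SpikingCleanup",
]


class SemanticPointer:
    """A D-dimensional real vector with pointer algebra sugar."""

    __slots__ = ("v", "name")

    def __init__(self, vector: np.ndarray, name: Optional[str] = None) -> None:
        self.v = np.asarray(vector, dtype=float)
        self.name = name

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.v, dtype=dtype)

    def __len__(self) -> int:
        return self.v.size

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.v))

    def similarity(self, other) -> float:
        return float(np.dot(self.v, np.asarray(other)))

    def __mul__(self, other):
        if np.isscalar(other):
            return SemanticPointer(self.v * other)
        return SemanticPointer(circular_convolution(self.v, np.asarray(other)))

    def __add__(self, other):
        return SemanticPointer(self.v + np.asarray(other))

    def __invert__(self):
        return SemanticPointer(approx_inverse(self.v))

    def __repr__(self) -> str:
        return f"SemanticPointer({self.name or 'anon'}, D={self.v.size})"


def _random_unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


class Vocabulary:
    """A seeded registry of named random unit vectors.

    Freshly generated entries are nearly orthogonal with high probability for
    D >= 64, which is what makes compressed role-filler binding decodable.
    """

    def __init__(self, dimensions: int = 512, rng_seed: int = 0) -> None:
        if dimensions < 1:
            raise ValueError("dimensions must be >= 1")
        self.dimensions = int(dimensions)
        self.rng_seed = int(rng_seed)
        self._rng = np.random.default_rng(rng_seed)
        self._entries: dict[str, SemanticPointer] = {}

    # -- creation / access ------------------------------------------------
    def make_pointer(self, name: str) -> SemanticPointer:
        if name in self._entries:
            raise ValueError(f"duplicate pointer name {name!r}")
        sp = SemanticPointer(_random_unit(self._rng, self.dimensions), name)
        self._entries[name] = sp
        return sp

    def make_orthogonal(self, names: Sequence[str]) -> list:
        """Register a mutually orthonormal set of pointers (QR of seeded
        Gaussians).  Used for control states, where cross-talk between
        condition pointers must be zero."""
        names = list(names)
        if len(names) > self.dimensions:
            raise ValueError("more orthogonal pointers than dimensions")
        G = self._rng.standard_normal((self.dimensions, len(names)))
        Q, _ = np.linalg.qr(G)
        return [self.add(n, Q[:, i]) for i, n in enumerate(names)]

    def add(self, name: str, vector: np.ndarray) -> SemanticPointer:
        if name in self._entries:
            raise ValueError(f"duplicate pointer name {name!r}")
        sp = SemanticPointer(np.asarray(vector, dtype=float), name)
        self._entries[name] = sp
        return sp

    def __getitem__(self, name: str) -> SemanticPointer:
        if name not in self._entries:
            return self.make_pointer(name)
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> list:
        return list(self._entries)

    def vectors(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        names = self.names if names is None else list(names)
        return np.array([self._entries[n].v for n in names])

    # -- persistence (names + seed suffice to reproduce vectors) ----------
    def to_json(self) -> str:
        return json.dumps({"dimensions": self.dimensions,
                           "rng_seed": self.rng_seed,
                           "names": self.names})

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        spec = json.loads(payload)
        vocab = cls(spec["dimensions"], spec["rng_seed"])
        for name in spec["names"]:
            vocab.make_pointer(name)
        return vocab


# ---------------------------------------------------------------------------
# Binding algebra
# ---------------------------------------------------------------------------

def circular_convolution(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c_k = sum_j a_j * b_{(k - j) mod D}, via FFT."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch in circular convolution")
    return np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=a.size)


def circular_convolution_direct(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """O(D^2) reference implementation of the cyclic sum."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch in circular convolution")
    d = a.size
    return np.array([np.dot(a, b[(k - np.arange(d)) % d]) for k in range(d)])


def circulant_matrix(a: np.ndarray) -> np.ndarray:
    """Matrix C with C @ x == circular_convolution(a, x).

    Binding with a *fixed* pointer is linear, so it can sit directly on a
    neural connection as a transform.
    """
    a = np.asarray(a, dtype=float)
    d = a.size
    idx = (np.arange(d)[:, None] - np.arange(d)[None, :]) % d
    return a[idx]


def approx_inverse(a: np.ndarray) -> np.ndarray:
    """Index-reversed vector: (a_0, a_{D-1}, a_{D-2}, ...).

    Acts as an approximate inverse under circular convolution for
    unitary-like vectors; exact involution.
    """
    a = np.asarray(a, dtype=float)
    return np.concatenate([a[:1], a[1:][::-1]])


def identity_pointer(dimensions: int) -> np.ndarray:
    """The binding identity (1, 0, ..., 0)."""
    v = np.zeros(dimensions)
    v[0] = 1.0
    return v


def bind_pair(word1, word2, vocab: Vocabulary) -> SemanticPointer:
    """ITEM1 (*) word1 + ITEM2 (*) word2, not renormalized.

    ITEM1/ITEM2 must already exist in the vocabulary (fixed role pointers).
    """
    for role in ("ITEM1", "ITEM2"):
        if role not in vocab:
            raise KeyError(f"role pointer {role!r} missing from vocabulary")
    w1 = np.asarray(vocab[word1] if isinstance(word1, str) else word1)
    w2 = np.asarray(vocab[word2] if isinstance(word2, str) else word2)
    return SemanticPointer(
        circular_convolution(vocab["ITEM1"].v, w1)
        + circular_convolution(vocab["ITEM2"].v, w2))


def unbind(pair, role, vocab: Vocabulary) -> np.ndarray:
    """Recover the filler bound to ``role`` (noisy; feed through cleanup)."""
    role_v = np.asarray(vocab[role] if isinstance(role, str) else role)
    return circular_convolution(np.asarray(pair), approx_inverse(role_v))


# ---------------------------------------------------------------------------
# Cleanup memory
# ---------------------------------------------------------------------------

def cleanup(x, vocab: Vocabulary, candidates: Sequence[str],
            threshold: float = 0.3):
    """Nearest candidate by dot product; "no match" below ``threshold``.

    Returns ``(name_or_None, score)``.  The mathematical form; see
    :class:`SpikingCleanup` for the neural associative layer.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    M = vocab.vectors(candidates)
    scores = M @ np.asarray(x, dtype=float)
    k = int(np.argmax(scores))
    best = float(scores[k])
    if best < threshold:
        return None, best
    return candidates[k], best


class SpikingCleanup:
    """Spiking associative cleanup: a block of thresholded neurons per
    candidate, whose decoded output snaps the input to the best candidate.

    Each neuron's encoder is its candidate's pointer; intercepts sit above
    the cleanup threshold so only inputs similar to a candidate drive its
    block.  Decoders are solved per block on the 1-D similarity response so
    the output is ``sum_c g(s_c) * candidate_c`` with g a soft step.
    """

    def __init__(self, name: str, vocab: Vocabulary,
                 candidates: Sequence[str], net: Network,
                 *, neurons_per_item: int = 20, threshold: float = 0.3,
                 intercept_width: float = 0.4) -> None:
        self.vocab = vocab
        self.candidates = list(candidates)
        if not self.candidates:
            raise ValueError("empty candidate set")
        n_items = len(self.candidates)
        d = vocab.dimensions
        M = vocab.vectors(self.candidates)
        encoders = np.repeat(M, neurons_per_item, axis=0)
        rng = net.rng
        intercepts = rng.uniform(threshold, threshold + intercept_width,
                                 size=n_items * neurons_per_item)
        max_rates = rng.uniform(200, 400, size=n_items * neurons_per_item)
        self.ensemble = net.ensemble(
            name, n_items * neurons_per_item, d,
            encoders=encoders, intercepts=intercepts, max_rates=max_rates)
        # per-block decoders on the scalar similarity response
        s = np.linspace(-1, 1, 200)
        dec = np.zeros((n_items * neurons_per_item, d))
        target = np.clip((s - threshold) / (1 - threshold), 0, 1)
        for c in range(n_items):
            sl = slice(c * neurons_per_item, (c + 1) * neurons_per_item)
            gains = self.ensemble.gains[sl]
            biases = self.ensemble.biases[sl]
            A = lif_rate(gains[None, :] * s[:, None] + biases[None, :],
                         self.ensemble.neuron_params)
            w = solve_decoders(A, target, (0.1 * A.max()) ** 2 * len(s))
            dec[sl] = w * M[c][None, :]
        self.decoders = dec

    def output_connection(self, net: Network, post, **kwargs):
        """Connect the cleanup output (decoded snap-to-candidate) to post."""
        conn = net.connect(self.ensemble, post, **kwargs)
        conn._fixed_decoders = self.decoders
        # Simulator hook: pre-solved decoders
        conn.eval_points = None
        conn.function = None
        return conn
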