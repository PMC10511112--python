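"""Semantic-pointer algebra: binding, unbinding, cleanup, vocabularies."""

import numpy as np
import pytest

from neurocog.core import Network, Simulator
from neurocog.spa import (SpikingCleanup, Vocabulary, approx_inverse,
                          bind_pair, circular_convolution,
                          circular_convolution_direct, circulant_matrix,
                          cleanup, identity_pointer, unbind)


class TestVocabulary:
    def test_pointers_are_unit_length(self):
        v = Vocabulary(128, rng_seed=1)
        for name in "abcdef":
            assert v.make_pointer(name).norm == pytest.approx(1.0, abs=1e-9)

    def test_random_pointers_nearly_orthogonal(self):
        v = Vocabulary(512, rng_seed=2)
        vs = [v.make_pointer(f"p{i}").v for i in range(100)]
        sims = [abs(np.dot(vs[i], vs[j]))
                for i in range(20) for j in range(i + 1, 20)]
        assert max(sims) < 0.2

    def test_duplicate_name_rejected(self):
        v = Vocabulary(16, rng_seed=3)
        v.make_pointer("x")
        with pytest.raises(ValueError):
            v.make_pointer("x")

    def test_seed_determinism_and_json_round_trip(self):
        a = Vocabulary(32, rng_seed=4)
        for n in ("p", "q", "r"):
            a.make_pointer(n)
        b = Vocabulary.from_json(a.to_json())
        for n in ("p", "q", "r"):
            assert np.array_equal(a[n].v, b[n].v)

    def test_orthogonal_set(self):
        v = Vocabulary(32, rng_seed=5)
        ptrs = v.make_orthogonal(["s1", "s2", "s3", "s4"])
        M = np.array([p.v for p in ptrs])
        assert np.allclose(M @ M.T, np.eye(4), atol=1e-10)


class TestCircularConvolution:
    @pytest.mark.parametrize("d", [4, 8, 64, 512])
    def test_fft_equals_direct_sum(self, d):
        rng = np.random.default_rng(d)
        a, b = rng.standard_normal(d), rng.standard_normal(d)
        assert np.allclose(circular_convolution(a, b),
                           circular_convolution_direct(a, b), atol=1e-10)

    def test_identity_element(self, rng):
        b = rng.standard_normal(16)
        assert np.allclose(circular_convolution(identity_pointer(16), b), b)

    def test_cyclic_shift(self):
        a = np.array([0.0, 1.0, 0.0, 0.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(circular_convolution(a, b), [4.0, 1.0, 2.0, 3.0])

    def test_commutativity(self, rng):
        a, b = rng.standard_normal(64), rng.standard_normal(64)
        assert np.allclose(circular_convolution(a, b),
                           circular_convolution(b, a))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            circular_convolution(np.zeros(4), np.zeros(8))

    def test_circulant_matrix_matches(self, rng):
        a, x = rng.standard_normal(32), rng.standard_normal(32)
        assert np.allclose(circulant_matrix(a) @ x,
                           circular_convolution(a, x), atol=1e-10)


class TestApproxInverse:
    def test_involution(self, rng):
        a = rng.standard_normal(64)
        assert np.allclose(approx_inverse(approx_inverse(a)), a)

    def test_identity_is_self_inverse(self):
        e = identity_pointer(16)
        assert np.allclose(approx_inverse(e), e)

    def test_unbinds_toward_identity(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(512)
            a /= np.linalg.norm(a)
            conv = circular_convolution(a, approx_inverse(a))
            if np.dot(conv, identity_pointer(512)) > 0.7:
                hits += 1
        assert hits >= 19


class TestBinding:
    def _vocab(self, d=512, n_words=32, seed=0):
        v = Vocabulary(d, rng_seed=seed)
        v.make_pointer("ITEM1")
        v.make_pointer("ITEM2")
        words = [f"w{i}" for i in range(n_words)]
        for w in words:
            v.make_pointer(w)
        return v, words

    def test_unbinding_recovers_filler_above_distractors(self):
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            v, words = self._vocab(seed=seed)
            pair = bind_pair("w0", "w1", v)
            est = unbind(pair, "ITEM1", v)
            sims = {w: float(np.dot(est, v[w].v)) for w in words}
            if max(sims, key=sims.get) == "w0":
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_missing_role_pointers_rejected(self):
        v = Vocabulary(64, rng_seed=9)
        v.make_pointer("a")
        v.make_pointer("b")
        with pytest.raises(KeyError):
            bind_pair("a", "b", v)

    def test_binding_linearity_same_word(self):
        v = Vocabulary(128, rng_seed=10)
        item = v.make_pointer("ITEM1")
        v.add("ITEM2", item.v)  # same role twice
        w = v.make_pointer("w")
        pair = bind_pair("w", "w", v)
        assert np.allclose(pair.v,
                           2 * circular_convolution(item.v, w.v))

    def test_order_matters(self):
        v, words = self._vocab(n_words=2, seed=11)
        p12 = bind_pair("w0", "w1", v)
        p21 = bind_pair("w1", "w0", v)
        sim = p12.similarity(p21) / (p12.norm * p21.norm)
        assert sim < 0.5


class TestCleanup:
    def test_exact_candidate(self):
        v = Vocabulary(256, rng_seed=12)
        cands = [f"c{i}" for i in range(8)]
        for c in cands:
            v.make_pointer(c)
        name, score = cleanup(v["c3"].v, v, cands)
        assert name == "c3"
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_robust_to_additive_noise(self):
        ok = 0
        for seed in range(50):
            v = Vocabulary(512, rng_seed=100 + seed)
            cands = [f"c{i}" for i in range(8)]
            for c in cands:
                v.make_pointer(c)
            noise = v.make_pointer("noise")
            x = v["c2"].v + 0.3 * noise.v
            name, _ = cleanup(x, v, cands)
            ok += name == "c2"
        assert ok >= 48

    def test_orthogonal_input_flags_no_match(self):
        v = Vocabulary(256, rng_seed=13)
        cands = ["c0", "c1"]
        for c in cands:
            v.make_pointer(c)
        probe = v.make_pointer("unrelated")
        # project out the candidate components
        x = probe.v.copy()
        for c in cands:
            x -= np.dot(x, v[c].v) * v[c].v
        name, score = cleanup(x, v, cands)
        assert name is None
        assert score < 0.3

    def test_empty_candidates_rejected(self):
        v = Vocabulary(16, rng_seed=14)
        with pytest.raises(ValueError):
            cleanup(np.zeros(16), v, [])

    def test_spiking_cleanup_snaps_to_candidate(self):
        v = Vocabulary(64, rng_seed=15)
        cands = [f"c{i}" for i in range(6)]
        for c in cands:
            v.make_pointer(c)
        net = Network(seed=16)
        cl = SpikingCleanup("cl", v, cands, net)
        noise = v.make_pointer("n")
        x = v["c1"].v + 0.3 * noise.v
        inp = net.node("in", x)
        net.connect(inp, cl.ensemble, synapse_tau=0.005)
        out = net.node("out", lambda t, y: y, size_in=64, size_out=64)
        cl.output_connection(net, out, synapse_tau=0.01)
        probe = net.probe(out, "output", synapse_tau=0.01)
        sim = Simulator(net)
        sim.run(0.15)
        decoded = sim.data(probe)[-10:].mean(axis=0)
        sims = {c: float(np.dot(decoded, v[c].v)) for c in cands}
        assert max(sims, key=sims.get) == "c1"
        # output is dominated by the snapped candidate
        others = [s for c, s in sims.items() if c != "c1"]
        assert sims["c1"] > 2 * max(np.abs(others))
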