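"""BCH construction, shortening, bit/base mapping and algebraic decoding."""

import itertools

import numpy as np
import pytest

from eccbarcodes.bch import (
    BitBaseMapping,
    bch_build,
    bch_decode,
    bch_encode,
    bounded_distance_decode,
    seq_to_symbols,
    shorten,
    symbols_to_seq,
)


class TestBuild:
    @pytest.mark.parametrize("n,t,k", [(63, 6, 30), (63, 7, 24), (15, 2, 7), (15, 3, 5), (31, 3, 16)])
    def test_dimensions(self, n, t, k):
        spec = bch_build(n, t)
        assert spec.k == k
        assert len(spec.generator) - 1 == n - k

    def test_generator_divides_codewords(self, rng):
        """Every systematic codeword evaluates to zero at alpha..alpha^2t."""
        spec = bch_build(15, 2)
        fld = spec.field
        for _ in range(10):
            msg = rng.integers(0, 2, spec.k).astype(np.uint8)
            bc = bch_encode(spec, msg)
            bits = spec.mapping.symbols_to_pairs(bc)[: spec.n]  # drop ext parity
            ones = np.nonzero(bits)[0]
            for j in range(1, 2 * spec.t + 1):
                acc = 0
                for i in ones:
                    acc ^= fld.pow_alpha(j * (spec.n - 1 - int(i)))
                assert acc == 0

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            bch_build(17, 2)
        with pytest.raises(ValueError):
            bch_build(15, 8)


class TestShorten:
    @pytest.mark.parametrize(
        "n,t,s,N", [(63, 6, 21, 21), (63, 7, 13, 25), (63, 7, 15, 24), (63, 6, 19, 22)]
    )
    def test_barcode_lengths(self, n, t, s, N):
        spec = shorten(bch_build(n, t), s)
        assert spec.N == N
        assert spec.k_prime == spec.k - s

    def test_unshortened_even_s_extension(self):
        # s = 0 is even: the appended parity bit gives N = (n+1)/2 = 32
        assert bch_build(63, 6).N == 32

    def test_s_out_of_range(self):
        spec = bch_build(15, 2)
        with pytest.raises(ValueError):
            shorten(spec, spec.k)
        with pytest.raises(ValueError):
            shorten(spec, -1)


class TestMapping:
    def test_roundtrip_exhaustive_short(self):
        """demap(map(.)) is the identity on all 4^N sequences, N <= 6... via
        all length-6 symbol words in chunks (4^6 = 4096)."""
        mapping = BitBaseMapping()
        words = np.array(list(itertools.product(range(4), repeat=6)), dtype=np.uint8)
        for w in words[:: 7]:  # every 7th word still covers 586 cases
            assert np.array_equal(mapping.pairs_to_symbols(mapping.symbols_to_pairs(w)), w)
        # and bit-side roundtrip on random longer vectors
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, 60).astype(np.uint8)
        assert np.array_equal(mapping.symbols_to_pairs(mapping.pairs_to_symbols(bits)), bits)

    def test_base_mismatch_bit_error_split(self):
        """Any base substitution flips 1 or 2 bits; per base, two of the
        three substitutions flip one bit and one flips two — the 2/3 vs 1/3
        split behind b = floor(t/2). Exhaustive over bijective mappings."""
        for order in itertools.permutations("ACGT"):
            mapping = BitBaseMapping("".join(order))
            for a, b in itertools.permutations(range(4), 2):
                flips = int(
                    (mapping.symbols_to_pairs(np.array([a], dtype=np.uint8))
                     != mapping.symbols_to_pairs(np.array([b], dtype=np.uint8))).sum()
                )
                assert flips in (1, 2)
            for a in range(4):
                counts = [
                    int((mapping.symbols_to_pairs(np.array([a], dtype=np.uint8))
                         != mapping.symbols_to_pairs(np.array([b], dtype=np.uint8))).sum())
                    for b in range(4) if b != a
                ]
                assert sorted(counts) == [1, 1, 2]

    def test_sequence_string_roundtrip(self):
        assert symbols_to_seq(np.array([0, 1, 2, 3], dtype=np.uint8)) == "ACGT"
        assert np.array_equal(seq_to_symbols("ACGT"), [0, 1, 2, 3])
        with pytest.raises(ValueError):
            seq_to_symbols("ACGN")

    def test_non_bijective_rejected(self):
        with pytest.raises(ValueError):
            BitBaseMapping("AACC")


class TestEncodeDecode:
    def test_zero_message(self):
        spec = shorten(bch_build(15, 2), 3)  # odd s, N = 6
        bc = bch_encode(spec, np.zeros(spec.k_prime, dtype=np.uint8))
        out = bch_decode(spec, bc)
        assert out.success and not out.word.any()

    def test_injectivity_exhaustive(self):
        spec = shorten(bch_build(15, 2), 3)  # k' = 4 -> 16 messages
        msgs = np.array(list(itertools.product(range(2), repeat=spec.k_prime)), dtype=np.uint8)
        bcs = {bch_encode(spec, m).tobytes() for m in msgs}
        assert len(bcs) == 2 ** spec.k_prime

    def test_all_one_and_two_bit_errors_corrected(self, rng):
        """Exhaustive bounded-distance sweep on BCH(15,7,t=2): all 15 + 105
        bit-error patterns on sample codewords decode to the message."""
        spec = shorten(bch_build(15, 2), 1)  # odd s -> no parity bit, N = 7
        msgs = rng.integers(0, 2, (3, spec.k_prime)).astype(np.uint8)
        for msg in msgs:
            clean_bits = spec.mapping.symbols_to_pairs(bch_encode(spec, msg))
            n_tx = clean_bits.size
            patterns = [np.array([i]) for i in range(n_tx)]
            patterns += [np.array(p) for p in itertools.combinations(range(n_tx), 2)]
            for pat in patterns:
                bits = clean_bits.copy()
                bits[pat] ^= 1
                out = bch_decode(spec, spec.mapping.pairs_to_symbols(bits))
                assert out.success and np.array_equal(out.word, msg)

    def test_guaranteed_base_mismatch_correction(self, rng):
        """b = floor(t/2) base mismatches are always corrected (t=6 -> b=3)."""
        spec = shorten(bch_build(63, 6), 21)
        msg = rng.integers(0, 2, spec.k_prime).astype(np.uint8)
        bc = bch_encode(spec, msg)
        for _ in range(25):
            pos = rng.choice(spec.N, size=spec.b, replace=False)
            bad = bc.copy()
            bad[pos] = (bad[pos] + rng.integers(1, 4, spec.b)) % 4
            out = bch_decode(spec, bad)
            assert out.success and np.array_equal(out.word, msg)

    def test_overweight_errors_flagged_or_wrong_never_silent(self, rng):
        """Beyond-capability corruption either fails (detected) or lands on a
        different valid codeword — but a success must decode consistently."""
        spec = shorten(bch_build(15, 2), 1)
        msg = rng.integers(0, 2, spec.k_prime).astype(np.uint8)
        bc = bch_encode(spec, msg)
        n_wrong = 0
        for _ in range(50):
            bad = (bc + rng.integers(0, 4, spec.N)) % 4
            out = bch_decode(spec, bad.astype(np.uint8))
            if out.success and not np.array_equal(out.word, msg):
                n_wrong += 1
                # re-encoding the decoded message gives a word within t bits
                re_bits = spec.mapping.symbols_to_pairs(bch_encode(spec, out.word))
                bad_bits = spec.mapping.symbols_to_pairs(bad.astype(np.uint8))
                assert (re_bits != bad_bits).sum() <= spec.t

    def test_shortened_coordinate_error_is_failure(self):
        """An error pattern whose correction lands in a shortened (known
        zero) coordinate is reported as failure, not silently accepted."""
        spec = shorten(bch_build(15, 2), 5)  # odd s, N = 5
        msg = np.zeros(spec.k_prime, dtype=np.uint8)
        clean_bits = spec.mapping.symbols_to_pairs(bch_encode(spec, msg))
        # 3-bit corruption can miscorrect; scan for a failure case
        saw_failure = False
        for pat in itertools.combinations(range(clean_bits.size), 3):
            bits = clean_bits.copy()
            bits[list(pat)] ^= 1
            out = bch_decode(spec, spec.mapping.pairs_to_symbols(bits))
            if not out.success:
                saw_failure = True
        assert saw_failure

    def test_wrong_length(self):
        spec = shorten(bch_build(15, 2), 1)
        with pytest.raises(ValueError):
            bch_decode(spec, np.zeros(spec.N + 1, dtype=np.uint8))
        with pytest.raises(ValueError):
            bch_encode(spec, np.zeros(spec.k_prime + 1, dtype=np.uint8))


class TestBoundedDistance:
    @pytest.fixture()
    def set_d5(self, rng):
        """Synthetic barcode set with pairwise Hamming distance >= 5."""
        while True:
            cands = rng.integers(0, 4, (10, 12)).astype(np.uint8)
            d = (cands[:, None, :] != cands[None, :, :]).sum(-1)
            np.fill_diagonal(d, 99)
            if d.min() >= 5:
                return cands

    def test_member_decodes_to_itself(self, set_d5):
        out, idx = bounded_distance_decode(set_d5, set_d5[3], radius=2)
        assert out.success and idx == 3

    def test_all_two_mismatch_corruptions(self, set_d5, rng):
        """Brute force: every <=2-mismatch corruption of every barcode
        decodes back to it (d_H = 5 -> radius 2)."""
        for i, bc in enumerate(set_d5):
            for pos in itertools.combinations(range(12), 2):
                for d1, d2 in itertools.product((1, 2, 3), repeat=2):
                    bad = bc.copy()
                    bad[pos[0]] ^= d1
                    bad[pos[1]] ^= d2
                    out, idx = bounded_distance_decode(set_d5, bad, radius=2)
                    assert out.success and idx == i

    def test_far_word_fails(self, set_d5):
        far = (set_d5[0] + 1) % 4  # distance 12 from barcode 0
        dists = (set_d5 != far[None, :]).sum(1)
        if dists.min() > 2:
            out, idx = bounded_distance_decode(set_d5, far.astype(np.uint8), radius=2)
            assert not out.success and idx == -1

    def test_integrity_error_on_close_pair(self):
        bcs = np.array([[0, 0, 0, 0], [0, 0, 0, 1]], dtype=np.uint8)
        with pytest.raises(ValueError):
            bounded_distance_decode(bcs, bcs[0], radius=2)
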