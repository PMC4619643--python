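"""Shortened binary BCH codes mapped to DNA barcodes.

A binary BCH code of length n = 2^m - 1 (n in {15, 31, 63}) with designed
error-correction capability t is shortened by fixing s leading information
bits to zero and dropping them from transmission, which leaves the
redundancy untouched while allowing intermediate barcode lengths:

    N = (n + 1 - s) / 2   for s even (an overall parity bit is appended),
    N = (n - s) / 2       for s odd,

bases per barcode, two bits per base.  Under any bijective bit-pair/base
mapping a single base mismatch flips one bit pair in one or two positions
(probabilities 2/3 and 1/3 on the quaternary symmetric channel), so a
t-bit-correcting code guarantees correction of at least b = floor(t/2) base
mismatches.

Decoding demaps bases to bits, reinserts the s zero bits, computes syndromes
over GF(2^m), runs Berlekamp–Massey for the error locator and a Chien search
for its roots.  The decoder is *incomplete*: it reports a detected failure
whenever the locator degree disagrees with the number of roots found or an
error lands in a shortened (known-zero) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gf import GF2m, build_gf2m
from .ldpc_codec import DecodeOutcome

__all__ = [
    "BASES",
    "BitBaseMapping",
    "DEFAULT_MAPPING",
    "BCHSpec",
    "bch_build",
    "shorten",
    "bch_encode",
    "bch_decode",
    "bounded_distance_decode",
    "symbols_to_seq",
    "seq_to_symbols",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def symbols_to_seq(symbols: np.ndarray) -> str:
    """GF(4) symbol array -> DNA string (0,1,2,3 -> A,C,G,T)."""
    return "".join(BASES[int(s)] for s in np.asarray(symbols))


def seq_to_symbols(seq: str) -> np.ndarray:
    """DNA string -> GF(4) symbol array; rejects non-ACGT characters."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc}") from exc


@dataclass(frozen=True)
class BitBaseMapping:
    """Bijection between bit pairs {00,01,10,11} and the four DNA bases.

    ``order`` lists the base assigned to each pair value 2*b0 + b1.  The
    default 00->A, 01->C, 10->G, 11->T makes the pair value coincide with
    the GF(4) symbol integer.
    """

    order: str = BASES

    def __post_init__(self):
        if sorted(self.order) != sorted(BASES):
            raise ValueError("mapping must be a bijection onto ACGT")

    def pairs_to_symbols(self, bits: np.ndarray) -> np.ndarray:
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.size % 2:
            raise ValueError("bit vector length must be even")
        vals = 2 * bits[0::2] + bits[1::2]
        lut = np.array([_BASE_INDEX[b] for b in self.order], dtype=np.uint8)
        return lut[vals]

    def symbols_to_pairs(self, symbols: np.ndarray) -> np.ndarray:
        symbols = np.asarray(symbols, dtype=np.uint8)
        inv = np.zeros(4, dtype=np.uint8)
        for val, b in enumerate(self.order):
            inv[_BASE_INDEX[b]] = val
        vals = inv[symbols]
        bits = np.empty(2 * symbols.size, dtype=np.uint8)
        bits[0::2] = vals >> 1
        bits[1::2] = vals & 1
        return bits


DEFAULT_MAPPING = BitBaseMapping()


@dataclass(frozen=True)
class BCHSpec:
    """Parameters of a (possibly shortened) binary BCH barcode code."""

    n: int
    k: int
    t: int
    s: int
    generator: np.ndarray  # GF(2) coefficients, ascending degree
    m: int
    mapping: BitBaseMapping = DEFAULT_MAPPING
    _field: GF2m = field(default=None, repr=False, compare=False)

    @property
    def k_prime(self) -> int:
        """Informative bits after shortening."""
        return self.k - self.s

    @property
    def N(self) -> int:
        """Barcode length in bases."""
        if self.s % 2 == 0:
            return (self.n + 1 - self.s) // 2
        return (self.n - self.s) // 2

    @property
    def b(self) -> int:
        """Guaranteed correctable base mismatches."""
        return self.t // 2

    @property
    def rate(self) -> float:
        return self.k / self.n

    @property
    def field(self) -> GF2m:
        fld = object.__getattribute__(self, "_field")
        if fld is None:
            fld = build_gf2m(self.m)
            object.__setattr__(self, "_field", fld)
        return fld

    @property
    def extended(self) -> bool:
        """True when an overall parity bit is appended (even s)."""
        return self.s % 2 == 0


def bch_build(n: int, t: int) -> BCHSpec:
    """Unshortened BCH code of length n = 2^m - 1 with designed capability t.

    The generator polynomial is the LCM of the minimal polynomials of
    alpha, alpha^2, ..., alpha^{2t}; k = n - deg(generator).
    """
    m = {15: 4, 31: 5, 63: 6}.get(n)
    if m is None:
        raise ValueError("code length n must be one of 15, 31, 63")
    fld = build_gf2m(m)
    gen = np.array([1], dtype=np.uint8)
    seen_cosets: set[int] = set()
    for e in range(1, 2 * t + 1):
        rep = e % fld.n
        coset = set()
        c = rep
        while c not in coset:
            coset.add(c)
            c = (2 * c) % fld.n
        key = min(coset)
        if key in seen_cosets:
            continue
        seen_cosets.add(key)
        gen = _gf2_poly_mul(gen, fld.minimal_polynomial(e))
    k = n - (len(gen) - 1)
    if k < 1:
        raise ValueError(f"t={t} infeasible for n={n}: no information bits left")
    return BCHSpec(n=n, k=k, t=t, s=0, generator=gen, m=m, _field=fld)


def shorten(spec: BCHSpec, s: int) -> BCHSpec:
    """Shorten by s bits: k' = k - s informative bits, redundancy unchanged."""
    if not 0 <= s < spec.k:
        raise ValueError(f"shortening depth s={s} must satisfy 0 <= s < k={spec.k}")
    return BCHSpec(
        n=spec.n, k=spec.k, t=spec.t, s=s, generator=spec.generator, m=spec.m,
        mapping=spec.mapping, _field=spec.field,
    )


def _gf2_poly_mul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    out = np.zeros(len(p) + len(q) - 1, dtype=np.uint8)
    for i, a in enumerate(p):
        if a:
            out[i : i + len(q)] ^= q
    return out


def _systematic_parity(spec: BCHSpec, info_bits: np.ndarray) -> np.ndarray:
    """Parity bits of m(x) x^{n-k} mod g(x) for the full-length info word."""
    r = spec.n - spec.k
    g = spec.generator  # ascending; degree r
    # long division of info(x)*x^r by g(x); info_bits[0] is the highest degree
    rem = np.zeros(spec.n, dtype=np.uint8)
    rem[:spec.k] = info_bits
    for i in range(spec.k):
        if rem[i]:
            # subtract g(x) aligned at degree (n-1-i)
            rem[i : i + r + 1] ^= g[::-1]
    parity = rem[spec.k :]
    return parity


def bch_encode(spec: BCHSpec, message: np.ndarray) -> np.ndarray:
    """Encode k' message bits to an N-base barcode (GF(4) symbol array).

    Systematic layout: the s shortened information positions are fixed to
    zero and omitted; the transmitted bits are [message | parity] with an
    appended overall even-parity bit when s is even.
    """
    message = np.asarray(message, dtype=np.uint8)
    if message.shape != (spec.k_prime,) or message.max(initial=0) > 1:
        raise ValueError(f"message must be {spec.k_prime} bits")
    info = np.zeros(spec.k, dtype=np.uint8)
    info[spec.s :] = message  # first s info bits are the shortened zeros
    parity = _systematic_parity(spec, info)
    bits = np.concatenate([message, parity])
    if spec.extended:
        bits = np.append(bits, bits.sum() % 2)
    return spec.mapping.pairs_to_symbols(bits)


def _berlekamp_massey(fld: GF2m, syndromes: list[int]) -> list[int]:
    """Error-locator polynomial (ascending coefficients) from 2t syndromes."""
    C = [1]
    B = [1]
    L = 0
    m_shift = 1
    b = 1
    for i, s_i in enumerate(syndromes):
        # discrepancy
        d = s_i
        for j in range(1, L + 1):
            if j < len(C) and C[j]:
                d ^= fld.mul(C[j], syndromes[i - j])
        if d == 0:
            m_shift += 1
        elif 2 * L <= i:
            T = C[:]
            coef = fld.mul(d, fld.inv(b))
            C = C + [0] * max(0, len(B) + m_shift - len(C))
            for j, bj in enumerate(B):
                if bj:
                    C[j + m_shift] ^= fld.mul(coef, bj)
            L = i + 1 - L
            B = T
            b = d
            m_shift = 1
        else:
            coef = fld.mul(d, fld.inv(b))
            C = C + [0] * max(0, len(B) + m_shift - len(C))
            for j, bj in enumerate(B):
                if bj:
                    C[j + m_shift] ^= fld.mul(coef, bj)
            m_shift += 1
    while len(C) > 1 and C[-1] == 0:
        C.pop()
    return C


def bch_decode(spec: BCHSpec, barcode: np.ndarray) -> DecodeOutcome:
    """Decode an N-base barcode; returns the corrected *message bits*.

    The outcome's ``word`` is the k'-bit message on success.  Failure is
    declared when Berlekamp–Massey/Chien cannot produce a consistent error
    pattern, or when a located error falls in a shortened coordinate (which
    is known to be zero, so an error there proves miscorrection).
    """
    barcode = np.asarray(barcode, dtype=np.uint8)
    if barcode.shape != (spec.N,):
        raise ValueError(f"barcode must have {spec.N} bases")
    bits = spec.mapping.symbols_to_pairs(barcode)
    ext_parity = None
    if spec.extended:
        ext_parity = int(bits[-1])
        bits = bits[:-1]
    # reinsert the s shortened zeros ahead of the transmitted info bits
    word = np.zeros(spec.n, dtype=np.uint8)
    word[spec.s : spec.k] = bits[: spec.k_prime]
    word[spec.k :] = bits[spec.k_prime :]

    fld = spec.field
    # syndromes S_j = r(alpha^j); bit i carries degree n-1-i
    ones = np.nonzero(word)[0]
    syndromes = []
    for jj in range(1, 2 * spec.t + 1):
        acc = 0
        for i in ones:
            acc ^= fld.pow_alpha(jj * (spec.n - 1 - int(i)))
        syndromes.append(acc)
    if not any(syndromes):
        return DecodeOutcome(
            word=word[spec.s : spec.k].copy(), status="success", iterations_used=1
        )
    locator = _berlekamp_massey(fld, syndromes)
    deg = len(locator) - 1
    if deg == 0 or deg > spec.t:
        return DecodeOutcome(word=None, status="failure", iterations_used=1)
    # Chien search: degree-d position has locator root alpha^{-d}
    error_bits = []
    for d in range(spec.n):
        val = 0
        for ci, c in enumerate(locator):
            if c:
                val ^= fld.mul(c, fld.pow_alpha((ci * (fld.n - d)) % fld.n))
        if val == 0:
            error_bits.append(spec.n - 1 - d)
    if len(error_bits) != deg:
        return DecodeOutcome(word=None, status="failure", iterations_used=1)
    if any(i < spec.s for i in error_bits):
        return DecodeOutcome(word=None, status="failure", iterations_used=1)
    corrected = word.copy()
    corrected[error_bits] ^= 1
    return DecodeOutcome(
        word=corrected[spec.s : spec.k].copy(), status="success", iterations_used=1
    )


def bounded_distance_decode(
    barcode_set: np.ndarray, received: np.ndarray, radius: int
) -> tuple[DecodeOutcome, int]:
    """Nearest-barcode decoding within a fixed Hamming radius.

    ``barcode_set`` is an (M, N) symbol array with verified minimum Hamming
    distance d_H; ``radius`` must be floor((d_H - 1)/2).  Returns the unique
    barcode within the radius (with its index) or a detected failure.  Two
    barcodes inside the radius violate the distance precondition and raise.
    """
    barcode_set = np.asarray(barcode_set, dtype=np.uint8)
    received = np.asarray(received, dtype=np.uint8)
    dists = (barcode_set != received[None, :]).sum(axis=1)
    hits = np.where(dists <= radius)[0]
    if hits.size > 1:
        raise ValueError(
            "two barcodes within the decoding radius: minimum-distance "
            "precondition violated"
        )
    if hits.size == 0:
        return DecodeOutcome(word=None, status="failure", iterations_used=1), -1
    idx = int(hits[0])
    return (
        DecodeOutcome(word=barcode_set[idx].copy(), status="success", iterations_used=1),
        idx,
    )
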