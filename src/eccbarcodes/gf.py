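"""Finite-field arithmetic for quaternary barcodes and binary BCH decoding.

Two small fields are needed:

* GF(4) = GF(2)[x]/(x^2+x+1) — the alphabet of barcode symbols.  Elements are
  the integers 0..3 whose 2-bit binary expansion is the polynomial coefficient
  vector, so addition is bitwise XOR and the bit<->base mapping used by the
  BCH layer is exact.
* GF(2^m), m in {4, 5, 6} — the extension fields over which BCH syndromes and
  error locators live (code lengths n = 2^m - 1 = 15, 31, 63).

Both are implemented with dense lookup tables; all operations accept numpy
arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GF4_ADD",
    "GF4_MUL",
    "GF4_INV",
    "gf4_add",
    "gf4_mul",
    "gf4_inv",
    "gf4_matmul",
    "GF2m",
    "build_gf2m",
]


def _build_gf4_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    add = np.zeros((4, 4), dtype=np.uint8)
    mul = np.zeros((4, 4), dtype=np.uint8)
    for a in range(4):
        for b in range(4):
            add[a, b] = a ^ b
            # polynomial multiplication mod x^2 + x + 1 on 2-bit operands
            prod = 0
            aa = a
            for bit in range(2):
                if (b >> bit) & 1:
                    prod ^= aa << bit
            # reduce bits 2..3 with x^2 = x + 1
            for bit in (3, 2):
                if (prod >> bit) & 1:
                    prod ^= (1 << bit) | (0b11 << (bit - 2))
            mul[a, b] = prod & 0b11
    inv = np.zeros(4, dtype=np.uint8)
    for a in range(1, 4):
        inv[a] = int(np.where(mul[a] == 1)[0][0])
    return add, mul, inv


GF4_ADD, GF4_MUL, GF4_INV = _build_gf4_tables()


def _check_gf4(*arrays) -> list[np.ndarray]:
    out = []
    for arr in arrays:
        a = np.asarray(arr)
        if a.size and (a.min() < 0 or a.max() > 3):
            raise ValueError("GF(4) elements must lie in {0,1,2,3}")
        out.append(a.astype(np.uint8))
    return out


def gf4_add(a, b):
    """Add two GF(4) elements (characteristic 2: a + a = 0)."""
    a, b = _check_gf4(a, b)
    return GF4_ADD[a, b]


def gf4_mul(a, b):
    """Multiply two GF(4) elements modulo x^2 + x + 1."""
    a, b = _check_gf4(a, b)
    return GF4_MUL[a, b]


def gf4_inv(a):
    """Multiplicative inverse in GF(4); raises on zero."""
    (a,) = _check_gf4(a)
    if np.any(a == 0):
        raise ZeroDivisionError("0 has no multiplicative inverse in GF(4)")
    return GF4_INV[a]


def gf4_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix product over GF(4).

    ``A`` is (r, t), ``B`` is (t, c); the result is the (r, c) GF(4) product.
    Used for encoding (s.G), syndromes (H.c) and duality checks (G.H^T).
    """
    A, B = _check_gf4(A, B)
    prods = GF4_MUL[A[:, :, None], B[None, :, :]]  # (r, t, c)
    return np.bitwise_xor.reduce(prods, axis=1)


_PRIMITIVE_POLY = {4: 0b10011, 5: 0b100101, 6: 0b1000011}


class GF2m:
    """GF(2^m) with log/antilog tables generated by a primitive polynomial.

    The conventional primitive polynomials x^4+x+1, x^5+x^2+1 and x^6+x+1 are
    used; any primitive choice yields an equivalent BCH code, so code
    equivalence rather than bit-identity is the contract.
    """

    def __init__(self, m: int):
        if m not in _PRIMITIVE_POLY:
            raise ValueError(f"unsupported extension degree m={m}; need m in {{4,5,6}}")
        self.m = m
        self.order = 2**m
        self.n = self.order - 1  # multiplicative group order; BCH length
        self.primitive_polynomial = _PRIMITIVE_POLY[m]

        exp = np.zeros(2 * self.n, dtype=np.int64)
        log = np.zeros(self.order, dtype=np.int64)
        x = 1
        for i in range(self.n):
            exp[i] = x
            log[x] = i
            x <<= 1
            if x & self.order:
                x ^= self.primitive_polynomial
        if x != 1:
            raise RuntimeError("polynomial is not primitive")  # pragma: no cover
        exp[self.n :] = exp[: self.n]
        self.exp = exp
        self.log = log

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return int(self.exp[self.log[a] + self.log[b]])

    def inv(self, a: int) -> int:
        if a == 0:
            raise ZeroDivisionError("0 has no inverse")
        return int(self.exp[self.n - self.log[a]])

    def pow_alpha(self, e: int) -> int:
        """alpha**e for the primitive element alpha."""
        return int(self.exp[e % self.n])

    # -- polynomial helpers (coefficient lists, ascending degree, GF(2^m)) --

    def poly_eval(self, coeffs: np.ndarray, x: int) -> int:
        acc = 0
        for c in reversed(coeffs):
            acc = self.mul(acc, x) ^ int(c)
        return acc

    def poly_mul(self, p, q) -> np.ndarray:
        out = np.zeros(len(p) + len(q) - 1, dtype=np.int64)
        for i, a in enumerate(p):
            if a == 0:
                continue
            for j, b in enumerate(q):
                out[i + j] ^= self.mul(int(a), int(b))
        return out

    def minimal_polynomial(self, e: int) -> np.ndarray:
        """Minimal polynomial of alpha**e over GF(2), via its cyclotomic coset.

        Returned as a GF(2) coefficient array (ascending degree).
        """
        coset = set()
        c = e % self.n
        while c not in coset:
            coset.add(c)
            c = (2 * c) % self.n
        poly = np.array([1], dtype=np.int64)
        for c in coset:
            poly = self.poly_mul(poly, [self.pow_alpha(c), 1])  # (x - alpha^c)
        if poly.max() > 1:
            raise RuntimeError("minimal polynomial not binary")  # pragma: no cover
        return poly.astype(np.uint8)


def build_gf2m(m: int) -> GF2m:
    """Construct GF(2^m) for m in {4, 5, 6}."""
    return GF2m(m)
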