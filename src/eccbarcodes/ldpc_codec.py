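"""Encoding and iterative decoding of quaternary LDPC barcodes.

Decoding is belief propagation (sum-product) on the code's factor graph over
GF(4).  Channel priors come from the quaternary symmetric channel: a received
symbol keeps its value with probability 1 - p_s and is any of the other three
with probability p_s/3 each.  Check-node updates are GF(4) convolutions,
computed through the 4-point Hadamard transform of the additive group
(Z/2)^2 — the convolution theorem turns the convolution into an entrywise
product.  After every iteration the entrywise-argmax word is tested against
the parity checks; the decoder stops early on a zero syndrome and otherwise
reports a *detected failure* after ``max_iterations`` — the event counted by
the read-loss probability p_d.

The batch decoder is vectorised over received words; the scalar
:func:`bp_decode` is a convenience wrapper around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gf import GF4_INV, GF4_MUL, gf4_matmul
from .ldpc_design import LDPCCodeSpec, ParityCheckMatrix

__all__ = [
    "DecodeOutcome",
    "encode",
    "encode_batch",
    "syndrome",
    "syndrome_batch",
    "BPDecoder",
    "bp_decode",
    "classify_outcome",
    "classify_batch",
]

CORRECT = "correct"
UNDETECTED = "undetected_error"
DETECTED = "detected_failure"

_PROB_FLOOR = 1e-30

# 4-point transform of (Z/2)^2: F[u, a] = (-1)^popcount(u & a); F @ F = 4 I.
_F = np.array(
    [[(-1) ** bin(u & a).count("1") for a in range(4)] for u in range(4)],
    dtype=np.float64,
)


@dataclass(frozen=True)
class DecodeOutcome:
    """Result of one decode: the word (if any), status, iterations used."""

    word: np.ndarray | None
    status: str  # "success" | "failure"
    iterations_used: int

    @property
    def success(self) -> bool:
        return self.status == "success"


def encode(spec: LDPCCodeSpec, message: np.ndarray) -> np.ndarray:
    """Codeword c = s.G over GF(4) for a length-k message s."""
    message = np.asarray(message, dtype=np.uint8)
    if message.shape != (spec.k,):
        raise ValueError(f"message must have length k={spec.k}")
    return gf4_matmul(message[None, :], spec.G)[0]


def encode_batch(spec: LDPCCodeSpec, messages: np.ndarray) -> np.ndarray:
    """Row-wise encoding of a (B, k) message array to (B, n) codewords."""
    messages = np.asarray(messages, dtype=np.uint8)
    if messages.ndim != 2 or messages.shape[1] != spec.k:
        raise ValueError(f"messages must be (B, {spec.k})")
    return gf4_matmul(messages, spec.G)


def syndrome(H: ParityCheckMatrix, word: np.ndarray) -> np.ndarray:
    """H.c over GF(4); the all-zero vector iff ``word`` is a codeword."""
    word = np.asarray(word, dtype=np.uint8)
    if word.shape != (H.n,):
        raise ValueError(f"word must have length n={H.n}")
    return syndrome_batch(H.entries, word[None, :])[0]


def syndrome_batch(H: np.ndarray, words: np.ndarray) -> np.ndarray:
    """(B, m) syndromes of a (B, n) batch of words."""
    prods = GF4_MUL[H[None, :, :], words[:, None, :]]
    return np.bitwise_xor.reduce(prods, axis=2)


class BPDecoder:
    """Sum-product decoder for a quaternary LDPC code under QSC priors.

    Parameters
    ----------
    spec : LDPCCodeSpec
        The code (H is taken from it; G is not needed for decoding).
    p_s : float
        Per-base mismatch probability, 0 < p_s < 3/4 (p_s = 3/4 would make
        the channel output independent of the input).
    max_iterations : int
        Iteration budget, counting the initial syndrome screen of the
        received word as iteration 1.
    """

    def __init__(self, spec: LDPCCodeSpec, p_s: float, max_iterations: int = 50):
        if not 0.0 < p_s < 0.75:
            raise ValueError("p_s must lie strictly between 0 and 3/4")
        self.spec = spec
        self.p_s = float(p_s)
        self.max_iterations = int(max_iterations)
        self.last_norm_error = 0.0  # max |sum(message) - 1| seen in last call

        H = spec.H.entries
        m, n = H.shape
        self.H = H
        checks, vars_ = np.nonzero(H)
        vals = H[checks, vars_]
        E = checks.size
        self._e_var = vars_
        # slot of each edge within its check row / variable column
        ce_slot = np.zeros(E, dtype=np.int64)
        counts = {}
        for e, c in enumerate(checks):
            ce_slot[e] = counts.get(c, 0)
            counts[c] = ce_slot[e] + 1
        vmax = max(counts.values())
        self._ce = (checks, ce_slot, int(vmax), m)
        ve_slot = np.zeros(E, dtype=np.int64)
        counts = {}
        for e, v in enumerate(vars_):
            ve_slot[e] = counts.get(v, 0)
            counts[v] = ve_slot[e] + 1
        j = max(counts.values())
        var_edges = np.full((n, j), -1, dtype=np.int64)
        for e, (v, s) in enumerate(zip(vars_, ve_slot)):
            var_edges[v, s] = e
        if (var_edges < 0).any():
            raise ValueError("column weight is not uniform")
        self._var_edges = var_edges
        self._j = j
        flat = np.zeros(E, dtype=np.int64)
        for v in range(n):
            for s in range(j):
                flat[var_edges[v, s]] = v * j + s
        self._var_edge_flat = flat
        # symbol permutations mapping code-domain beliefs to the x = h*c
        # domain where every check reads sum(x) = 0, and back
        self._perm_to_x = GF4_MUL[GF4_INV[vals]][:, :]  # (E,4): x -> c index
        self._perm_from_x = GF4_MUL[vals][:, :]  # (E,4): c -> x index

    # ------------------------------------------------------------------

    def _priors(self, received: np.ndarray) -> np.ndarray:
        B, n = received.shape
        P = np.full((B, n, 4), self.p_s / 3.0)
        idx = np.ogrid[:B, :n]
        P[idx[0], idx[1], received] = 1.0 - self.p_s
        return P

    def decode_batch(
        self, received: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Decode a (B, n) batch.

        Returns ``(words, success, iterations)`` where ``words`` is (B, n)
        (the received word is echoed for failures), ``success`` is a boolean
        mask and ``iterations`` counts syndrome tests performed per word.
        """
        received = np.asarray(received, dtype=np.uint8)
        if received.ndim != 2 or received.shape[1] != self.spec.n:
            raise ValueError(f"received must be (B, {self.spec.n})")
        B = received.shape[0]
        out_words = received.copy()
        out_success = np.zeros(B, dtype=bool)
        out_iters = np.full(B, 1, dtype=np.int64)
        self.last_norm_error = 0.0

        synd = syndrome_batch(self.H, received)
        clean = ~synd.any(axis=1)
        out_success[clean] = True
        active = np.where(~clean)[0]
        if active.size == 0 or self.max_iterations <= 1:
            return out_words, out_success, out_iters

        P = self._priors(received[active])
        checks, ce_slot, vmax, m = self._ce
        E = checks.size
        j = self._j
        erange = np.arange(E)
        Q = P[:, self._e_var, :]

        for it in range(2, self.max_iterations + 1):
            Ba = active.size
            # ---- check-node update (x-domain, transform trick) ----
            Qx = Q[:, erange[:, None], self._perm_to_x]
            T = Qx @ _F
            Tg = np.ones((Ba, m, vmax, 4))
            Tg[:, checks, ce_slot] = T
            pre = np.ones_like(Tg)
            np.cumprod(Tg[:, :, :-1], axis=2, out=pre[:, :, 1:])
            suf = np.ones_like(Tg)
            np.cumprod(Tg[:, :, :0:-1], axis=2, out=suf[:, :, -2::-1])
            loo = pre * suf
            Rx = (loo[:, checks, ce_slot] @ _F) * 0.25
            R = Rx[:, erange[:, None], self._perm_from_x]
            np.clip(R, _PROB_FLOOR, None, out=R)
            R /= R.sum(axis=2, keepdims=True)

            # ---- posterior & tentative word ----
            Rg = R[:, self._var_edges]  # (Ba, n, j, 4)
            prodR = Rg.prod(axis=2)
            post = P * prodR
            post /= post.sum(axis=2, keepdims=True)
            hard = post.argmax(axis=2).astype(np.uint8)  # ties -> smaller symbol
            synd = syndrome_batch(self.H, hard)
            done = ~synd.any(axis=1)
            out_iters[active] = it
            if done.any():
                idx = active[done]
                out_words[idx] = hard[done]
                out_success[idx] = True
                keep = ~done
                active = active[keep]
                if active.size == 0:
                    break
                P, R, Rg, prodR = P[keep], R[keep], Rg[keep], prodR[keep]

            if it == self.max_iterations:
                break

            # ---- variable-node update (leave-one-out over the j checks) ----
            loo_var = np.empty_like(Rg)
            for s in range(j):
                others = [t for t in range(j) if t != s]
                prod = Rg[:, :, others[0]].copy()
                for t in others[1:]:
                    prod *= Rg[:, :, t]
                loo_var[:, :, s] = prod
            Qg = P[:, :, None, :] * loo_var
            Qg /= Qg.sum(axis=3, keepdims=True)
            Q = Qg.reshape(Qg.shape[0], self.spec.n * j, 4)[:, self._var_edge_flat]
            err = np.abs(Q.sum(axis=2) - 1.0).max() if Q.size else 0.0
            self.last_norm_error = max(self.last_norm_error, float(err))

        return out_words, out_success, out_iters


def bp_decode(
    spec: LDPCCodeSpec,
    received: np.ndarray,
    p_s: float,
    max_iterations: int = 50,
) -> DecodeOutcome:
    """Decode a single received word; see :class:`BPDecoder`."""
    dec = BPDecoder(spec, p_s, max_iterations)
    words, success, iters = dec.decode_batch(np.asarray(received)[None, :])
    if success[0]:
        return DecodeOutcome(word=words[0], status="success", iterations_used=int(iters[0]))
    return DecodeOutcome(word=None, status="failure", iterations_used=int(iters[0]))


def classify_outcome(outcome: DecodeOutcome, transmitted: np.ndarray) -> str:
    """Partition a decode into correct / undetected_error / detected_failure.

    Undetected errors (a *wrong* codeword accepted by the decoder) feed the
    sample-misassignment probability p_u; detected failures feed the
    read-loss probability p_d.
    """
    if outcome.status == "failure":
        return DETECTED
    if np.array_equal(outcome.word, np.asarray(transmitted, dtype=np.uint8)):
        return CORRECT
    return UNDETECTED


def classify_batch(
    words: np.ndarray, success: np.ndarray, transmitted: np.ndarray
) -> tuple[int, int, int]:
    """Counts (correct, undetected, detected) for a decoded batch."""
    equal = (words == transmitted).all(axis=1)
    n_correct = int((success & equal).sum())
    n_undetected = int((success & ~equal).sum())
    n_detected = int((~success).sum())
    return n_correct, n_undetected, n_detected
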