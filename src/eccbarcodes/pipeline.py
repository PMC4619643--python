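"""From a code to a deployable barcode set.

Codewords become barcodes in three steps: symbols are permuted by an
S-random interleaver (breaking homopolymer runs and decorrelating channel
errors), the resulting sequences are screened against sequencing-chemistry
constraints (longest homopolymer run, G+C content), and survivors are
numbered as samples.  The set's multiplexing capacity M is the number of
surviving sequences and its barcoding rate is B = log4(M)/N, the fraction of
informative quads per base; chemistry screening only removes candidates, so
B <= k/n always.

For small message spaces (q^k up to 10^7) enumeration is exhaustive and M is
exact; beyond that a Monte Carlo sample of messages estimates M with a
binomial standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bch import BCHSpec, bch_encode, symbols_to_seq
from .ldpc_codec import encode_batch
from .ldpc_design import LDPCCodeSpec

__all__ = [
    "Interleaver",
    "ChemistryConstraints",
    "BarcodeSet",
    "build_srandom_interleaver",
    "identity_interleaver",
    "default_spread",
    "apply_interleaver",
    "deinterleave",
    "passes_chemistry",
    "chemistry_mask",
    "enumerate_barcodes",
    "barcoding_rate",
    "barcode_set_from_code",
]


@dataclass(frozen=True)
class Interleaver:
    """A permutation of barcode positions with spread parameter S.

    ``permutation[i]`` is the output position of input symbol i.  The
    S-spread property: any two inputs within distance S land more than S
    apart.
    """

    permutation: np.ndarray
    spread: int

    def __post_init__(self):
        perm = np.asarray(self.permutation, dtype=np.int64)
        object.__setattr__(self, "permutation", perm)
        if sorted(perm.tolist()) != list(range(perm.size)):
            raise ValueError("not a permutation")

    @property
    def N(self) -> int:
        return self.permutation.size

    def satisfies_spread(self, S: int | None = None) -> bool:
        S = self.spread if S is None else S
        p = self.permutation
        for i in range(self.N):
            for j in range(i + 1, min(i + S + 1, self.N)):
                if abs(int(p[i]) - int(p[j])) <= S:
                    return False
        return True


def default_spread(N: int) -> int:
    """Feasibility heuristic S = floor(sqrt(N/2)) for S-random interleavers."""
    return int(np.sqrt(N / 2))


def identity_interleaver(N: int) -> Interleaver:
    return Interleaver(permutation=np.arange(N), spread=0)


def build_srandom_interleaver(
    N: int,
    S: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 200,
) -> Interleaver:
    """Semirandom (S-random) interleaver on N positions.

    Output positions are drawn one input at a time, rejecting candidates
    that would put two inputs within distance S at outputs within distance
    S; a stuck draw restarts with fresh randomness.  If ``max_attempts``
    restarts fail, the spread is relaxed to S-1 with a warning.
    """
    rng = np.random.default_rng(rng)
    if S is None:
        S = default_spread(N)
    if S < 0:
        raise ValueError("spread must be >= 0")
    if S == 0:
        return Interleaver(permutation=rng.permutation(N), spread=0)
    for _ in range(max_attempts):
        perm = np.full(N, -1, dtype=np.int64)
        avail = set(range(N))
        ok = True
        for i in range(N):
            recent = perm[max(0, i - S) : i]
            cands = [p for p in avail if all(abs(p - int(r)) > S for r in recent)]
            if not cands:
                ok = False
                break
            choice = int(rng.choice(np.array(sorted(cands))))
            perm[i] = choice
            avail.discard(choice)
        if ok:
            return Interleaver(permutation=perm, spread=S)
    warnings.warn(
        f"S-random interleaver infeasible at S={S} after {max_attempts} "
        f"attempts; falling back to S={S - 1}"
    )
    return build_srandom_interleaver(N, S - 1, rng, max_attempts)


def apply_interleaver(seq: np.ndarray, ivl: Interleaver) -> np.ndarray:
    """Permute symbols: output position perm[i] carries input symbol i.

    Accepts a length-N sequence or an (M, N) batch.
    """
    seq = np.asarray(seq)
    if seq.shape[-1] != ivl.N:
        raise ValueError(f"sequence length must be {ivl.N}")
    out = np.empty_like(seq)
    out[..., ivl.permutation] = seq
    return out


def deinterleave(seq: np.ndarray, ivl: Interleaver) -> np.ndarray:
    """Inverse of :func:`apply_interleaver`."""
    seq = np.asarray(seq)
    if seq.shape[-1] != ivl.N:
        raise ValueError(f"sequence length must be {ivl.N}")
    return seq[..., ivl.permutation]


@dataclass(frozen=True)
class ChemistryConstraints:
    """Screening rules adapted from pyrosequencing barcode design tools."""

    max_homopolymer_run: int = 2
    gc_min: float = 0.40
    gc_max: float = 0.60

    def __post_init__(self):
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.max_homopolymer_run < 1:
            raise ValueError("max_homopolymer_run must be >= 1")

    @classmethod
    def unconstrained(cls, N: int) -> "ChemistryConstraints":
        return cls(max_homopolymer_run=max(N, 1), gc_min=0.0, gc_max=1.0)


def _max_runs(symbols: np.ndarray) -> np.ndarray:
    """Longest single-symbol run per row of an (M, N) symbol array."""
    eq = symbols[:, 1:] == symbols[:, :-1]
    cur = np.ones(symbols.shape[0], dtype=np.int64)
    best = cur.copy()
    for col in range(eq.shape[1]):
        cur = np.where(eq[:, col], cur + 1, 1)
        np.maximum(best, cur, out=best)
    return best


def chemistry_mask(symbols: np.ndarray, c: ChemistryConstraints) -> np.ndarray:
    """Boolean pass mask for an (M, N) GF(4) symbol array (C=1, G=2)."""
    symbols = np.asarray(symbols, dtype=np.uint8)
    if symbols.ndim != 2 or symbols.shape[1] == 0:
        raise ValueError("need a non-empty (M, N) symbol array")
    if symbols.max(initial=0) > 3:
        raise ValueError("symbols must be GF(4) values 0..3 (ACGT)")
    runs_ok = _max_runs(symbols) <= c.max_homopolymer_run
    gc = ((symbols == 1) | (symbols == 2)).mean(axis=1)
    # tiny epsilon so fractions like 0.6 = 3/5 are not lost to binary rounding
    eps = 1e-9
    gc_ok = (gc >= c.gc_min - eps) & (gc <= c.gc_max + eps)
    return runs_ok & gc_ok


def passes_chemistry(seq, c: ChemistryConstraints) -> tuple[bool, str | None]:
    """Check one sequence; the reason names the first failed rule."""
    from .bch import seq_to_symbols

    symbols = seq_to_symbols(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if symbols.size == 0:
        raise ValueError("empty sequence")
    arr = symbols[None, :]
    if _max_runs(arr)[0] > c.max_homopolymer_run:
        return False, "homopolymer"
    if not chemistry_mask(arr, c)[0]:
        return False, "gc"
    return True, None


@dataclass(frozen=True)
class BarcodeSet:
    """The deployable product: M chemistry-valid barcodes of length N.

    ``codewords`` are the pre-interleaving code-domain sequences (GF(4)
    symbols for LDPC; mapped base symbols for BCH) and ``barcodes`` the
    transmitted, interleaved sequences.  Sample IDs are ordinals in
    lexicographic message order after filtering.
    """

    barcodes: np.ndarray  # (M, N) uint8 symbols, post-interleaving
    codewords: np.ndarray  # (M, N) uint8 symbols, pre-interleaving
    messages: np.ndarray  # (M, k) message symbols/bits
    code_spec: object  # LDPCCodeSpec | BCHSpec | None (random sets)
    interleaver: Interleaver
    constraints: ChemistryConstraints
    mode: str = "exhaustive"
    total_messages: int = 0  # q^k of the unfiltered message space
    m_hat: float | None = None  # Monte Carlo estimate of M (montecarlo mode)
    m_hat_se: float | None = None
    d_min: int | None = None  # verified minimum distance (random sets)

    @property
    def M(self) -> int:
        return self.barcodes.shape[0]

    @property
    def N(self) -> int:
        return self.barcodes.shape[1]

    @property
    def B(self) -> float:
        return barcoding_rate(self.M, self.N)

    def sequences(self) -> list[str]:
        return [symbols_to_seq(row) for row in self.barcodes]


def barcoding_rate(M: int, N: int) -> float:
    """B = log4(M)/N, the informative quads per barcode base."""
    if M < 1 or N < 1:
        raise ValueError("need M >= 1 and N >= 1")
    return float(np.log(M) / np.log(4.0) / N)


def _enumerate_messages(q: int, k: int) -> np.ndarray:
    """All q^k length-k messages in lexicographic order, as an array."""
    grids = np.meshgrid(*[np.arange(q, dtype=np.uint8)] * k, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _encode_messages(code_spec, messages: np.ndarray) -> np.ndarray:
    if isinstance(code_spec, LDPCCodeSpec):
        return encode_batch(code_spec, messages)
    if isinstance(code_spec, BCHSpec):
        return np.stack([bch_encode(code_spec, msg) for msg in messages])
    raise TypeError(f"unsupported code spec {type(code_spec).__name__}")


def enumerate_barcodes(
    code_spec,
    ivl: Interleaver | None = None,
    constraints: ChemistryConstraints | None = None,
    mode: str = "exhaustive",
    sample_size: int = 100_000,
    rng: np.random.Generator | None = None,
) -> BarcodeSet:
    """Encode, interleave and chemistry-screen the code's message space.

    Exhaustive mode (q^k <= 10^7) returns the exact multiplexing capacity M;
    Monte Carlo mode samples ``sample_size`` messages and reports
    M_hat = q^k * pass_fraction with its binomial standard error, keeping
    the sampled survivors as the barcode list.
    """
    if isinstance(code_spec, LDPCCodeSpec):
        q, k = 4, code_spec.k
    elif isinstance(code_spec, BCHSpec):
        q, k = 2, code_spec.k_prime
    else:
        raise TypeError(f"unsupported code spec {type(code_spec).__name__}")
    total = q**k
    if constraints is None:
        constraints = ChemistryConstraints()

    if mode == "exhaustive":
        if total > 10**7:
            raise ValueError(
                f"q^k = {total} too large for exhaustive screening; "
                "use mode='montecarlo'"
            )
        messages = _enumerate_messages(q, k)
    elif mode == "montecarlo":
        rng = np.random.default_rng(rng)
        messages = rng.integers(0, q, size=(sample_size, k)).astype(np.uint8)
        # lexicographic ID order within the sample
        order = np.lexsort(messages.T[::-1])
        messages = messages[order]
    else:
        raise ValueError("mode must be 'exhaustive' or 'montecarlo'")

    codewords = _encode_messages(code_spec, messages)
    if ivl is None:
        ivl = identity_interleaver(codewords.shape[1])
    barcodes = apply_interleaver(codewords, ivl)
    mask = chemistry_mask(barcodes, constraints)

    m_hat = m_hat_se = None
    if mode == "montecarlo":
        frac = mask.mean()
        m_hat = total * float(frac)
        m_hat_se = total * float(np.sqrt(frac * (1 - frac) / mask.size))
    return BarcodeSet(
        barcodes=barcodes[mask],
        codewords=codewords[mask],
        messages=messages[mask],
        code_spec=code_spec,
        interleaver=ivl,
        constraints=constraints,
        mode=mode,
        total_messages=total,
        m_hat=m_hat,
        m_hat_se=m_hat_se,
    )


def barcode_set_from_code(
    code_spec,
    unconstrained: bool = False,
    ivl: Interleaver | None = None,
    rng: np.random.Generator | None = None,
) -> BarcodeSet:
    """Convenience wrapper: full barcode set for a code.

    With ``unconstrained=True`` the chemistry filter passes everything and
    the identity interleaver is used — the configuration for channel
    benchmarking of the bare code, where screening is irrelevant to the
    decoder's error rates.
    """
    n = code_spec.n if isinstance(code_spec, LDPCCodeSpec) else code_spec.N
    constraints = ChemistryConstraints.unconstrained(n) if unconstrained else None
    if ivl is None and not unconstrained:
        ivl = build_srandom_interleaver(n, rng=np.random.default_rng(rng))
    return enumerate_barcodes(code_spec, ivl=ivl, constraints=constraints)
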