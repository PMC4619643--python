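"""Construction and selection of short quaternary LDPC parity-check matrices.

Short LDPC codes for DNA barcoding (a few tens of symbols) are built in two
stages: the *support* of the sparse parity-check matrix H is optimised with
the Progressive Edge Growth (PEG) algorithm, which places Tanner-graph edges
greedily so as to maximise local girth; the non-zero entries are then filled
with random values from {1, 2, 3} in GF(4).

Candidate fills are ranked with a diversity score

    D(H) = (mu_hc - sigma_hc) * (mu_dr - sigma_dr)

where (mu_hc, sigma_hc) are the mean and standard deviation of the normalised
pairwise Hamming distances between columns of H and (mu_dr, sigma_dr) those
of the pairwise cosine dissimilarities between rows.  High column diversity
pushes the minimum distance up (d_min equals the smallest number of linearly
dependent columns of H); high row diversity decorrelates the component
parity subcodes seen by the iterative decoder.  The best-scoring fill out of
a pool (default 1000) defines the code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .gf import GF4_INV, GF4_MUL, gf4_matmul

__all__ = [
    "ParityCheckMatrix",
    "DiversityStats",
    "LDPCCodeSpec",
    "peg_construct",
    "quaternary_fill",
    "diversity_stats",
    "gf4_rref",
    "gf4_rank",
    "generator_from_parity",
    "select_best",
    "validate_dscore",
]


@dataclass(frozen=True)
class ParityCheckMatrix:
    """An m x n parity-check matrix over GF(4) with column weight j."""

    entries: np.ndarray  # (m, n) uint8, values 0..3
    j: int

    def __post_init__(self):
        H = np.ascontiguousarray(np.asarray(self.entries, dtype=np.uint8))
        object.__setattr__(self, "entries", H)
        if H.ndim != 2:
            raise ValueError("H must be 2-dimensional")
        if H.max(initial=0) > 3:
            raise ValueError("entries must be GF(4) values 0..3")
        colw = (H != 0).sum(axis=0)
        if not np.all(colw == self.j):
            raise ValueError(f"every column must have exactly j={self.j} non-zeros")

    @property
    def m(self) -> int:
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        return self.entries.shape[1]

    @property
    def row_weights(self) -> np.ndarray:
        return (self.entries != 0).sum(axis=1)

    def is_regular(self) -> bool:
        """True when n*j = m*v holds for an integral row weight v."""
        return (self.j * self.n) % self.m == 0 and bool(
            np.all(self.row_weights == self.j * self.n // self.m)
        )


@dataclass(frozen=True)
class DiversityStats:
    mu_hc: float
    sigma_hc: float
    mu_dr: float
    sigma_dr: float

    @property
    def d_score(self) -> float:
        return (self.mu_hc - self.sigma_hc) * (self.mu_dr - self.sigma_dr)


@dataclass(frozen=True)
class LDPCCodeSpec:
    """A quaternary LDPC code: parity-check matrix H and generator G.

    G spans the null space of H over GF(4) (G.H^T = 0) and is systematic on
    the identified information set.  ``rank_deficient`` flags candidates
    where rank(H) < m, i.e. k > n - m.
    """

    H: ParityCheckMatrix
    G: np.ndarray  # (k, n) uint8
    rank_deficient: bool = False
    info_set: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.H.n

    @property
    def k(self) -> int:
        return self.G.shape[0]


def peg_construct(n: int, m: int, j: int, rng: np.random.Generator) -> np.ndarray:
    """Binary m x n PEG template with exactly j ones per column.

    Edges are placed one variable node at a time.  The first edge of a
    variable goes to a minimum-degree check; each subsequent edge goes to a
    check node as far as possible from the variable in the current subgraph
    (an unreachable check if one exists, otherwise one at maximal BFS depth),
    with ties broken by lowest current degree then lowest index.  ``rng``
    shuffles nothing: construction is deterministic given (n, m, j); it is
    accepted for interface symmetry with the quaternary fill stage.
    """
    if j > m:
        raise ValueError(f"infeasible design: column weight j={j} exceeds m={m}")
    if m >= n:
        raise ValueError("need m < n for a code with k >= 1")

    H = np.zeros((m, n), dtype=np.uint8)
    check_deg = np.zeros(m, dtype=np.int64)
    var_nbrs: list[list[int]] = [[] for _ in range(n)]
    check_nbrs: list[list[int]] = [[] for _ in range(m)]

    def farthest_checks(v: int) -> np.ndarray:
        """BFS depth of every check node from variable v; -1 if unreachable."""
        depth = np.full(m, -1, dtype=np.int64)
        seen_v = np.zeros(n, dtype=bool)
        seen_v[v] = True
        frontier = list(var_nbrs[v])
        d = 0
        for c in frontier:
            depth[c] = 0
        while frontier:
            nxt_vars = []
            for c in frontier:
                for u in check_nbrs[c]:
                    if not seen_v[u]:
                        seen_v[u] = True
                        nxt_vars.append(u)
            frontier = []
            d += 1
            for u in nxt_vars:
                for c in var_nbrs[u]:
                    if depth[c] < 0:
                        depth[c] = d
                        frontier.append(c)
        return depth

    for v in range(n):
        for l in range(j):
            if l == 0:
                candidates = np.arange(m)
            else:
                depth = farthest_checks(v)
                unreached = np.where(depth < 0)[0]
                if unreached.size:
                    candidates = unreached
                else:
                    candidates = np.where(depth == depth.max())[0]
            # drop checks already wired to v (parallel edges not allowed)
            candidates = np.array([c for c in candidates if H[c, v] == 0])
            best_deg = check_deg[candidates].min()
            c = int(candidates[check_deg[candidates] == best_deg][0])
            H[c, v] = 1
            check_deg[c] += 1
            var_nbrs[v].append(c)
            check_nbrs[c].append(v)
    return H


def quaternary_fill(template: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace each 1 of a binary template by a uniform value from {1,2,3}."""
    template = np.asarray(template)
    out = np.zeros_like(template, dtype=np.uint8)
    support = template != 0
    out[support] = rng.integers(1, 4, size=int(support.sum()), dtype=np.uint8)
    return out


def diversity_stats(H: ParityCheckMatrix | np.ndarray) -> DiversityStats:
    """Column/row diversity statistics and the D score of a candidate H.

    Columns: all n(n-1)/2 pairwise Hamming distances between columns,
    comparing entries as GF(4) values and normalising by m.  Rows: all
    m(m-1)/2 pairwise cosine dissimilarities (1 - cosine similarity) between
    rows treated as real integer vectors; an all-zero row is assigned
    dissimilarity 1 against any other row.
    """
    M = H.entries if isinstance(H, ParityCheckMatrix) else np.asarray(H)
    m, n = M.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    Mf = M.astype(np.float64)
    col_d = pdist(Mf.T, metric="hamming")
    zero_rows = ~Mf.any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_d = pdist(Mf, metric="cosine")
    if zero_rows.any():  # cosine is undefined against a zero vector
        row_d = np.nan_to_num(row_d, nan=1.0)
    return DiversityStats(
        mu_hc=float(col_d.mean()),
        sigma_hc=float(col_d.std()),
        mu_dr=float(row_d.mean()),
        sigma_dr=float(row_d.std()),
    )


def gf4_rref(M: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Reduced row-echelon form over GF(4); returns (R, pivot columns)."""
    R = np.asarray(M, dtype=np.uint8).copy()
    rows, cols = R.shape
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        if r == rows:
            break
        nz = np.where(R[r:, c] != 0)[0]
        if nz.size == 0:
            continue
        p = r + int(nz[0])
        if p != r:
            R[[r, p]] = R[[p, r]]
        R[r] = GF4_MUL[GF4_INV[R[r, c]], R[r]]
        for i in range(rows):
            if i != r and R[i, c] != 0:
                R[i] ^= GF4_MUL[R[i, c], R[r]]
        pivots.append(c)
        r += 1
    return R, pivots


def gf4_rank(M: np.ndarray) -> int:
    return len(gf4_rref(M)[1])


def generator_from_parity(H: ParityCheckMatrix) -> LDPCCodeSpec:
    """Generator matrix G with G.H^T = 0, by Gaussian elimination over GF(4).

    k = n - rank(H); G is systematic (identity) on the non-pivot columns of
    the reduced H.  A rank-deficient H yields k > n - m and sets the
    ``rank_deficient`` flag so callers may reject the candidate.
    """
    R, pivots = gf4_rref(H.entries)
    n = H.n
    free = np.array([c for c in range(n) if c not in set(pivots)], dtype=np.int64)
    k = free.size
    G = np.zeros((k, n), dtype=np.uint8)
    for idx, f in enumerate(free):
        G[idx, f] = 1
        for r, p in enumerate(pivots):
            G[idx, p] = R[r, f]  # -R[r,f] == R[r,f] in characteristic 2
    spec = LDPCCodeSpec(
        H=H, G=G, rank_deficient=len(pivots) < H.m, info_set=free
    )
    if np.any(gf4_matmul(G, H.entries.T)):
        raise RuntimeError("null-space construction failed")  # pragma: no cover
    return spec


def select_best(
    n: int,
    m: int,
    pool_size: int = 1000,
    rng: np.random.Generator | None = None,
    j: int = 3,
    return_pool: bool = False,
):
    """Best D-scoring quaternary fill out of a pool over one PEG template.

    A single binary PEG template is built for (n, m, j) and filled
    ``pool_size`` times with random GF(4) values; fills whose H is
    rank-deficient over GF(4) are discarded and regenerated, so k = n - m
    always holds for the returned code.  Ties in D are broken by generation
    order (first wins).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(rng)
    template = peg_construct(n, m, j, rng)
    pool: list[tuple[ParityCheckMatrix, float]] = []
    guard = 0
    while len(pool) < pool_size:
        H = ParityCheckMatrix(quaternary_fill(template, rng), j=j)
        if gf4_rank(H.entries) < m:
            guard += 1
            if guard > 50 * pool_size:
                raise RuntimeError("could not find full-rank fills")
            continue
        pool.append((H, diversity_stats(H).d_score))
    scores = np.array([s for _, s in pool])
    best = int(np.argmax(scores))  # argmax returns the first maximum: first wins
    if return_pool:
        return pool[best][0], pool
    return pool[best][0]


def validate_dscore(
    num_sets: int,
    set_size: int,
    n: int,
    m: int,
    p_s: float,
    trials: int,
    rng: np.random.Generator | None = None,
    j: int = 3,
) -> tuple[float, float]:
    """Spearman correlation between D scores and empirical log10 p_e.

    For each of ``num_sets`` sets a fresh PEG template is drawn and
    ``set_size`` random quaternary fills are scored; the best-D code of each
    set is simulated over the quaternary symmetric channel at mismatch rate
    ``p_s`` for ``trials`` decodes.  The returned coefficient is the plain
    Spearman rho between D and log10 p_e across the selected codes (a useful
    score should be negative: higher diversity, lower error rate).  Codes
    with zero observed errors are excluded with a warning; fewer than 3
    usable points or a constant D vector raises.
    """
    from .channel import ChannelModel, estimate_rates
    from .pipeline import barcode_set_from_code

    if num_sets < 3:
        raise ValueError("need at least 3 sets for a rank correlation")
    rng = np.random.default_rng(rng)
    points: list[tuple[float, float]] = []
    for _ in range(num_sets):
        template = peg_construct(n, m, j, rng)
        best_H, best_d = None, -np.inf
        picked = 0
        while picked < set_size:
            H = ParityCheckMatrix(quaternary_fill(template, rng), j=j)
            if gf4_rank(H.entries) < m:
                continue
            picked += 1
            d = diversity_stats(H).d_score
            if d > best_d:
                best_H, best_d = H, d
        spec = generator_from_parity(best_H)
        bset = barcode_set_from_code(spec, unconstrained=True, rng=rng)
        res = estimate_rates(
            bset, ChannelModel(p_s), T=1, C=trials, rng=rng
        )
        if res.p_e == 0:
            warnings.warn(
                "selected code had zero observed errors; excluded from the "
                "rank correlation (raise trials or p_s)"
            )
            continue
        points.append((best_d, np.log10(res.p_e)))
    if len(points) < 3:
        raise RuntimeError("fewer than 3 usable (D, log10 p_e) points")
    d_vals = np.array([p[0] for p in points])
    pe_vals = np.array([p[1] for p in points])
    if np.ptp(d_vals) == 0:
        raise RuntimeError("constant D scores: rank correlation undefined")
    rho, pval = spearmanr(d_vals, pe_vals)
    return float(rho), float(pval)
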