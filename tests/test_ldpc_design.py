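"""PEG templates, quaternary fills, the D diversity score and G derivation."""

import itertools

import numpy as np
import pytest

from eccbarcodes.gf import gf4_matmul
from eccbarcodes.ldpc_design import (
    DiversityStats,
    ParityCheckMatrix,
    diversity_stats,
    generator_from_parity,
    gf4_rank,
    peg_construct,
    quaternary_fill,
    select_best,
    validate_dscore,
)


class TestPEG:
    @pytest.mark.parametrize(
        "n,m", [(19, 15), (12, 9), (21, 16), (23, 17), (24, 17), (23, 19), (25, 20)]
    )
    def test_column_weight_and_girth(self, n, m, rng):
        T = peg_construct(n, m, 3, rng)
        assert np.all(T.sum(axis=0) == 3)
        # no 4-cycles: no two columns share more than one row
        overlap = T.T.astype(int) @ T.astype(int)
        np.fill_diagonal(overlap, 0)
        assert overlap.max() <= 1

    def test_regular_when_divisible(self, rng):
        # n*j = m*v with v = 4: the 12-symbol, 9-check configuration
        T = peg_construct(12, 9, 3, rng)
        assert np.all(T.sum(axis=1) == 4)

    def test_infeasible_degree(self, rng):
        with pytest.raises(ValueError):
            peg_construct(10, 3, 4, rng)
        with pytest.raises(ValueError):
            peg_construct(10, 10, 3, rng)


class TestQuaternaryFill:
    def test_support_preserved(self, rng):
        T = peg_construct(19, 15, 3, rng)
        H = quaternary_fill(T, rng)
        assert np.array_equal(H != 0, T != 0)
        assert set(np.unique(H[T != 0])) <= {1, 2, 3}
        assert quaternary_fill(np.zeros((4, 6), dtype=np.uint8), rng).sum() == 0

    def test_values_uniform(self, rng):
        T = peg_construct(12, 9, 3, rng)
        n_fill, reps = int(T.sum()), 10_000
        counts = np.zeros(4)
        for _ in range(reps):
            vals, cnt = np.unique(quaternary_fill(T, rng), return_counts=True)
            counts[vals] += cnt
        total = n_fill * reps
        p, sigma = 1 / 3, np.sqrt((1 / 3) * (2 / 3) / (n_fill * reps))
        for v in (1, 2, 3):
            assert abs(counts[v] / total - p) < 3 * sigma


class TestDiversityStats:
    def test_identical_columns_and_rows(self):
        H = ParityCheckMatrix(np.ones((2, 2), dtype=np.uint8), j=2)
        ds = diversity_stats(H)
        assert ds.mu_hc == 0
        assert ds.mu_dr == pytest.approx(0, abs=1e-12)
        assert ds.d_score == pytest.approx(0, abs=1e-12)

    def test_identity_matrix_hand_computation(self):
        ds = diversity_stats(np.eye(2, dtype=np.uint8))
        assert ds.mu_hc == pytest.approx(1.0)
        assert ds.sigma_hc == pytest.approx(0.0)
        assert ds.mu_dr == pytest.approx(1.0)  # orthogonal rows
        assert ds.sigma_dr == pytest.approx(0.0)
        assert ds.d_score == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        H = quaternary_fill(peg_construct(12, 9, 3, rng), rng)
        d0 = diversity_stats(H).d_score
        for _ in range(5):
            perm = H[rng.permutation(9)][:, rng.permutation(12)]
            assert diversity_stats(perm).d_score == pytest.approx(d0)

    def test_diverse_columns_beat_identical_columns(self):
        # same support pattern -> identical row statistics; columns all
        # distinct vs columns all equal
        base = np.array([[1, 1], [2, 3]], dtype=np.uint8)
        same = np.array([[1, 1], [2, 2]], dtype=np.uint8)
        assert diversity_stats(base).d_score > diversity_stats(same).d_score

    def test_zero_row_guard(self):
        H = np.array([[0, 0, 0], [1, 2, 3]], dtype=np.uint8)
        ds = diversity_stats(H)
        assert ds.mu_dr == pytest.approx(1.0)

    def test_bounds(self, rng):
        for _ in range(20):
            H = quaternary_fill(peg_construct(16, 12, 3, rng), rng)
            ds = diversity_stats(H)
            assert 0 <= ds.mu_hc <= 1 and ds.sigma_hc >= 0
            assert 0 <= ds.mu_dr <= 2 and ds.sigma_dr >= 0


class TestGeneratorFromParity:
    def test_duality_and_exhaustive_nullspace(self, ldpc_12_3):
        spec = ldpc_12_3
        H = spec.H
        assert spec.G.shape == (3, 12)
        assert not gf4_matmul(spec.G, H.entries.T).any()
        assert gf4_rank(spec.G) + gf4_rank(H.entries) == spec.n
        # every one of the 4^k codewords has zero syndrome (exhaustive, k=3)
        msgs = np.array(list(itertools.product(range(4), repeat=3)), dtype=np.uint8)
        cws = gf4_matmul(msgs, spec.G)
        assert not gf4_matmul(cws, H.entries.T).any()
        assert len({cw.tobytes() for cw in cws}) == 64

    def test_19_4_shape(self, ldpc_19_4):
        assert ldpc_19_4.G.shape == (4, 19)
        assert not ldpc_19_4.rank_deficient

    def test_rank_deficient_flagged(self):
        # third row is the sum of the first two: rank 2 < m = 3
        H = np.array(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 1]], dtype=np.uint8
        )
        spec = generator_from_parity(ParityCheckMatrix(H, j=2))
        assert spec.rank_deficient
        assert spec.k == 2  # n - rank = 4 - 2


class TestSelectBest:
    def test_argmax_contract(self, rng):
        best, pool = select_best(12, 9, pool_size=30, rng=rng, return_pool=True)
        best_score = diversity_stats(best).d_score
        assert all(best_score >= s for _, s in pool)
        assert gf4_rank(best.entries) == 9

    def test_pool_of_one(self, rng):
        H = select_best(12, 9, pool_size=1, rng=rng)
        assert isinstance(H, ParityCheckMatrix)

    def test_default_pool_size(self):
        import inspect

        assert inspect.signature(select_best).parameters["pool_size"].default == 1000

    def test_deterministic_given_seed(self):
        a = select_best(12, 9, pool_size=20, rng=np.random.default_rng(3))
        b = select_best(12, 9, pool_size=20, rng=np.random.default_rng(3))
        assert np.array_equal(a.entries, b.entries)


class TestValidateDscore:
    def test_too_few_sets(self, rng):
        with pytest.raises(ValueError):
            validate_dscore(2, 5, 12, 9, 0.05, 1000, rng)

    def test_zero_error_codes_excluded(self, rng):
        # p_s so small that no errors are ever seen -> all points excluded
        with pytest.warns(UserWarning), pytest.raises(RuntimeError):
            validate_dscore(3, 2, 12, 9, 1e-9, 200, rng)
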