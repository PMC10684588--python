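import numpy as np
import pandas as pd
import pytest

from diaclust.matrix import LOG2, IntensityMatrix
from diaclust.nmf import (
    consensus_cluster,
    cophenetic_correlation,
    dispersion,
    nmf_fit,
    pca_embed,
    relevance_scores,
    select_rank,
)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_cophenetic(C):
    """UPGMA agglomeration coded from scratch: cluster distance is the mean
    of original pairwise distances; cophenetic distance of a pair is the
    height at which their clusters merge."""
    n = C.shape[0]
    D = 1.0 - C
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1:]:
                dist = np.mean([D[i, j] for i in clusters[a]
                                for j in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = dist
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    iu = np.triu_indices(n, 1)
    x, y = D[iu], coph[iu]
    return float(np.corrcoef(x, y)[0, 1])


def random_consensus(seed, n=8):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 1, size=(n, n))
    C = (A + A.T) / 2
    np.fill_diagonal(C, 1.0)
    return C


def block_consensus(sizes):
    n = sum(sizes)
    C = np.zeros((n, n))
    start = 0
    for s in sizes:
        C[start:start + s, start:start + s] = 1.0
        start += s
    return C


# --------------------------------------------------------------------------
# nmf_fit
# --------------------------------------------------------------------------

class TestNMFFit:
    def test_exact_rank_one_input(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1, 2, size=(20, 1))
        h = rng.uniform(1, 2, size=(1, 10))
        V = w @ h
        W, H, errors = nmf_fit(V, k=1, seed=1, max_iter=2000, tol=0)
        rel = errors[-1] / np.linalg.norm(V)
        assert rel < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_error_sequence_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.uniform(0, 5, size=(15, 8))
        _, _, errors = nmf_fit(V, k=3, seed=seed, max_iter=200, tol=0)
        diffs = np.diff(errors)
        assert (diffs <= 1e-9).all()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 5, size=(12, 7))
        W1, H1, _ = nmf_fit(V, k=2, seed=42)
        W2, H2, _ = nmf_fit(V, k=2, seed=42)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            nmf_fit(np.array([[1.0, -0.1], [0.5, 2.0], [1.0, 1.0]]), k=1)

    def test_factors_nonnegative(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 5, size=(10, 6))
        W, H, _ = nmf_fit(V, k=3, seed=0)
        assert (W >= 0).all() and (H >= 0).all()

    def test_matches_sklearn_reconstruction_quality(self):
        # independent route: sklearn's multiplicative-update NMF should reach
        # a comparable Frobenius error on the same problem
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        V = rng.uniform(0.1, 5, size=(30, 12))
        _, _, errors = nmf_fit(V, k=4, seed=0, max_iter=1000, tol=1e-9)
        sk = NMF(n_components=4, solver="mu", beta_loss="frobenius",
                 init="random", random_state=0, max_iter=1000, tol=1e-9)
        Wk = sk.fit_transform(V)
        sk_err = np.linalg.norm(V - Wk @ sk.components_)
        assert errors[-1] <= sk_err * 1.05


# --------------------------------------------------------------------------
# consensus, dispersion, cophenetic
# --------------------------------------------------------------------------

class TestConsensus:
    def _two_block_V(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1, 2, size=20)
        V = np.tile(base[:, None], (1, 10)) + rng.normal(0, 0.01, (20, 10))
        V[:10, :5] += 5.0
        V[10:, 5:] += 5.0
        return np.abs(V)

    def test_perfect_blocks_give_exact_01_consensus(self):
        V = self._two_block_V()
        ids = [f"S{i}" for i in range(10)]
        res = consensus_cluster(V, ids, k=2, n_runs=10, seed=0)
        expected = block_consensus([5, 5])
        np.testing.assert_array_equal(res.consensus.to_numpy(), expected)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="n_runs"):
            consensus_cluster(np.ones((4, 3)) + np.eye(4, 3), ["a", "b", "c"],
                              k=2, n_runs=1, seed=0)

    def test_consensus_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        V = rng.uniform(0.5, 3, size=(15, 8))
        res = consensus_cluster(V, [f"S{i}" for i in range(8)], k=3,
                                n_runs=5, seed=1)
        C = res.consensus.to_numpy()
        np.testing.assert_array_equal(C, C.T)
        np.testing.assert_array_equal(np.diag(C), np.ones(8))
        assert C.min() >= 0 and C.max() <= 1


class TestDispersion:
    def test_perfect_block_consensus_is_one(self):
        assert dispersion(block_consensus([3, 5])) == pytest.approx(1.0)

    def test_half_matrix_with_unit_diagonal(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert dispersion(C) == pytest.approx(0.5)

    def test_all_half_matrix_is_zero(self):
        C = np.full((4, 4), 0.5)
        assert dispersion(C) == pytest.approx(0.0)

    @pytest.mark.parametrize("sizes", [[2, 2], [1, 3, 4], [5]])
    def test_ideal_blocks_any_partition(self, sizes):
        assert dispersion(block_consensus(sizes)) == pytest.approx(1.0)


class TestCophenetic:
    def test_perfect_blocks_give_one(self):
        C = block_consensus([3, 4])
        assert cophenetic_correlation(C) == pytest.approx(1.0)

    def test_constant_off_diagonal_undefined(self):
        C = np.full((4, 4), 0.3)
        np.fill_diagonal(C, 1.0)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(cophenetic_correlation(C))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        C = random_consensus(seed, n=8)
        ours = cophenetic_correlation(C)
        oracle = brute_force_cophenetic(C)
        assert ours == pytest.approx(oracle, abs=1e-12)


# --------------------------------------------------------------------------
# rank selection
# --------------------------------------------------------------------------

def _fake_sweep(coph, disp, k_start=2):
    out = []
    for i, (c, d) in enumerate(zip(coph, disp)):
        r = consensus_stub(k_start + i, c, d)
        out.append(r)
    return out


def consensus_stub(k, coph, disp):
    from diaclust.nmf import ConsensusResult

    n = 4
    return ConsensusResult(
        rank=k,
        consensus=pd.DataFrame(np.eye(n)),
        cophenetic=coph,
        dispersion=disp,
        labels=pd.Series(np.ones(n, dtype=int)),
        best_W=np.ones((5, k)),
        best_H=np.ones((k, n)),
        n_runs=2,
    )


class TestSelectRank:
    def test_joint_local_maximum(self):
        sweep = _fake_sweep([0.80, 0.85, 0.99, 0.90, 0.88],
                            [0.5, 0.6, 0.9, 0.7, 0.6])
        assert select_rank(sweep) == 4

    def test_decreasing_sequences_fall_back_to_global_max(self):
        sweep = _fake_sweep([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        with pytest.warns(UserWarning, match="local maximum"):
            assert select_rank(sweep) == 2

    def test_smallest_joint_peak_wins(self):
        sweep = _fake_sweep([0.8, 0.9, 0.7, 0.95, 0.6],
                            [0.5, 0.7, 0.5, 0.8, 0.4])
        assert select_rank(sweep) == 3

    def test_short_sweep_warns(self):
        sweep = _fake_sweep([0.7, 0.9], [0.5, 0.6])
        with pytest.warns(UserWarning, match="shorter"):
            assert select_rank(sweep) == 3

    def test_non_contiguous_sweep_rejected(self):
        sweep = [consensus_stub(2, 0.9, 0.9), consensus_stub(4, 0.8, 0.8)]
        with pytest.raises(ValueError, match="contiguous"):
            select_rank(sweep)


# --------------------------------------------------------------------------
# relevance scores
# --------------------------------------------------------------------------

class TestRelevance:
    def test_one_hot_row_scores_one(self):
        res = relevance_scores(np.array([[8.0, 0.0], [1.0, 1.0]]), ["a", "b"])
        assert res.scores["a"] == pytest.approx(1.0)

    def test_uniform_row_scores_zero(self):
        res = relevance_scores(np.array([[5.0, 5.0], [8.0, 0.0]]), ["a", "b"])
        assert res.scores["a"] == pytest.approx(0.0)

    def test_three_one_row_entropy_value(self):
        res = relevance_scores(np.array([[3.0, 1.0], [1.0, 1.0]]), ["a", "b"])
        # 1 - H(0.75, 0.25) = 0.18872187554086717
        assert res.scores["a"] == pytest.approx(0.18872187554086717, abs=1e-12)

    def test_row_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 3, size=(10, 4))
        scaled = W.copy()
        scaled[3] *= 17.0
        a = relevance_scores(W, [f"p{i}" for i in range(10)])
        b = relevance_scores(scaled, [f"p{i}" for i in range(10)])
        assert a.scores["p3"] == pytest.approx(b.scores["p3"])

    def test_scores_bounded(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 5, size=(50, 3))
        res = relevance_scores(W, [f"p{i}" for i in range(50)])
        assert ((res.scores >= 0) & (res.scores <= 1)).all()

    def test_zero_row_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            res = relevance_scores(np.array([[0.0, 0.0], [1.0, 2.0]]),
                                   ["z", "p"])
        assert res.scores["z"] == 0.0

    def test_strict_percentile_selection(self):
        W = np.array([[1.0, 0.0]] * 9 + [[1.0, 1.0]])
        res = relevance_scores(W, [f"p{i}" for i in range(10)],
                               percentile_threshold=90.0)
        # 90th percentile of (1,...,1,0) is 1; strict > selects nothing
        assert res.selected == []


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class TestPCA:
    def _matrix(self, arr):
        return IntensityMatrix(
            pd.DataFrame(arr, index=[f"P{i}" for i in range(arr.shape[0])],
                         columns=[f"S{j}" for j in range(arr.shape[1])]),
            scale=LOG2)

    def test_collinear_samples_single_component(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        arr = np.vstack([5 + t, 3 + 2 * t, 10 - t])
        scores, ev = pca_embed(self._matrix(arr), impute=True)
        assert ev[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(10, 2, size=(12, 7))
        scores, ev = pca_embed(self._matrix(arr), impute=True,
                               n_components=3)
        X = arr.T - arr.T.mean(axis=0)
        cov = X.T @ X / (X.shape[0] - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        oracle = X @ vecs[:, :3]
        for j in range(3):
            got = scores.iloc[:, j].to_numpy()
            ref = oracle[:, j]
            assert (np.allclose(got, ref, atol=1e-8)
                    or np.allclose(got, -ref, atol=1e-8))
        np.testing.assert_allclose(ev[:3], vals[:3] / vals.sum(), atol=1e-8)

    def test_unimputed_restricts_to_complete_proteins(self):
        arr = np.random.default_rng(0).normal(10, 1, size=(6, 4))
        arr[0, 1] = np.nan
        scores, _ = pca_embed(self._matrix(arr), impute=False)
        assert scores.shape == (4, 2)

    def test_too_few_complete_proteins_rejected(self):
        arr = np.random.default_rng(0).normal(10, 1, size=(3, 4))
        arr[0, 1] = np.nan
        arr[1, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pca_embed(self._matrix(arr), impute=False)

    def test_imputed_requires_complete(self):
        arr = np.random.default_rng(0).normal(10, 1, size=(4, 4))
        arr[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            pca_embed(self._matrix(arr), impute=True)
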