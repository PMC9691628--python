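import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from twinmethyl.network import (
    GREY,
    CorrelationNetworkModules,
    NetworkConfig,
    adjacency,
    blockwise_modules,
    cor_pvalue_student,
    detect_modules,
    eigengene_matrix,
    merge_modules,
    module_colors,
    module_eigengene,
    module_trait_correlation,
    tom_similarity,
)


def correlated_block(rng, n_samples, size, r):
    """Windows sharing a latent driver with pairwise correlation ~r."""
    d = rng.normal(0, 1, n_samples)
    return np.sqrt(r) * d[:, None] + np.sqrt(1 - r) * rng.normal(
        0, 1, (n_samples, size)
    )


class TestAdjacency:
    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x + 3, x])
        A, kept = adjacency(X, 9)
        assert A[0, 1] == pytest.approx(1.0)

    def test_exactly_uncorrelated_pair_has_zero_adjacency(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        z = np.array([0.0, 1.0, 0.0, -1.0])
        A, _ = adjacency(np.column_stack([x, z, x + z]), 6)
        assert A[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_negative_half_correlation_to_the_sixth(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        z = np.array([0.0, 1.0, 0.0, -1.0])
        y = -x + np.sqrt(3) * z  # sample correlation exactly -0.5
        A, _ = adjacency(np.column_stack([x, y]), 6)
        assert A[0, 1] == pytest.approx(0.5**6)

    def test_zero_variance_window_dropped_with_warning(self, rng):
        X = rng.normal(0, 1, (10, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            A, kept = adjacency(X, 6)
        assert A.shape == (2, 2)
        np.testing.assert_array_equal(kept, [0, 2])


def tom_oracle(A):
    """Triple-loop brute force of the unsigned TOM formula."""
    n = A.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return tom


class TestTom:
    def test_two_node_half_adjacency(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.5 / (0.5 + 1 - 0.5))

    def test_complete_graph_has_unit_tom(self):
        A = np.ones((5, 5))
        np.testing.assert_allclose(tom_similarity(A), np.ones((5, 5)))

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_triple_loop_oracle(self, n, rng):
        A = rng.random((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        np.testing.assert_allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)

    def test_bounds_symmetry_and_unit_diagonal(self, rng):
        A = rng.random((12, 12)) ** 3
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(A)
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self, rng):
        A = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


class TestDetectModules:
    def test_two_planted_blocks_recovered_with_grey_background(self, rng):
        X = np.hstack(
            [
                correlated_block(rng, 40, 50, 0.9),
                correlated_block(rng, 40, 50, 0.9),
                rng.normal(0, 1, (40, 100)),
            ]
        )
        A, _ = adjacency(X, 6)
        labels = detect_modules(1 - tom_similarity(A))
        truth = np.array([0] * 50 + [1] * 50)
        assert adjusted_rand_score(truth, labels[:100]) >= 0.9
        assert (labels[100:] == GREY).mean() > 0.9

    def test_independent_noise_yields_all_grey(self, rng):
        X = rng.normal(0, 1, (40, 400))
        A, _ = adjacency(X, 6)
        labels = detect_modules(1 - tom_similarity(A))
        assert (labels == GREY).all()

    def test_duplicate_profiles_always_co_module(self, rng):
        base = rng.normal(0, 1, 30)
        X = np.column_stack(
            [base + 1e-9 * i for i in range(10)] + [rng.normal(0, 1, (30, 50)).T[i] for i in range(50)]
        )
        A, _ = adjacency(X, 6)
        labels = detect_modules(1 - tom_similarity(A), min_module_size=5)
        assert len(set(labels[:10])) == 1 and labels[0] != GREY

    def test_fewer_windows_than_min_size_all_grey(self, rng):
        diss = 1 - np.eye(5)
        with pytest.warns(UserWarning):
            labels = detect_modules(diss, min_module_size=30)
        assert (labels == GREY).all()


class TestEigengene:
    def test_identical_profiles_give_that_profile(self, rng):
        prof = rng.normal(0, 1, 20)
        X = np.column_stack([prof, 2 * prof + 1, -0.5 * prof])
        e = module_eigengene(X)
        z = (prof - prof.mean()) / prof.std(ddof=1)
        assert abs(np.corrcoef(e, z)[0, 1]) == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(0, 1, (15, 6))
        e = module_eigengene(X)
        # oracle: leading eigenvector of Z Z^T via eigh
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        w, V = np.linalg.eigh(Z @ Z.T)
        lead = V[:, -1]
        assert abs(np.dot(e, lead)) == pytest.approx(1.0, abs=1e-10)

    def test_variance_explained_is_maximal(self, rng):
        X = rng.normal(0, 1, (12, 5))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        e = module_eigengene(X)
        var_e = np.sum((e @ Z) ** 2)
        for j in range(Z.shape[1]):
            d = Z[:, j] / np.linalg.norm(Z[:, j])
            assert var_e >= np.sum((d @ Z) ** 2) - 1e-9

    def test_sign_convention_mean_member_correlation_nonneg(self, rng):
        X = rng.normal(0, 1, (10, 4)) + rng.normal(0, 1, (10, 1))
        e = module_eigengene(X)
        cors = [np.corrcoef(e, X[:, j])[0, 1] for j in range(4)]
        assert np.mean(cors) >= 0

    def test_invariant_to_member_order_and_affine_rescale(self, rng):
        X = rng.normal(0, 1, (10, 5)) + 0.5 * rng.normal(0, 1, (10, 1))
        e1 = module_eigengene(X)
        X2 = X[:, ::-1].copy()
        X2[:, 0] = 3.0 * X2[:, 0] - 7.0
        e2 = module_eigengene(X2)
        assert abs(np.dot(e1, e2)) == pytest.approx(1.0, abs=1e-9)

    def test_single_member_module(self, rng):
        prof = rng.normal(0, 1, 8)
        e = module_eigengene(prof[:, None])
        z = (prof - prof.mean()) / prof.std(ddof=1)
        assert np.allclose(e, z / np.linalg.norm(z))


class TestMergeModules:
    def _profiles_with_drivers(self, rng, cors, size=20, n=60):
        """Modules whose eigengenes correlate per the given matrix."""
        L = np.linalg.cholesky(np.asarray(cors))
        drivers = rng.normal(0, 1, (n, len(cors))) @ L.T
        cols, labels = [], []
        for m in range(len(cors)):
            for _ in range(size):
                cols.append(drivers[:, m] + 0.05 * rng.normal(0, 1, n))
                labels.append(m)
        return np.column_stack(cols), np.array(labels)

    def test_highly_correlated_pair_merges(self, rng):
        X, labels = self._profiles_with_drivers(
            rng, [[1.0, 0.9], [0.9, 1.0]]
        )
        merged = merge_modules(X, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 1

    def test_dissimilar_modules_stay_separate(self, rng):
        X, labels = self._profiles_with_drivers(
            rng, [[1.0, 0.3], [0.3, 1.0]]
        )
        merged = merge_modules(X, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 2

    def test_chain_collapses_to_fixed_point(self, rng):
        # A~B 0.9, B~C 0.9, A~C 0.65: A and C are too dissimilar to merge
        # directly (1 - 0.65 > 0.25), but after A+B merge the recomputed
        # eigengene correlates ~0.8 with C, so the chain collapses
        cors = [[1.0, 0.9, 0.65], [0.9, 1.0, 0.9], [0.65, 0.9, 1.0]]
        X, labels = self._profiles_with_drivers(rng, cors)
        merged = merge_modules(X, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 1


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene_gives_unit_correlation(self, rng):
        eig = pd.DataFrame({"m": rng.normal(0, 1, 20)})
        traits = pd.DataFrame({"t": eig["m"]})
        full, _ = module_trait_correlation(eig, traits)
        assert full.r.loc["m", "t"] == pytest.approx(1.0)
        assert full.p.loc["m", "t"] == 0.0

    def test_exactly_zero_correlation_gives_p_one(self):
        x = np.array([1.0, 0.0, -1.0, 0.0, 1.0, -1.0])
        z = np.array([0.0, 1.0, 0.0, -1.0, 1.0, -1.0])
        z = z - (z @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        full, _ = module_trait_correlation(
            pd.DataFrame({"m": x}), pd.DataFrame({"t": z})
        )
        assert full.p.loc["m", "t"] == pytest.approx(1.0)

    def test_closed_form_matches_scipy_pearsonr(self, rng):
        from scipy.stats import pearsonr

        eig = pd.DataFrame({"m": rng.normal(0, 1, 25)})
        traits = pd.DataFrame({"t": rng.normal(0, 1, 25)})
        full, _ = module_trait_correlation(eig, traits)
        r_ref, p_ref = pearsonr(eig["m"], traits["t"])
        assert full.r.loc["m", "t"] == pytest.approx(r_ref)
        assert full.p.loc["m", "t"] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_trait_reported_na(self, rng):
        eig = pd.DataFrame({"m": rng.normal(0, 1, 10)})
        traits = pd.DataFrame({"t": np.ones(10)})
        full, _ = module_trait_correlation(eig, traits)
        assert np.isnan(full.r.loc["m", "t"])

    def test_filtered_view_drops_uninformative_rows_and_columns(self, rng):
        e1 = rng.normal(0, 1, 30)
        eig = pd.DataFrame({"hit": e1, "dud": rng.normal(0, 1, 30)})
        traits = pd.DataFrame(
            {"driven": e1 + 0.1 * rng.normal(0, 1, 30), "noise": rng.normal(0, 1, 30)}
        )
        _, filt = module_trait_correlation(eig, traits, p_filter=0.001)
        assert list(filt.r.index) == ["hit"]
        assert list(filt.r.columns) == ["driven"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cor_pvalue_student(0.5, 3)


class TestBlockwise:
    def test_single_block_bypass_matches_direct_path(self, rng):
        X = np.hstack(
            [correlated_block(rng, 30, 40, 0.8), rng.normal(0, 1, (30, 60))]
        )
        cfg = NetworkConfig(power=6, max_block_size=15_000)
        labels = blockwise_modules(X, cfg)
        A, kept = adjacency(X, 6)
        direct = detect_modules(1 - tom_similarity(A))
        direct = merge_modules(X[:, kept], direct, cfg.merge_cut_height)
        np.testing.assert_array_equal(labels, direct)

    def test_modules_split_across_blocks_reunite_after_merge(self, rng):
        X = np.hstack(
            [
                correlated_block(rng, 40, 60, 0.9),
                correlated_block(rng, 40, 60, 0.9),
            ]
        )
        cfg = NetworkConfig(
            power=6, max_block_size=45, min_module_size=10, random_state=0
        )
        labels = blockwise_modules(X, cfg)
        # each planted module ends up under a single final label
        for sl in (slice(0, 60), slice(60, 120)):
            mods = set(labels[sl]) - {GREY}
            assert len(mods) == 1
        assert labels[0] != labels[60]

    def test_block_partition_is_seed_deterministic(self, rng):
        X = rng.normal(0, 1, (20, 120))
        cfg = NetworkConfig(power=6, max_block_size=50, min_module_size=10, random_state=3)
        np.testing.assert_array_equal(
            blockwise_modules(X, cfg), blockwise_modules(X, cfg)
        )


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        est = CorrelationNetworkModules(power=6, min_module_size=10)
        params = est.get_params()
        assert params["power"] == 6
        clone(est)  # must be cloneable
        X = np.hstack(
            [correlated_block(rng, 30, 20, 0.9), rng.normal(0, 1, (30, 40))]
        )
        est.fit(X)
        assert est.labels_.shape == (60,)
        assert est.n_modules_ >= 1
        assert est.eigengenes_.shape == (30, est.n_modules_)
        assert set(est.module_colors_[est.labels_ == GREY]) <= {"grey"}

    def test_fit_transform_returns_eigengene_matrix(self, rng):
        X = np.hstack(
            [correlated_block(rng, 25, 20, 0.9), rng.normal(0, 1, (25, 30))]
        )
        est = CorrelationNetworkModules(power=6, min_module_size=10)
        out = est.fit_transform(X)
        assert out.shape == (25, est.n_modules_)


def test_module_color_names():
    labels = np.array([0, 1, GREY, 0])
    colors = module_colors(labels)
    assert list(colors) == ["turquoise", "blue", "grey", "turquoise"]
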