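import numpy as np
import pytest
from scipy import stats

from corescaffold import CohortSpec, UndefinedMetricError, generate_cohort
from corescaffold.decomposition import (compare_lesion_vs_intact,
                                        edge_effect_tensor,
                                        intact_metric_pca,
                                        lesion_correlation_matrix, mpca, pca,
                                        PCAResult, _NODAL_METRICS)
from corescaffold.graph_metrics import (characteristic_path_length,
                                        distance_matrix, eccentricity)
from corescaffold.lesion_sweep import node_lesion_sweep, remove_edge, all_pairs
from conftest import identical_cohort, make_connectome
import oracles

from test_multivariate_stats import make_node_table


class TestLesionCorrelationMatrix:
    def test_identical_effect_vectors_give_all_ones(self, rng):
        v = rng.normal(size=8)
        tab = make_node_table(np.zeros(8), [v, v, v, v])
        R = lesion_correlation_matrix(tab, metric="lambda").R
        assert np.allclose(R, 1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        tab = make_node_table(np.zeros(8), list(rng.normal(size=(5, 8))))
        R = lesion_correlation_matrix(tab, metric="lambda").R
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.nanmax(np.abs(R)) <= 1.0

    def test_matches_elementwise_pearson_oracle(self, rng):
        X = rng.normal(size=(5, 8))
        tab = make_node_table(np.zeros(8), list(X))
        R = lesion_correlation_matrix(tab, metric="lambda").R
        ref = oracles.pairwise_pearson(X)
        for i in range(5):
            for j in range(5):
                assert R[i, j] == pytest.approx(ref[i, j], abs=1e-10)
                r_sp = stats.pearsonr(X[i], X[j]).statistic if i != j else 1.0
                assert R[i, j] == pytest.approx(r_sp, abs=1e-10)

    def test_zero_variance_row_flagged_missing(self, rng):
        X = rng.normal(size=(4, 8))
        X[2] = 3.14  # identical effect across subjects
        tab = make_node_table(np.zeros(8), list(X))
        cm = lesion_correlation_matrix(tab, metric="lambda")
        assert np.isnan(cm.R[2, 0]) and np.isnan(cm.R[0, 2])
        assert cm.R[2, 2] == 1.0
        assert cm.n_missing > 0

    def test_subject_order_invariance(self, rng):
        X = rng.normal(size=(5, 8))
        perm = rng.permutation(8)
        a = lesion_correlation_matrix(
            make_node_table(np.zeros(8), list(X)), "lambda").R
        b = lesion_correlation_matrix(
            make_node_table(np.zeros(8), list(X[:, perm])), "lambda").R
        assert np.allclose(a, b, atol=1e-12)


class TestPCA:
    def test_rank_one_matrix_first_component_captures_everything(self, rng):
        v = rng.normal(size=6)
        M = np.outer(v, v)
        with pytest.warns(UserWarning, match="truncating"):
            res = pca(M, n_components=3)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_covariance_gives_equal_fractions(self):
        # columns orthogonal with equal norms -> covariance proportional to I
        H = np.array([[1, 1, 1],
                      [-1, 1, -1],
                      [1, -1, -1],
                      [-1, -1, 1]], dtype=float)
        res = pca(H, n_components=3)
        assert np.allclose(res.variance_fraction, 1 / 3)

    def test_matches_eigendecomposition_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(6, 6))
        M = (X + X.T) / 2
        res = pca(M, n_components=4)
        C = np.cov(M, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(res.variance_fraction, evals[:4] / evals.sum(),
                           atol=1e-12)
        for c in range(4):
            dot = abs(res.loadings[:, c] @ evecs[:, c])
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_sum_to_one_with_full_rank(self, rng):
        X = rng.normal(size=(20, 6))
        res = pca(X, n_components=6)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_loadings_orthonormal_and_sign_fixed(self, rng):
        X = rng.normal(size=(15, 5))
        res = pca(X, n_components=5)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5),
                           atol=1e-10)
        for c in range(5):
            col = res.loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0


class TestIntactMetricPCA:
    def test_identical_subjects_degenerate(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 3)]:
            W[i, j] = W[j, i] = 1.0
        cohort = identical_cohort(W, n_subjects=4)
        with pytest.raises(UndefinedMetricError):
            intact_metric_pca(cohort, "betweenness")

    def test_loadings_cover_all_lesionable_parcels(self, small_cohort):
        res = intact_metric_pca(small_cohort, "eccentricity", n_components=2)
        assert res.loadings.shape[0] == small_cohort.G

    def test_pipeline_equals_manual_composition(self, small_cohort):
        res = intact_metric_pca(small_cohort, "eccentricity", n_components=2)
        X = np.stack([eccentricity(distance_matrix(c)) for c in small_cohort],
                     axis=1)
        R = oracles.pairwise_pearson(X)
        manual = pca(R, n_components=2)
        assert np.allclose(res.variance_fraction, manual.variance_fraction)
        assert np.allclose(res.loadings, manual.loadings, atol=1e-10)


class TestCompareLesionVsIntact:
    def _pcares(self, loadings):
        loadings = np.asarray(loadings, dtype=float)
        q, _ = np.linalg.qr(loadings)
        return PCAResult(loadings=q,
                         variance_fraction=np.ones(q.shape[1]) / q.shape[1])

    def test_identical_loadings_correlate_perfectly(self, rng):
        v = rng.normal(size=(10, 1))
        table = compare_lesion_vs_intact(self._pcares(v),
                                         {"betweenness": self._pcares(v)})
        assert table["r"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_pearson(self, rng):
        a = self._pcares(rng.normal(size=(10, 2)))
        b = self._pcares(rng.normal(size=(10, 2)))
        table = compare_lesion_vs_intact(a, {"clustering": b})
        for _, row in table.iterrows():
            x = a.loadings[:, int(row.lesion_component) - 1]
            y = b.loadings[:, int(row.intact_component) - 1]
            assert row.r == pytest.approx(stats.pearsonr(x, y).statistic,
                                          abs=1e-12)

    def test_mismatched_parcel_sets_rejected(self, rng):
        a = self._pcares(rng.normal(size=(10, 1)))
        b = self._pcares(rng.normal(size=(8, 1)))
        with pytest.raises(ValueError):
            compare_lesion_vs_intact(a, {"eccentricity": b})


class TestEdgeEffectTensor:
    def test_symmetric_in_first_two_modes(self, small_cohort):
        t = edge_effect_tensor(small_cohort, nodal_metric="eccentricity")
        C = np.where(np.isnan(t.C), 0.0, t.C)
        assert np.allclose(C, np.transpose(C, (1, 0, 2)))

    def test_matches_brute_force_recomputation(self):
        cohort = generate_cohort(CohortSpec(G=6, n_subjects=5, n_modules=2,
                                            seed=17))
        t = edge_effect_tensor(cohort, nodal_metric="eccentricity")
        fn = _NODAL_METRICS["eccentricity"]
        for (k, kp) in all_pairs(6):
            d_nodal = np.zeros((5, 6))
            d_lam = np.zeros(5)
            for si, subject in enumerate(cohort):
                if subject.weights[k, kp] == 0:
                    continue
                les = remove_edge(subject, int(k), int(kp))
                d_nodal[si] = fn(les) - fn(subject)
                d_lam[si] = (characteristic_path_length(distance_matrix(les))
                             - characteristic_path_length(
                                 distance_matrix(subject)))
            if not np.any(d_lam != 0):
                assert np.all(np.isnan(t.C[k, kp]))
                continue
            for kpp in range(6):
                x = d_nodal[:, kpp]
                if x.std(ddof=1) == 0 or d_lam.std(ddof=1) == 0:
                    assert np.isnan(t.C[k, kp, kpp])
                else:
                    ref = stats.pearsonr(x, d_lam).statistic
                    assert t.C[k, kp, kpp] == pytest.approx(ref, abs=1e-10)

    def test_unaffected_node_in_tree_has_zero_effect(self):
        # path graph: removing the far (2,3) edge never changes distances
        # among {0,1}; with eccentricity the near nodes' values do change,
        # so instead check the per-subject effect matrix directly
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        c = make_connectome(W)
        les = remove_edge(c, 0, 1)
        ecc0 = eccentricity(distance_matrix(c))
        ecc1 = eccentricity(distance_matrix(les))
        # nodes 2 and 3 keep finite distances only to {1,2,3}; their
        # eccentricity to the surviving component is unchanged or smaller
        assert ecc1[3] <= ecc0[3]


class TestMPCA:
    def test_rank_one_tensor_fully_captured(self, rng):
        a, b, c = rng.normal(size=5), rng.normal(size=5), rng.normal(size=5)
        T = np.einsum("i,j,k->ijk", a, b, c)
        res = mpca(T, n_components_per_mode=(1, 1))
        assert res.captured_variation == pytest.approx(1.0, abs=1e-10)
        assert res.converged

    def test_monotone_in_component_count(self, rng):
        T = rng.normal(size=(5, 5, 5))
        r11 = mpca(T, n_components_per_mode=(1, 1))
        r22 = mpca(T, n_components_per_mode=(2, 2))
        assert r22.captured_variation >= r11.captured_variation - 1e-12

    def test_refinement_never_worse_than_hosvd_truncation(self, rng):
        for _ in range(5):
            T = rng.normal(size=(5, 5, 5))
            res = mpca(T, n_components_per_mode=(1, 1))
            # direct higher-order SVD truncation oracle
            samples = [T[:, :, k] for k in range(5)]
            mean = sum(samples) / 5
            A = [s - mean for s in samples]
            total = sum(float((x ** 2).sum()) for x in A)

            def top(S):
                evals, evecs = np.linalg.eigh(S)
                return evecs[:, [np.argmax(evals)]]

            U1 = top(sum(x @ x.T for x in A))
            U2 = top(sum(x.T @ x for x in A))
            hosvd = sum(float(((U1.T @ x @ U2) ** 2).sum()) for x in A) / total
            assert res.captured_variation >= hosvd - 1e-12

    def test_projections_orthonormal(self, rng):
        T = rng.normal(size=(6, 6, 6))
        res = mpca(T, n_components_per_mode=(2, 2))
        for U in res.mode_projections:
            assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)

    def test_missing_entries_imputed_and_counted(self, rng):
        T = rng.normal(size=(4, 4, 4))
        T[0, 1, 2] = np.nan
        res = mpca(T)
        assert res.n_imputed == 1
        assert np.isfinite(res.captured_variation)
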