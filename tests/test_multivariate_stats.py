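import numpy as np
import pytest
from scipy import stats

from corescaffold import CohortSpec, default_bridges, generate_cohort
from corescaffold.lesion_sweep import (NodeLesionTable, edge_lesion_sweep,
                                       node_lesion_sweep)
from corescaffold.multivariate_stats import (bonferroni_threshold,
                                             edge_significance,
                                             extract_scaffold,
                                             hotelling_paired, paired_t_node,
                                             t_score_table)
import oracles


class TestBonferroni:
    def test_edge_family_thresholds(self):
        m = 165 * 164 // 2
        assert m == 13530
        assert bonferroni_threshold(0.05, m) == pytest.approx(3.7e-6, rel=0.01)
        assert bonferroni_threshold(0.0001, m) == pytest.approx(7.4e-9,
                                                                rel=0.01)

    def test_single_comparison_is_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


def make_node_table(intact, lesioned_by_parcel):
    """Minimal NodeLesionTable over the lambda metric."""
    parcels = np.arange(len(lesioned_by_parcel))
    N = len(intact)
    lesioned = {
        "lambda": np.array(lesioned_by_parcel, dtype=float),
        "local_efficiency_avg": np.array(lesioned_by_parcel, dtype=float),
    }
    intact_d = {"lambda": np.asarray(intact, float),
                "local_efficiency_avg": np.asarray(intact, float)}
    return NodeLesionTable(parcels=parcels,
                           subjects=tuple(f"s{i}" for i in range(N)),
                           lesioned=lesioned, intact=intact_d, n_missing=0)


class TestPairedT:
    def test_no_effect_gives_t_zero_p_one(self):
        tab = make_node_table([1.0, 1.1, 1.2], [[1.0, 1.1, 1.2]])
        res = paired_t_node(tab)
        assert all(r.t == 0 and r.p == 1.0 and not r.significant for r in res)

    def test_constant_shift_is_degenerate(self):
        tab = make_node_table([1.0, 1.1, 1.2], [[1.5, 1.6, 1.7]])
        res = paired_t_node(tab)
        assert all(r.degenerate for r in res)
        assert not any(r.significant for r in res)

    def test_matches_textbook_paired_t(self, rng):
        intact = rng.normal(2.0, 0.3, size=10)
        lesioned = intact + rng.normal(0.2, 0.15, size=10)
        tab = make_node_table(intact, [lesioned])
        r = paired_t_node(tab)[0]
        ref_t, ref_p = stats.ttest_rel(intact, lesioned)
        assert r.t == pytest.approx(ref_t, abs=1e-10)
        assert r.p == pytest.approx(ref_p, abs=1e-12)
        assert r.mean_healthy == pytest.approx(intact.mean())
        assert r.sd_lesioned == pytest.approx(lesioned.std(ddof=1))

    def test_requires_three_subjects(self):
        tab = make_node_table([1.0, 2.0], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            paired_t_node(tab)

    def test_t_score_table_shape(self, small_cohort):
        tab = node_lesion_sweep(small_cohort)
        df = t_score_table(paired_t_node(tab))
        assert df.shape == (tab.n_lesions, 2)


class TestHotelling:
    def test_all_zero_differences(self):
        X = np.random.default_rng(0).normal(size=(8, 4))
        r = hotelling_paired(X, X)
        assert (r.T2, r.F, r.p) == (0.0, 0.0, 1.0)

    def test_univariate_case_equals_squared_paired_t(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 20))
            a = rng.normal(size=(n, 1))
            b = rng.normal(size=(n, 1))
            r = hotelling_paired(a, b)
            t, _ = stats.ttest_rel(a[:, 0], b[:, 0])
            assert r.F == pytest.approx(t * t, abs=1e-10)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            lesioned = rng.normal(size=(12, 4))
            intact = rng.normal(size=(12, 4))
            r = hotelling_paired(lesioned, intact)
            T2_ref, F_ref = oracles.hotelling_T2(lesioned, intact)
            assert r.T2 == pytest.approx(T2_ref, rel=1e-10)
            assert r.F == pytest.approx(F_ref, rel=1e-10)
            assert r.p == pytest.approx(stats.f.sf(F_ref, 4, 8), rel=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        lesioned = rng.normal(size=(15, 4))
        intact = rng.normal(size=(15, 4))
        r0 = hotelling_paired(lesioned, intact)
        scale = np.array([3.0, 0.1, 7.0, 1.0])
        shift = np.array([1.0, -2.0, 0.0, 5.0])
        r1 = hotelling_paired(lesioned * scale + shift, intact * scale + shift)
        assert r1.T2 == pytest.approx(r0.T2, rel=1e-9)

    def test_constant_nonzero_difference_is_rank_deficient(self):
        intact = np.random.default_rng(1).normal(size=(10, 4))
        lesioned = intact + np.array([0.0, 0.5, 0.0, 0.0])
        r = hotelling_paired(lesioned, intact)
        assert r.rank_deficient and r.df1 == 0 and r.p == 1.0

    def test_mixed_constant_and_noisy_components(self, rng):
        # one constant-shift column + noisy columns: effective rank 3
        intact = rng.normal(size=(12, 4))
        delta = rng.normal(size=(12, 4)) * [1, 0, 1, 1]
        lesioned = intact + delta + [0.0, 0.7, 0.0, 0.0]
        r = hotelling_paired(lesioned, intact)
        assert r.rank_deficient and r.df1 == 3

    def test_nan_rows_dropped_pairwise(self, rng):
        lesioned = rng.normal(size=(12, 4))
        intact = rng.normal(size=(12, 4))
        lesioned_nan = lesioned.copy()
        lesioned_nan[3, 2] = np.nan
        r = hotelling_paired(lesioned_nan, intact)
        keep = np.arange(12) != 3
        ref = hotelling_paired(lesioned[keep], intact[keep])
        assert r.n_dropped == 1 and r.T2 == pytest.approx(ref.T2)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            hotelling_paired(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))

    def test_type_one_error_calibration(self, rng):
        # uncorrected false-positive rate under the null, N=30, p=4
        n_rep, N, p = 1500, 30, 4
        hits = 0
        for _ in range(n_rep):
            r = hotelling_paired(rng.normal(size=(N, p)),
                                 rng.normal(size=(N, p)))
            hits += r.p < 0.05
        rate = hits / n_rep
        sigma = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * sigma


class TestEdgeSignificanceAndScaffold:
    def test_m_defaults_to_all_pairs(self, small_cohort):
        tab = edge_lesion_sweep(small_cohort)
        res = edge_significance(tab)
        assert len(res) == small_cohort.G * (small_cohort.G - 1) // 2

    def test_absent_everywhere_pair_non_testable(self, small_cohort):
        tab = edge_lesion_sweep(small_cohort)
        res = edge_significance(tab)
        absent = [r for pi, r in enumerate(res)
                  if tab.edge_presence[pi] == 0]
        assert absent, "expected at least one absent pair in the sparse cohort"
        for r in absent:
            assert not r.testable and not r.significant and r.T2 == 0.0

    def test_planted_bridge_attains_maximum_F(self):
        spec = CohortSpec(G=20, n_subjects=40, n_modules=4,
                          planted_edges=default_bridges(20, 4, 1, seed=6),
                          seed=6)
        cohort = generate_cohort(spec)
        res = edge_significance(edge_lesion_sweep(cohort))
        best = max(res, key=lambda r: r.F)
        assert best.pair == spec.planted_edges[0]

    def test_scaffold_nesting_and_ranking(self, planted_spec):
        cohort = generate_cohort(planted_spec)
        res = edge_significance(edge_lesion_sweep(cohort))
        lenient = extract_scaffold(res, alpha=0.05)
        stringent = extract_scaffold(res, alpha=0.0001)
        assert {r.pair for r in stringent} <= {r.pair for r in lenient}
        fvals = [r.F for r in lenient]
        assert fvals == sorted(fvals, reverse=True)

    def test_empty_scaffold_when_nothing_significant(self, small_cohort):
        tab = edge_lesion_sweep(small_cohort)
        res = edge_significance(tab)
        assert extract_scaffold(res, alpha=1e-12) == []

    def test_circos_link_export(self, tmp_path, planted_spec):
        from corescaffold.multivariate_stats import write_circos_links
        cohort = generate_cohort(planted_spec)
        res = edge_significance(edge_lesion_sweep(cohort))
        scaffold = extract_scaffold(res, alpha=0.05)
        write_circos_links(scaffold, cohort.parcellation,
                           tmp_path / "links.tsv")
        lines = (tmp_path / "links.tsv").read_text().strip().split("\n")
        assert lines[0] == "parcel_a\tparcel_b\tF"
        assert len(lines) == len(scaffold) + 1
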