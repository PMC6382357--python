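import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from evintegra import differential as diff
from evintegra.synthetic_data import SyntheticConfig, generate_dataset

from conftest import make_matrix


def _ab(m):
    return m.sample_ids[:2], m.sample_ids[2:]


class TestFoldChange:
    def test_equal_means_unity(self):
        m = make_matrix([[2.0, 2.0, 2.0, 2.0]])
        (r,) = diff.fold_change(m, *_ab(m))
        assert r.fc == 1.0 and r.log2fc == 0.0

    def test_halving_gives_minus_one_log2(self):
        m = make_matrix([[2.0, 2.0, 1.0, 1.0]])
        (r,) = diff.fold_change(m, *_ab(m))
        assert r.fc == 0.5 and r.log2fc == -1.0

    def test_zero_denominator_undefined_policy(self):
        m = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        (r,) = diff.fold_change(m, *_ab(m), zero_policy="undefined")
        assert r.status == "undefined_zero" and r.fc is None

    def test_epsilon_policy_defines_ratio(self):
        m = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        (r,) = diff.fold_change(m, *_ab(m), zero_policy="epsilon", epsilon=1.0)
        assert r.fc == 2.0

    def test_reciprocity(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.lognormal(1, 1, (20, 4)))
        a, b = _ab(m)
        fwd = diff.fold_change(m, a, b)
        rev = diff.fold_change(m, b, a)
        for f, r in zip(fwd, rev):
            assert f.fc * r.fc == pytest.approx(1.0, rel=1e-12)

    def test_overlapping_groups_rejected(self):
        m = make_matrix(np.ones((1, 4)))
        with pytest.raises(ValueError):
            diff.fold_change(m, m.sample_ids[:2], m.sample_ids[1:3])


class TestZscore:
    def test_linear_row_closed_form(self):
        # 3-sample design built manually: row [1,2,3] has sample sd exactly 1
        from evintegra.tables_io import SampleMeta, ExpressionMatrix

        samples = [
            SampleMeta("s1", "MKN45", "2D", "cell", 1),
            SampleMeta("s2", "MKN45", "2D", "cell", 2),
            SampleMeta("s3", "MKN45", "3D", "cell", 1),
        ]
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f0"],
                            columns=["s1", "s2", "s3"])
        z = diff.zscore_rows(ExpressionMatrix(data, samples))
        assert np.allclose(z.data.loc["f0"], [-1.0, 0.0, 1.0])
        assert z.unit_label == "Z-score"

    def test_constant_row_emitted_as_missing_with_warning(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = diff.zscore_rows(m)
        assert z.data.loc["f0"].isna().all()
        assert not z.data.loc["f1"].isna().any()

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.lognormal(0, 1, (15, 6)))
        z = diff.zscore_rows(m)
        assert np.allclose(z.data.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.data.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_single_sample_rejected(self):
        from evintegra.tables_io import SampleMeta, ExpressionMatrix

        data = pd.DataFrame([[1.0]], index=["f0"], columns=["s1"])
        m = ExpressionMatrix(data, [SampleMeta("s1", "MKN45", "2D", "cell", 1)])
        with pytest.raises(ValueError):
            diff.zscore_rows(m)


class TestHierarchicalOrder:
    def test_identical_columns_merge_first_at_zero(self):
        m = make_matrix([[1.0, 3.0, 1.0, 7.0], [2.0, 4.0, 2.0, 9.0]])
        res = diff.hierarchical_order(m, axis="samples")
        i, j, h = res.merges[0]
        assert {i, j} == {0, 2} and h == 0.0

    def test_three_collinear_points_average_linkage(self):
        # features at 0, 1, 10 on a line: merge (0,1) at d=1, then with 10
        m = make_matrix([[0.0, 0.0], [1.0, 1.0], [10.0, 10.0]])
        res = diff.hierarchical_order(m, axis="features")
        assert res.merges[0][:2] == (0, 1)
        assert res.merges[0][2] == pytest.approx(np.sqrt(2))
        # average linkage: d({0,1}, {10}) = (d(0,10)+d(1,10))/2 = 9.5*sqrt(2)
        assert res.merges[1][2] == pytest.approx(9.5 * np.sqrt(2))

    def test_leaf_order_is_permutation_of_labels(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(0, 1, (9, 4)) ** 2)
        res = diff.hierarchical_order(m, axis="features")
        assert sorted(res.ordered_labels) == sorted(m.feature_ids)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(12)
        for linkage in ("average", "complete", "single"):
            m = make_matrix(rng.lognormal(0, 1, (12, 4)))
            res = diff.hierarchical_order(m, linkage=linkage)
            heights = [h for _, _, h in res.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_linkage_on_tie_free_data(self):
        """Independent cross-check: merge heights match scipy's agglomerative
        clustering on generic (tie-free) data."""
        rng = np.random.default_rng(23)
        vals = rng.normal(0, 1, (10, 5)) ** 2
        from evintegra.tables_io import SampleMeta, ExpressionMatrix

        samples = [
            SampleMeta(f"s{j}", "MKN45", "2D" if j < 3 else "3D", "cell", j % 3 + 1)
            for j in range(5)
        ]
        data = pd.DataFrame(vals, index=[f"f{i}" for i in range(10)],
                            columns=[s.sample_id for s in samples])
        em = ExpressionMatrix(data, samples)
        for linkage in ("average", "complete", "single"):
            ours = diff.hierarchical_order(em, linkage=linkage)
            theirs = sch.linkage(vals, method=linkage, metric="euclidean")
            assert np.allclose(
                sorted(h for _, _, h in ours.merges), sorted(theirs[:, 2])
            )

    def test_missing_values_rejected(self):
        m = make_matrix([[1.0, np.nan, 2.0, 3.0], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="impute or drop"):
            diff.hierarchical_order(m)


class TestTopDiscriminating:
    def test_planted_features_fill_top_k(self):
        """n=4/group, +1.5 log2 effect, sd 0.25: all 20 planted proteins
        must rank in the top 20."""
        ds = generate_dataset(
            SyntheticConfig(n_replicates=4, protein_log2fc_3d=-1.5, seed=11)
        )
        p = ds["protein_matrix"]
        a = [s.sample_id for s in p.samples if s.condition == "2D"]
        b = [s.sample_id for s in p.samples if s.condition == "3D"]
        top = diff.top_discriminating(p, a, b, k=20)
        planted = {e.protein_id for e in ds["truth"].planted_edges}
        assert set(top.index) == planted

    def test_identical_groups_ranking_deterministic(self):
        m = make_matrix(np.tile([[1.0, 2.0]], (5, 2)))
        a, b = _ab(m)
        t1 = diff.top_discriminating(m, a, b, k=5)
        t2 = diff.top_discriminating(m, a, b, k=5)
        assert list(t1.index) == list(t2.index) == sorted(m.feature_ids)

    def test_k_equal_feature_count_returns_all(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.lognormal(0, 1, (7, 4)))
        top = diff.top_discriminating(m, *_ab(m), k=7)
        assert len(top) == 7

    def test_mannwhitney_route_matches_exact_test(self):
        from evintegra.ev_yield_stats import mann_whitney_exact

        rng = np.random.default_rng(6)
        vals = rng.lognormal(0, 1, (5, 8))
        from conftest import full_design_matrix

        m = full_design_matrix(
            np.hstack([vals[:, :4], vals[:, 4:]])
        )
        a = [s.sample_id for s in m.samples if s.condition == "2D"]
        b = [s.sample_id for s in m.samples if s.condition == "3D"]
        top = diff.top_discriminating(m, a, b, k=5, test="mannwhitney")
        for f in top.index:
            xa = np.log2(m.data.loc[f, a].to_numpy(dtype=float))
            xb = np.log2(m.data.loc[f, b].to_numpy(dtype=float))
            assert top.loc[f, "p"] == pytest.approx(
                mann_whitney_exact(xa, xb).p_two_sided
            )


class TestQpcr:
    @pytest.mark.parametrize(
        "ct2d,ct3d,expected",
        [(20.0, 20.0, 1.0), (20.0, 19.0, 2.0), (20.0, 23.0, 0.125)],
    )
    def test_comparative_ddct(self, ct2d, ct3d, expected):
        table = pd.DataFrame(
            [{"target_id": "m1", "replicate": "r1", "ct_2d": ct2d, "ct_3d": ct3d}]
        )
        (rec,) = diff.qpcr_relative_expression(table)
        assert rec.rel_expr == pytest.approx(expected)

    def test_missing_ct_skipped_with_warning(self):
        table = pd.DataFrame(
            [
                {"target_id": "m1", "replicate": "r1", "ct_2d": np.nan, "ct_3d": 20.0},
                {"target_id": "m1", "replicate": "r2", "ct_2d": 21.0, "ct_3d": 20.0},
            ]
        )
        with pytest.warns(UserWarning, match="missing CT"):
            recs = diff.qpcr_relative_expression(table)
        assert len(recs) == 1 and recs[0].replicate == "r2"


class TestControlNormalizedRatio:
    def test_all_equal_is_unity(self):
        assert diff.control_normalized_ratio(2, 2, 2, 2) == 1.0

    def test_halved_signal(self):
        assert diff.control_normalized_ratio(1, 2, 2, 2) == 0.5

    def test_hand_arithmetic(self):
        assert diff.control_normalized_ratio(3, 2, 1, 2) == 3.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            diff.control_normalized_ratio(1, 0, 1, 1)
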