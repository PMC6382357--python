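import itertools

import numpy as np
import pytest

from evintegra import detection_sets as ds
from evintegra.tables_io import BiotypeMap

from conftest import full_design_matrix, make_matrix


def _grouping2(matrix):
    return ds.make_grouping(matrix, by=("condition",))


class TestCallDetected:
    def test_all_zero_replicates_not_detected(self):
        m = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        det = ds.call_detected(m, _grouping2(m))
        assert not det.detected.loc["f0", "2D"]

    def test_single_positive_replicate_is_detected(self):
        m = make_matrix([[0.0, 3.2, 0.0, 0.0]])
        det = ds.call_detected(m, _grouping2(m), min_replicates=1)
        assert det.detected.loc["f0", "2D"]

    @pytest.mark.parametrize(
        "threshold,expected", [(0.0, True), (0.15, False)]
    )
    def test_min_replicates_with_threshold(self, threshold, expected):
        m = make_matrix([[0.1, 0.2, 0.0, 0.0]])
        det = ds.call_detected(m, _grouping2(m), threshold=threshold, min_replicates=2)
        assert bool(det.detected.loc["f0", "2D"]) is expected

    def test_missing_values_never_exceed_threshold(self):
        m = make_matrix([[np.nan, np.nan, 1.0, 1.0]])
        det = ds.call_detected(m, _grouping2(m))
        assert not det.detected.loc["f0", "2D"]
        assert det.detected.loc["f0", "3D"]

    def test_empty_group_rejected(self):
        m = make_matrix([[1.0, 1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="empty group"):
            ds.call_detected(m, {"g": []})

    def test_monotone_in_threshold_and_min_replicates(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(0, 1, (30, 4)) * (rng.random((30, 4)) > 0.4)
        m = make_matrix(vals)
        g = _grouping2(m)
        base = ds.call_detected(m, g, threshold=0.0, min_replicates=1)
        for thr, mr in [(0.5, 1), (0.0, 2), (2.0, 2)]:
            harder = ds.call_detected(m, g, threshold=thr, min_replicates=mr)
            assert not (harder.detected & ~base.detected).any().any()


class TestVennPartition:
    def test_hand_enumerated_two_group_partition(self):
        m = make_matrix([[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 1]],
                        feature_ids=["a", "b", "c"])
        det = ds.call_detected(m, _grouping2(m))
        part = ds.venn_partition(det)
        assert part.regions == {
            ("2D",): {"a"}, ("3D",): {"b"}, ("2D", "3D"): {"c"},
        }

    def test_all_groups_shared_single_region(self):
        m = make_matrix(np.ones((3, 4)))
        det = ds.call_detected(m, _grouping2(m))
        part = ds.venn_partition(det)
        assert list(part.regions) == [("2D", "3D")]
        assert len(part.regions[("2D", "3D")]) == 3

    def test_partition_matches_brute_force_signatures(self):
        """Disjointness + union conservation vs brute-force per-feature
        signatures on random detection patterns."""
        rng = np.random.default_rng(17)
        vals = (rng.random((40, 8)) > 0.5).astype(float)
        m = full_design_matrix(vals)
        grouping = ds.make_grouping(m)
        det = ds.call_detected(m, grouping)
        part = ds.venn_partition(det)
        # brute force: recompute each feature's signature directly
        expected = {}
        for f in m.feature_ids:
            sig = tuple(
                g for g in grouping
                if any(m.data.loc[f, s] > 0 for s in grouping[g])
            )
            if sig:
                expected.setdefault(sig, set()).add(f)
        assert part.regions == expected
        # disjoint and conserving
        all_feats = [f for v in part.regions.values() for f in v]
        assert len(all_feats) == len(set(all_feats))
        detected = set(det.detected.index[det.detected.any(axis=1)])
        assert part.all_features() == detected

    def test_fewer_than_two_groups_rejected(self):
        m = make_matrix(np.ones((2, 4)))
        det = ds.call_detected(m, {"only": m.sample_ids})
        with pytest.raises(ValueError):
            ds.venn_partition(det)


def test_composite_set_include_exclude():
    """The shared-by-cells, 3D-EV-only construction."""
    vals = np.array(
        [
            # 2Dc 2Dc 2De 2De 3Dc 3Dc 3De 3De
            [1, 1, 0, 0, 1, 1, 1, 1],  # in both cells + 3D EV, not 2D EV
            [1, 1, 1, 1, 1, 1, 1, 1],  # everywhere
            [0, 0, 0, 0, 1, 1, 1, 1],  # 3D only
        ],
        dtype=float,
    )
    m = full_design_matrix(vals, feature_ids=["hit", "ubiquitous", "only3d"])
    det = ds.call_detected(m, ds.make_grouping(m))
    got = ds.composite_set(
        det, include=["2D_cell", "3D_cell", "3D_EV"], exclude=["2D_EV"]
    )
    assert got == {"hit"}


class TestBiotypeComposition:
    def _biotypes(self):
        return BiotypeMap(
            {"f0": "miRNA", "f1": "miRNA", "f2": "miRNA", "f3": "snRNA"}
        )

    def test_pure_mirna_group_is_100_percent(self):
        m = make_matrix(np.ones((3, 4)))
        comp = ds.biotype_composition(
            m, BiotypeMap({f: "miRNA" for f in m.feature_ids}), _grouping2(m)
        )
        assert np.allclose(comp["miRNA"], 100.0)

    def test_three_to_one_split(self):
        m = make_matrix(np.ones((4, 4)))
        comp = ds.biotype_composition(m, self._biotypes(), _grouping2(m))
        assert comp.loc["2D", "miRNA"] == pytest.approx(75.0)
        assert comp.loc["2D", "snRNA"] == pytest.approx(25.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(3)
        vals = (rng.random((4, 4)) > 0.3).astype(float)
        vals[:, 0] = 1.0  # ensure 2D group has detections
        m = make_matrix(vals)
        comp = ds.biotype_composition(m, self._biotypes(), _grouping2(m))
        sums = comp.sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_group_without_detections_is_undefined_not_zero(self):
        m = make_matrix([[1.0, 1.0, 0.0, 0.0]])
        comp = ds.biotype_composition(
            m, BiotypeMap({"f0": "miRNA"}), _grouping2(m)
        )
        assert comp.loc["3D"].isna().all()

    def test_missing_biotype_is_error(self):
        m = make_matrix(np.ones((2, 4)))
        with pytest.raises(ValueError, match="f1"):
            ds.biotype_composition(m, BiotypeMap({"f0": "miRNA"}), _grouping2(m))


class TestHousekeepingFilter:
    def test_constant_high_expressor_selected(self):
        m = make_matrix([[12000.0] * 4])
        assert ds.select_housekeeping_candidates(m) == ["f0"]

    def test_one_sample_below_detection_rejected(self):
        m = make_matrix([[12000.0, 12000.0, 12000.0, 9000.0]])
        assert ds.select_housekeeping_candidates(m) == []

    def test_fold_change_above_bound_rejected(self):
        # 20000/12000 = 1.67 > 1.5
        m = make_matrix([[12000.0, 12000.0, 20000.0, 20000.0]])
        assert ds.select_housekeeping_candidates(m) == []

    def test_fold_change_exactly_at_bound_kept(self):
        m = make_matrix([[12000.0, 12000.0, 18000.0, 18000.0]])
        assert ds.select_housekeeping_candidates(m) == ["f0"]

    def test_group_mean_mode_less_strict_than_pairwise(self):
        # within-group spread large, group means equal
        m = make_matrix([[11000.0, 18000.0, 18000.0, 11000.0]])
        grouping = _grouping2(m)
        assert ds.select_housekeeping_candidates(m) == []
        assert ds.select_housekeeping_candidates(
            m, mode="group_mean", grouping=grouping
        ) == ["f0"]
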