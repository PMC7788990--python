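import numpy as np
import pytest

from disteval.formats import ContactPrediction
from disteval.geometry import (
    ALL_CLASSES,
    LONG_ONLY,
    MEDIUM_LONG,
    DistanceMap,
    SeparationClass,
)
from disteval.metrics import (
    distances_to_contact_ranking,
    evaluate,
    lddt,
    mae,
    pcc_distances,
    precision_topk,
    rmse,
    standardize,
)
from disteval.synthetic import SyntheticSpec, make_distogram, make_prediction


def pair_map(L, entries):
    """DistanceMap from {(i, j): distance}, 1-based, mirrored."""
    values = np.zeros((L, L))
    mask = np.zeros((L, L), dtype=bool)
    for (i, j), d in entries.items():
        values[i - 1, j - 1] = values[j - 1, i - 1] = d
        mask[i - 1, j - 1] = mask[j - 1, i - 1] = True
    return DistanceMap(values, mask)


class TestStandardize:
    def test_low_values_ceiled(self):
        dmap = pair_map(3, {(1, 2): 2.9})
        assert standardize(dmap).values[0, 1] == 3.5

    def test_high_values_masked(self):
        dmap = pair_map(3, {(1, 2): 25.0})
        assert not standardize(dmap).mask[0, 1]

    def test_in_range_unchanged(self):
        dmap = pair_map(3, {(1, 2): 10.0})
        assert standardize(dmap).values[0, 1] == 10.0

    def test_idempotent(self, true60):
        once = standardize(true60)
        twice = standardize(once)
        assert np.array_equal(once.mask, twice.mask)
        assert np.allclose(once.values[once.mask], twice.values[twice.mask])

    def test_range_invariant(self, true60):
        std = standardize(true60)
        vals = std.values[std.mask]
        assert vals.min() >= 3.5 and vals.max() <= 20.0


# two long-range pairs: true {4, 10}, pred {5, 12} -> errors {1, 2}
TRUE2 = pair_map(40, {(1, 30): 4.0, (2, 40): 10.0})
PRED2 = pair_map(40, {(1, 30): 5.0, (2, 40): 12.0})


class TestMaeRmse:
    def test_identity_zero(self, true60):
        assert mae(true60, true60, ALL_CLASSES)[0] == 0.0
        assert rmse(true60, true60, ALL_CLASSES)[0] == 0.0

    def test_hand_computed_mae(self):
        value, n = mae(PRED2, TRUE2, LONG_ONLY)
        assert value == pytest.approx(1.5)
        assert n == 2

    def test_hand_computed_rmse(self):
        value, n = rmse(PRED2, TRUE2, LONG_ONLY)
        assert value == pytest.approx(np.sqrt(2.5))

    def test_constant_error_rmse_equals_mae(self):
        pred = pair_map(40, {(1, 30): 6.0, (2, 40): 12.0})
        assert rmse(pred, TRUE2, LONG_ONLY)[0] == pytest.approx(2.0)
        assert mae(pred, TRUE2, LONG_ONLY)[0] == pytest.approx(2.0)

    def test_empty_pair_set_is_none(self):
        value, n = mae(PRED2, TRUE2, {SeparationClass.SHORT})
        assert value is None and n == 0

    def test_true_above_20_excluded(self):
        true = pair_map(40, {(1, 30): 22.0, (2, 40): 10.0})
        pred = pair_map(40, {(1, 30): 5.0, (2, 40): 11.0})
        value, n = mae(pred, true, LONG_ONLY)
        assert n == 1 and value == pytest.approx(1.0)

    def test_rmse_ge_mae_random(self, true60):
        rng = np.random.default_rng(11)
        for seed in range(5):
            pred = make_prediction(true60, SyntheticSpec(60, 2.0, seed=seed))
            for classes in (ALL_CLASSES, MEDIUM_LONG, LONG_ONLY):
                m, _ = mae(pred, true60, classes)
                r, _ = rmse(pred, true60, classes)
                assert r >= m


class TestPcc:
    def test_perfect_correlation(self, true60):
        assert pcc_distances(true60, true60, MEDIUM_LONG)[0] == pytest.approx(1.0)

    def test_anti_correlation(self, true60):
        flipped = DistanceMap(30.0 - true60.values, true60.mask.copy())
        assert pcc_distances(flipped, true60, MEDIUM_LONG)[0] == pytest.approx(-1.0)

    def test_noisy_between_zero_and_one(self, true60):
        pred = make_prediction(true60, SyntheticSpec(60, 1.0, seed=5))
        value, _ = pcc_distances(pred, true60, MEDIUM_LONG)
        assert 0.0 < value < 1.0

    def test_improves_as_noise_shrinks(self, true60):
        vals = []
        for sigma in (4.0, 1.0, 0.25):
            pred = make_prediction(true60, SyntheticSpec(60, sigma, seed=5))
            vals.append(pcc_distances(pred, true60, MEDIUM_LONG)[0])
        assert vals[0] < vals[1] < vals[2]

    def test_constant_input_is_none(self):
        true = pair_map(40, {(1, 30): 5.0, (2, 40): 5.0, (3, 39): 5.0})
        pred = pair_map(40, {(1, 30): 5.0, (2, 40): 6.0, (3, 39): 7.0})
        assert pcc_distances(pred, true, LONG_ONLY)[0] is None


class TestLddt:
    def test_identity_is_one(self, true60):
        for sep in (6, 12, 24):
            value, n = lddt(true60, true60, sep)
            assert value == 1.0 and n > 0

    def test_single_pair_partial_credit(self):
        true = pair_map(20, {(1, 10): 6.0})
        pred = pair_map(20, {(1, 10): 6.7})
        assert lddt(pred, true, 6)[0] == pytest.approx(0.75)

    def test_single_pair_all_tolerances_failed(self):
        true = pair_map(20, {(1, 10): 6.0})
        pred = pair_map(20, {(1, 10): 11.0})
        assert lddt(pred, true, 6)[0] == 0.0

    def test_masked_prediction_not_preserved(self):
        true = pair_map(20, {(1, 10): 6.0, (2, 12): 7.0})
        pred = pair_map(20, {(1, 10): 6.0})
        assert lddt(pred, true, 6)[0] == pytest.approx(0.5)

    def test_reference_excludes_far_true_pairs(self):
        # true distance 16 is past the 15 A inclusion radius
        true = pair_map(20, {(1, 10): 16.0})
        assert lddt(true, true, 6)[0] is None

    def test_no_reference_pairs_is_none(self):
        true = pair_map(10, {(1, 5): 6.0})
        assert lddt(true, true, 6)[0] is None


class TestContactRanking:
    def test_ascending_distance_order(self):
        pred = pair_map(60, {(1, 30): 5.0, (2, 40): 7.0})
        ranked = distances_to_contact_ranking(pred)
        ordered = sorted(ranked.pairs, key=lambda p: -p[2])
        assert [p[:2] for p in ordered] == [(1, 30), (2, 40)]

    def test_above_threshold_not_a_contact_call(self):
        pred = pair_map(60, {(1, 30): 5.0, (2, 40): 9.0})
        assert distances_to_contact_ranking(pred).pair_set() == {(1, 30)}

    def test_masked_pair_excluded(self):
        pred = pair_map(60, {(1, 30): 5.0, (2, 40): 6.0})
        pred.mask[1, 39] = pred.mask[39, 1] = False
        assert distances_to_contact_ranking(pred).pair_set() == {(1, 30)}

    def test_confidence_in_unit_interval(self, true60):
        for _, _, c in distances_to_contact_ranking(true60).pairs:
            assert 0.0 <= c <= 1.0

    def test_equal_distances_tie_lexicographic(self):
        pred = pair_map(60, {(2, 40): 5.0, (1, 30): 5.0})
        true = pair_map(60, {(1, 30): 5.0, (2, 40): 9.0})
        ranked = distances_to_contact_ranking(pred)
        # top-1: lexicographic winner (1, 30) is the true contact
        value, n = precision_topk(ranked, true, LONG_ONLY, "topL5", 5)
        assert n == 1 and value == 1.0


class TestPrecisionTopk:
    def test_all_true_contacts(self):
        true = pair_map(60, {(1, 30): 5.0, (2, 40): 6.0})
        pred = ContactPrediction([(1, 30, 0.9), (2, 40, 0.8)])
        value, n = precision_topk(pred, true, LONG_ONLY, "topL", 60)
        assert value == 1.0 and n == 2

    def test_topL5_k_of_10_is_2(self):
        true = pair_map(60, {(1, 30): 5.0, (2, 40): 9.1, (3, 50): 5.0})
        pred = ContactPrediction([(1, 30, 0.9), (2, 40, 0.8), (3, 50, 0.7)])
        value, n = precision_topk(pred, true, LONG_ONLY, "topL5", 10)
        assert n == 2  # k = floor(10 / 5)
        assert value == pytest.approx(0.5)

    def test_topL5_minimum_k_is_1(self):
        true = pair_map(60, {(1, 30): 5.0})
        pred = ContactPrediction([(1, 30, 0.9)])
        _, n = precision_topk(pred, true, LONG_ONLY, "topL5", 3)
        assert n == 1

    def test_class_filter(self):
        true = pair_map(60, {(1, 10): 5.0, (1, 40): 9.0})
        pred = ContactPrediction([(1, 10, 0.99), (1, 40, 0.5)])
        value, _ = precision_topk(pred, true, LONG_ONLY, "topL", 60)
        assert value == 0.0  # the short-range hit is filtered out

    def test_unevaluable_pairs_consume_no_slot(self):
        true = pair_map(60, {(2, 40): 5.0})
        pred = ContactPrediction([(1, 30, 0.99), (2, 40, 0.5)])
        value, n = precision_topk(pred, true, LONG_ONLY, "topL5", 5)
        assert n == 1 and value == 1.0

    def test_no_evaluable_predictions_is_none(self):
        true = pair_map(60, {(2, 40): 5.0})
        pred = ContactPrediction([(1, 5, 0.9)])
        value, n = precision_topk(pred, true, LONG_ONLY, "topL", 60)
        assert value is None and n == 0


class TestUpperTriangleOnly:
    def test_lower_triangle_corruption_changes_nothing(self, chain60, true60):
        rec, _ = chain60
        pred = make_prediction(true60, SyntheticSpec(60, 1.0, seed=2))
        baseline = evaluate(pred, rec)
        corrupted = pred.copy()
        il, jl = np.tril_indices(60, k=-1)
        corrupted.values[il, jl] = 999.0
        report = evaluate(corrupted, rec)
        for key, mv in baseline.metrics.items():
            assert report[key].value == mv.value, key
            assert report[key].n == mv.n


class TestEvaluate:
    def test_identity_report(self, chain60, true60):
        rec, _ = chain60
        report = evaluate(true60, rec)
        for key in ("mae_long", "mae_medium_long", "rmse_long", "rmse_medium_long"):
            assert report[key].value == 0.0
        for key in ("lddt_sep6", "lddt_sep12", "lddt_sep24"):
            assert report[key].value == 1.0
        for key in (
            "precision_topL5_long",
            "precision_topL_long",
            "precision_topL5_medlong",
            "precision_topL_medlong",
        ):
            assert report[key].value == 1.0
        assert report.L == 60

    def test_contact_only_input_skips_distance_fields(self, chain60):
        rec, _ = chain60
        report = evaluate(ContactPrediction([(1, 30, 0.9)]), rec)
        assert report["mae_long"].value is None
        assert report["precision_topL5_long"].value is not None

    def test_distogram_input_populates_both_families(self, chain60, true60):
        rec, _ = chain60
        dg = make_distogram(true60, sharpness=0.3)
        report = evaluate(dg, rec)
        assert report["mae_long"].value is not None
        assert report["precision_topL5_long"].value is not None

    def test_length_mismatch_reports_both_lengths(self, chain60):
        rec, _ = chain60
        small = pair_map(10, {(1, 5): 4.0})
        with pytest.raises(ValueError, match="10.*60|60.*10"):
            evaluate(small, rec)

    def test_report_serialization(self, chain60, true60):
        rec, _ = chain60
        report = evaluate(true60, rec)
        text = report.to_text()
        assert "mae_long" in text and "n=" in text
        data = report.to_dict()
        assert data["L"] == 60
        assert data["metrics"]["lddt_sep24"]["value"] == 1.0


class TestNoiseDegradation:
    def test_lddt_down_mae_up(self, true60):
        sigmas = (0.5, 1.0, 2.0, 4.0)
        mean_lddt, mean_mae = [], []
        for sigma in sigmas:
            ls, ms = [], []
            for seed in range(20):
                pred = make_prediction(true60, SyntheticSpec(60, sigma, seed=seed))
                ls.append(lddt(pred, true60, 6)[0])
                ms.append(mae(pred, true60, ALL_CLASSES)[0])
            mean_lddt.append(np.mean(ls))
            mean_mae.append(np.mean(ms))
        assert all(a > b for a, b in zip(mean_lddt, mean_lddt[1:]))
        assert all(a < b for a, b in zip(mean_mae, mean_mae[1:]))
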