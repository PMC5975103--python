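"""Activation/target maps, score endpoints and the confusion-count oracle."""

import numpy as np
import pytest

import ciuq
from ciuq.errors import DomainError
from ciuq.scoring import MISMATCH_CODES, ActivationMap, TargetMap


@pytest.fixture(scope="module")
def target(mean_ctx):
    return mean_ctx.target


@pytest.fixture(scope="module")
def amap(mean_ctx):
    return mean_ctx.activation_map()


class TestTargetMap:
    def test_peak_weight_is_one_at_contact_place(self, target, mean_ctx):
        for e in range(12):
            j = np.argmin(np.abs(target.fiber_arc_mm - target.contact_arc_mm[e]))
            assert target.weights[j, e] == pytest.approx(1.0, abs=0.01)

    def test_band_edge_weight(self, target, cfg):
        """Gaussian sigma solves w(edge) = band_edge_weight."""
        sigma = cfg.scoring.band_halfwidth_mm / np.sqrt(
            2 * np.log(1 / cfg.scoring.band_edge_weight)
        )
        w_edge = np.exp(-cfg.scoring.band_halfwidth_mm**2 / (2 * sigma**2))
        assert w_edge == pytest.approx(0.1, rel=1e-12)

    def test_sign_structure(self, target, cfg):
        ds = np.abs(target.fiber_arc_mm[:, None] - target.contact_arc_mm[None, :])
        in_band = ds <= cfg.scoring.band_halfwidth_mm
        assert np.all(target.weights[in_band] > 0)
        np.testing.assert_allclose(target.weights[~in_band], -0.25)

    def test_each_column_has_both_signs(self, target):
        assert np.all((target.weights > 0).any(axis=0))
        assert np.all((target.weights < 0).any(axis=0))


class TestSplitMap:
    def test_partition(self, amap, target):
        for label in amap.contacts:
            near, far = ciuq.split_map(amap, target, label)
            assert np.all(near ^ far)

    def test_near_field_is_half_turn(self, amap, target):
        near, _ = ciuq.split_map(amap, target, "E6")
        e = target.contacts.index("E6")
        inside = np.abs(target.fiber_theta - target.contact_theta[e]) <= np.pi / 2
        np.testing.assert_array_equal(near, inside)

    def test_apex_has_closer_cross_turn_bundles(self, mean_ctx, target):
        """3D proximity of the other turn is tighter for apical contacts."""
        dists = []
        for label in ("E1", "E12"):
            e = target.contacts.index(label)
            _, far = ciuq.split_map(mean_ctx.activation_map(), target, label)
            pos = mean_ctx.insertion.contact_xyz[e]
            dists.append(np.linalg.norm(mean_ctx.fibers.xyz[far] - pos, axis=1).min())
        assert dists[0] < dists[1]


class TestElectrodeScore:
    def test_ideal_profile_scores_100(self, target):
        w = target.weights[:, 5]
        assert ciuq.electrode_score(w > 0, w) == pytest.approx(100.0)

    def test_zero_stimulation_scores_50(self, target):
        w = target.weights[:, 5]
        assert ciuq.electrode_score(np.zeros_like(w, bool), w) == pytest.approx(50.0)

    def test_inverse_profile_scores_0(self, target):
        w = target.weights[:, 5]
        assert ciuq.electrode_score(w < 0, w) == pytest.approx(0.0)

    def test_negative_only_column_maps_to_0_100(self):
        w = np.array([-0.25, -0.25, -0.25, -0.25])
        assert ciuq.electrode_score(np.zeros(4, bool), w) == pytest.approx(100.0)
        assert ciuq.electrode_score(np.ones(4, bool), w) == pytest.approx(0.0)
        assert ciuq.electrode_score(np.array([1, 1, 0, 0], bool), w) == pytest.approx(50.0)

    def test_all_zero_weights_flagged_undefined(self):
        assert np.isnan(ciuq.electrode_score(np.zeros(3, bool), np.zeros(3)))

    def test_monotonicity(self, target, rng):
        """In-band activation never lowers the score; out-of-band never raises."""
        w = target.weights[:, 5]
        active = rng.random(len(w)) < 0.3
        base = ciuq.electrode_score(active, w)
        for j in np.flatnonzero(~active)[:20]:
            bumped = active.copy()
            bumped[j] = True
            s = ciuq.electrode_score(bumped, w)
            if w[j] > 0:
                assert s >= base - 1e-12
            else:
                assert s <= base + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            ciuq.electrode_score(np.zeros(3, bool), np.zeros(4))


class TestGlobalScores:
    def test_perfect_map(self, target):
        amap = ActivationMap((target.weights > 0), target.contacts)
        spec, sens = ciuq.global_scores(amap, target)
        assert spec == 1.0 and sens == 1.0

    def test_all_active_map(self, target):
        amap = ActivationMap(np.ones_like(target.weights, bool), target.contacts)
        spec, sens = ciuq.global_scores(amap, target)
        assert spec == 0.0 and sens == 1.0

    def test_toy_map_hand_count(self):
        # 4 bundles x 3 contacts, confusion counted by hand
        w = np.array(
            [[1.0, -0.25, -0.25], [0.5, 1.0, -0.25], [-0.25, 0.5, 1.0], [-0.25, -0.25, 0.5]]
        )
        act = np.array([[1, 0, 0], [1, 1, 1], [0, 0, 1], [1, 0, 0]], dtype=bool)
        t = TargetMap(
            weights=w,
            contacts=["E1", "E2", "E3"],
            contact_arc_mm=np.zeros(3),
            contact_theta=np.zeros(3),
            fiber_arc_mm=np.zeros(4),
            fiber_theta=np.zeros(4),
            band_halfwidth_mm=1.5,
        )
        amap = ActivationMap(act, ["E1", "E2", "E3"])
        # positives: (0,0),(1,0),(1,1),(2,1),(2,2),(3,2) -> TP: (0,0),(1,0),(1,1),(2,2) = 4, FN = 2
        # negatives: 6 cells -> FP: (1,2),(3,0) = 2, TN = 4
        spec, sens = ciuq.global_scores(amap, t)
        assert spec == pytest.approx(4 / 6)
        assert sens == pytest.approx(4 / 6)

    def test_matches_bruteforce_on_random_maps(self, target, rng):
        for _ in range(100):
            act = rng.random(target.weights.shape) < rng.uniform(0.05, 0.6)
            amap = ActivationMap(act, target.contacts)
            spec, sens = ciuq.global_scores(amap, target)
            tp = tn = fp = fn = 0
            for i in range(act.shape[0]):
                for e in range(act.shape[1]):
                    pos = target.weights[i, e] > 0
                    if act[i, e] and pos:
                        tp += 1
                    elif act[i, e]:
                        fp += 1
                    elif pos:
                        fn += 1
                    else:
                        tn += 1
            assert spec == pytest.approx(tn / (tn + fp))
            assert sens == pytest.approx(tp / (tp + fn))


class TestMismatchMap:
    def test_identical_maps_no_errors(self, target):
        amap = ActivationMap(target.weights > 0, target.contacts)
        mm = ciuq.mismatch_map(amap, target)
        assert not np.isin(mm, [MISMATCH_CODES["FP"], MISMATCH_CODES["FN"]]).any()

    def test_single_flip_single_error(self, target):
        act = target.weights > 0
        act[10, 3] = ~act[10, 3]
        mm = ciuq.mismatch_map(ActivationMap(act, target.contacts), target)
        errors = np.isin(mm, [MISMATCH_CODES["FP"], MISMATCH_CODES["FN"]])
        assert errors.sum() == 1

    def test_categories_partition_cells(self, amap, target):
        mm = ciuq.mismatch_map(amap, target)
        counts = [(mm == c).sum() for c in MISMATCH_CODES.values()]
        assert sum(counts) == 334 * 12

    def test_consistent_with_global_scores(self, amap, target):
        mm = ciuq.mismatch_map(amap, target)
        tn = (mm == MISMATCH_CODES["TN"]).sum()
        fp = (mm == MISMATCH_CODES["FP"]).sum()
        spec, _ = ciuq.global_scores(amap, target)
        assert spec == pytest.approx(tn / (tn + fp))


class TestScoreSet:
    def test_scores_within_bounds(self, mean_ctx):
        sc = mean_ctx.score()
        valid = ~np.isnan(sc.local)
        assert np.all((sc.local[valid] >= 0) & (sc.local[valid] <= 100))
        valid = ~np.isnan(sc.cross_turn)
        assert np.all((sc.cross_turn[valid] >= 0) & (sc.cross_turn[valid] <= 100))
        assert 0 <= sc.specificity <= 1 and 0 <= sc.sensitivity <= 1

    def test_map_csv_roundtrip(self, amap, tmp_path):
        path = tmp_path / "amap.csv"
        amap.to_csv(path)
        back = ActivationMap.from_csv(path)
        np.testing.assert_array_equal(back.matrix, amap.matrix)
        assert back.contacts == amap.contacts
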