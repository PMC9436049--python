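import numpy as np
import pytest

from concord import (
    agreed_volume_at_cl,
    analysis_region,
    apparent_agreement_map,
    assemble_observer_set,
    classify_conformity,
    classify_kappa,
    fleiss_kappa,
    generalized_ci,
    volume_stats,
)
from concord.agreement import DegenerateAgreementError, EmptyRegionError

from conftest import mask_from_array, random_panel


def brute_force_fleiss(obs, region):
    """Independent oracle: per-voxel double loop over rater pairs."""
    stack = obs.stack()
    R = obs.n_observers
    idx = np.argwhere(region)
    agreements = []
    for i in idx:
        ratings = [int(stack[(j, *i)]) for j in range(R)]
        agree = sum(
            ratings[a] == ratings[b]
            for a in range(R)
            for b in range(R)
            if a != b
        )
        agreements.append(agree / (R * (R - 1)))
    p_bar = float(np.mean(agreements))
    marked = sum(int(stack[(j, *i)]) for i in idx for j in range(R))
    p1 = marked / (len(idx) * R)
    p_e = p1**2 + (1 - p1) ** 2
    return p_bar, p_e, (p_bar - p_e) / (1 - p_e)


def brute_force_ci(obs):
    """Independent oracle: explicit pairwise intersections/unions."""
    masks = [m.voxels.astype(bool) for m in obs.masks]
    inter = union = 0
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter += int((masks[i] & masks[j]).sum())
            union += int((masks[i] | masks[j]).sum())
    return inter / union


class TestVolumeStats:
    def test_identical_panel_degenerate(self, identical_panel):
        vs = volume_stats(identical_panel)
        common = identical_panel.masks[0].volume_cm3
        assert (
            vs.min_cm3 == vs.max_cm3 == vs.mean_cm3
            == vs.union_cm3 == vs.intersection_cm3 == common
        )
        assert vs.sd_cm3 == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10, 20), dtype=np.uint8)
        b = np.zeros((10, 10, 20), dtype=np.uint8)
        a[:, :, :10] = 1  # 1000 voxels = 1 cm3 at unit spacing... scale up
        b[:, :, 10:] = 1
        obs = assemble_observer_set(
            [mask_from_array(a, spacing=(2.0, 2.0, 2.5)),
             mask_from_array(b, spacing=(2.0, 2.0, 2.5))],
            ["a", "b"], "disjoint",
        )
        vs = volume_stats(obs)
        assert vs.intersection_cm3 == 0.0
        assert vs.union_cm3 == pytest.approx(vs.per_observer_cm3[0] * 2)
        assert vs.mean_cm3 == pytest.approx(vs.per_observer_cm3[0])

    def test_nested_boxes(self):
        # nested 1 / 2 / 3 cm3 boxes at unit spacing
        masks = []
        for n_vox in (1000, 2000, 3000):
            v = np.zeros((20, 20, 20), dtype=np.uint8)
            v[:10, :10, :10] = 1  # 1000
            if n_vox >= 2000:
                v[10:20, :10, :10] = 1
            if n_vox >= 3000:
                v[:10, 10:20, :10] = 1
            masks.append(mask_from_array(v))
        vs = volume_stats(assemble_observer_set(masks, ["a", "b", "c"], "nested"))
        assert vs.union_cm3 == pytest.approx(3.0)
        assert vs.intersection_cm3 == pytest.approx(1.0)
        assert vs.mean_cm3 == pytest.approx(2.0)
        assert vs.sd_cm3 == pytest.approx(1.0)

    def test_ordering_invariant(self, small_panel):
        vs = volume_stats(small_panel)
        assert (
            vs.intersection_cm3 <= vs.min_cm3 <= vs.mean_cm3
            <= vs.max_cm3 <= vs.union_cm3
        )


class TestAnalysisRegion:
    def test_whole_lattice_union(self):
        m = mask_from_array(np.ones((5, 5, 5)))
        obs = assemble_observer_set([m, m], ["a", "b"], "c")
        assert analysis_region(obs, margin_mm=0).all()

    def test_single_voxel_margins(self):
        v = np.zeros((11, 11, 11), dtype=np.uint8)
        v[5, 5, 5] = 1
        obs = assemble_observer_set(
            [mask_from_array(v)] * 2, ["a", "b"], "c"
        )
        assert analysis_region(obs, margin_mm=0).sum() == 1
        assert analysis_region(obs, margin_mm=2).sum() == 125  # 5x5x5

    def test_margin_in_mm_not_voxels(self):
        v = np.zeros((11, 11, 11), dtype=np.uint8)
        v[5, 5, 5] = 1
        obs = assemble_observer_set(
            [mask_from_array(v, spacing=(2.0, 2.0, 2.0))] * 2, ["a", "b"], "c"
        )
        # 2 mm margin = 1 voxel per side at 2 mm spacing
        assert analysis_region(obs, margin_mm=2).sum() == 27

    def test_empty_union_raises(self):
        m = mask_from_array(np.zeros((4, 4, 4)))
        obs = assemble_observer_set([m, m], ["a", "b"], "c")
        with pytest.raises(EmptyRegionError):
            analysis_region(obs)


class TestApparentAgreementMap:
    def test_identical_panel_equals_common_mask(self, identical_panel):
        amap = apparent_agreement_map(identical_panel)
        np.testing.assert_array_equal(amap, identical_panel.masks[0].voxels)

    def test_fractions(self):
        v1 = np.zeros((3, 1, 1), dtype=np.uint8)
        v1[0] = 1
        v2 = np.ones((3, 1, 1), dtype=np.uint8)
        obs = assemble_observer_set(
            [mask_from_array(v1), mask_from_array(v2), mask_from_array(v2)],
            ["a", "b", "c"], "frac",
        )
        amap = apparent_agreement_map(obs)
        assert amap[0, 0, 0] == pytest.approx(1.0)
        assert amap[1, 0, 0] == pytest.approx(2 / 3)

    def test_integral_equals_mean_volume(self, small_panel):
        amap = apparent_agreement_map(small_panel)
        vv = small_panel.grid.voxel_volume_mm3 / 1000.0
        assert amap.sum() * vv == pytest.approx(volume_stats(small_panel).mean_cm3)


class TestAgreedVolumeAtCl:
    def test_endpoints_are_union_and_intersection(self, rng):
        for _ in range(10):
            obs = random_panel(rng, n_obs=int(rng.integers(2, 7)))
            counts = obs.rating_counts()
            np.testing.assert_array_equal(
                agreed_volume_at_cl(obs, 0.0).voxels, (counts > 0).astype(np.uint8)
            )
            np.testing.assert_array_equal(
                agreed_volume_at_cl(obs, 1.0).voxels,
                (counts == obs.n_observers).astype(np.uint8),
            )

    def test_cl80_of_nine_needs_eight(self):
        # 3 voxels marked by 9 / 8 / 7 observers respectively
        masks = []
        for j in range(9):
            v = np.zeros((3, 1, 1), dtype=np.uint8)
            v[0] = 1
            if j < 8:
                v[1] = 1
            if j < 7:
                v[2] = 1
            masks.append(mask_from_array(v))
        obs = assemble_observer_set(masks, [f"o{j}" for j in range(9)], "toy")
        got = agreed_volume_at_cl(obs, 0.8).voxels.ravel()
        np.testing.assert_array_equal(got, [1, 1, 0])  # ceil(0.8 * 9) = 8

    def test_monotone_nesting_in_cl(self, rng):
        obs = random_panel(rng, n_obs=5)
        prev = agreed_volume_at_cl(obs, 0.0).voxels
        for cl in np.linspace(0.1, 1.0, 10):
            cur = agreed_volume_at_cl(obs, float(cl)).voxels
            assert not (cur & ~prev).any(), f"not nested at cl={cl}"
            prev = cur


class TestFleissKappa:
    def test_perfect_agreement(self, identical_panel):
        region = analysis_region(identical_panel, margin_mm=0)
        res = fleiss_kappa(identical_panel, region)
        assert res.kappa == pytest.approx(1.0)
        assert res.apparent_agreement == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_hand_computed_two_rater_example(self):
        # ratings per voxel: (1,1), (0,0), (1,0)
        a = mask_from_array(np.array([1, 0, 1]).reshape(3, 1, 1))
        b = mask_from_array(np.array([1, 0, 0]).reshape(3, 1, 1))
        obs = assemble_observer_set([a, b], ["a", "b"], "hand")
        res = fleiss_kappa(obs, np.ones((3, 1, 1), dtype=bool))
        assert res.apparent_agreement == pytest.approx(2 / 3)
        assert res.chance_agreement == pytest.approx(1 / 2)
        assert res.kappa == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle(self, rng):
        for n_obs in (2, 3, 5):
            obs = random_panel(rng, shape=(6, 5, 4), n_obs=n_obs)
            region = analysis_region(obs, margin_mm=0)
            res = fleiss_kappa(obs, region)
            p_bar, p_e, kappa = brute_force_fleiss(obs, region)
            assert res.apparent_agreement == pytest.approx(p_bar, abs=1e-12)
            assert res.chance_agreement == pytest.approx(p_e, abs=1e-12)
            assert res.kappa == pytest.approx(kappa, abs=1e-12)

    def test_region_matters_and_is_recorded(self, rng):
        # panel confined to a sub-block so the bounding box is a strict
        # subset of the lattice
        masks = []
        for _ in range(4):
            v = np.zeros((12, 12, 12), dtype=np.uint8)
            v[3:8, 3:8, 3:8] = rng.random((5, 5, 5)) < 0.5
            masks.append(mask_from_array(v))
        obs = assemble_observer_set(masks, list("abcd"), "sub")
        bbox = analysis_region(obs, margin_mm=0)
        whole = np.ones(obs.grid.shape, dtype=bool)
        assert not bbox.all()
        k_bbox = fleiss_kappa(obs, bbox)
        k_whole = fleiss_kappa(obs, whole)
        assert k_bbox.region_voxels < k_whole.region_voxels
        assert k_bbox.apparent_agreement < k_whole.apparent_agreement
        assert k_bbox.kappa != pytest.approx(k_whole.kappa, abs=1e-9)

    def test_rater_order_invariance(self, rng):
        obs = random_panel(rng, n_obs=5)
        region = analysis_region(obs, margin_mm=5)
        base = fleiss_kappa(obs, region)
        perm = assemble_observer_set(
            list(obs.masks[::-1]), list(obs.observer_labels[::-1]), obs.case_id
        )
        res = fleiss_kappa(perm, region)
        assert res.kappa == pytest.approx(base.kappa, abs=1e-15)

    def test_degenerate_all_one_category(self):
        m = mask_from_array(np.ones((4, 4, 4)))
        obs = assemble_observer_set([m, m], ["a", "b"], "full")
        with pytest.raises(DegenerateAgreementError):
            fleiss_kappa(obs, np.ones((4, 4, 4), dtype=bool))

    def test_significance_fields(self, small_panel):
        res = fleiss_kappa(small_panel, analysis_region(small_panel, margin_mm=0))
        assert np.isfinite(res.z_statistic)
        assert 0 < res.p_value <= 1


class TestClassification:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.573, "moderate"),
            (0.0, "no"),
            (-0.1, "no"),
            (0.85, "excellent"),
            (0.2, "slight"),
            (0.4, "fair"),
            (0.6, "moderate"),
            (0.8, "substantial"),
            (1.0, "excellent"),
        ],
    )
    def test_kappa_bins(self, kappa, label):
        assert classify_kappa(kappa) == label

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_kappa(1.2)

    @pytest.mark.parametrize(
        "ci,label",
        [(0.487, "weak"), (0.372, "weak"), (0.5, "intermediate"),
         (0.69, "intermediate"), (0.7, "suitable"), (1.0, "suitable")],
    )
    def test_conformity_bins(self, ci, label):
        assert classify_conformity(ci) == label


class TestGeneralizedCI:
    def test_identical_masks(self, identical_panel):
        res = generalized_ci(identical_panel)
        assert res.ci_gen == pytest.approx(1.0)
        assert res.label == "suitable"

    def test_two_masks_partial_overlap(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a.flat[:8] = 1
        b.flat[4:12] = 1  # |A|=|B|=8, overlap 4, union 12
        obs = assemble_observer_set(
            [mask_from_array(a), mask_from_array(b)], ["a", "b"], "pair"
        )
        assert generalized_ci(obs).ci_gen == pytest.approx(1 / 3)

    def test_two_raters_equals_jaccard(self, rng):
        for _ in range(5):
            obs = random_panel(rng, n_obs=2)
            a, b = (m.voxels.astype(bool) for m in obs.masks)
            jac = (a & b).sum() / (a | b).sum()
            assert generalized_ci(obs).ci_gen == pytest.approx(jac, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for n_obs in (3, 5, 9):
            obs = random_panel(rng, shape=(6, 6, 6), n_obs=n_obs)
            assert generalized_ci(obs).ci_gen == pytest.approx(
                brute_force_ci(obs), abs=1e-12
            )

    def test_order_invariance_and_bounds(self, rng):
        obs = random_panel(rng, n_obs=4)
        res = generalized_ci(obs)
        assert 0.0 <= res.ci_gen <= 1.0
        perm = assemble_observer_set(
            list(obs.masks[::-1]), list(obs.observer_labels[::-1]), obs.case_id
        )
        assert generalized_ci(perm).ci_gen == pytest.approx(res.ci_gen, abs=1e-15)

    def test_all_empty_rejected(self):
        m = mask_from_array(np.zeros((4, 4, 4)))
        obs = assemble_observer_set([m, m], ["a", "b"], "empty")
        with pytest.raises(ValueError):
            generalized_ci(obs)
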