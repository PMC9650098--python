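"""Morphometry: projection, thresholding, apposition, areas, fiber-type
classification, and round-trip recovery of generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmtflab as nl
from nmtflab.morphometry import clean_mask


def _stack_from_volumes(post, pre, pixel_size=0.176, z_step=2.0):
    return nl.NMJStack(post=np.asarray(post), pre=np.asarray(pre),
                       pixel_size_um=pixel_size, z_step_um=z_step, provenance={})


class TestProjectStack:
    def test_single_slice_projection_is_identity(self):
        img = np.full((1, 16, 16), 10.0)
        img[0, 4:8, 4:8] = 100.0
        stack = _stack_from_volumes(img, img)
        post, pre, n = nl.project_stack(stack, slice_range=(0, 0))
        np.testing.assert_array_equal(post, img[0])
        assert n == 1

    def test_auto_range_selects_signal_slices(self):
        """Signal confined to slices 2-9 of 12 -> auto-range projects 8 slices."""
        params = nl.NMJShapeParams(n_slices=12, occupied_slices=(2, 9), seed=11)
        stack, _ = nl.render_nmj_stack(params)
        _, _, n = nl.project_stack(stack)
        assert n == 8

    def test_all_zero_stack_is_an_error(self):
        z = np.zeros((4, 8, 8))
        with pytest.raises(ValueError, match="no signal slices"):
            nl.project_stack(_stack_from_volumes(z, z))


class TestThresholdChannel:
    def test_two_level_image_separates_exactly(self):
        img = np.full((32, 32), 10.0)
        img[8:16, 8:16] = 100.0
        mask, info = nl.threshold_channel(img, "otsu")
        np.testing.assert_array_equal(mask, img == 100.0)
        assert info["method"] == "otsu"
        assert 10.0 < info["threshold"] < 100.0

    def test_jaccard_against_true_mask(self, default_stack):
        stack, gt = default_stack
        post_img, _, _ = nl.project_stack(stack)
        mask, _ = nl.threshold_channel(post_img, "otsu")
        mask = clean_mask(mask, stack.pixel_size_um, keep_largest=True)
        inter = np.logical_and(mask, gt.post_mask).sum()
        union = np.logical_or(mask, gt.post_mask).sum()
        assert inter / union >= 0.9

    def test_fixed_zero_threshold_degenerate(self):
        img = np.full((8, 8), 10.0)
        mask, info = nl.threshold_channel(img, "fixed:0")
        assert mask.all()
        assert info == {"method": "fixed", "threshold": 0.0}

    def test_constant_image_rejected_under_otsu(self):
        with pytest.raises(ValueError, match="non-constant"):
            nl.threshold_channel(np.ones((8, 8)), "otsu")


class TestApposition:
    def test_identical_masks_full_apposition(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        assert nl.compute_apposition(m, m) == 100.0

    def test_disjoint_masks_zero(self):
        post = np.zeros((10, 10), bool)
        post[:3] = True
        pre = ~post
        assert nl.compute_apposition(pre, post) == 0.0

    def test_pixel_count_arithmetic(self):
        post = np.zeros((30, 30), bool)
        post[:, :20] = False
        post.ravel()[:200] = True
        pre = np.zeros_like(post)
        pre.ravel()[:120] = True
        assert nl.compute_apposition(pre, post) == pytest.approx(60.0)

    def test_empty_post_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nl.compute_apposition(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_invariant_to_intensity_rescaling(self, default_stack):
        """Otsu-based apposition does not change when a channel is rescaled."""
        stack, _ = default_stack
        post_img, pre_img, _ = nl.project_stack(stack)

        def appo(post_i, pre_i):
            post_m, _ = nl.threshold_channel(post_i)
            pre_m, _ = nl.threshold_channel(pre_i)
            return nl.compute_apposition(pre_m, post_m)

        base = appo(post_img, pre_img)
        scaled = appo(post_img * 2.5, pre_img * 0.5)
        assert scaled == pytest.approx(base, abs=1e-9)


class TestAreas:
    def test_full_rectangle_fills_bbox(self):
        m = np.zeros((12, 12), bool)
        m[3:7, 2:10] = True
        csa, ortho, rel = nl.compute_areas(m, 1.0)
        assert rel == 100.0
        assert csa == ortho == 32.0

    def test_pixel_area_arithmetic(self):
        m = np.zeros((20, 20), bool)
        m.ravel()[:100] = True
        csa, _, _ = nl.compute_areas(m, 0.5)
        assert csa == pytest.approx(25.0)

    def test_relative_planar_area_bounded(self, default_stack):
        stack, _ = default_stack
        post_img, _, _ = nl.project_stack(stack)
        mask, _ = nl.threshold_channel(post_img)
        _, _, rel = nl.compute_areas(mask, stack.pixel_size_um)
        assert rel <= 100.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nl.compute_areas(np.zeros((4, 4), bool), 1.0)


class TestClassifyFiberType:
    @pytest.mark.parametrize("area, diameter, expected", [
        (400.0, 40.0, "I_IIa"),
        (600.0, 60.0, "IIx_IIb"),
        (600.0, 40.0, "excluded"),
        (400.0, 60.0, "excluded"),
        (500.0, 50.0, "excluded"),   # exact boundary falls in the gap
    ])
    def test_truth_table(self, area, diameter, expected):
        assert nl.classify_fiber_type(area, diameter) == expected

    @given(st.floats(min_value=1.0, max_value=1200.0),
           st.floats(min_value=1.0, max_value=120.0))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_rule_consistency(self, area, diameter):
        cls = nl.classify_fiber_type(area, diameter)
        if cls == "I_IIa":
            assert area < 500.0 and diameter < 50.0
        elif cls == "IIx_IIb":
            assert area > 500.0 and diameter > 50.0
        else:
            assert not ((area < 500.0 and diameter < 50.0)
                        or (area > 500.0 and diameter > 50.0))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            nl.classify_fiber_type(0.0, 40.0)


class TestRoundTrip:
    def test_single_stack_recovery(self, default_stack):
        stack, gt = default_stack
        m = nl.measure_nmj(stack, gt.fiber_diameter_um)
        assert m.apposition_pct == pytest.approx(gt.apposition_pct, abs=2.0)
        assert m.endplate_csa_um2 == pytest.approx(gt.endplate_csa_um2, rel=0.05)
        assert m.relative_planar_area_pct == pytest.approx(
            gt.relative_planar_area_pct, abs=3.0)

    def test_cohort_mean_recovery(self):
        """Over a synthetic cohort at default noise, mean recovered apposition,
        endplate CSA and relative planar area are each within 5% relative
        error of the generator truth."""
        cohort = nl.generate_nmj_cohort(n_per_class_per_animal=3, n_animals=4,
                                        seed=5)
        meas = [nl.measure_nmj(s, gt.fiber_diameter_um) for s, gt, _ in cohort]
        for attr in ("apposition_pct", "endplate_csa_um2",
                     "relative_planar_area_pct"):
            got = np.mean([getattr(m, attr) for m in meas])
            want = np.mean([getattr(gt, attr) for _, gt, _ in cohort])
            assert got == pytest.approx(want, rel=0.05)

    def test_noise_degrades_but_does_not_bias(self):
        """Heavy noise (10% of peak signal) shifts mean apposition <= 2 points."""
        deltas = []
        for seed in range(1, 7):
            params = nl.NMJShapeParams(noise_sd=90.0, seed=seed)
            stack, gt = nl.render_nmj_stack(params)
            m = nl.measure_nmj(stack, gt.fiber_diameter_um)
            deltas.append(m.apposition_pct - gt.apposition_pct)
        assert abs(np.mean(deltas)) <= 2.0

    def test_class_mean_apposition_recovery(self):
        cohort = nl.generate_nmj_cohort(n_per_class_per_animal=3, n_animals=2,
                                        seed=3)
        samples = [(s, {**meta}) for s, _, meta in cohort]
        per_nmj, per_class, per_animal = nl.analyze_nmj_cohort(samples)
        truth = {}
        for _, gt, meta in cohort:
            truth.setdefault(meta["requested_class"], []).append(gt.apposition_pct)
        for cls, vals in truth.items():
            got = per_nmj[per_nmj["fiber_type_class"] == cls]["apposition_pct"]
            if len(got):
                assert got.mean() == pytest.approx(np.mean(vals), abs=2.0)

    def test_cohort_table_contracts(self, default_stack):
        stack, gt = default_stack
        meta = {"animal_id": "r1", "fiber_diameter_um": gt.fiber_diameter_um}
        per_nmj, per_class, per_animal = nl.analyze_nmj_cohort([(stack, meta)])
        # single NMJ per animal: the per-animal mean equals that NMJ
        assert per_animal.loc[0, "apposition_pct"] == per_nmj.loc[0, "apposition_pct"]
        # an all-excluded cohort leaves the typed table empty but not the overall
        mismatched = {"animal_id": "r1", "fiber_diameter_um": 60.0}  # small NMJ, thick fiber
        per_nmj2, per_class2, per_animal2 = nl.analyze_nmj_cohort([(stack, mismatched)])
        assert (per_nmj2["fiber_type_class"] == "excluded").all()
        assert per_class2.empty
        assert len(per_animal2) == 1
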