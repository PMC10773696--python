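import numpy as np
import pytest

from endoframe import fixtures, preprocess
from endoframe.frame import Frame, LabeledDataset
from endoframe.preprocess import (
    AugmentationPlan,
    apply_manipulation,
    augment_dataset,
    augmentation_quota,
    build_mask,
    detect_strong,
    expand_weak,
    remove_reflections,
    to_grayscale,
)

from conftest import make_solid_frame


class TestToGrayscale:
    def test_white(self):
        assert to_grayscale(make_solid_frame((255, 255, 255)))[0, 0] == 255

    def test_black(self):
        assert to_grayscale(make_solid_frame((0, 0, 0)))[0, 0] == 0

    def test_bt601_weights(self):
        # round(0.299*100 + 0.587*200 + 0.114*50) = round(153.0) = 153
        assert to_grayscale(make_solid_frame((100, 200, 50)))[0, 0] == 153


class TestDetectStrong:
    def test_above_threshold(self):
        gray = np.full((4, 4), 200, dtype=np.uint8)
        assert (detect_strong(gray) == 255).all()

    def test_boundary_is_strict(self):
        gray = np.full((4, 4), 180, dtype=np.uint8)
        assert detect_strong(gray).sum() == 0

    def test_dim_frame_empty(self):
        gray = np.full((4, 4), 100, dtype=np.uint8)
        assert detect_strong(gray).sum() == 0

    def test_monotone_in_threshold(self, rng):
        gray = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        sizes = [int((detect_strong(gray, t) > 0).sum()) for t in (100, 150, 180, 220)]
        assert sizes == sorted(sizes, reverse=True)


class TestExpandWeak:
    def test_weak_neighbour_joins(self):
        gray = np.zeros((3, 3), dtype=np.uint8)
        gray[1, 1] = 200
        gray[1, 2] = 160
        strong = detect_strong(gray)
        out = expand_weak(gray, strong)
        assert out[1, 2] == 255

    def test_disconnected_weak_stays_out(self):
        gray = np.zeros((5, 5), dtype=np.uint8)
        gray[0, 0] = 200
        gray[4, 4] = 160  # not reachable through any weak chain
        out = expand_weak(gray, detect_strong(gray))
        assert out[4, 4] == 0

    def test_empty_seed_gives_empty_mask(self):
        gray = np.full((6, 6), 160, dtype=np.uint8)  # all weak, no strong
        out = expand_weak(gray, np.zeros_like(gray))
        assert out.sum() == 0

    def test_monotone_superset_of_strong(self, rng):
        gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        strong = detect_strong(gray)
        out = expand_weak(gray, strong)
        assert (out[strong > 0] == 255).all()

    def test_idempotent_at_fixed_point(self, rng):
        gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        once = expand_weak(gray, detect_strong(gray))
        twice = expand_weak(gray, once)
        np.testing.assert_array_equal(once, twice)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expand_weak(np.zeros((3, 3), np.uint8), np.zeros((4, 4), np.uint8))

    def test_chain_propagation(self):
        # strong seed at one end, weak chain across the row
        gray = np.zeros((3, 7), dtype=np.uint8)
        gray[1, 0] = 220
        gray[1, 1:6] = 140
        out = expand_weak(gray, detect_strong(gray))
        assert (out[1, :6] == 255).all()
        assert out[1, 6] == 0


class TestBuildMask:
    def test_covers_ground_truth_cores(self, reflected):
        frame, truth = reflected
        gray = to_grayscale(frame)
        mask = build_mask(frame)
        cores = gray > 180
        assert (mask[cores] == 255).all()

    def test_dilate_zero_equals_raw_expansion(self, reflected):
        frame, _ = reflected
        gray = to_grayscale(frame)
        raw = expand_weak(gray, detect_strong(gray))
        np.testing.assert_array_equal(build_mask(frame, dilate_px=0), raw)

    def test_reflection_free_frame_empty(self, small_frame):
        assert build_mask(small_frame).sum() == 0

    def test_negative_dilation_rejected(self, small_frame):
        with pytest.raises(ValueError):
            build_mask(small_frame, dilate_px=-1)


class TestRemoveReflections:
    def test_empty_mask_is_identity(self, small_frame):
        mask = np.zeros(small_frame.shape, dtype=np.uint8)
        out = remove_reflections(small_frame, mask)
        np.testing.assert_array_equal(out.pixels, small_frame.pixels)

    def test_constant_frame_stays_constant(self):
        f = make_solid_frame((90, 60, 70))
        mask = np.zeros(f.shape, dtype=np.uint8)
        mask[10:20, 10:20] = 255
        for method in ("fmm_telea", "navier_stokes"):
            out = remove_reflections(f, mask, method=method)
            np.testing.assert_array_equal(out.pixels, f.pixels)

    @pytest.mark.parametrize("method", ["fmm_telea", "navier_stokes"])
    def test_unmasked_pixels_bit_exact(self, reflected, method):
        frame, _ = reflected
        mask = build_mask(frame)
        out = remove_reflections(frame, mask, method=method)
        np.testing.assert_array_equal(out.pixels[mask == 0], frame.pixels[mask == 0])

    def test_detections_reduced(self, reflected):
        frame, _ = reflected
        before = int((detect_strong(to_grayscale(frame)) > 0).sum())
        out = remove_reflections(frame, build_mask(frame))
        after = int((detect_strong(to_grayscale(out)) > 0).sum())
        assert before > 0
        assert after < before

    def test_unknown_method_rejected(self, reflected):
        frame, _ = reflected
        with pytest.raises(ValueError):
            remove_reflections(frame, build_mask(frame), method="magic")


class TestAugmentationQuota:
    def test_kvasir_v2_profile(self):
        quota = augmentation_quota({"out_of_patient": 9, "stool_plenty": 2331})
        assert quota["out_of_patient"] == 2555  # floor(2331*1.1 - 9)

    def test_single_class(self):
        assert augmentation_quota({"A": 10}) == {"A": 1}  # floor(11 - 10)

    def test_balanced_totals(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            counts = {f"c{i}": int(rng.integers(1, 500)) for i in range(n)}
            quota = augmentation_quota(counts)
            totals = [counts[c] + quota[c] for c in counts]
            assert max(totals) - min(totals) <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            augmentation_quota({})


class TestApplyManipulation:
    def test_flip_is_involution(self, textured_frame):
        # same seed draws the same axis, so flipping twice restores the frame
        once = apply_manipulation(textured_frame, "flip", np.random.default_rng(3))
        twice = apply_manipulation(once, "flip", np.random.default_rng(3))
        np.testing.assert_array_equal(twice.pixels, textured_frame.pixels)

    def test_resize_draw_bounds(self):
        f = make_solid_frame((50, 50, 50), h=300, w=300)
        for seed in range(10):
            out = apply_manipulation(f, "resize", np.random.default_rng(seed))
            assert 256 <= out.shape[0] <= 300
            assert 256 <= out.shape[1] <= 300

    def test_crop_bounds_small_frame(self, textured_frame):
        out = apply_manipulation(textured_frame, "crop", np.random.default_rng(0))
        assert out.shape[0] <= 256 and out.shape[1] <= 256

    def test_zero_sigma_noise_is_identity(self, textured_frame):
        out = apply_manipulation(
            textured_frame, "noise", np.random.default_rng(0), sigma=0.0
        )
        np.testing.assert_array_equal(out.pixels, textured_frame.pixels)

    def test_output_valid_uint8(self, textured_frame):
        for kind in preprocess.MANIPULATIONS:
            out = apply_manipulation(textured_frame, kind, np.random.default_rng(1))
            assert out.pixels.dtype == np.uint8

    def test_unknown_kind_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            apply_manipulation(textured_frame, "shear", np.random.default_rng(0))


class TestAugmentDataset:
    def _two_class(self, class_specs):
        imb = fixtures.ImbalanceSpec(
            {class_specs[0].name: 4, class_specs[1].name: 10}
        )
        return fixtures.make_dataset(class_specs[:2], imb, seed=6)

    def test_totals_balanced(self, class_specs):
        data = self._two_class(class_specs)
        plan = AugmentationPlan(quota=augmentation_quota(data.class_counts()), seed=1)
        out = augment_dataset(data, plan)
        counts = out.class_counts()
        assert counts[class_specs[0].name] == 11  # floor(1.1 * 10)
        assert counts[class_specs[1].name] == 11

    def test_deterministic(self, class_specs):
        data = self._two_class(class_specs)
        plan = AugmentationPlan(quota=augmentation_quota(data.class_counts()), seed=2)
        a = augment_dataset(data, plan)
        b = augment_dataset(data, plan)
        assert a.manifest().to_csv(index=False) == b.manifest().to_csv(index=False)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_provenance_recorded(self, class_specs):
        data = self._two_class(class_specs)
        plan = AugmentationPlan(quota=augmentation_quota(data.class_counts()), seed=3)
        out = augment_dataset(data, plan)
        originals = {f.id for f in data}
        for f in out.frames[len(data):]:
            assert f.source_id in originals

    def test_originals_untouched(self, class_specs):
        data = self._two_class(class_specs)
        plan = AugmentationPlan(quota=augmentation_quota(data.class_counts()), seed=4)
        out = augment_dataset(data, plan)
        for fa, fb in zip(data, out.frames[: len(data)]):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_missing_quota_rejected(self, class_specs):
        data = self._two_class(class_specs)
        with pytest.raises(ValueError):
            augment_dataset(data, AugmentationPlan(quota={class_specs[0].name: 1}))

    def test_unseen_quota_class_warns(self, class_specs):
        data = self._two_class(class_specs)
        quota = augmentation_quota(data.class_counts())
        quota["ghost"] = 5
        with pytest.warns(UserWarning, match="ghost"):
            augment_dataset(data, AugmentationPlan(quota=quota))
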