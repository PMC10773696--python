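import numpy as np
import pytest

from endoframe.features import (
    MinMaxScaler,
    auto_color_correlogram,
    color_histogram,
    extract_bank,
    fit_scaler,
    glcm,
    haralick,
    lbp_histogram,
    lbp_map,
    lire_descriptor,
    ltp_maps,
    scale,
)
from endoframe.features.bank import ALL_DESCRIPTORS, bank_spans, compute_descriptor, descriptor_dim
from endoframe.features.color import quantize_colors
from endoframe.features.lire import LIRE_DIMS
from endoframe.features.texture import GLCMMatrix, glcm_all_directions, quantize
from endoframe.frame import Frame

from conftest import make_solid_frame

# ---------------------------------------------------------------- oracles

_CLOCKWISE_R1 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def naive_lbp_r1(gray):
    """Per-pixel loop oracle for radius-1 codes (integer positions)."""
    h, w = gray.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            code = 0
            for p, (dy, dx) in enumerate(_CLOCKWISE_R1):
                if gray[y + dy, x + dx] >= gray[y, x]:
                    code += 2**p
            out[y - 1, x - 1] = code
    return out


def naive_ltp_r1(gray):
    h, w = gray.shape
    up = np.zeros((h - 2, w - 2), dtype=int)
    lo = np.zeros((h - 2, w - 2), dtype=int)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            for p, (dy, dx) in enumerate(_CLOCKWISE_R1):
                n, c = gray[y + dy, x + dx], gray[y, x]
                if n > c:
                    up[y - 1, x - 1] += 2**p
                elif n < c:
                    lo[y - 1, x - 1] += 2**p
    return up, lo


def naive_glcm(gray, levels, distance, direction):
    """Brute-force ordered-pair enumeration over the whole image."""
    q = quantize(gray, levels)
    h, w = q.shape
    off = {"horizontal": (0, distance), "vertical": (distance, 0),
           "diag_up": (-distance, distance), "diag_down": (distance, distance)}[direction]
    counts = np.zeros((levels, levels), dtype=int)
    for y in range(h):
        for x in range(w):
            ny, nx = y + off[0], x + off[1]
            if 0 <= ny < h and 0 <= nx < w:
                counts[q[y, x], q[ny, nx]] += 1
                counts[q[ny, nx], q[y, x]] += 1
    return counts


def naive_correlogram(px, levels, distances):
    idx, palette = quantize_colors(px, levels)
    h, w = idx.shape
    out = np.zeros(palette * len(distances))
    for di, k in enumerate(distances):
        same = np.zeros(palette)
        tot = np.zeros(palette)
        for y in range(h):
            for x in range(w):
                for dy in range(-k, k + 1):
                    for dx in range(-k, k + 1):
                        if max(abs(dy), abs(dx)) != k:
                            continue
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w:
                            tot[idx[y, x]] += 1
                            if idx[ny, nx] == idx[y, x]:
                                same[idx[y, x]] += 1
        nz = tot > 0
        block = np.zeros(palette)
        block[nz] = same[nz] / tot[nz]
        out[di * palette : (di + 1) * palette] = block
    return out


# ---------------------------------------------------------------- LBP / LTP

class TestLBP:
    def test_constant_image_codes_255(self):
        gray = np.full((8, 8), 77, dtype=np.uint8)
        assert (lbp_map(gray, 1).codes == 255).all()

    def test_isolated_bright_center(self):
        gray = np.zeros((3, 3), dtype=np.uint8)
        gray[1, 1] = 200
        assert lbp_map(gray, 1).codes[0, 0] == 0

    def test_hand_computed_patch(self):
        patch = np.array([[5, 2, 3], [4, 6, 1], [7, 8, 9]], dtype=np.uint8)
        # neighbours clockwise from top-middle: 2,3,1,9,8,7,4,5 vs centre 6
        # bits: 0,0,0,1,1,1,0,0 -> 2^3 + 2^4 + 2^5 = 56
        assert lbp_map(patch, 1).codes[0, 0] == 56

    def test_matches_naive_oracle_radius1(self, rng):
        for _ in range(5):
            gray = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            np.testing.assert_array_equal(lbp_map(gray, 1).codes, naive_lbp_r1(gray))

    def test_radius_bounds(self):
        with pytest.raises(ValueError):
            lbp_map(np.zeros((8, 8), np.uint8), 0)


class TestLBPHistogram:
    def test_blocks_normalized(self, rng):
        gray = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        hist = lbp_histogram(gray, radii=(1, 2))
        assert hist[:256].sum() == pytest.approx(1.0)
        assert hist[256:].sum() == pytest.approx(1.0)

    def test_dim_for_five_radii(self, rng):
        gray = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        assert lbp_histogram(gray, radii=(1, 2, 3, 4, 5)).shape == (1280,)

    def test_invariant_under_shared_offset(self, rng):
        gray = rng.integers(0, 230, size=(16, 16)).astype(np.uint8)
        a = lbp_histogram(gray, radii=(1,))
        b = lbp_histogram(gray + 10, radii=(1,))
        np.testing.assert_allclose(a, b)

    def test_empty_radii_rejected(self):
        with pytest.raises(ValueError):
            lbp_histogram(np.zeros((8, 8), np.uint8), radii=())


class TestLTP:
    def test_constant_image_all_zero(self):
        gray = np.full((8, 8), 99, dtype=np.uint8)
        up, lo = ltp_maps(gray, 1)
        assert (up.codes == 0).all() and (lo.codes == 0).all()

    def test_brighter_ring(self):
        gray = np.full((3, 3), 200, dtype=np.uint8)
        gray[1, 1] = 10
        up, lo = ltp_maps(gray, 1)
        assert up.codes[0, 0] == 255 and lo.codes[0, 0] == 0

    def test_upper_lower_bits_disjoint(self, rng):
        gray = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        up, lo = ltp_maps(gray, 1)
        assert (up.codes & lo.codes == 0).all()

    def test_matches_naive_oracle_radius1(self, rng):
        gray = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        up, lo = ltp_maps(gray, 1)
        oup, olo = naive_ltp_r1(gray)
        np.testing.assert_array_equal(up.codes, oup)
        np.testing.assert_array_equal(lo.codes, olo)


# ---------------------------------------------------------------- GLCM / Haralick

class TestGLCM:
    def test_two_by_two_example(self):
        img = np.array([[0, 0], [0, 255]], dtype=np.uint8)  # levels 0 and 1
        m = glcm(img, levels=2, distance=1, direction="horizontal")
        assert m.counts[0, 0] == 2
        assert m.counts[0, 1] == 1
        assert m.counts[1, 0] == 1

    def test_constant_image_single_cell(self):
        img = np.full((6, 6), 200, dtype=np.uint8)
        m = glcm(img, levels=8, distance=1, direction="vertical")
        q = quantize(img, 8)[0, 0]
        assert m.counts[q, q] == m.counts.sum()

    def test_symmetric_and_total(self, rng):
        img = rng.integers(0, 256, size=(7, 7)).astype(np.uint8)
        for d in ("horizontal", "vertical", "diag_up", "diag_down"):
            m = glcm(img, levels=4, distance=2, direction=d)
            np.testing.assert_array_equal(m.counts, m.counts.T)
            np.testing.assert_array_equal(m.counts, naive_glcm(img, 4, 2, d))

    def test_transpose_swaps_directions(self, rng):
        img = rng.integers(0, 256, size=(6, 8)).astype(np.uint8)
        h = glcm(img, 4, 1, "horizontal").counts
        v = glcm(img.T, 4, 1, "vertical").counts
        np.testing.assert_array_equal(h, v)

    def test_excessive_distance_warns_empty(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        with pytest.warns(UserWarning):
            m = glcm(img, 2, 10, "horizontal")
        assert m.counts.sum() == 0


class TestHaralick:
    def test_normalization_identity(self, rng):
        img = rng.integers(0, 256, size=(9, 9)).astype(np.uint8)
        for m in glcm_all_directions(img, levels=4):
            assert haralick(m)[0] == pytest.approx(1.0)

    def test_constant_image(self):
        img = np.full((6, 6), 42, dtype=np.uint8)
        stats = haralick(glcm(img, 8, 1, "horizontal"))
        # single-cell mass: contrast 0, angular second moment 1
        assert stats[2] == pytest.approx(0.0)
        assert stats[1] == pytest.approx(1.0)

    def test_hand_computed_two_level_matrix(self):
        counts = np.array([[4, 2], [2, 0]])
        m = GLCMMatrix(counts=counts, levels=2, distance=1, direction="horizontal")
        stats = haralick(m)
        p = counts / 8.0
        assert stats[1] == pytest.approx((p**2).sum())  # ASM = 0.375
        assert stats[2] == pytest.approx(0.5 + 0.0)  # contrast: cells (0,1),(1,0)
        mu = 0.25  # marginal mean of i
        var = (0 - mu) ** 2 * 0.75 + (1 - mu) ** 2 * 0.25
        assert stats[4] == pytest.approx(var)

    def test_zero_matrix_rejected(self):
        m = GLCMMatrix(np.zeros((2, 2), int), 2, 1, "horizontal")
        with pytest.raises(ValueError):
            haralick(m)


# ---------------------------------------------------------------- colour

class TestColorHistogram:
    def test_uniform_frame_one_bin_per_channel(self):
        f = make_solid_frame((100, 150, 200))
        hist = color_histogram(f, "RGB", 64)
        for c in range(3):
            block = hist[c * 64 : (c + 1) * 64]
            assert block.max() == pytest.approx(1.0)
            assert (block > 0).sum() == 1

    def test_blocks_sum_to_one(self, textured_frame):
        for space in ("RGB", "HSV"):
            hist = color_histogram(textured_frame, space, 32)
            for c in range(3):
                assert hist[c * 32 : (c + 1) * 32].sum() == pytest.approx(1.0)

    def test_two_tone_split(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:5] = 128
        hist = color_histogram(Frame(px), "RGB", 64)
        block = hist[:64]
        assert block[0] == pytest.approx(0.5)
        assert block[32] == pytest.approx(0.5)

    def test_bad_bins_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            color_histogram(textured_frame, "RGB", 1)


class TestAutoColorCorrelogram:
    def test_single_color_is_one(self):
        f = make_solid_frame((100, 40, 60), h=12, w=12)
        acc = auto_color_correlogram(f, levels=8, distances=(1, 2))
        assert acc.max() == pytest.approx(1.0)
        assert (acc > 0).sum() == 2  # one colour x two distances

    def test_probability_range(self, textured_frame):
        acc = auto_color_correlogram(textured_frame, levels=64, distances=(1, 3))
        assert acc.min() >= 0.0 and acc.max() <= 1.0

    def test_matches_bruteforce_small_images(self, rng):
        for _ in range(3):
            px = rng.integers(0, 256, size=(6, 6, 3)).astype(np.uint8)
            ours = auto_color_correlogram(Frame(px), levels=8, distances=(1, 2))
            oracle = naive_correlogram(px, 8, (1, 2))
            np.testing.assert_allclose(ours, oracle)

    def test_two_color_toy_hand_check(self):
        px = np.zeros((3, 3, 3), dtype=np.uint8)
        px[1, 1] = 255
        ours = auto_color_correlogram(Frame(px), levels=8, distances=(1,))
        oracle = naive_correlogram(px, 8, (1,))
        np.testing.assert_allclose(ours, oracle)
        # the centre's 8 ring neighbours are all the other colour
        idx, _ = quantize_colors(px, 8)
        assert ours[idx[1, 1]] == 0.0


# ---------------------------------------------------------------- LIRE bank

class TestLireDescriptors:
    @pytest.mark.parametrize("name,dim", sorted(LIRE_DIMS.items()))
    def test_dims_frozen(self, textured_frame, name, dim):
        assert lire_descriptor(textured_frame, name).shape == (dim,)

    def test_uniform_frame_has_no_edges(self):
        vec = lire_descriptor(make_solid_frame((80, 90, 100), h=64, w=64), "edge_histogram")
        assert vec.sum() == 0.0

    def test_deterministic(self, textured_frame):
        for name in ("cedd", "gabor", "phog"):
            a = lire_descriptor(textured_frame, name)
            b = lire_descriptor(textured_frame, name)
            np.testing.assert_array_equal(a, b)

    def test_unknown_name_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            lire_descriptor(textured_frame, "surf")


# ---------------------------------------------------------------- scaler

class TestScaler:
    def test_min_to_zero_max_to_one(self):
        x = np.array([[0.0, 5.0], [2.0, 15.0], [1.0, 10.0]])
        sc = fit_scaler(x)
        out = sc.transform(x)
        assert out.min(axis=0) == pytest.approx([0.0, 0.0])
        assert out.max(axis=0) == pytest.approx([1.0, 1.0])

    def test_out_of_range_clamps(self):
        sc = fit_scaler(np.array([[0.0], [10.0]]))
        assert scale(sc, np.array([-5.0]))[0] == 0.0
        assert scale(sc, np.array([50.0]))[0] == 1.0

    def test_constant_dimension_maps_to_zero(self):
        sc = fit_scaler(np.array([[3.0, 1.0], [3.0, 2.0]]))
        out = scale(sc, np.array([3.0, 1.5]))
        assert out[0] == 0.0

    def test_scale_before_fit_rejected(self):
        with pytest.raises(ValueError):
            scale(None, np.array([1.0]))


# ---------------------------------------------------------------- fused bank

class TestExtractBank:
    def test_lbp_only_dim(self, textured_frame):
        vec, spans = extract_bank(textured_frame, ("lbp",))
        assert vec.shape == (1280,)
        assert spans == {"lbp": (0, 1280)}

    def test_spans_contiguous_and_cover(self, textured_frame):
        vec, spans = extract_bank(textured_frame, ("lbp", "tamura", "color_layout"))
        ordered = sorted(spans.values())
        assert ordered[0][0] == 0
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            assert a1 == b0
        assert ordered[-1][1] == vec.shape[0]

    def test_removing_descriptor_removes_span(self, textured_frame):
        full, spans = extract_bank(textured_frame, ("tamura", "color_layout"))
        reduced, _ = extract_bank(textured_frame, ("tamura",))
        lo, hi = spans["tamura"]
        np.testing.assert_allclose(full[lo:hi], reduced)

    def test_empty_config_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            extract_bank(textured_frame, ())

    def test_registry_dims_consistent(self, textured_frame):
        for name in ALL_DESCRIPTORS:
            fv = compute_descriptor(textured_frame, name)
            assert fv.dim == descriptor_dim(name)

    def test_bank_spans_matches_extraction(self, textured_frame):
        config = ("lbp", "gabor", "haralick")
        _, spans = extract_bank(textured_frame, config)
        assert spans == bank_spans(config)
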