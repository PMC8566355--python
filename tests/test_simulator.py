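"""Simulator tests, anchored by a naive per-pixel 1-based-index oracle.

The oracle functions below are written directly from the defining
1-based equations (wrap rule, support masking, ternary map, brightness
sums, correction) with explicit Python loops, independently of the
vectorized implementation they check.
"""

import warnings

import numpy as np
import pytest
from dataclasses import replace

from mrwrap import (
    PhantomSpec,
    generate_phantom,
    binary_pattern,
    make_artifact_layer,
    overlay,
    wrapped_area_map,
    brightness_sums,
    apply_brightness_correction,
    simulate,
    simulate_level,
    psnr,
    BrightnessSums,
    DEFAULT_LEVEL_PRESETS,
)
from mrwrap.simulator import DegenerateGeometryError


# ---------------------------------------------------------------------------
# brute-force oracle (1-based indices, per-pixel loops)
# ---------------------------------------------------------------------------


def oracle_layer(img, d, r, side):
    m_max, n_max = img.shape
    out = np.zeros_like(img, dtype=np.float64)
    for m in range(1, m_max + 1):
        for n in range(1, n_max + 1):
            if side == "right":
                if d + n <= n_max:
                    out[m - 1, n - 1] = 0.0
                else:
                    out[m - 1, n - 1] = img[m - 1, (d + n - n_max) - 1] * r
            else:  # mirrored: leftmost d columns get the rightmost d of img
                if n <= d:
                    out[m - 1, n - 1] = img[m - 1, (n_max - d + n) - 1] * r
    return out


def oracle_pattern(img):
    out = np.zeros(img.shape, dtype=np.uint8)
    for m in range(img.shape[0]):
        for n in range(img.shape[1]):
            out[m, n] = 1 if img[m, n] > 0 else 0
    return out


def oracle_overlay(img, layer):
    out = np.zeros_like(img, dtype=np.float64)
    for m in range(img.shape[0]):
        for n in range(img.shape[1]):
            f = 1.0 if img[m, n] > 0 else 0.0
            out[m, n] = (img[m, n] + layer[m, n]) * f
    return out


def oracle_v(f, fhat):
    out = np.zeros(f.shape, dtype=np.uint8)
    for m in range(f.shape[0]):
        for n in range(f.shape[1]):
            out[m, n] = (int(f[m, n]) + int(fhat[m, n])) * int(f[m, n])
    return out


def oracle_sums(img, v):
    i1 = i2 = 0.0
    for m in range(img.shape[0]):
        for n in range(img.shape[1]):
            if v[m, n] == 1:
                i1 += img[m, n]
            elif v[m, n] == 2:
                i2 += img[m, n]
    return i1, i2


def oracle_correction(i_r, v, i1, i2, mode):
    out = i_r.astype(np.float64).copy()
    if mode == "as_printed":
        factor = i2 / i1
    elif mode == "inverted":
        factor = i1 / i2
    else:  # preserve_ratio: wrapped-area brightness returns to i2
        cur = sum(
            i_r[m, n]
            for m in range(v.shape[0])
            for n in range(v.shape[1])
            if v[m, n] == 2
        )
        factor = i2 / cur if cur > 0 else 1.0
    for m in range(v.shape[0]):
        for n in range(v.shape[1]):
            if v[m, n] == 2:
                out[m, n] *= factor
    return out


def oracle_simulate(img, d, r, side, mode):
    layer = oracle_layer(img, d, r, side)
    f = oracle_pattern(img)
    fhat = oracle_pattern(layer)
    i_r = oracle_overlay(img, layer)
    v = oracle_v(f, fhat)
    i1, i2 = oracle_sums(img, v)
    if (v == 2).sum() == 0:
        return i_r
    return oracle_correction(i_r, v, i1, i2, mode)


def random_image_with_background(rng, shape):
    """Nonnegative random image with an exact-zero border band."""
    img = rng.random(shape)
    width = max(1, shape[1] // 6)
    img[:, :width] = 0.0
    img[:, -width:] = 0.0
    img[: max(1, shape[0] // 8), :] = 0.0
    return img


# ---------------------------------------------------------------------------
# operation-level tests
# ---------------------------------------------------------------------------


class TestBinaryPattern:
    def test_all_zero_image(self):
        assert np.array_equal(binary_pattern(np.zeros((4, 4))), np.zeros((4, 4)))

    def test_definition_example(self):
        img = np.array([[0, 0.5], [1.0, 0]])
        assert np.array_equal(binary_pattern(img), [[0, 1], [1, 0]])

    def test_matches_loop_oracle(self, rng):
        img = rng.random((8, 8)) * (rng.random((8, 8)) > 0.4)
        assert np.array_equal(binary_pattern(img), oracle_pattern(img))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="negative"):
            binary_pattern(np.array([[-1.0, 0.0]]))


class TestArtifactLayer:
    def test_hand_example_right_shift(self):
        img = np.array([[1.0, 2, 3], [4, 5, 6]])
        layer = make_artifact_layer(img, d=1, r=0.5, side="right")
        assert np.allclose(layer, [[0, 0, 0.5], [0, 0, 2.0]])

    def test_full_shift_is_scaled_copy(self, rng):
        img = rng.random((5, 7))
        layer = make_artifact_layer(img, d=7, r=0.8)
        assert np.allclose(layer, 0.8 * img)

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_matches_oracle(self, rng, side):
        img = rng.random((8, 8))
        for d in (1, 3, 8):
            r = float(rng.uniform(0.1, 1.5))
            assert np.allclose(
                make_artifact_layer(img, d, r, side),
                oracle_layer(img, d, r, side),
                atol=1e-15,
            )

    def test_prewrap_columns_exactly_zero(self, rng):
        img = rng.random((6, 10)) + 0.1
        layer = make_artifact_layer(img, d=4, r=1.0, side="right")
        assert np.all(layer[:, : 10 - 4] == 0.0)

    @pytest.mark.parametrize(
        "kw, msg",
        [({"d": 0}, "shift distance"), ({"d": 9}, "shift distance"),
         ({"r": 0.0}, "intensity"), ({"r": -1.0}, "intensity")],
    )
    def test_parameter_errors(self, kw, msg):
        img = np.ones((4, 8))
        args = {"d": 2, "r": 0.5} | kw
        with pytest.raises(ValueError, match=msg):
            make_artifact_layer(img, **args)


class TestOverlayAndMap:
    def test_overlay_all_positive_is_plain_sum(self, rng):
        img = rng.random((5, 5)) + 0.1
        layer = rng.random((5, 5))
        assert np.allclose(overlay(img, layer), img + layer)

    def test_overlay_hand_example(self):
        img = np.array([[0.0, 2], [3, 0]])
        layer = np.ones((2, 2))
        assert np.allclose(overlay(img, layer), [[0, 3], [4, 0]])

    def test_overlay_matches_oracle(self, rng):
        img = rng.random((8, 8)) * (rng.random((8, 8)) > 0.3)
        layer = rng.random((8, 8)) * (rng.random((8, 8)) > 0.5)
        assert np.allclose(overlay(img, layer), oracle_overlay(img, layer))

    def test_overlay_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            overlay(np.ones((2, 2)), np.ones((3, 3)))

    def test_v_all_ones_gives_all_twos(self):
        f = np.ones((3, 3), dtype=np.uint8)
        assert np.all(wrapped_area_map(f, f) == 2)

    def test_v_hand_example(self):
        f = np.array([[1, 1], [0, 1]], dtype=np.uint8)
        fhat = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        assert np.array_equal(wrapped_area_map(f, fhat), [[1, 2], [0, 1]])

    def test_v_matches_oracle_and_counts_overlap(self, rng):
        f = (rng.random((8, 8)) > 0.4).astype(np.uint8)
        fhat = (rng.random((8, 8)) > 0.4).astype(np.uint8)
        v = wrapped_area_map(f, fhat)
        assert np.array_equal(v, oracle_v(f, fhat))
        assert (v == 2).sum() == np.logical_and(f, fhat).sum()


class TestBrightnessAndCorrection:
    def test_sums_no_wrap_gives_zero_i2(self):
        img = np.ones((3, 3))
        v = np.ones((3, 3), dtype=np.uint8)
        s = brightness_sums(img, v)
        assert s.wrapped_sum == 0.0 and s.unwrapped_sum == 9.0

    def test_sums_hand_example(self):
        img = np.array([[1.0, 2], [3, 4]])
        v = np.array([[1, 2], [1, 2]], dtype=np.uint8)
        s = brightness_sums(img, v)
        assert s.unwrapped_sum == 4.0 and s.wrapped_sum == 6.0

    def test_sums_match_oracle_and_partition_support(self, rng):
        img = rng.random((8, 8)) * (rng.random((8, 8)) > 0.3)
        f = binary_pattern(img)
        fhat = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        v = wrapped_area_map(f, fhat)
        s = brightness_sums(img, v)
        i1, i2 = oracle_sums(img, v)
        assert np.isclose(s.unwrapped_sum, i1) and np.isclose(s.wrapped_sum, i2)
        assert np.isclose(s.unwrapped_sum + s.wrapped_sum, img[f.astype(bool)].sum())

    def test_correction_identity_when_no_wrap(self, rng):
        i_r = rng.random((4, 4))
        v = np.ones((4, 4), dtype=np.uint8)
        out = apply_brightness_correction(i_r, v, BrightnessSums(5.0, 0.0))
        assert np.array_equal(out, i_r)

    def test_correction_as_printed_hand_example(self):
        i_r = np.array([[2.0, 4.0]])
        v = np.array([[1, 2]], dtype=np.uint8)
        out = apply_brightness_correction(
            i_r, v, BrightnessSums(2.0, 1.0), mode="as_printed"
        )
        assert np.allclose(out, [[2.0, 2.0]])

    def test_correction_preserve_ratio_restores_wrapped_brightness(self, rng):
        img = np.zeros((6, 8))
        img[1:5, 1:7] = rng.random((4, 6)) + 0.2
        layer = make_artifact_layer(img, 5, 0.9)
        i_r = overlay(img, layer)
        v = wrapped_area_map(binary_pattern(img), binary_pattern(layer))
        s = brightness_sums(img, v)
        out = apply_brightness_correction(i_r, v, s, mode="preserve_ratio")
        assert np.isclose(out[v == 2].sum(), s.wrapped_sum)

    def test_degenerate_geometry_error(self):
        i_r = np.ones((2, 2))
        v = np.full((2, 2), 2, dtype=np.uint8)
        with pytest.raises(DegenerateGeometryError, match="reduce the shift"):
            apply_brightness_correction(i_r, v, BrightnessSums(0.0, 4.0))

    @pytest.mark.parametrize("mode", ["as_printed", "preserve_ratio", "inverted"])
    def test_correction_matches_oracle(self, rng, mode):
        img = random_image_with_background(rng, (10, 12)) + 0.0
        layer = make_artifact_layer(img, 7, 0.8)
        i_r = overlay(img, layer)
        v = wrapped_area_map(binary_pattern(img), binary_pattern(layer))
        s = brightness_sums(img, v)
        if (v == 2).sum() == 0 or s.wrapped_sum == 0:
            pytest.skip("degenerate draw")
        out = apply_brightness_correction(i_r, v, s, mode=mode)
        exp = oracle_correction(i_r, v, s.unwrapped_sum, s.wrapped_sum, mode)
        assert np.allclose(out, exp, atol=1e-12)


# ---------------------------------------------------------------------------
# full-chain tests
# ---------------------------------------------------------------------------


class TestSimulate:
    def test_hand_composed_chain(self):
        img = np.array([[1.0, 2, 3], [4, 5, 6]])
        sample = simulate(img, d=1, r=0.5, side="right")
        # layer [[0,0,0.5],[0,0,2.0]]; I_r = I + layer (all-positive support);
        # V = [[1,1,2],[1,1,2]]; I1 = 1+2+4+5 = 12, I2 = 3+6 = 9;
        # as-printed factor 9/12 = 0.75 on the wrapped column.
        assert np.allclose(sample.overlay, [[1, 2, 3.5], [4, 5, 8.0]])
        assert np.array_equal(sample.artifact_mask, [[0, 0, 1], [0, 0, 1]])
        assert np.allclose(sample.artifacted, [[1, 2, 3.5 * 0.75], [4, 5, 8.0 * 0.75]])

    def test_off_mask_identity_and_background_preservation(self, phantom_batch):
        rng = np.random.default_rng(0)
        checked = 0
        for img in phantom_batch:
            for level in (1, 2, 3, 4, 5):
                s = simulate_level(img, level, seed=int(rng.integers(2**31)))
                off = s.artifact_mask == 0
                assert np.array_equal(s.artifacted[off], s.clean[off])
                assert np.all(s.artifacted[s.clean == 0] == 0)
                assert set(np.unique(s.artifact_mask)) <= {0, 1}
                checked += 1
        assert checked == 100

    def test_r_limit_recovers_clean_under_preserve_ratio(self, phantom64):
        s = simulate(phantom64, d=20, r=1e-9, correction="preserve_ratio")
        assert np.abs(s.artifacted - phantom64).max() < 1e-6

    def test_empty_support_raises(self):
        with pytest.raises(ValueError, match="support"):
            simulate(np.zeros((8, 8)), 2, 0.5)

    def test_warns_when_shift_misses_anatomy(self):
        img = np.zeros((16, 16))
        img[:, 6:10] = 1.0  # central band; d=2 wraps only background
        with pytest.warns(UserWarning, match="artifact-free"):
            s = simulate(img, d=2, r=0.5)
        assert s.artifact_mask.sum() == 0
        assert np.array_equal(s.artifacted, img)

    @pytest.mark.parametrize("mode", ["as_printed", "preserve_ratio", "inverted"])
    def test_vectorized_chain_equals_oracle(self, mode):
        rng = np.random.default_rng(7)
        for _ in range(20):
            h = int(rng.integers(8, 17))
            w = int(rng.integers(8, 17))
            img = random_image_with_background(rng, (h, w))
            if (img > 0).sum() == 0:
                continue
            d = int(rng.integers(1, w + 1))
            r = float(rng.uniform(0.1, 1.3))
            side = ["left", "right"][int(rng.integers(2))]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    got = simulate(img, d, r, side, correction=mode).artifacted
                except DegenerateGeometryError:
                    continue
            expected = oracle_simulate(img, d, r, side, mode)
            assert np.abs(got - expected).max() < 1e-12


class TestDistortionLevels:
    def test_presets_are_monotone(self):
        ds = [DEFAULT_LEVEL_PRESETS[k][0] for k in sorted(DEFAULT_LEVEL_PRESETS)]
        rs = [DEFAULT_LEVEL_PRESETS[k][1] for k in sorted(DEFAULT_LEVEL_PRESETS)]
        assert ds == sorted(ds) and rs == sorted(rs)

    def test_level1_less_degraded_than_level5(self, phantom64):
        """Graded severity under the smooth (ratio-preserving) correction.

        The as-printed I2/I1 correction makes PSNR non-monotone in the
        shift distance (the darkening factor approaches 1 as the wrapped
        area grows), so graded severity is a property of the
        preserve_ratio mode."""
        s1 = simulate_level(phantom64, 1, seed=4, correction="preserve_ratio")
        s5 = simulate_level(phantom64, 5, seed=4, correction="preserve_ratio")
        assert psnr(s1.clean, s1.artifacted) > psnr(s5.clean, s5.artifacted)

    def test_fixed_seed_is_deterministic(self, phantom64):
        a = simulate_level(phantom64, 3, seed=99)
        b = simulate_level(phantom64, 3, seed=99)
        assert np.array_equal(a.artifacted, b.artifacted)
        assert a.side == b.side and a.d == b.d

    def test_unknown_level_raises(self, phantom64):
        with pytest.raises(ValueError, match="unknown distortion level"):
            simulate_level(phantom64, 6)

    def test_psnr_nonincreasing_in_r_under_preserve_ratio(self, phantom64):
        vals = [
            psnr(phantom64, simulate(phantom64, 20, r, correction="preserve_ratio").artifacted)
            for r in (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
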