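import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from chromaseg import morphology
from chromaseg.morphology import MorphologyParams


def close_oracle(mask, se_halfwidth, iterations):
    """First-principles closing: shift-union dilation, shift-intersection erosion.

    Outside-image pixels count as background for the dilation and
    foreground for the erosion.
    """
    offsets = [
        (dy, dx)
        for dy in range(-se_halfwidth, se_halfwidth + 1)
        for dx in range(-se_halfwidth, se_halfwidth + 1)
    ]

    def shift(a, dy, dx, fill):
        out = np.full_like(a, fill)
        h, w = a.shape
        ys = slice(max(dy, 0), min(h + dy, h))
        xs = slice(max(dx, 0), min(w + dx, w))
        ys_src = slice(max(-dy, 0), min(h - dy, h))
        xs_src = slice(max(-dx, 0), min(w - dx, w))
        out[ys, xs] = a[ys_src, xs_src]
        return out

    def dilate(a):
        out = np.zeros_like(a)
        for dy, dx in offsets:
            out |= shift(a, dy, dx, False)
        return out

    def erode(a):
        out = np.ones_like(a)
        for dy, dx in offsets:
            out &= shift(a, dy, dx, True)
        return out

    for _ in range(iterations):
        mask = dilate(mask)
    for _ in range(iterations):
        mask = erode(mask)
    return mask


class TestRemoveOutliers:
    @pytest.mark.parametrize("mode", ["bright", "dark"])
    @pytest.mark.parametrize("fill", [True, False])
    def test_uniform_mask_unchanged(self, mode, fill):
        mask = np.full((9, 9), fill)
        out = morphology.remove_outliers(mask, 2, 50, mode)
        assert np.array_equal(out, mask)

    def test_isolated_speck_removed_bright(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 5] = True
        out = morphology.remove_outliers(mask, 2, 50, "bright")
        assert not out.any()

    def test_isolated_speck_unchanged_dark(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 5] = True
        out = morphology.remove_outliers(mask, 2, 50, "dark")
        assert np.array_equal(out, mask)

    def test_single_hole_filled_dark(self):
        mask = np.ones((11, 11), dtype=bool)
        mask[5, 5] = False
        out = morphology.remove_outliers(mask, 2, 50, "dark")
        assert out.all()

    def test_single_hole_unchanged_bright(self):
        mask = np.ones((11, 11), dtype=bool)
        mask[5, 5] = False
        out = morphology.remove_outliers(mask, 2, 50, "bright")
        assert np.array_equal(out, mask)

    def test_matches_npmedian_semantics(self, rng):
        # the correlation-count median must equal an explicit np.median of
        # the 0/255 neighbourhood values, truncated at edges
        mask = rng.random((12, 14)) < 0.4
        radius, deviation = 2, 50
        fp = morphology._disk_footprint(radius)
        offs = [(dy - radius, dx - radius) for dy, dx in zip(*np.nonzero(fp))]
        got = morphology.remove_outliers(mask, radius, deviation, "bright")
        h, w = mask.shape
        for y in range(h):
            for x in range(w):
                vals = [
                    255.0 if mask[y + dy, x + dx] else 0.0
                    for dy, dx in offs
                    if 0 <= y + dy < h and 0 <= x + dx < w
                ]
                med = float(np.median(vals))
                value = 255.0 if mask[y, x] else 0.0
                expected = med if value - med > deviation else value
                assert got[y, x] == (expected == 255.0), (y, x)

    def test_only_deviating_pixels_change(self, rng):
        mask = rng.random((20, 20)) < 0.5
        for mode in ("bright", "dark"):
            out = morphology.remove_outliers(mask, 2, 50, mode)
            changed = out != mask
            if mode == "bright":
                assert np.all(mask[changed])  # bright mode only removes foreground
            else:
                assert np.all(~mask[changed])  # dark mode only adds foreground

    def test_bad_args(self):
        with pytest.raises(ValueError):
            morphology.remove_outliers(np.zeros((3, 3), bool), 0, 50, "bright")
        with pytest.raises(ValueError):
            morphology.remove_outliers(np.zeros((3, 3), bool), 2, 50, "sideways")


class TestBinaryClose:
    def test_empty_mask(self):
        out = morphology.binary_close(np.zeros((8, 8), dtype=bool), 1, 1)
        assert not out.any()

    def test_center_hole_in_5x5_square_filled(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        mask[4, 4] = False
        out = morphology.binary_close(mask, 1, 1)
        expected = np.zeros((9, 9), dtype=bool)
        expected[2:7, 2:7] = True
        assert np.array_equal(out, expected)

    def test_matches_first_principles_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((64, 64)) < rng.uniform(0.2, 0.8)
            hw = int(rng.integers(1, 3))
            it = int(rng.integers(1, 3))
            assert np.array_equal(
                morphology.binary_close(mask, hw, it), close_oracle(mask, hw, it)
            )

    def test_border_foreground_not_shrunk(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:4, 0:4] = True
        out = morphology.binary_close(mask, 1, 1)
        assert np.all(out[mask])

    @settings(max_examples=25, deadline=None)
    @given(mask=hnp.arrays(bool, (16, 16)))
    def test_idempotent(self, mask):
        once = morphology.binary_close(mask, 1, 1)
        assert np.array_equal(morphology.binary_close(once, 1, 1), once)

    @settings(max_examples=25, deadline=None)
    @given(mask=hnp.arrays(bool, (20, 20)))
    def test_extensive_on_interior(self, mask):
        hw, it = 1, 1
        out = morphology.binary_close(mask, hw, it)
        interior = np.zeros_like(mask)
        d = hw * it
        interior[d:-d, d:-d] = True
        assert np.all(out[mask & interior])


def _disk_nest(shape, cy, cx, r):
    # disk-like nest (a square's sharp corners would legitimately be
    # shaved by the majority-median pass)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r + r


class TestRepairMask:
    def test_speck_removed_and_hole_filled(self):
        mask = _disk_nest((40, 40), 22, 22, 12)
        mask[22, 22] = False  # 1-px hole
        mask[2, 2] = True  # isolated speck
        out = morphology.repair_mask(mask, MorphologyParams())
        assert not out[2, 2]
        assert out[22, 22]
        assert np.all(out[_disk_nest((40, 40), 22, 22, 12)])

    def test_clean_nest_unchanged(self):
        mask = _disk_nest((40, 40), 20, 20, 14)
        out = morphology.repair_mask(mask, MorphologyParams())
        assert np.array_equal(out, mask)

    def test_equals_manual_composition(self, rng):
        params = MorphologyParams()
        for _ in range(10):
            mask = rng.random((48, 48)) < rng.uniform(0.2, 0.8)
            expected = morphology.remove_outliers(
                mask, params.bright_radius, params.bright_deviation, "bright"
            )
            expected = morphology.binary_close(
                expected, params.close_se_halfwidth, params.close_iterations
            )
            expected = morphology.remove_outliers(
                expected, params.dark_radius, params.dark_deviation, "dark"
            )
            assert np.array_equal(morphology.repair_mask(mask, params), expected)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MorphologyParams(bright_radius=0)
        with pytest.raises(ValueError):
            MorphologyParams(dark_deviation=300)
        with pytest.raises(ValueError):
            MorphologyParams(close_iterations=0)
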