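"""Tests for pixel- and trace-level quantification operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copulse.io import Trace
from copulse.synth import generate_cell_image, triangular_kernel
from copulse.trace_quant import (PixelSet, focus_compactness,
                                 nuclear_localization_score, pcp_activity,
                                 positive_frames, subtract_background,
                                 transient_response_amplitude)


def _grid_coords(n):
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([xs.ravel(), ys.ravel()])[:n].astype(float)


class TestNuclearLocalizationScore:
    def test_uniform_pixels_score_zero(self):
        px = PixelSet(np.full(50, 7.0), _grid_coords(50))
        assert nuclear_localization_score(px) == 0.0

    def test_direct_arithmetic(self):
        values = np.concatenate([np.full(95, 10.0), np.full(5, 110.0)])
        px = PixelSet(values, _grid_coords(100))
        assert nuclear_localization_score(px) == pytest.approx(100.0)

    @given(st.floats(-50, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 100, 60)
        px = PixelSet(values, _grid_coords(60))
        shifted = PixelSet(values + c, _grid_coords(60))
        assert nuclear_localization_score(shifted) == pytest.approx(
            nuclear_localization_score(px), abs=1e-9)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            nuclear_localization_score(PixelSet(np.ones(4), _grid_coords(4)))


class TestFocusCompactness:
    def test_coincident_pixels(self):
        coords = np.zeros((10, 2))
        d, flag = focus_compactness(PixelSet(np.arange(10.0), coords), 3.0)
        assert d == 0.0 and flag

    def test_line_of_ten_pixels(self):
        # positions 0..9 on a line: mean over 45 pairs = 11/3
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        d, _ = focus_compactness(PixelSet(np.full(10, 5.0), coords), 100.0)
        assert d == pytest.approx(11 / 3)

    def test_strict_threshold_boundary(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        d, flag = focus_compactness(PixelSet(np.full(10, 5.0), coords), 11 / 3)
        assert not flag  # strict <

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (20, 2))
        values = rng.uniform(0, 1, 20)
        d1, _ = focus_compactness(PixelSet(values, coords), 3.0)
        d2, _ = focus_compactness(PixelSet(values, coords + [120.0, -55.0]), 3.0)
        assert d1 == pytest.approx(d2)

    def test_scattered_bright_pixels_not_compact(self):
        values, coords, _ = generate_cell_image(100, 0.1, 100.0, seed=3,
                                                compact=False)
        _, flag = focus_compactness(PixelSet(values, coords), 3.0)
        assert not flag

    def test_compact_nucleus_flagged_positive(self):
        values, coords, gain = generate_cell_image(100, 0.1, 100.0, seed=3)
        _, flag = focus_compactness(PixelSet(values, coords), 3.0)
        assert flag
        # and the localization score recovers the gain
        score = nuclear_localization_score(PixelSet(values, coords))
        assert score == pytest.approx(gain, abs=1e-9)


class TestSubtractBackground:
    def test_exact_cubic_removed(self):
        t = np.arange(0, 100, 2.0)
        v = 3.0 - 0.5 * t + 0.01 * t**2 - 1e-4 * t**3
        out = subtract_background(Trace("c", "MSN2", t, v))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_constant_background(self):
        t = np.arange(0, 50, 2.0)
        out = subtract_background(Trace("c", "MSN2", t, np.full(t.size, 4.2)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_flagged_pulse_preserved(self):
        t = np.arange(0, 200, 2.0)
        baseline = 1.0 + 0.02 * t
        pulse = triangular_kernel(t, 100.0, 10.0, 6.0)
        pos = pulse > 0
        out = subtract_background(Trace("c", "MSN2", t, baseline + pulse,
                                        positive=pos))
        np.testing.assert_allclose(out.values[~pos], 0.0, atol=1e-8)
        assert out.values[t == 100.0][0] == pytest.approx(10.0, abs=1e-6)

    def test_too_few_background_frames(self):
        t = np.arange(0, 20, 2.0)
        pos = np.ones(t.size, bool)
        pos[:3] = False
        with pytest.raises(ValueError):
            subtract_background(Trace("c", "MSN2", t, np.zeros(t.size),
                                      positive=pos))


class TestTransientResponse:
    def test_flat_trace(self):
        t = np.arange(0, 100, 2.0)
        tr = Trace("c", "MSN2", t, np.full(t.size, 3.0))
        assert transient_response_amplitude(tr, 50.0) == 0.0

    def test_step_response(self):
        t = np.arange(0, 100, 2.0)
        v = np.where(t > 50.0, 7.0, 0.0)
        tr = Trace("c", "MSN2", t, v)
        assert transient_response_amplitude(tr, 50.0) == pytest.approx(7.0)

    def test_triangular_pulse_post_stress(self):
        t = np.arange(0, 100, 2.0)
        v = 2.0 + triangular_kernel(t, 60.0, 10.0, 8.0)
        tr = Trace("c", "MSN2", t, v)
        assert transient_response_amplitude(tr, 50.0) == pytest.approx(10.0)

    def test_insufficient_coverage(self):
        t = np.arange(0, 30, 2.0)
        with pytest.raises(ValueError):
            transient_response_amplitude(Trace("c", "MSN2", t, np.zeros(t.size)), 12.0)


class TestPcpActivity:
    def test_single_slice_identity(self):
        rng = np.random.default_rng(2)
        px = PixelSet(rng.uniform(0, 10, 30), _grid_coords(30))
        assert pcp_activity([px]) == nuclear_localization_score(px)

    def test_identical_slices(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 10, 30)
        stack = [PixelSet(values, _grid_coords(30)) for _ in range(3)]
        assert pcp_activity(stack) == nuclear_localization_score(stack[0])

    def test_focus_in_one_slice_dominates(self):
        coords = _grid_coords(30)
        dim = PixelSet(np.full(30, 1.0), coords)
        bright_vals = np.full(30, 1.0)
        bright_vals[:5] = 50.0
        bright = PixelSet(bright_vals, coords)
        assert pcp_activity([dim, bright, dim]) == pytest.approx(
            nuclear_localization_score(bright))

    def test_mismatched_coords_rejected(self):
        a = PixelSet(np.ones(12), _grid_coords(12))
        b = PixelSet(np.ones(12), _grid_coords(12) + 1.0)
        with pytest.raises(ValueError):
            pcp_activity([a, b])


def test_read_pixel_sets_round_trip(tmp_path):
    import pandas as pd
    from copulse.trace_quant import read_pixel_sets
    df = pd.DataFrame({
        "cell_id": ["a"] * 6 + ["b"] * 6,
        "frame": [0, 0, 0, 1, 1, 1] * 2,
        "x": [0, 1, 2] * 4,
        "y": [0, 0, 1] * 4,
        "value": np.arange(12.0),
    })
    path = tmp_path / "pixels.csv"
    df.to_csv(path, index=False)
    sets = read_pixel_sets(path)
    assert set(sets) == {("a", 0), ("a", 1), ("b", 0), ("b", 1)}
    np.testing.assert_allclose(sets[("b", 1)].values, [9.0, 10.0, 11.0])


def test_positive_frames_from_synthetic_images():
    frames = []
    for compact in (True, False, True):
        values, coords, _ = generate_cell_image(100, 0.1, 80.0, seed=5,
                                                compact=compact)
        frames.append(PixelSet(values, coords))
    flags = positive_frames(frames, 3.0)
    assert flags.tolist() == [True, False, True]
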