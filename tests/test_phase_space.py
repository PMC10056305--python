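"""Phase portrait construction: normalization, Gaussian upsampling,
delay embedding, grid rasterization and its invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecgpsr as e
from ecgpsr.phase_space import UPSAMPLE_FACTOR


class TestNormalize:
    def test_closed_form(self):
        assert np.allclose(e.normalize([2, 4, 6]), [0, 0.5, 1])

    def test_identity_on_normalized_input(self):
        x = [0, 0.25, 1]
        assert np.allclose(e.normalize(x), x)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            e.normalize([1.0, 1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
    def test_bounds_and_monotonicity(self, xs):
        x = np.asarray(xs)
        if x.max() == x.min():
            return
        out = e.normalize(x)
        assert out.min() == 0.0 and out.max() == 1.0
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)


class TestUpsampleGaussian:
    def test_constant_maps_to_constant(self):
        out = e.upsample_gaussian(np.full(20, 0.5), 10)
        assert out.size == 10 * 19 + 1
        assert np.allclose(out, 0.5, atol=1e-9)

    def test_linear_ramp_follows_ideal_line(self):
        x = np.linspace(0, 1, 11)
        out = e.upsample_gaussian(x, 10)
        ideal = np.linspace(0, 1, 101)
        assert np.max(np.abs(out - ideal)) < 0.01

    def test_factor_one_near_identity_on_smooth_signal(self):
        t = np.linspace(0, 1, 50)
        x = 1.5 + np.sin(2 * np.pi * t)
        out = e.upsample_gaussian(x, 1)
        assert np.all(np.abs(out - x) <= 0.01 * np.abs(x))

    def test_length_formula(self):
        for n, f in [(2, 1), (5, 3), (20, 10)]:
            assert e.upsample_gaussian(np.arange(n, dtype=float), f).size \
                == f * (n - 1) + 1

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            e.upsample_gaussian(np.arange(5.0), 0)


class TestEmbed:
    def test_printed_definition(self):
        pts = e.embed(np.array([0, 0.5, 1, 0.5]), 1)
        assert np.allclose(pts, [(0, 0.5), (0.5, 1), (1, 0.5)])

    def test_zero_delay_lies_on_diagonal(self):
        pts = e.embed(np.linspace(0, 1, 9), 0)
        assert np.allclose(pts[:, 0], pts[:, 1])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 60), st.integers(0, 59))
    def test_point_count(self, n, tau):
        if tau >= n:
            return
        x = np.linspace(0, 1, n)
        assert e.embed(x, tau).shape == (n - tau, 2)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError):
            e.embed(np.linspace(0, 1, 5), 5)


def _brute_force_rasterize(points, r):
    """Independent oracle: double loop over points x cells."""
    grid = np.zeros((r, r), dtype=np.uint8)
    for x, y in points:
        for row in range(r):
            for col in range(r):
                x_lo, x_hi = col / r, (col + 1) / r
                y_hi_row = r - 1 - row
                y_lo, y_hi = y_hi_row / r, (y_hi_row + 1) / r
                in_x = x_lo <= x < x_hi or (col == r - 1 and x == 1.0)
                in_y = y_lo <= y < y_hi or (y_hi_row == r - 1 and y == 1.0)
                if in_x and in_y:
                    grid[row, col] = 1
    return grid


class TestRasterize:
    def test_origin_lands_bottom_left(self):
        grid = e.rasterize(np.array([[0.0, 0.0]]), 16)
        assert grid.sum() == 1 and grid[15, 0] == 1

    def test_unit_corner_lands_top_right(self):
        grid = e.rasterize(np.array([[1.0, 1.0]]), 16)
        assert grid.sum() == 1 and grid[0, 15] == 1

    def test_uniform_diagonal_occupies_diagonal_cells(self):
        t = np.linspace(0, 1, 10000)
        grid = e.rasterize(np.column_stack([t, t]), 32)
        expected = np.eye(32, dtype=np.uint8)[::-1]
        assert np.array_equal(grid, expected)

    @pytest.mark.parametrize("r", [2, 5, 16, 32])
    def test_oracle_equivalence(self, r):
        rng = np.random.default_rng(r)
        pts = rng.random((40, 2))
        assert np.array_equal(e.rasterize(pts, r),
                              _brute_force_rasterize(pts, r))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            e.rasterize(np.array([[1.2, 0.5]]), 8)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([4, 8, 16]))
    def test_monotone_refinement(self, seed, r):
        """Every cell occupied at partition r is covered by an occupied
        descendant at partition 2r."""
        pts = np.random.default_rng(seed).random((30, 2))
        coarse = e.rasterize(pts, r)
        fine = e.rasterize(pts, 2 * r)
        covered = (fine.reshape(r, 2, r, 2).max(axis=(1, 3)) > 0)
        assert np.all(coarse[coarse == 1] <= covered[coarse == 1])


class TestResizePortrait:
    def test_identity_when_sizes_match(self):
        g = np.eye(8, dtype=np.uint8)
        assert np.array_equal(e.resize_portrait(g, 8), g)

    def test_block_replication(self):
        g = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        out = e.resize_portrait(g, 4)
        expected = np.array([[1, 1, 0, 0], [1, 1, 0, 0],
                             [0, 0, 1, 1], [0, 0, 1, 1]], dtype=np.uint8)
        assert np.array_equal(out, expected)

    def test_occupied_fraction_preserved(self):
        g = (np.random.default_rng(0).random((16, 16)) < 0.3).astype(np.uint8)
        out = e.resize_portrait(g, 256)
        assert out.mean() == g.mean()

    @pytest.mark.parametrize("p", [4, 12])
    def test_bad_output_size_rejected(self, p):
        g = np.ones((8, 8), dtype=np.uint8)
        if p < 8:
            with pytest.raises(ValueError):
                e.resize_portrait(g, p)
        else:  # 12 not divisible by 8
            with pytest.raises(ValueError):
                e.resize_portrait(g, p)


class TestBeatToPortrait:
    def test_tau_conversion_at_upsampled_rate(self):
        assert e.tau_ms_to_samples(20, 1000) == 200
        assert e.tau_ms_to_samples(2, 1000) == 20

    def test_portrait_shows_multiple_loops(self, subject):
        """At tau = 20 ms the QRS outer loop and T inner loop enclose
        distinct background regions."""
        beat_samples = e.beat_waveform(subject, 1000.0)
        beat = e.BeatSegment(
            samples=beat_samples,
            fiducial_offset=int(round(0.35 * beat_samples.size)),
            cycle_len=beat_samples.size, subject_id=subject.subject_id)
        portrait = e.beat_to_portrait(beat, 20, 256, 256, 1000.0)
        assert e.count_holes(portrait.grid) >= 2

    def test_small_delay_hugs_diagonal(self, one_beat):
        p_small = e.beat_to_portrait(one_beat, 2, 256, 256, 1000.0)
        p_large = e.beat_to_portrait(one_beat, 20, 256, 256, 1000.0)
        assert p_small.grid.sum() < p_large.grid.sum()

    def test_affine_invariance(self, one_beat):
        """Scaling and offsetting a beat leaves the portrait bit-identical."""
        scaled = dataclasses.replace(one_beat,
                                     samples=3.7 * one_beat.samples - 1.2)
        a = e.beat_to_portrait(one_beat, 20, 64, 256, 1000.0)
        b = e.beat_to_portrait(scaled, 20, 64, 256, 1000.0)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.image, b.image)

    def test_time_reversal_transpose_duality(self, one_beat):
        """Rasterizing the reversed beat gives the transpose-reflection of
        the forward grid (the point set maps (x, y) -> (y, x))."""
        rev = dataclasses.replace(one_beat, samples=one_beat.samples[::-1])
        fwd = e.beat_to_portrait(one_beat, 20, 64, 64, 1000.0)
        bwd = e.beat_to_portrait(rev, 20, 64, 64, 1000.0)
        assert np.array_equal(bwd.grid, fwd.grid.T[::-1, ::-1])

    def test_resized_image_matches_network_input(self, one_beat):
        p = e.beat_to_portrait(one_beat, 24, 32, 32, 1000.0)
        assert p.image.shape == (32, 32)
        assert set(np.unique(p.image)) <= {0, 1}
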