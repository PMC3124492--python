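"""Landscapes: assembly, common-grid pooling, averaging, normalization."""

import numpy as np
import pandas as pd
import pytest

from stripquant import (
    IntensityProfile,
    Landscape,
    average_surface,
    build_landscape,
    normalize_by_prestimulus,
    ratio_frames,
    resample_to_common_grid,
    smooth_profile,
)
from stripquant.preprocess import CellMask, FrameStack


def make_profile(vals, t, cell="c", grid=None):
    vals = np.asarray(vals, float)
    x = np.linspace(0, 1, vals.size) if grid is None else grid
    return IntensityProfile(x, vals / vals.sum(), time_min=t, cell_id=cell)


def bump_profile(center, t=0.0, cell="c", grid=101, amp=1.0):
    x = np.linspace(0, 1, grid)
    v = 0.3 + amp * np.exp(-0.5 * ((x - center) / 0.08) ** 2)
    return IntensityProfile(x, v / v.sum(), time_min=t, cell_id=cell)


class TestBuildLandscape:
    def test_single_profile(self):
        p = make_profile([1, 2, 1], 5.0)
        L = build_landscape([p])
        assert L.values.shape == (1, 3)
        np.testing.assert_allclose(L.values[0], p.intensity)

    def test_rows_sorted_by_time(self):
        ps = [make_profile([1, 2, 1], t) for t in (4.0, -2.0, 1.0)]
        L = build_landscape(ps)
        np.testing.assert_allclose(L.times_min, [-2.0, 1.0, 4.0])

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_landscape([make_profile([1, 1], 0.0), make_profile([1, 2], 0.0)])

    def test_rows_obey_unit_sum(self):
        L = build_landscape([bump_profile(0.7, t) for t in range(5)])
        np.testing.assert_allclose(L.values.sum(axis=1), 1.0, atol=1e-9)

    def test_peak_tracks_simulated_front(self, clean_movie):
        from stripquant import quantify_stack, BackgroundRegion

        spec, stack, truth = clean_movie
        res = quantify_stack(
            stack,
            background_region=BackgroundRegion.from_rectangle(stack.shape, 0, 0, 10, 10),
        )
        L = res.landscape
        # at the frame of maximal front-bump amplitude the landscape peak
        # in the distal half sits near the bump center
        f = int(np.argmax(truth.front_amplitude))
        dist = L.x_norm >= 0.5
        peak_x = L.x_norm[dist][np.argmax(L.values[f][dist])]
        bump_x = (truth.edge_cols[f] - spec.front_bump.offset_px - res.junction_x) / (
            truth.edge_cols[f] - res.junction_x
        )
        assert abs(peak_x - bump_x) <= 0.05


class TestResample:
    def _landscape(self, times, cell="c"):
        ps = [make_profile([1.0, 1.0 + t, 1.0], t, cell=cell) for t in times]
        return build_landscape(ps)

    def test_existing_time_exact(self):
        L = self._landscape([0.0, 2.0, 4.0])
        pts = resample_to_common_grid([L], [2.0])
        row = pts[pts["time_min"] == 2.0]["value"].to_numpy()
        np.testing.assert_allclose(row, L.values[1])

    def test_linear_interpolation_midpoint(self):
        p0 = make_profile([1.0, 0.0 + 1e-12, 1.0], 0.0)
        p1 = make_profile([0.5, 1.0, 0.5], 2.0)
        L = build_landscape([p0, p1])
        pts = resample_to_common_grid([L], [1.0])
        got = pts["value"].to_numpy()
        np.testing.assert_allclose(got, (L.values[0] + L.values[1]) / 2)

    def test_no_extrapolation_bookkeeping(self):
        La = self._landscape([0.0, 1.0, 2.0, 3.0, 4.0], "a")  # 1-min cadence
        Lb = self._landscape([0.0, 2.0, 4.0], "b")  # 2-min cadence
        Lc = self._landscape([1.0, 2.0, 3.0], "c")  # short coverage
        pts = resample_to_common_grid([La, Lb, Lc], np.arange(5.0))
        counts = pts.groupby("time_min")["cell_id"].nunique()
        assert counts[0.0] == 2 and counts[1.0] == 3 and counts[4.0] == 2

    def test_empty_coverage_rejected(self):
        L = self._landscape([0.0, 1.0])
        with pytest.raises(ValueError, match="no cell covers"):
            resample_to_common_grid([L], [10.0])


class TestAverageSurface:
    def test_single_cell_reduction(self):
        """With one contributing cell the average equals that cell's
        smoothed landscape (same smoother, same parameters)."""
        ps = [bump_profile(0.7, t) for t in range(3)]
        smoothed = [smooth_profile(p) for p in ps]
        L = build_landscape(smoothed)
        pts = resample_to_common_grid([L], L.times_min)
        pop = average_surface(pts, L.x_norm)
        expected = np.stack([smooth_profile(p).intensity for p in smoothed])
        np.testing.assert_allclose(pop.surface.values, expected, atol=1e-9)

    def test_duplication_invariance(self):
        Ls = [
            build_landscape([bump_profile(0.6, t, cell=c) for t in range(3)])
            for c in ("a", "b")
        ]
        pts1 = resample_to_common_grid([Ls[0]], [0.0, 1.0, 2.0])
        pts2 = resample_to_common_grid(Ls, [0.0, 1.0, 2.0])
        s1 = average_surface(pts1, Ls[0].x_norm).surface.values
        s2 = average_surface(pts2, Ls[0].x_norm).surface.values
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_monte_carlo_mean_within_3se(self, rng):
        """A 10-cell noisy cohort's average stays within 3 SE of the known
        mean profile at every grid point."""
        grid = np.linspace(0, 1, 101)
        true = 0.3 + np.exp(-0.5 * ((grid - 0.7) / 0.1) ** 2)
        true = true / true.sum()
        n, sd = 10, 0.10 * true.max()
        cells = []
        for c in range(n):
            noisy = np.clip(true + rng.normal(0, sd, grid.size), 1e-12, None)
            noisy = noisy / noisy.sum()
            cells.append(
                build_landscape([IntensityProfile(grid, noisy, 0.0, f"c{c}")])
            )
        pts = resample_to_common_grid(cells, [0.0])
        avg = average_surface(pts, grid).surface.values[0]
        se = sd / np.sqrt(n)
        # loess averaging also smooths across x, tightening the estimate;
        # 3 SE of the per-point sample mean bounds the error comfortably
        assert np.all(np.abs(avg - true) < 3 * se)

    def test_sparse_time_dropped(self):
        pts = pd.DataFrame(
            {
                "cell_id": ["a"] * 3,
                "time_min": [0.0] * 3,
                "x_norm": [0.0, 0.5, 1.0],
                "value": [0.3, 0.4, 0.3],
            }
        )
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="fewer than"):
                average_surface(pts, np.linspace(0, 1, 5))


class TestNormalizeByPrestimulus:
    def _landscape(self, rows, times):
        grid = np.linspace(0, 1, rows.shape[1])
        return Landscape(np.asarray(times, float), grid, rows, "c")

    def test_reference_row_becomes_ones(self):
        row = np.array([0.2, 0.3, 0.5])
        L = self._landscape(np.stack([row, row * 1.5]), [-1.0, 1.0])
        out = normalize_by_prestimulus(L)
        np.testing.assert_allclose(out.values[0], 1.0)
        assert out.normalized

    def test_time_constant_landscape_all_ones(self):
        row = np.array([0.1, 0.4, 0.5])
        L = self._landscape(np.tile(row, (4, 1)), [-2.0, -1.0, 1.0, 2.0])
        np.testing.assert_allclose(normalize_by_prestimulus(L).values, 1.0)

    def test_gauge_invariance(self, rng):
        """Multiplying the landscape by any time-constant spatial function
        leaves the normalized output unchanged."""
        vals = rng.uniform(0.5, 1.5, (6, 11))
        L = self._landscape(vals, np.arange(6.0) - 2.0)
        gauge = rng.uniform(0.2, 3.0, 11)
        Lg = self._landscape(vals * gauge, L.times_min)
        np.testing.assert_allclose(
            normalize_by_prestimulus(L).values,
            normalize_by_prestimulus(Lg).values,
            atol=1e-9,
        )

    def test_doubling_front_region(self):
        grid = np.linspace(0, 1, 101)
        base = np.full(101, 1.0)
        post = base.copy()
        post[grid >= 0.9] *= 2.0
        L = Landscape(np.array([-1.0, 5.0]), grid, np.stack([base, post]), "c")
        out = normalize_by_prestimulus(L)
        front = grid >= 0.9
        assert np.allclose(out.values[1][front], 2.0, rtol=0.05)
        assert np.allclose(out.values[1][(grid > 0.3) & (grid < 0.7)], 1.0, rtol=0.05)

    def test_near_zero_reference_masked(self):
        rows = np.array([[1.0, 0.001, 1.0], [1.0, 1.0, 1.0]])
        L = self._landscape(rows, [-1.0, 1.0])
        out = normalize_by_prestimulus(L)
        assert np.isnan(out.values[1][1])

    def test_no_prestim_rows_rejected(self):
        L = self._landscape(np.ones((2, 3)), [1.0, 2.0])
        with pytest.raises(ValueError, match="pre-stimulation"):
            normalize_by_prestimulus(L)


class TestRatioFrames:
    def _stacks(self, num, den):
        mk = lambda a: FrameStack(np.asarray(a, float), 0.39, 1.0, 0)
        return mk(num), mk(den)

    def test_equal_channels_ratio_one(self):
        num, den = self._stacks(np.full((1, 4, 4), 5.0), np.full((1, 4, 4), 5.0))
        mask = CellMask(np.ones((4, 4), bool), 1.0)
        out = ratio_frames(num, den, [mask])
        np.testing.assert_allclose(out[0], 1.0)

    def test_threefold_ratio_and_outside_nan(self):
        den = np.full((1, 4, 4), 2.0)
        num, den = self._stacks(3 * den, den)
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        out = ratio_frames(num, den, [CellMask(m, 1.0)])
        assert np.allclose(out[0][m], 3.0)
        assert np.isnan(out[0][~m]).all()

    def test_zero_denominator_undefined(self):
        d = np.full((1, 4, 4), 2.0)
        d[0, 2, 2] = 0.0
        num, den = self._stacks(np.ones((1, 4, 4)), d)
        out = ratio_frames(num, den, [CellMask(np.ones((4, 4), bool), 1.0)])
        assert np.isnan(out[0, 2, 2])
        assert np.isfinite(out[0, 0, 0])

    def test_shape_mismatch_rejected(self):
        num, _ = self._stacks(np.ones((1, 4, 4)), np.ones((1, 4, 4)))
        _, den = self._stacks(np.ones((1, 5, 5)), np.ones((1, 5, 5)))
        with pytest.raises(ValueError, match="geometry"):
            ratio_frames(num, den, [CellMask(np.ones((4, 4), bool), 1.0)])
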