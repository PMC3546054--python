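"""Intensity extraction: selection heuristics against brute-force oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucloc as nl
from conftest import random_region


def brute_nucleus(smoothed, region, radius=3.0):
    """Oracle: row-major argmax, then explicit distance check per pixel."""
    pix = sorted(zip(region.rows.tolist(), region.cols.tolist()))
    # row-major tie-break: first pixel among maxima
    maxval = max(smoothed[p] for p in pix)
    best = next(p for p in pix if smoothed[p] == maxval)
    return {
        p for p in pix
        if (p[0] - best[0]) ** 2 + (p[1] - best[1]) ** 2 <= radius**2
    }


def brute_cytosol(smoothed, region, nucleus, k=90):
    """Oracle: full sort of remaining pixels by (-intensity, row, col)."""
    pix = sorted(zip(region.rows.tolist(), region.cols.tolist()))
    remaining = [p for p in pix if p not in nucleus]
    remaining.sort(key=lambda p: (-smoothed[p], p[0], p[1]))
    return set(remaining[:k])


class TestSmoothFrame:
    def test_constant_raster_unchanged(self):
        frame = np.full((20, 20), 7.0)
        assert np.allclose(nl.smooth_frame(frame, 2.0), frame)

    def test_impulse_peak_stays_at_impulse(self):
        frame = np.zeros((21, 21))
        frame[13, 7] = 100.0
        out = nl.smooth_frame(frame, 1.5)
        assert np.unravel_index(np.argmax(out), out.shape) == (13, 7)

    def test_interior_impulse_preserves_total_intensity(self):
        frame = np.zeros((41, 41))
        frame[20, 20] = 1000.0
        out = nl.smooth_frame(frame, 1.0)
        assert abs(out.sum() - frame.sum()) / frame.sum() < 0.005


class TestDefineNucleus:
    def test_29_pixel_disc_around_interior_bright_pixel(self):
        frame = np.full((11, 11), 10.0)
        frame[5, 5] = 100.0
        rows, cols = np.mgrid[0:11, 0:11]
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        nuc = nl.define_nucleus(frame, region, 3.0)
        got = set(zip(nuc[0].tolist(), nuc[1].tolist()))
        expected = {
            (5 + dr, 5 + dc)
            for dr in range(-3, 4)
            for dc in range(-3, 4)
            if dr * dr + dc * dc <= 9
        }
        assert len(expected) == 29
        assert got == expected

    def test_disc_clipped_at_region_edge(self):
        frame = np.full((11, 11), 10.0)
        frame[0, 0] = 100.0
        rows, cols = np.mgrid[0:11, 0:11]
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        nuc = nl.define_nucleus(frame, region, 3.0)
        assert 1 <= len(nuc[0]) < 29

    def test_uniform_region_tie_broken_row_major(self):
        frame = np.full((11, 11), 5.0)
        rows, cols = np.mgrid[2:9, 2:9]
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        nuc = nl.define_nucleus(frame, region, 3.0)
        got = set(zip(nuc[0].tolist(), nuc[1].tolist()))
        assert got == brute_nucleus(frame, region)
        assert (2, 2) in got  # centred on the first pixel in row-major order


class TestDefineCytosol:
    def test_exactly_90_when_119_pixel_region(self):
        # 119-pixel region with a 29-pixel nucleus leaves exactly 90
        frame = np.full((20, 20), 10.0)
        rows, cols = np.mgrid[3:20, 3:10]  # 17x7 = 119 pixels
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        frame[10, 6] = 100.0  # disc of radius 3 fits inside the region
        nuc = nl.define_nucleus(frame, region, 3.0)
        assert len(nuc[0]) == 29
        cyt = nl.define_cytosol(frame, region, nuc, 90)
        assert len(cyt[0]) == 90

    def test_fallback_returns_all_with_warning(self):
        frame = np.full((20, 20), 10.0)
        frame[10, 5] = 100.0
        rows, cols = np.mgrid[6:16, 1:11]  # 100 px
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        nuc = nl.define_nucleus(frame, region, 3.0)
        assert len(nuc[0]) == 29
        with pytest.warns(UserWarning, match="cytosolic pixels"):
            cyt = nl.define_cytosol(frame, region, nuc, 90)
        assert len(cyt[0]) == 71

    def test_gradient_region_matches_sort_oracle(self):
        frame = np.add.outer(np.arange(30.0), np.arange(30.0) * 0.37)
        rows, cols = np.mgrid[5:20, 5:20]
        region = nl.CellRegion("c", rows.ravel(), cols.ravel())
        nuc = nl.define_nucleus(frame, region, 3.0)
        nuc_set = set(zip(nuc[0].tolist(), nuc[1].tolist()))
        cyt = nl.define_cytosol(frame, region, nuc, 90)
        got = set(zip(cyt[0].tolist(), cyt[1].tolist()))
        assert got == brute_cytosol(frame, region, nuc_set, 90)

    def test_random_regions_match_oracles(self, rng):
        for i in range(50):
            region = random_region(rng, f"c{i}")
            frame = rng.uniform(0, 100, size=(64, 64))
            sm = nl.smooth_frame(frame, 2.0)
            nuc = nl.define_nucleus(sm, region, 3.0)
            nuc_set = set(zip(nuc[0].tolist(), nuc[1].tolist()))
            assert nuc_set == brute_nucleus(sm, region)
            cyt = nl.define_cytosol(sm, region, nuc, 90)
            cyt_set = set(zip(cyt[0].tolist(), cyt[1].tolist()))
            assert cyt_set == brute_cytosol(sm, region, nuc_set, 90)
            assert not (nuc_set & cyt_set)
            assert (nuc_set | cyt_set) <= region.pixel_set()


class TestExtractTrajectory:
    def _uniform_stack(self, value=50.0, n_frames=4):
        frames = np.full((n_frames, 24, 24), value)
        return nl.ImageStack(frames, np.arange(n_frames) * 4.0)

    def _disc_region(self, centre=(12, 12), radius=7):
        rows, cols = [], []
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr * dr + dc * dc <= radius * radius:
                    rows.append(centre[0] + dr)
                    cols.append(centre[1] + dc)
        return nl.CellRegion("c", np.array(rows), np.array(cols))

    def test_uniform_cell_gives_zero(self):
        traj = nl.extract_trajectory(self._uniform_stack(), self._disc_region())
        assert np.allclose(traj.loc_value, 0.0, atol=1e-12)

    def test_nucleus_at_1p5x_gives_0p5(self):
        region = self._disc_region()
        frames = np.full((3, 24, 24), 100.0)
        for dr in range(-3, 4):
            for dc in range(-3, 4):
                if dr * dr + dc * dc <= 9:
                    frames[:, 12 + dr, 12 + dc] = 150.0
        stack = nl.ImageStack(frames, np.arange(3) * 4.0)
        traj = nl.extract_trajectory(stack, region)
        assert np.allclose(traj.loc_value, 0.5, atol=1e-12)

    def test_scale_invariance(self, rng):
        region = self._disc_region()
        frames = rng.uniform(50, 150, size=(5, 24, 24))
        s1 = nl.ImageStack(frames, np.arange(5) * 4.0)
        s2 = nl.ImageStack(frames * 10.0, np.arange(5) * 4.0)
        t1 = nl.extract_trajectory(s1, region)
        t2 = nl.extract_trajectory(s2, region)
        assert np.allclose(t1.loc_value, t2.loc_value, atol=1e-12)


class TestExpressionResponse:
    def test_cells_equal_background_gives_zero(self):
        frames = np.full((3, 30, 30), 100.0)
        stack = nl.ImageStack(frames, np.arange(3) * 600.0)
        region = nl.CellRegion("a", *np.mgrid[20:26, 20:26].reshape(2, -1))
        pop, _ = nl.expression_response(stack, [region], (0, 5, 0, 5))
        assert np.allclose(pop.response, 0.0)

    def test_two_cell_arithmetic(self):
        frames = np.full((2, 30, 30), 100.0)
        frames[:, 10:14, 10:14] = 110.0
        frames[:, 20:24, 20:24] = 120.0
        stack = nl.ImageStack(frames, np.arange(2) * 600.0)
        a = nl.CellRegion("a", *np.mgrid[10:14, 10:14].reshape(2, -1))
        b = nl.CellRegion("b", *np.mgrid[20:24, 20:24].reshape(2, -1))
        pop, per_cell = nl.expression_response(stack, [a, b], (0, 5, 0, 5))
        assert np.allclose(pop.response, 15.0)
        assert np.allclose(per_cell[0].response, 10.0)
        assert np.allclose(per_cell[1].response, 20.0)

    def test_background_location_independent_in_uniform_background(self):
        frames = np.full((2, 30, 30), 100.0)
        frames[:, 10:14, 10:14] = 130.0
        stack = nl.ImageStack(frames, np.arange(2) * 600.0)
        region = nl.CellRegion("a", *np.mgrid[10:14, 10:14].reshape(2, -1))
        p1, _ = nl.expression_response(stack, [region], (0, 5, 0, 5))
        p2, _ = nl.expression_response(stack, [region], (22, 29, 22, 29))
        assert np.allclose(p1.response, p2.response)

    def test_overlapping_background_rejected(self):
        frames = np.full((2, 30, 30), 100.0)
        stack = nl.ImageStack(frames, np.arange(2) * 600.0)
        region = nl.CellRegion("a", *np.mgrid[2:6, 2:6].reshape(2, -1))
        with pytest.raises(ValueError, match="overlap"):
            nl.expression_response(stack, [region], (0, 5, 0, 5))


class TestRendererExtractorConsistency:
    def test_noise_free_extraction_equals_analytic_ratio(self):
        sc = nl.SimScenario(n_cells=4, archetype_weights=(0.5, 0, 0.5), seed=8,
                            duration=200.0, lag_median=60.0)
        trajs, truth = nl.simulate_population(sc)
        layout = nl.grid_layout(4, nuclear_gain=1.8)
        stack, regions = nl.render_frames(truth, layout, sc)
        for i, traj in enumerate(nl.extract_trajectories(stack, regions)):
            analytic = np.where(truth.states[i] == 1, 0.8, 0.0)
            assert np.max(np.abs(traj.loc_value - analytic)) < 1e-9


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=1000), seed=st.integers(0, 10))
def test_loc_value_scale_invariance_property(scale, seed):
    """Multiplying all intensities by c > 0 leaves loc_value unchanged."""
    rng = np.random.default_rng(seed)
    frames = rng.uniform(10, 200, size=(2, 24, 24))
    rows, cols = np.mgrid[4:20, 4:20]
    region = nl.CellRegion("c", rows.ravel(), cols.ravel())
    t1 = nl.extract_trajectory(nl.ImageStack(frames, [0.0, 4.0]), region)
    t2 = nl.extract_trajectory(nl.ImageStack(frames * scale, [0.0, 4.0]), region)
    assert np.allclose(t1.loc_value, t2.loc_value, atol=1e-9)
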