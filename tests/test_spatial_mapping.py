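"""Mark geometry, overlap computation, filtering and cell aggregation."""

import numpy as np
import pytest

from lipotrace.io_formats import LabelImage
from lipotrace.spatial_mapping import (
    AblationMark,
    MarkGrid,
    aggregate_cell_profile,
    compute_overlap,
    filter_and_assign,
    fit_mark_grid,
    rasterize_grid,
)


def make_mark(mark_id=0, centre=(0.0, 0.0), radius=5.0, overlap=None):
    m = AblationMark(mark_id=mark_id, grid_index=(0, 0), centre=centre,
                     radius=radius)
    if overlap is not None:
        m.overlap = overlap
    return m


class TestGridGeometry:
    def test_axis_aligned_2x2_centres(self):
        grid = MarkGrid(origin=(0, 0), pitch=10, rotation=0.0, radius=5,
                        shape=(2, 2))
        centres = [m.centre for m in rasterize_grid(grid)]
        assert centres == [(0, 0), (10, 0), (0, 10), (10, 10)]

    def test_quarter_turn_rotates_centres(self):
        grid = MarkGrid(origin=(0, 0), pitch=10, rotation=np.pi / 2, radius=5,
                        shape=(1, 2))
        (x0, y0), (x1, y1) = [m.centre for m in rasterize_grid(grid)]
        assert (x0, y0) == (0, 0)
        assert x1 == pytest.approx(0.0, abs=1e-9)
        assert y1 == pytest.approx(10.0, abs=1e-9)

    def test_fit_recovers_exact_grid(self):
        truth = MarkGrid(origin=(3.0, 7.0), pitch=10.0, rotation=0.1,
                         radius=5.0, shape=(3, 3))
        marks = rasterize_grid(truth)
        grid, rms = fit_mark_grid([m.centre for m in marks],
                                  [m.grid_index for m in marks])
        assert rms < 1e-9
        assert grid.pitch == pytest.approx(10.0)
        assert grid.rotation == pytest.approx(0.1)
        assert grid.origin[0] == pytest.approx(3.0)

    def test_fit_roundtrips_annotated_centres(self):
        truth = MarkGrid(origin=(12.0, -4.0), pitch=9.7, rotation=-0.07,
                         radius=5.0, shape=(4, 5))
        marks = rasterize_grid(truth)
        pick = marks[::4][:5]
        grid, _ = fit_mark_grid([m.centre for m in pick],
                                [m.grid_index for m in pick],
                                shape=truth.shape)
        refit = rasterize_grid(grid)
        for orig, new in zip(marks, refit):
            assert abs(orig.centre[0] - new.centre[0]) < 0.5
            assert abs(orig.centre[1] - new.centre[1]) < 0.5

    def test_fit_with_jitter_recovers_pitch_within_1pct(self):
        rng = np.random.default_rng(8)
        truth = MarkGrid(origin=(0, 0), pitch=10.0, rotation=0.05, radius=5,
                         shape=(6, 6))
        marks = rasterize_grid(truth)
        centres = [(m.centre[0] + rng.normal(0, 0.3),
                    m.centre[1] + rng.normal(0, 0.3)) for m in marks]
        grid, _ = fit_mark_grid(centres, [m.grid_index for m in marks])
        assert grid.pitch == pytest.approx(10.0, rel=0.01)

    def test_underdetermined_and_collinear_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_mark_grid([(0, 0), (10, 0)], [(0, 0), (0, 1)])
        with pytest.raises(ValueError):
            fit_mark_grid([(0, 0), (10, 0), (20, 0)],
                          [(0, 0), (0, 1), (0, 2)])


class TestOverlap:
    def test_mark_inside_single_cell(self):
        labels = LabelImage(np.full((40, 40), 3, dtype=np.int32), pixel_size=1.0)
        mark = make_mark(centre=(20.0, 20.0), radius=5.0)
        compute_overlap([mark], labels)
        assert mark.overlap == {3: 1.0}
        assert mark.intracellular_cell == 3

    def test_mark_on_background_only(self):
        labels = LabelImage(np.zeros((40, 40), dtype=np.int32))
        mark = make_mark(centre=(20.0, 20.0), radius=5.0)
        compute_overlap([mark], labels)
        assert mark.overlap == {}
        assert mark.intracellular_cell is None

    def test_mark_outside_image_empty_map(self):
        labels = LabelImage(np.ones((10, 10), dtype=np.int32))
        mark = make_mark(centre=(100.0, 100.0), radius=3.0)
        compute_overlap([mark], labels)
        assert mark.overlap == {}

    def test_straddling_boundary_is_half_by_pixel_count(self):
        arr = np.zeros((60, 60), dtype=np.int32)
        arr[:, 30:] = 1  # straight vertical boundary at x=30 µm
        labels = LabelImage(arr, pixel_size=1.0)
        mark = make_mark(centre=(30.0, 30.0), radius=8.0)
        compute_overlap([mark], labels)
        # oracle: count rasterized circle pixels on the labelled side
        cols, rows = np.meshgrid(np.arange(60) + 0.5, np.arange(60) + 0.5)
        inside = (cols - 30) ** 2 + (rows - 30) ** 2 <= 64
        expected = (inside & (arr == 1)).sum() / inside.sum()
        assert mark.overlap[1] == pytest.approx(expected)
        assert abs(mark.overlap[1] - 0.5) < 0.05

    def test_sum_of_overlaps_bounded_by_one(self):
        arr = np.zeros((30, 30), dtype=np.int32)
        arr[:15] = 1
        arr[15:] = 2
        labels = LabelImage(arr)
        mark = make_mark(centre=(15.0, 15.0), radius=6.0)
        compute_overlap([mark], labels)
        assert sum(mark.overlap.values()) <= 1.0 + 1e-12


class TestFilterAndAssign:
    def _toy_marks(self):
        """10 marks: 3 below the intensity filter, then 4 below overlap."""
        marks, totals = [], {}
        for i in range(10):
            if i < 3:
                totals[i] = 150.0  # < 200 → dropped
                overlap = {1: 0.9}
            elif i < 7:
                totals[i] = 500.0
                overlap = {1: 0.2}  # < 0.30 → not intracellular
            else:
                totals[i] = 500.0
                overlap = {1: 0.6}
            marks.append(make_mark(mark_id=i, overlap=overlap))
        return marks, totals

    def test_counting_example(self):
        marks, totals = self._toy_marks()
        assigned = filter_and_assign(marks, totals)
        assert sorted(assigned[1]) == [7, 8, 9]
        assert sum(len(v) for v in assigned.values()) == 3

    def test_argmax_cell_wins(self):
        mark = make_mark(mark_id=0, overlap={2: 0.35, 1: 0.40})
        assigned = filter_and_assign([mark], {0: 1000.0})
        assert assigned == {1: [0]}

    def test_overlap_tie_broken_by_lower_cell_id(self):
        mark = make_mark(mark_id=0, overlap={5: 0.4, 2: 0.4})
        assigned = filter_and_assign([mark], {0: 1000.0})
        assert assigned == {2: [0]}

    def test_boundary_values(self):
        # exactly at threshold: total == 200 kept ("less than 200" dropped),
        # overlap == 0.30 kept ("at least 30%")
        mark = make_mark(mark_id=0, overlap={1: 0.30})
        assert filter_and_assign([mark], {0: 200.0}) == {1: [0]}
        assert filter_and_assign([mark], {0: 199.9}) == {}

    def test_threshold_sweep_is_monotone(self):
        rng = np.random.default_rng(6)
        marks = [make_mark(mark_id=i, overlap={1: rng.random()})
                 for i in range(50)]
        totals = {i: rng.uniform(0, 1000) for i in range(50)}
        counts = []
        for thr in [0, 100, 200, 400, 800, 1600]:
            assigned = filter_and_assign(marks, totals, min_total_intensity=thr)
            counts.append(sum(len(v) for v in assigned.values()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_each_mark_assigned_to_at_most_one_cell(self):
        rng = np.random.default_rng(13)
        marks = []
        for i in range(30):
            overlap = {1: rng.random() * 0.6, 2: rng.random() * 0.6}
            marks.append(make_mark(mark_id=i, overlap=overlap))
        assigned = filter_and_assign(marks, {i: 1000.0 for i in range(30)})
        all_ids = [m for v in assigned.values() for m in v]
        assert len(all_ids) == len(set(all_ids))


class TestAggregation:
    def test_identical_profiles_preserved(self):
        p = np.array([0.5, 0.3, 0.2])
        out = aggregate_cell_profile([p, p, p])
        assert np.allclose(out, p)

    def test_median_ignores_outlier_entrywise(self):
        clean = np.array([0.6, 0.3, 0.1])
        outlier = np.array([0.0, 0.0, 1.0])
        out = aggregate_cell_profile([clean, clean, outlier])
        med = np.median(np.vstack([clean, clean, outlier]), axis=0)
        assert np.allclose(out, med / med.sum())
        assert np.allclose(out, clean)

    def test_single_mark_passthrough(self):
        p = np.array([0.25, 0.25, 0.5])
        assert np.allclose(aggregate_cell_profile([p]), p)

    def test_zero_marks_gives_missing(self):
        assert aggregate_cell_profile([]) is None

    def test_invariant_to_mark_ordering(self):
        rng = np.random.default_rng(3)
        profiles = [rng.dirichlet(np.ones(9)) for _ in range(7)]
        a = aggregate_cell_profile(profiles)
        b = aggregate_cell_profile(profiles[::-1])
        assert np.array_equal(a, b)


class TestEndToEndRecovery:
    def test_cell_profiles_match_ground_truth(self, small_field):
        from lipotrace.spatial_mapping import build_cell_records

        recs = build_cell_records(small_field["pixels"], small_field["marks"],
                                  small_field["labels"], small_field["panel"])
        truth = small_field["truth"].cells.set_index("cell_id")
        errs_p, errs_u = [], []
        for r in recs:
            fit = r.fits.get("C16:0")
            if fit is None:
                continue
            errs_p.append(abs(fit.p - truth.loc[r.cell_id, "p"]))
            errs_u.append(abs(fit.uptake - truth.loc[r.cell_id, "uptake"]))
        assert len(errs_p) >= 35
        assert np.median(errs_p) < 0.03
        assert np.median(errs_u) < 0.05

    def test_marks_with_centre_in_cell_match_area_expectation(self, small_field):
        labels = small_field["labels"]
        marks = small_field["marks"]
        img = labels.labels
        n_in = 0
        for m in marks:
            c = int(m.centre[0] / labels.pixel_size)
            r = int(m.centre[1] / labels.pixel_size)
            if 0 <= r < img.shape[0] and 0 <= c < img.shape[1] and img[r, c] > 0:
                n_in += 1
        mean_area = small_field["truth"].cells["area_um2"].mean()
        expected = mean_area / small_field["grid"].pitch ** 2
        observed = n_in / len(small_field["truth"].cells)
        assert observed == pytest.approx(expected, rel=0.2)
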