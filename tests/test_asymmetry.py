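"""Extended Laplace operator and the per-unit asymmetry statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pimidetect import (
    asymmetry_score,
    call_units,
    extended_laplace,
    records_to_frame,
    score_units,
    summarize,
    threshold_from_clean,
)
from pimidetect.asymmetry import AsymmetryRecord


def patch_grid(values):
    """Build a (R, C, 1, 1) unit array from a 2-D matrix of scalars."""
    v = np.asarray(values, dtype=float)
    return v[:, :, None, None]


class TestExtendedLaplace:
    def test_identical_patches_cancel(self, rng):
        patch = rng.uniform(0, 1, (8, 8))
        units = np.tile(patch, (3, 3, 1, 1))
        lap = extended_laplace(units)
        assert np.all(np.abs(lap.units[1, 1]) <= 1e-12)
        assert lap.valid_mask[1, 1] and lap.valid_mask.sum() == 1

    def test_hand_computed_stencil(self):
        units = patch_grid([[1, 2, 3], [4, 10, 6], [7, 8, 9]])
        lap = extended_laplace(units)
        assert lap.units[1, 1, 0, 0] == pytest.approx(10 - 40 / 8, abs=1e-15)

    def test_affine_in_index_annihilated(self):
        i, j = np.meshgrid(np.arange(6), np.arange(7), indexing="ij")
        units = patch_grid(2.0 + 0.3 * i - 1.7 * j)
        lap = extended_laplace(units)
        assert np.all(np.abs(lap.units[lap.valid_mask]) <= 1e-12)

    @given(alpha=st.floats(-5, 5), beta=st.floats(-5, 5))
    def test_linearity(self, alpha, beta):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (4, 4, 3, 3))
        y = rng.uniform(-1, 1, (4, 4, 3, 3))
        lap_lin = extended_laplace(alpha * x + beta * y)
        expected = alpha * extended_laplace(x).units + beta * extended_laplace(y).units
        assert np.allclose(lap_lin.units, expected, atol=1e-10)

    def test_invalid_neighbour_propagates(self):
        units = np.ones((4, 4, 2, 2))
        valid = np.ones((4, 4), dtype=bool)
        valid[0, 0] = False
        lap = extended_laplace(units, valid_mask=valid)
        assert not lap.valid_mask[1, 1]
        assert lap.valid_mask[2, 2]

    def test_small_grid_raises(self):
        with pytest.raises(ValueError):
            extended_laplace(np.ones((2, 3, 4, 4)))


class TestAsymmetryScore:
    def test_mirror_symmetric_patch_scores_zero(self, rng):
        half = rng.uniform(0.1, 1.0, (5, 8))
        patch = np.vstack([half, half[::-1]])
        r = asymmetry_score(patch)
        assert r.score == 0.0
        assert r.direction == "none"

    def test_worked_example_positive(self):
        # A = 2, B = 1, Isum = 3 -> 3 * (2 + 0.5 - 2) = 1.5
        patch = np.array([[2.0], [0.0], [1.0]])  # odd height: middle row excluded
        r = asymmetry_score(patch)
        assert (r.A, r.B, r.i_sum) == (2.0, 1.0, 3.0)
        assert r.score == pytest.approx(1.5, abs=1e-15)
        assert r.direction == "bottom"

    def test_worked_example_opposite_signs(self):
        # A = 1, B = -1, Isum = 1 -> 1 * (-1 - 1 - 2) = -4
        patch = np.array([[1.0], [-1.0]])
        r = asymmetry_score(patch)
        assert r.score == pytest.approx(-4.0, abs=1e-15)

    def test_middle_row_excluded_in_odd_patches(self):
        patch = np.array([[1.0], [100.0], [1.0]])
        r = asymmetry_score(patch)
        assert r.A == r.B == 1.0
        assert r.score == 0.0

    def test_zero_half_sum_marks_invalid(self):
        r = asymmetry_score(np.array([[0.0], [1.0]]))
        assert not r.valid
        assert np.isnan(r.score)

    def test_no_positive_pixels_scores_zero_but_valid(self):
        r = asymmetry_score(np.array([[-1.0], [-2.0]]))
        assert r.valid
        assert r.i_sum == 0.0
        assert r.score == 0.0

    def test_flip_swaps_halves_and_direction(self, rng):
        patch = rng.uniform(-1, 1, (6, 6))
        r = asymmetry_score(patch)
        rf = asymmetry_score(patch[::-1])
        assert rf.A == pytest.approx(r.B, rel=1e-12)
        assert rf.B == pytest.approx(r.A, rel=1e-12)
        if r.valid and rf.valid:
            assert rf.score == pytest.approx(r.score, rel=1e-12)
            if r.direction != "none":
                assert rf.direction != r.direction
                assert rf.signed_score == pytest.approx(-r.signed_score, rel=1e-12)


class TestCallsAndSummary:
    def _rec(self, score, valid=True, i=0, j=0):
        return AsymmetryRecord(
            i=i, j=j, A=1.0, B=1.0, i_sum=1.0, score=score,
            signed_score=score, valid=valid,
        )

    @pytest.mark.parametrize(
        "score,expected", [(7.5, True), (-8.0, True), (3.0, False), (7.0, False)]
    )
    def test_threshold_rule(self, score, expected):
        (r,) = call_units([self._rec(score)], threshold=7.0)
        assert r.call is expected

    def test_invalid_records_never_called(self):
        (r,) = call_units([self._rec(50.0, valid=False)])
        assert not r.call

    def test_misdetection_fraction_one_of_six(self):
        import pandas as pd

        truth = pd.DataFrame(
            {"i": range(7), "j": [0] * 7, "virus": [True] * 6 + [False],
             "side": ["top"] * 6 + ["none"]}
        )
        records = [self._rec(20.0, i=i) for i in range(5)]  # 5 of 6 called
        records += [self._rec(1.0, i=5), self._rec(1.0, i=6)]
        records = call_units(records)
        s = summarize(records, truth)
        assert s["tp"] == 5 and s["fn"] == 1 and s["fp"] == 0
        assert s["p_mis_hat"] == pytest.approx(1 / 6)

    def test_specificity_and_sensitivity_edges(self):
        import pandas as pd

        truth = pd.DataFrame({"i": [0, 1], "j": [0, 0], "virus": [False, False],
                              "side": ["none", "none"]})
        s = summarize(call_units([self._rec(0.1, i=0), self._rec(0.2, i=1)]), truth)
        assert s["specificity"] == 1.0
        truth_all = pd.DataFrame({"i": [0, 1], "j": [0, 0], "virus": [True, True],
                                  "side": ["top", "top"]})
        s = summarize(call_units([self._rec(10.0, i=0), self._rec(12.0, i=1)]), truth_all)
        assert s["sensitivity"] == 1.0

    def test_threshold_recalibration(self):
        records = [self._rec(s) for s in (0.5, -2.0, 1.0)]
        assert threshold_from_clean(records, margin=2.0) == pytest.approx(4.0)


class TestScoreUnits:
    def test_planted_virus_dominates_clean_interior(self, small_scene_spec):
        from pimidetect import build_scene, segment_units
        from pimidetect.grid import ArrayLayout

        maps, truth = build_scene(small_scene_spec)
        u = small_scene_spec.unit_px
        layout = ArrayLayout(
            origin_px=((u - 1) / 2, (u - 1) / 2), pitch_px=float(u),
            rows=small_scene_spec.rows, cols=small_scene_spec.cols, unit_px=u,
        )
        grid = segment_units(maps["sindelta"], layout)
        records = score_units(grid)
        df = records_to_frame(records)
        virus = df[(df.i == 2) & (df.j == 2)]
        clean = df[df.valid & ~((df.i == 2) & (df.j == 2))]
        assert abs(virus.score.iloc[0]) > clean.score.abs().max()

    def test_report_rows_equal_grid_size_and_valid_is_interior(self, small_scene_spec):
        from pimidetect import build_scene, segment_units
        from pimidetect.grid import ArrayLayout

        maps, _ = build_scene(small_scene_spec)
        u = small_scene_spec.unit_px
        layout = ArrayLayout(
            origin_px=((u - 1) / 2, (u - 1) / 2), pitch_px=float(u),
            rows=5, cols=5, unit_px=u,
        )
        grid = segment_units(maps["sindelta"], layout)
        df = records_to_frame(score_units(grid))
        assert len(df) == 25
        assert df.valid.sum() == 9  # 3x3 interior of a 5x5 lattice
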