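import math

import numpy as np
import pytest

from torsobaro.errors import UndefinedIndexError
from torsobaro.frame_io import mirror_columns
from torsobaro.indices import (
    COPCurve,
    compute_all,
    compute_cop,
    compute_paa,
    compute_saa,
    compute_sii,
    compute_tai,
    compute_tba,
    compute_waa,
    _offset_angle,
)
from torsobaro.landmarks import IntensityCurve
from torsobaro.preprocess import ROIFrame

from .conftest import analyze_phantom, clean_params


def roi_from(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = values > 0 if mask is None else mask
    return ROIFrame(values=np.where(mask, values, 0.0), mask=mask)


class TestCOP:
    def test_symmetric_row_is_on_axis(self):
        values = np.zeros((160, 100))
        values[50, 39:60] = 7.0  # symmetric about column 49
        cop = compute_cop(roi_from(values), 20, 80)
        assert cop.cop[0] == pytest.approx(49.0)

    def test_point_mass(self):
        values = np.zeros((160, 100))
        values[10, 40] = 5.0
        cop = compute_cop(roi_from(values), 20, 80)
        assert cop.rows[0] == 10 and cop.cop[0] == 40.0

    def test_weighted_mean(self):
        values = np.zeros((160, 100))
        values[33, 40] = 100.0
        values[33, 60] = 300.0
        cop = compute_cop(roi_from(values), 20, 80)
        assert cop.cop[0] == pytest.approx(55.0)

    def test_empty_range_is_error(self):
        with pytest.raises(UndefinedIndexError):
            compute_cop(roi_from(np.zeros((160, 100))), 20, 80)


def cop_curve(rows, values, weight=None):
    rows = np.asarray(rows)
    return COPCurve(
        rows=rows,
        cop=np.asarray(values, dtype=float),
        support=(0, 99),
        weight=None if weight is None else np.asarray(weight, float),
    )


class TestTBA:
    def test_straight_cop_gives_zero(self):
        j = np.arange(20, 120)
        tba, apexes = compute_tba(cop_curve(j, 45 + 0.05 * j))
        assert tba == 0.0 and apexes == []

    def test_sinusoid_matches_analytic_angle(self):
        # cop = 50 + 5 sin(pi (j-20)/40): inflection slopes +-5*pi/40, so the
        # inter-tangent angle is 2*atan(0.3927) = 42.89 deg (smoothing and
        # finite differences attenuate the tangent slightly); the domain
        # covers 1.5 periods so an apex has interior inflections on both sides
        j = np.arange(20, 141)
        cop = 50 + 5 * np.sin(np.pi * (j - 20) / 40.0)
        tba, apexes = compute_tba(cop_curve(j, cop))
        assert tba == pytest.approx(42.89, abs=1.0)
        assert len(apexes) >= 1

    def test_max_over_apices_of_unequal_sharpness(self):
        # two Gaussian bumps; the per-apex angle is 2*atan(A e^-0.5 / sigma)
        j = np.arange(0, 160)
        a1, s1, a2, s2 = 3.0, 14.0, 6.0, 12.0
        cop = (
            50.0
            + a1 * np.exp(-0.5 * ((j - 45) / s1) ** 2)
            - a2 * np.exp(-0.5 * ((j - 110) / s2) ** 2)
        )
        expected = [
            2 * math.degrees(math.atan(a * math.exp(-0.5) / s))
            for a, s in ((a1, s1), (a2, s2))
        ]
        tba, apexes = compute_tba(cop_curve(j, cop))
        assert tba == pytest.approx(max(expected), abs=1.5)
        per_apex = sorted(a.angle_deg for a in apexes)
        assert tba == max(per_apex)

    def test_too_few_rows_is_error(self):
        with pytest.raises(UndefinedIndexError, match=">= 7"):
            compute_tba(cop_curve(np.arange(5), np.zeros(5)))


class TestSII:
    def test_equal_regions_give_100(self):
        v = np.zeros(160)
        v[40:60] = 30.0
        v[60:80] = 30.0
        curve = IntensityCurve(rows=np.arange(160), values=v)
        sii = compute_sii(curve, np.arange(40, 60), np.arange(60, 80), 10.0)
        assert sii == pytest.approx(100.0)

    def test_two_to_one_ratio(self):
        v = np.zeros(160)
        v[40:50] = 70.0  # sum over threshold v=10: 600
        v[60:70] = 40.0  # 300
        curve = IntensityCurve(rows=np.arange(160), values=v)
        sii = compute_sii(curve, np.arange(40, 50), np.arange(60, 70), 10.0)
        assert sii == pytest.approx(200.0)

    def test_zero_denominator_is_undefined(self):
        v = np.full(160, 10.0)
        curve = IntensityCurve(rows=np.arange(160), values=v)
        with pytest.raises(UndefinedIndexError, match="denominator"):
            compute_sii(curve, np.arange(40, 50), np.arange(60, 70), 10.0)


class TestTAI:
    def test_mirror_symmetric_imprint_is_zero(self):
        values = np.zeros((160, 100))
        values[30:60, 30:69] = 500.0
        tai, n = compute_tai(roi_from(values), 25, 70)
        assert tai == 0.0 and n > 0

    def test_hand_computed_four_cell_instance(self):
        # overlap cells (1-based cols 40/45/55/60 -> 0-based 39/44/54/59):
        # pair (44, 54) = (100, 100) contributes 0 twice; pair (39, 59) =
        # (150, 100) contributes |1-150/100| + |1-100/150| = 0.8333;
        # TAI = 100 * 0.8333/4 = 20.83%
        values = np.zeros((160, 100))
        values[30, 39] = 150.0
        values[30, 44] = 100.0
        values[30, 54] = 100.0
        values[30, 59] = 100.0
        values[31, 44] = 10.0  # low cells keep the band threshold below 100
        values[31, 54] = 10.0
        roi = roi_from(values)
        tai, n = compute_tai(roi, 29, 32)
        assert n == 4
        assert tai == pytest.approx(100 * (0.5 + 1 / 3) / 4, abs=1e-9)

    def test_mirror_invariance(self, scoliotic_case):
        _, roi, _ = scoliotic_case
        tai, _ = compute_tai(roi, 20, 85)
        mroi = ROIFrame(
            values=mirror_columns(roi.values),
            mask=mirror_columns(roi.mask.astype(float)) > 0.5,
        )
        mtai, _ = compute_tai(mroi, 20, 85)
        assert mtai == pytest.approx(tai, abs=1e-9)

    def test_empty_overlap_is_undefined(self):
        values = np.zeros((160, 100))
        values[30:40, 5:15] = 100.0  # entirely left of the axis, no mirror overlap
        with pytest.raises(UndefinedIndexError, match="overlap"):
            compute_tai(roi_from(values), 28, 42)


class TestOffsetAngles:
    def test_level_points_give_zero(self):
        assert compute_saa((30.0, 30.0), (30.0, 70.0)) == 0.0
        assert compute_waa((70.0, 28.0), (70.0, 72.0)) == 0.0
        assert compute_paa((140.0, 35.0), (140.0, 65.0)) == 0.0

    def test_trigonometry_examples(self):
        assert compute_saa((30, 30), (34, 70)) == pytest.approx(
            math.degrees(math.atan(4 / 40)), abs=1e-9
        )
        assert compute_paa((140, 35), (142, 65)) == pytest.approx(
            math.degrees(math.atan(2 / 30)), abs=1e-9
        )
        assert compute_waa((70, 28), (74, 72)) == pytest.approx(
            math.degrees(math.atan(4 / 44)), abs=1e-9
        )

    def test_swapping_sides_flips_sign_keeps_magnitude(self):
        mag, signed = _offset_angle((30, 30), (34, 70), "SAA")
        mag2, signed2 = _offset_angle((34, 70), (30, 30), "SAA")
        assert mag == pytest.approx(mag2)
        assert signed == pytest.approx(-signed2)

    def test_coincident_columns_rejected(self):
        with pytest.raises(UndefinedIndexError):
            _offset_angle((30, 50), (40, 50), "SAA")


class TestComputeAll:
    def test_symmetric_phantom_near_zero_asymmetry(self, symmetric_roi):
        idx = compute_all(symmetric_roi)
        assert idx.failures == {}
        for name in ("tba", "tai", "saa", "waa", "paa"):
            assert abs(getattr(idx, name)) < 0.5
        assert np.isfinite(idx.sii) and idx.sii > 0

    def test_scoliotic_phantom_elevated_indices(self, symmetric_roi, scoliotic_case):
        _, _, idx = scoliotic_case
        ref = compute_all(symmetric_roi)
        assert idx.tba > ref.tba + 5
        assert idx.tai > ref.tai + 3
        assert idx.waa > ref.waa + 1
        assert all(v is not None for v in idx.as_dict().values())

    def test_straight_flanks_fail_only_waa(self):
        # rectangular torso: no waist narrowing, so only WAA is undefined
        j = np.arange(160, dtype=float)[:, None]
        i = np.arange(100, dtype=float)[None, :]
        amp = (
            300.0
            + 500 * np.exp(-0.5 * ((j - 40) / 8) ** 2)
            - 150 * np.exp(-0.5 * ((j - 85) / 9) ** 2)
            + 600 * np.exp(-0.5 * ((j - 110) / 8) ** 2)
        )
        inside = (j >= 20) & (j < 130) & (i >= 25) & (i < 74)
        values = np.where(inside, amp, 0.0)
        values += 500 * np.exp(-0.5 * ((j - 40) / 4) ** 2 - 0.5 * ((i - 35) / 4) ** 2) * inside
        values += 500 * np.exp(-0.5 * ((j - 40) / 4) ** 2 - 0.5 * ((i - 63) / 4) ** 2) * inside
        idx = compute_all(roi_from(values))
        assert "waa" in idx.failures and idx.waa is None
        for name in ("tba", "sii", "tai", "saa"):
            assert getattr(idx, name) is not None, idx.failures

    def test_scale_invariance(self, scoliotic_case):
        _, roi, idx = scoliotic_case
        scaled = ROIFrame(values=roi.values * 3.0, mask=roi.mask)
        idx2 = compute_all(scaled)
        for name in ("tba", "sii", "tai", "saa", "waa", "paa"):
            assert getattr(idx2, name) == pytest.approx(getattr(idx, name), abs=1e-9)
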