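"""The six torsobarographic indices.

* TBA (torsobarography angle, deg) — pressure-image analogue of the Cobb
  angle: the maximum inter-tangent angle at the inflection rows flanking a
  center-of-pressure curve extremum.
* SII (sagittal imbalance index, %) — reference-corrected ratio of summed
  mean pressure in the thoracic vs lumbar row regions.
* TAI (torso asymmetry index, %) — mean absolute relative difference
  between the segmented torso imprint and its mirror image.
* SAA / WAA / PAA (deg) — offset angles between the scapula centers, waist
  apices and upper-pelvic-edge midpoints.

All angle indices are reported as magnitudes (signed values are kept in
the diagnostics for laterality); slopes in columns-per-row are
dimensionless because the grid pitch is equal on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import IndexConfig, LandmarkConfig
from .errors import LandmarkFailure, UndefinedIndexError
from .frame_io import mirror_columns
from .landmarks import (
    IntensityCurve,
    LandmarkSet,
    _moving_average,
    detect_longitudinal_landmarks,
    detect_pelvic_contour,
    locate_scapulae,
    locate_waist_apices,
    mean_intensity_curve,
)
from .preprocess import ROIFrame

__all__ = [
    "COPCurve",
    "CurvatureApex",
    "IndexSet",
    "compute_cop",
    "compute_tba",
    "compute_sii",
    "compute_tai",
    "compute_saa",
    "compute_paa",
    "compute_waa",
    "compute_all",
]

INDEX_NAMES = ("tba", "sii", "tai", "saa", "waa", "paa")


@dataclass
class COPCurve:
    """Per-row pressure-weighted mean column of the imprint."""

    rows: np.ndarray
    cop: np.ndarray
    support: tuple  # (i_pl, i_pr)
    weight: np.ndarray | None = None  # per-row total pressure in the range


@dataclass
class CurvatureApex:
    j_apex: int
    j_ipa: int  # inflection row above (cranial)
    j_ipb: int  # inflection row below (caudal)
    slope_above: float
    slope_below: float

    @property
    def angle_deg(self) -> float:
        return abs(
            math.degrees(math.atan(self.slope_above) - math.atan(self.slope_below))
        )


@dataclass
class IndexSet:
    tba: float | None = None
    sii: float | None = None
    tai: float | None = None
    saa: float | None = None
    waa: float | None = None
    paa: float | None = None
    diagnostics: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def compute_cop(roi: ROIFrame, i_pl: int, i_pr: int) -> COPCurve:
    """COP(j) = sum(i * I(j,i)) / sum(I(j,i)) over i in [i_pl, i_pr]."""
    if not i_pl < i_pr:
        raise ValueError(f"need i_pl < i_pr, got ({i_pl}, {i_pr})")
    sub = roi.values[:, i_pl : i_pr + 1]
    den = sub.sum(axis=1)
    rows = np.flatnonzero(den > 0)
    if len(rows) == 0:
        raise UndefinedIndexError("no row with pressure in the COP column range")
    cols = np.arange(i_pl, i_pr + 1)
    cop = (sub[rows] * cols).sum(axis=1) / den[rows]
    return COPCurve(rows=rows, cop=cop, support=(i_pl, i_pr), weight=den[rows])


def _longest_run(rows: np.ndarray) -> slice:
    breaks = np.flatnonzero(np.diff(rows) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks + 1, len(rows)]
    k = int(np.argmax(ends - starts))
    return slice(starts[k], ends[k])


def compute_tba(
    cop_curve: COPCurve, config: IndexConfig | None = None
) -> tuple[float, list[CurvatureApex]]:
    """Maximum inter-tangent angle over all COP curvature apices (deg).

    The COP curve is smoothed with a moving average before differentiation
    (tangent estimates on raw integer-weighted curves are noise dominated);
    inflections are sign changes of the central second difference; tangent
    slopes are central differences.  A straight frontal curve (no interior
    extremum) yields TBA = 0.
    """
    cfg = config or IndexConfig()
    rows = cop_curve.rows
    cop = cop_curve.cop
    if cop_curve.weight is not None:
        # the first/last taper rows carry almost no pressure and their COP
        # is dominated by mask quantization; keep substantive rows only
        solid = cop_curve.weight >= cfg.min_row_weight_frac * cop_curve.weight.max()
        rows, cop = rows[solid], cop[solid]
    run = _longest_run(rows)
    rows = rows[run]
    cop = cop[run]
    if len(rows) < 7:
        raise UndefinedIndexError(f"COP defined on {len(rows)} rows; need >= 7")
    s = _moving_average(cop, cfg.cop_smooth_rows)
    maxima, _ = find_peaks(s, prominence=cfg.cop_peak_prominence)
    minima, _ = find_peaks(-s, prominence=cfg.cop_peak_prominence)
    extrema = np.sort(np.concatenate([maxima, minima]))
    if len(extrema) == 0:
        return 0.0, []
    d2 = s[2:] - 2 * s[1:-1] + s[:-2]  # d2[m] ~ f''(m + 1)
    # mask-quantization ripple leaves tiny oscillations in d2; smooth it
    # before locating curvature sign changes
    d2s = _moving_average(d2, cfg.d2_smooth_rows)
    sg = np.sign(d2s)
    for m in range(1, len(sg)):  # carry sign through exact zeros
        if sg[m] == 0:
            sg[m] = sg[m - 1]
    sign_change = np.flatnonzero(sg[:-1] != sg[1:]) + 1
    # smoothing edge effects distort curvature near the curve ends
    guard = 4
    sign_change = sign_change[(sign_change >= guard) & (sign_change <= len(s) - 1 - guard)]
    inflections = np.unique(sign_change)
    apexes = []
    for e in extrema:
        above = inflections[inflections < e]
        below = inflections[inflections > e]
        if len(above) == 0 or len(below) == 0:
            continue
        ja, jb = int(above[-1]), int(below[0])
        if jb - ja < cfg.min_apex_span_rows:
            continue
        slope = lambda k: float((s[k + 1] - s[k - 1]) / 2) if 0 < k < len(s) - 1 else 0.0
        apexes.append(
            CurvatureApex(
                j_apex=int(rows[e]),
                j_ipa=int(rows[ja]),
                j_ipb=int(rows[jb]),
                slope_above=slope(ja),
                slope_below=slope(jb),
            )
        )
    if not apexes:
        return 0.0, []
    return max(a.angle_deg for a in apexes), apexes


def compute_sii(
    pbar: IntensityCurve,
    omega_th: np.ndarray,
    omega_lu: np.ndarray,
    v_pbar: float,
) -> float:
    """SII = 100 * sum_th(pbar - v) / sum_lu(pbar - v), in percent."""
    if len(omega_th) == 0 or len(omega_lu) == 0:
        raise UndefinedIndexError("empty thoracic or lumbar region")
    v = np.asarray(pbar.values, dtype=float)
    num = float((v[np.asarray(omega_th)] - v_pbar).sum())
    den = float((v[np.asarray(omega_lu)] - v_pbar).sum())
    if den <= 0:
        raise UndefinedIndexError(f"SII denominator {den:.3g} <= 0 in the lumbar region")
    return 100.0 * num / den


def compute_tai(roi: ROIFrame, j_ts: int, j_lmin: int) -> tuple[float, int]:
    """Mean absolute relative mirror difference of the segmented imprint (%).

    Rows [j_ts, j_lmin] only (the accentuated sacral imprint would dominate
    otherwise); the imprint is segmented at the mean masked pressure of the
    band; the sum runs over every cell whose mirrored partner is also
    segmented, so both members of each mirrored pair contribute.
    Returns (TAI, overlap cell count).
    """
    if not j_ts < j_lmin:
        raise ValueError(f"need j_ts < j_lmin, got ({j_ts}, {j_lmin})")
    band = roi.values[j_ts : j_lmin + 1]
    band_mask = roi.mask[j_ts : j_lmin + 1]
    if not band_mask.any():
        raise UndefinedIndexError("no masked cells in the torso band")
    thr = band[band_mask].mean()
    seg = np.where(band_mask & (band >= thr), band, 0.0)
    mirrored = mirror_columns(seg, roi.geometry.i_sym)
    overlap = (seg > 0) & (mirrored > 0)
    n = int(overlap.sum())
    if n == 0:
        raise UndefinedIndexError("segmented imprint and its mirror do not overlap")
    tai = 100.0 * float(np.abs(1.0 - seg[overlap] / mirrored[overlap]).mean())
    return tai, n


def _offset_angle(p_l: tuple, p_r: tuple, what: str) -> tuple[float, float]:
    """(magnitude, signed) offset angle in degrees between two bilateral
    points; positive signed value = right point more caudal."""
    dj = p_r[0] - p_l[0]
    di = p_r[1] - p_l[1]
    if di == 0:
        raise UndefinedIndexError(f"{what}: bilateral points share a column")
    # orient by column so relabeling the sides flips the sign
    signed = math.degrees(math.atan(dj / di)) * (1.0 if di > 0 else -1.0)
    return abs(signed), signed


def compute_saa(P_s_l: tuple, P_s_r: tuple) -> float:
    """Shoulder asymmetry angle between the scapula centers (deg)."""
    return _offset_angle(P_s_l, P_s_r, "SAA")[0]


def compute_paa(P_p_l: tuple, P_p_r: tuple) -> float:
    """Pelvis asymmetry angle between the upper-pelvic-edge midpoints (deg)."""
    return _offset_angle(P_p_l, P_p_r, "PAA")[0]


def compute_waa(P_w_l: tuple, P_w_r: tuple) -> float:
    """Waist asymmetry angle between the waist apices (deg)."""
    return _offset_angle(P_w_l, P_w_r, "WAA")[0]


def compute_all(
    roi: ROIFrame,
    landmark_config: LandmarkConfig | None = None,
    index_config: IndexConfig | None = None,
) -> IndexSet:
    """Landmarks plus all six indices, with per-index failure records.

    A landmark failure disables only the indices that depend on it; the
    remaining indices are still computed (e.g. a frame without pelvic rows
    loses PAA but keeps the other five, with the COP column range falling
    back to the mask extent).
    """
    lcfg = landmark_config or LandmarkConfig()
    icfg = index_config or IndexConfig()
    out = IndexSet()
    pbar = mean_intensity_curve(roi)
    try:
        lm = detect_longitudinal_landmarks(pbar, lcfg)
    except LandmarkFailure as exc:
        out.failures = {name: str(exc) for name in INDEX_NAMES}
        return out
    out.diagnostics.update(
        j_ts=lm.j_ts, j_scap=lm.j_scap, j_tl=lm.j_tl, j_lmin=lm.j_lmin, j_sac=lm.j_sac
    )

    try:
        detect_pelvic_contour(roi, lm, lcfg)
        out.paa = compute_paa(lm.P_p_l, lm.P_p_r)
        out.diagnostics["paa_signed"] = _offset_angle(lm.P_p_l, lm.P_p_r, "PAA")[1]
        i_pl, i_pr = lm.i_pl, lm.i_pr
    except (LandmarkFailure, UndefinedIndexError) as exc:
        out.failures["paa"] = str(exc)
        cols = np.flatnonzero(roi.mask.any(axis=0))
        i_pl, i_pr = int(cols[0]), int(cols[-1])
    out.diagnostics["cop_range"] = (i_pl, i_pr)

    try:
        cop = compute_cop(roi, i_pl, i_pr)
        out.tba, apexes = compute_tba(cop, icfg)
        out.diagnostics["apex_count"] = len(apexes)
        out.diagnostics["apexes"] = [
            (a.j_apex, a.j_ipa, a.j_ipb, a.angle_deg) for a in apexes
        ]
    except UndefinedIndexError as exc:
        out.failures["tba"] = str(exc)

    try:
        out.sii = compute_sii(pbar, lm.omega_th, lm.omega_lu, lm.v_pbar)
    except UndefinedIndexError as exc:
        out.failures["sii"] = str(exc)

    try:
        out.tai, n_overlap = compute_tai(roi, lm.j_ts, lm.j_lmin)
        out.diagnostics["tai_overlap_cells"] = n_overlap
    except UndefinedIndexError as exc:
        out.failures["tai"] = str(exc)

    try:
        locate_scapulae(roi, lm, lcfg)
        out.saa = compute_saa(lm.P_s_l, lm.P_s_r)
        out.diagnostics["saa_signed"] = _offset_angle(lm.P_s_l, lm.P_s_r, "SAA")[1]
    except (LandmarkFailure, UndefinedIndexError) as exc:
        out.failures["saa"] = str(exc)

    try:
        locate_waist_apices(roi, lm, lcfg)
        out.waa = compute_waa(lm.P_w_l, lm.P_w_r)
        out.diagnostics["waa_signed"] = _offset_angle(lm.P_w_l, lm.P_w_r, "WAA")[1]
    except (LandmarkFailure, UndefinedIndexError) as exc:
        out.failures["waa"] = str(exc)

    out.diagnostics["landmarks"] = lm
    return out
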