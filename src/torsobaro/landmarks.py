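"""Anatomical landmark detection on the masked analysis frame.

The supine dorsal imprint has a reproducible longitudinal structure: the
scapulae produce a thoracic pressure peak, the lumbar lordosis a trough,
and the sacrum a caudal peak.  Longitudinal landmarks are extrema and
inflections of the row-wise mean pressure curve pbar(j); the pelvic
contour is traced with the Canny detector; scapula centers are bilateral
peaks in the thoracic rows; waist apices are the most medial points of the
adaptively segmented lateral flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.feature import canny

from .config import LandmarkConfig
from .errors import LandmarkFailure
from .preprocess import ROIFrame

__all__ = [
    "IntensityCurve",
    "LandmarkSet",
    "mean_intensity_curve",
    "detect_longitudinal_landmarks",
    "detect_pelvic_contour",
    "locate_scapulae",
    "locate_waist_apices",
    "detect_all",
]


@dataclass
class IntensityCurve:
    """A per-row scalar curve on the grid (mean pressure or COP)."""

    rows: np.ndarray
    values: np.ndarray
    kind: str = "mean_intensity"


@dataclass
class LandmarkSet:
    """All anatomical rows, points and regions used for index extraction.

    Rows are 0-based grid rows; points are (row, col) tuples with float
    sub-cell precision where refinement applies.  ``omega_th``/``omega_lu``
    are the thoracic and lumbar row ranges used by the sagittal imbalance
    index.
    """

    j_ts: int | None = None
    j_scap: int | None = None
    j_tl: int | None = None
    j_lmin: int | None = None
    j_sac: int | None = None
    omega_th: np.ndarray | None = None
    omega_lu: np.ndarray | None = None
    v_pbar: float | None = None
    i_pl: int | None = None
    i_pr: int | None = None
    P_s_l: tuple | None = None
    P_s_r: tuple | None = None
    P_w_l: tuple | None = None
    P_w_r: tuple | None = None
    P_p_l: tuple | None = None
    P_p_r: tuple | None = None
    diagnostics: dict = field(default_factory=dict)

    def check_ordering(self) -> None:
        rows = [self.j_ts, self.j_scap, self.j_tl, self.j_lmin, self.j_sac]
        if all(r is not None for r in rows) and not all(
            a < b for a, b in zip(rows, rows[1:])
        ):
            raise LandmarkFailure(
                "landmark rows out of anatomical order: "
                f"j_ts={self.j_ts} j_scap={self.j_scap} j_tl={self.j_tl} "
                f"j_lmin={self.j_lmin} j_sac={self.j_sac}"
            )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def mean_intensity_curve(roi: ROIFrame) -> IntensityCurve:
    """pbar(j): mean of the masked cells of each row (0 where none)."""
    counts = roi.mask.sum(axis=1)
    sums = roi.values.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pbar = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return IntensityCurve(rows=np.arange(len(pbar)), values=pbar, kind="mean_intensity")


def detect_longitudinal_landmarks(
    pbar: IntensityCurve, config: LandmarkConfig | None = None
) -> LandmarkSet:
    """Torso start, scapular/sacral maxima, lumbar minimum, thoracolumbar
    inflection and the thoracic/lumbar regions, from pbar(j)."""
    cfg = config or LandmarkConfig()
    v = np.asarray(pbar.values, dtype=float)
    support = v > 0
    if not support.any():
        raise LandmarkFailure("pbar(j) has no support")

    k = cfg.sustained_support_rows
    run = np.convolve(support.astype(int), np.ones(k, dtype=int), mode="valid")
    starts = np.flatnonzero(run == k)
    if len(starts) == 0:
        raise LandmarkFailure(f"no {k} consecutive supported rows")
    j_ts = int(starts[0])

    smooth = _moving_average(v, cfg.pbar_smooth_rows)
    prominence = cfg.peak_prominence_frac * smooth.max()
    peaks, _ = find_peaks(smooth, prominence=prominence, distance=cfg.peak_min_distance)
    if len(peaks) < 2:
        raise LandmarkFailure(
            f"found {len(peaks)} prominent maxima in pbar(j); need the scapular "
            "and sacral peaks (is the imprint complete?)"
        )
    j_scap = int(peaks[0])
    j_sac = int(peaks[-1])
    interior = smooth[j_scap + 1 : j_sac]
    j_lmin = int(j_scap + 1 + np.argmin(interior))
    v_pbar = float(v[j_ts : j_lmin + 1].min())

    # thoracolumbar junction: first convexity change of pbar between the
    # scapular peak and the lumbar minimum
    d2 = np.diff(smooth, 2)  # d2[m] ~ f''(m + 1)
    j_tl = None
    for j in range(j_scap + 1, j_lmin):
        m = j - 1
        if 0 <= m < len(d2) - 1 and d2[m] < 0 <= d2[m + 1]:
            j_tl = j + 1
            break
    fallback = j_tl is None
    if fallback:
        j_tl = (j_scap + j_lmin) // 2
    j_tl = int(min(max(j_tl, j_scap + 1), j_lmin - 1))

    lm = LandmarkSet(
        j_ts=j_ts,
        j_scap=j_scap,
        j_tl=j_tl,
        j_lmin=j_lmin,
        j_sac=j_sac,
        omega_th=np.arange(j_ts, j_tl),
        omega_lu=np.arange(j_tl, j_lmin + 1),
        v_pbar=v_pbar,
        diagnostics={"pbar_peaks": peaks.tolist(), "j_tl_fallback": fallback},
    )
    lm.check_ordering()
    return lm


def detect_pelvic_contour(
    roi: ROIFrame, lm: LandmarkSet, config: LandmarkConfig | None = None
) -> LandmarkSet:
    """Canny contour of the sacral/pelvic sub-image (rows >= j_lmin).

    Sets ``i_pl``/``i_pr`` (lateral contour extremes, the torso-width
    reference) and ``P_p_l``/``P_p_r`` (midpoints of the upper pelvic edge
    chains on each side of the symmetry axis).
    """
    cfg = config or LandmarkConfig()
    if lm.j_lmin is None or lm.j_sac is None:
        raise LandmarkFailure("pelvic detection requires j_lmin and j_sac")
    i_sym = roi.geometry.i_sym
    sub = roi.values[lm.j_lmin :, :]
    if sub.shape[0] < 5 or sub.max() <= 0:
        raise LandmarkFailure("no pelvic rows below the lumbar minimum")
    edges = canny(
        sub / sub.max(),
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low_quantile,
        high_threshold=cfg.canny_high_quantile,
        use_quantiles=True,
    )
    ej, ei = np.nonzero(edges)
    if len(ei) < 10:
        raise LandmarkFailure("pelvic contour too sparse for Canny detection")
    ej = ej + lm.j_lmin
    i_pl, i_pr = int(ei.min()), int(ei.max())
    if not (i_pl < i_sym < i_pr):
        raise LandmarkFailure(
            f"pelvic contour extremes ({i_pl}, {i_pr}) do not bracket i_sym"
        )

    # columns belonging to the sacral imprint, from the sacral-maximum row
    sac_row = roi.values[lm.j_sac]
    if sac_row.max() <= 0:
        raise LandmarkFailure("no pressure on the sacral-maximum row")
    sac_cols = np.flatnonzero(sac_row >= cfg.sacral_column_frac * sac_row.max())
    upper = (ej < lm.j_sac) & np.isin(ei, sac_cols)
    uj, ui = ej[upper], ei[upper]
    # per column, the edge pixel closest to the sacral maximum marks the
    # cranial boundary of the sacral imprint
    chain_j, chain_i = [], []
    for col in np.unique(ui):
        rows = uj[ui == col]
        chain_j.append(rows.max())
        chain_i.append(col)
    chain_j = np.array(chain_j, dtype=float)
    chain_i = np.array(chain_i, dtype=float)
    # stray edge pixels from lateral structures occasionally survive the
    # column restriction; trim rows far from the chain median
    keep = np.abs(chain_j - np.median(chain_j)) <= 5
    chain_j, chain_i = chain_j[keep], chain_i[keep]
    # split the halves about the sacral pressure centroid, not i_sym: with a
    # bent thorax the centered imprint leaves the pelvis slightly off-axis
    sac_center = float((sac_row[sac_cols] * sac_cols).sum() / sac_row[sac_cols].sum())
    left = chain_i < sac_center
    right = chain_i > sac_center
    if left.sum() < 3 or right.sum() < 3:
        raise LandmarkFailure("upper pelvic edge incomplete on one side")
    lm.i_pl, lm.i_pr = i_pl, i_pr
    lm.P_p_l = (float(chain_j[left].mean()), float(chain_i[left].mean()))
    lm.P_p_r = (float(chain_j[right].mean()), float(chain_i[right].mean()))
    lm.diagnostics["pelvic_edge_pixels"] = int(len(ei))
    return lm


def locate_scapulae(
    roi: ROIFrame, lm: LandmarkSet, config: LandmarkConfig | None = None
) -> tuple[tuple, tuple]:
    """Bilateral scapular pressure peaks in the thoracic rows [j_ts, j_tl).

    Each side's highest strict local maximum is refined to the
    pressure-weighted centroid of its 3x3 neighborhood.
    """
    if lm.j_ts is None or lm.j_tl is None:
        raise LandmarkFailure("scapula search requires the thoracic region")
    i_sym = roi.geometry.i_sym
    values = roi.values
    points = []
    for side, cols in (("left", slice(0, i_sym)), ("right", slice(i_sym + 1, None))):
        band = values[lm.j_ts : lm.j_tl, cols]
        if band.size == 0 or band.max() <= 0:
            raise LandmarkFailure(f"no {side} scapular peak in the thoracic region")
        r, c = np.unravel_index(np.argmax(band), band.shape)
        j = int(r + lm.j_ts)
        i = int(c + (0 if side == "left" else i_sym + 1))
        patch = values[max(j - 1, 0) : j + 2, max(i - 1, 0) : i + 2]
        if patch.shape != (3, 3) or values[j, i] < patch.max():
            raise LandmarkFailure(f"no {side} scapular peak: maximum is not interior")
        # scapular peaks are broad domes; refine the center as the centroid
        # of the near-peak cap (robust sub-cell precision on flat peaks)
        j0, j1 = max(j - 6, 0), j + 7
        i0, i1 = max(i - 6, 0), i + 7
        cap = values[j0:j1, i0:i1] - 0.97 * values[j, i]
        cap = np.clip(cap, 0.0, None)
        jj, ii = np.mgrid[j0:j1, i0:i1]
        w = cap.sum()
        points.append((float((jj * cap).sum() / w), float((ii * cap).sum() / w)))
    lm.P_s_l, lm.P_s_r = points
    return lm.P_s_l, lm.P_s_r


def _boundary_apex(rows: np.ndarray, boundary: np.ndarray, medial_is_max: bool) -> tuple:
    """Most medial point of an integer flank-boundary curve.

    Integer boundaries plateau around the true apex, so the apex row is the
    center of the first contiguous plateau of most-medial columns (half-cell
    tolerance), with the half-row case resolved toward the smaller row.
    """
    b = boundary if medial_is_max else -boundary
    extreme = b.max()
    at = b >= extreme - 0.5
    k0 = int(np.argmax(at))  # first row achieving the extreme
    k1 = k0
    while k1 + 1 < len(at) and at[k1 + 1]:
        k1 += 1
    row = int(math.floor((rows[k0] + rows[k1]) / 2.0 + 0.5 - 1e-9))
    k_mid = int(np.flatnonzero(rows == row)[0])
    return (row, int(boundary[k_mid]))


def locate_waist_apices(
    roi: ROIFrame, lm: LandmarkSet, config: LandmarkConfig | None = None
) -> tuple[tuple, tuple]:
    """Waist apices: the most medial lateral-boundary point per side.

    The flank boundary is taken per row from an adaptive segmentation at
    ``waist_threshold_frac`` of the mean masked pressure; the apex is the
    row in (j_scap, j_sac) where the boundary is most medial, ties broken
    toward the smaller row.
    """
    cfg = config or LandmarkConfig()
    if lm.j_scap is None or lm.j_sac is None:
        raise LandmarkFailure("waist search requires j_scap and j_sac")
    thr = cfg.waist_threshold_frac * roi.masked_values().mean()
    rows = np.arange(lm.j_scap + 1, lm.j_sac)
    lb = np.full(len(rows), np.nan)
    rb = np.full(len(rows), np.nan)
    for k, j in enumerate(rows):
        cols = np.flatnonzero((roi.values[j] >= thr) & roi.mask[j])
        if len(cols):
            lb[k], rb[k] = cols[0], cols[-1]
    valid = ~np.isnan(lb)
    if valid.sum() < 5:
        raise LandmarkFailure("waist contour undefined: too few segmented rows")
    lbv, rbv, rv = lb[valid], rb[valid], rows[valid]
    if np.ptp(lbv) < 1 or np.ptp(rbv) < 1:
        raise LandmarkFailure("no medial extremum: flanks are straight")
    lm.P_w_l = _boundary_apex(rv, lbv, medial_is_max=True)
    lm.P_w_r = _boundary_apex(rv, rbv, medial_is_max=False)
    lm.diagnostics["waist_threshold"] = float(thr)
    return lm.P_w_l, lm.P_w_r


def detect_all(roi: ROIFrame, config: LandmarkConfig | None = None) -> LandmarkSet:
    """Run every detector; partial failures raise from the failing stage."""
    cfg = config or LandmarkConfig()
    lm = detect_longitudinal_landmarks(mean_intensity_curve(roi), cfg)
    detect_pelvic_contour(roi, lm, cfg)
    locate_scapulae(roi, lm, cfg)
    locate_waist_apices(roi, lm, cfg)
    lm.check_ordering()
    return lm
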