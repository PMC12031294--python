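"""Synthetic supine-torso pressure phantoms with known ground truth.

The generator emulates the morphology of a dorsal pressure imprint on the
160 x 100 mat: a waist-narrowed lateral envelope, bilateral scapular
pressure peaks, a thoracic ridge following the spine midline, a lumbar
low-pressure trough, a prominent (optionally oblique) sacral imprint, an
optional unilateral hump, plus the acquisition artifacts the preprocessing
stage must reject — multiplicative breathing modulation, motion-spike
frames and clothing-fold speckle.

Deformities are parameterized so that every index has a well-posed ground
truth: the spine midline deviates laterally by a Gaussian bump whose
inter-tangent angle at its two inflection rows equals ``bend_angle_deg``
(matching the TBA definition); scapula centers, waist-dip rows and pelvic
obliquity are programmed directly.  Ground-truth waist apices are computed
from the generated clean frame with the same adaptive-threshold boundary
definition the landmark stage uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .config import LandmarkConfig
from .errors import PhantomParameterError, ValidationError
from .frame_io import PressureFrame, PressureRecording, grid_geometry

__all__ = ["PhantomParams", "GroundTruth", "CohortSpec", "generate_phantom", "generate_cohort"]

# relative component amplitudes (scaled by PhantomParams.amplitude_scale)
_ENV_AMP = 0.55
_SCAP_AMP = 0.75
_RIDGE_AMP = 0.35
_SACRUM_AMP = 0.60
_LUMBAR_DIP = 0.30
_FOLD_AMP = 800.0


@dataclass
class PhantomParams:
    """Ground-truth deformity and acquisition parameters.

    All asymmetry amplitudes are >= 0 with separate sign/side switches;
    ``seed`` fully determines the generated recording.
    """

    bend_angle_deg: float = 0.0      # frontal spinal bend, 0..40
    bend_direction: int = 1          # +1: apex deviates to larger i
    apex_row: int = 56               # row of the frontal-curve apex
    bend_sigma_rows: float = 18.0    # scale of the lateral-deviation bump
    shoulder_offset_rows: float = 0.0  # j(right scapula) - j(left scapula)
    waist_offset_rows: float = 0.0     # right minus left waist-dip row
    pelvic_obliquity_deg: float = 0.0  # coronal pelvis tilt (signed)
    hump_amplitude: float = 0.0        # unilateral hump, relative amplitude
    hump_side: int = -1                # -1: left of the spine, +1: right
    thoracic_lumbar_balance: float = 1.0  # scales the thoracic ridge
    torso_start_row: int = 18
    torso_length_rows: int = 112
    torso_width_cols: int = 52
    waist_depth_cols: float = 6.0
    waist_sigma_rows: float = 10.0
    amplitude_scale: float = 4000.0
    noise_sd: float = 25.0
    n_fold_artifacts: int = 3
    breathing_depth: float = 0.08
    n_motion_spikes: int = 2
    n_frames: int = 100
    seed: int = 0

    def validate(self) -> None:
        g = grid_geometry()
        half = self.torso_width_cols / 2
        amp = _bend_amplitude(self.bend_angle_deg, self.bend_sigma_rows)
        j_end = self.torso_start_row + self.torso_length_rows
        if self.torso_start_row < 5 or j_end > g.n_rows - 5:
            raise PhantomParameterError(
                f"torso rows [{self.torso_start_row}, {j_end}] leave < 5-row margins"
            )
        if amp + 1.25 * half > g.i_sym - 5:
            raise PhantomParameterError(
                f"torso width {self.torso_width_cols} with bend amplitude "
                f"{amp:.1f} cols exceeds the lateral margins"
            )
        for name in ("bend_angle_deg", "hump_amplitude", "waist_depth_cols",
                     "noise_sd", "breathing_depth", "amplitude_scale"):
            if getattr(self, name) < 0:
                raise PhantomParameterError(f"{name} must be >= 0")
        if not 0 <= self.bend_angle_deg <= 40:
            raise PhantomParameterError("bend_angle_deg must be in [0, 40]")
        if self.bend_angle_deg > 0:
            rows = _key_rows(self)
            lo = rows["scap"] + 16
            hi = rows["lumbar"] - 26
            if not lo <= self.apex_row <= hi:
                raise PhantomParameterError(
                    f"apex_row {self.apex_row} outside [{lo}, {hi}]: the bend's "
                    "inflection rows must clear the scapular and pelvic regions"
                )


@dataclass
class GroundTruth:
    """Expected landmark positions and implied index values of a phantom."""

    j_ts: int
    j_scap: float
    j_lmin: int
    j_sac: int
    scap_left: tuple
    scap_right: tuple
    waist_left: tuple
    waist_right: tuple
    tba_deg: float
    saa_deg: float
    waa_deg: float
    paa_deg: float
    params: PhantomParams


def _bend_amplitude(angle_deg: float, sigma: float) -> float:
    """Lateral-deviation amplitude whose Gaussian bump has inter-tangent
    angle ``angle_deg`` at its inflection rows (x = +/- sigma)."""
    return sigma * math.exp(0.5) * math.tan(math.radians(angle_deg) / 2.0)


def _key_rows(p: PhantomParams) -> dict:
    L = p.torso_length_rows
    ts = p.torso_start_row
    return {
        "scap": ts + round(0.16 * L),
        "hump": ts + round(0.52 * L),
        "lumbar": ts + round(0.60 * L),
        "waist": ts + round(0.63 * L),
        "sacrum": ts + round(0.81 * L),
        "end": ts + L,
    }


def _base_frame(p: PhantomParams) -> np.ndarray:
    """Clean relative-pressure imprint (before scale, artifacts, noise)."""
    g = grid_geometry()
    rows = _key_rows(p)
    j = np.arange(g.n_rows, dtype=float)[:, None]
    i = np.arange(g.n_cols, dtype=float)[None, :]

    amp = _bend_amplitude(p.bend_angle_deg, p.bend_sigma_rows) * p.bend_direction
    dev = amp * np.exp(-((j - p.apex_row) ** 2) / (2 * p.bend_sigma_rows**2))
    # the pelvis is rigid and anchors the spine: the lateral deviation fades
    # out caudal of the lumbar region (leaves the apex/inflection rows of
    # the bend untouched, so the programmed angle stays well defined)
    dev = dev * 0.5 * (1 - np.tanh((j - (rows["lumbar"] + 10)) / 4.0))
    c = g.i_sym + dev  # spine midline column per row

    half = p.torso_width_cols / 2
    # pelvic flare: the hip imprint is the widest structure, so the pelvic
    # contour brackets the whole (bend-shifted) torso in the COP column range
    flare = 6.0 * 0.5 * (1 + np.tanh((j - (rows["sacrum"] - 12)) / 5.0))
    w_l = half + flare - p.waist_depth_cols * np.exp(
        -((j - rows["waist"]) ** 2) / (2 * p.waist_sigma_rows**2)
    )
    w_r = half + flare - p.waist_depth_cols * np.exp(
        -((j - (rows["waist"] + p.waist_offset_rows)) ** 2) / (2 * p.waist_sigma_rows**2)
    )
    x = i - c
    width = np.where(x < 0, w_l, w_r)
    env_lat = np.exp(-((x / width) ** 4))
    taper = 0.5 * (1 + np.tanh((j - p.torso_start_row - 2) / 1.5)) * 0.5 * (
        1 - np.tanh((j - rows["end"] + 2) / 1.5)
    )
    env_long = taper * (
        1 - _LUMBAR_DIP * np.exp(-((j - rows["lumbar"]) ** 2) / (2 * 9.0**2))
    )
    frame = _ENV_AMP * env_long * env_lat

    ridge_long = np.where(
        j <= rows["scap"] + 20,
        1.0,
        np.exp(-((j - rows["scap"] - 20) ** 2) / (2 * 15.0**2)),
    )
    frame += (
        _RIDGE_AMP
        * p.thoracic_lumbar_balance
        * taper
        * ridge_long
        * np.exp(-0.5 * (x / 5.0) ** 2)
    )

    # scapulae, sacrum and hump all ride on the local spine midline c(j), so
    # each row's cross-section is symmetric about c(j) for a bend-only
    # phantom and the COP curve equals the programmed midline exactly
    j_sl = rows["scap"] - p.shoulder_offset_rows / 2.0
    j_sr = rows["scap"] + p.shoulder_offset_rows / 2.0
    i_sl = float(g.i_sym + dev[int(round(j_sl)), 0] - 17.0)
    i_sr = float(g.i_sym + dev[int(round(j_sr)), 0] + 17.0)
    for js, side in ((j_sl, -1.0), (j_sr, +1.0)):
        frame += _SCAP_AMP * np.exp(
            -0.5 * ((j - js) / 9.0) ** 2 - 0.5 * ((x - side * 17.0) / 7.0) ** 2
        )

    # the pelvis is rigid: the sacral imprint sits at one column (the
    # midline at the sacral row), not bent along the spine curve
    x_sac = i - (g.i_sym + dev[rows["sacrum"], 0])
    tilt = math.tan(math.radians(p.pelvic_obliquity_deg))
    dj_sac = j - (rows["sacrum"] + tilt * x_sac)
    frame += _SACRUM_AMP * np.exp(-((dj_sac / 8.0) ** 4) - ((x_sac / 15.0) ** 4))

    if p.hump_amplitude > 0:
        frame += p.hump_amplitude * np.exp(
            -0.5 * ((j - rows["hump"]) / 10.0) ** 2
            - 0.5 * ((x - p.hump_side * 11.0) / 8.0) ** 2
        )
    frame = frame * p.amplitude_scale
    # truncate the far envelope tails so the imprint keeps hard lateral
    # margins (the even grid's unpaired border column stays empty)
    frame[frame < 0.0025 * p.amplitude_scale] = 0.0
    return frame, (j_sl, i_sl, j_sr, i_sr)


def _waist_ground_truth(base: np.ndarray, p: PhantomParams) -> tuple[tuple, tuple]:
    """Waist apices of the clean frame, via the adaptive-boundary definition."""
    rows = _key_rows(p)
    cfg = LandmarkConfig()
    from .preprocess import denoise

    base = denoise(base)  # the apices of the imprint as observed after filtering
    support = base >= 0.05 * base.max()
    thr = cfg.waist_threshold_frac * base[support].mean()
    jr = np.arange(rows["scap"] + 1, rows["sacrum"])
    lb = np.full(len(jr), np.nan)
    rb = np.full(len(jr), np.nan)
    for k, jj in enumerate(jr):
        cols = np.flatnonzero((base[jj] >= thr) & support[jj])
        if len(cols):
            lb[k], rb[k] = cols[0], cols[-1]
    valid = ~np.isnan(lb)
    lbv, rbv, jv = lb[valid], rb[valid], jr[valid]
    from .landmarks import _boundary_apex

    return (
        _boundary_apex(jv, lbv, medial_is_max=True),
        _boundary_apex(jv, rbv, medial_is_max=False),
    )


def _refine_peak(base: np.ndarray, j0: int, i0: int) -> tuple:
    """Centroid of the near-peak cap around (j0, i0) on the clean frame; the
    field maximum sits slightly medial of the programmed blob center because
    the envelope background slopes toward the midline."""
    win = base[j0 - 8 : j0 + 9, i0 - 8 : i0 + 9]
    r, c = np.unravel_index(np.argmax(win), win.shape)
    j, i = j0 - 8 + r, i0 - 8 + c
    cap = np.clip(base[j - 6 : j + 7, i - 6 : i + 7] - 0.97 * base[j, i], 0.0, None)
    jj, ii = np.mgrid[j - 6 : j + 7, i - 6 : i + 7]
    return float((jj * cap).sum() / cap.sum()), float((ii * cap).sum() / cap.sum())


def _ground_truth(base: np.ndarray, scap_pts, p: PhantomParams) -> GroundTruth:
    rows = _key_rows(p)
    j_sl, i_sl, j_sr, i_sr = scap_pts
    (j_sl, i_sl) = _refine_peak(base, int(round(j_sl)), int(round(i_sl)))
    (j_sr, i_sr) = _refine_peak(base, int(round(j_sr)), int(round(i_sr)))
    support = base.max(axis=1) >= 0.05 * base.max()
    j_ts = int(np.flatnonzero(support)[0])
    saa = math.degrees(math.atan((j_sr - j_sl) / (i_sr - i_sl)))
    wl, wr = _waist_ground_truth(base, p)
    waa = math.degrees(math.atan((wr[0] - wl[0]) / (wr[1] - wl[1])))
    return GroundTruth(
        j_ts=j_ts,
        j_scap=(j_sl + j_sr) / 2.0,
        j_lmin=rows["lumbar"],
        j_sac=rows["sacrum"],
        scap_left=(j_sl, i_sl),
        scap_right=(j_sr, i_sr),
        waist_left=wl,
        waist_right=wr,
        tba_deg=p.bend_angle_deg,
        saa_deg=abs(saa),
        waa_deg=abs(waa),
        paa_deg=abs(p.pelvic_obliquity_deg),
        params=p,
    )


def generate_phantom(params: PhantomParams) -> tuple[PressureRecording, GroundTruth]:
    """Generate a recording (``params.n_frames`` frames at 10 Hz) plus its
    ground truth.  Bit-identical for identical params (including seed)."""
    params.validate()
    g = grid_geometry()
    rng = np.random.default_rng(params.seed)
    base, scap_pts = _base_frame(params)
    gt = _ground_truth(base, scap_pts, params)

    fold_img = np.zeros_like(base)
    if params.n_fold_artifacts > 0:
        torso_rows = np.flatnonzero(base.max(axis=1) > 0.1 * base.max())
        for _ in range(params.n_fold_artifacts):
            r = int(rng.integers(torso_rows[0], torso_rows[-1] - 1))
            cc = int(rng.integers(g.i_sym - 20, g.i_sym + 20))
            fold_img[r : r + 2, cc : cc + 2] += _FOLD_AMP

    n = params.n_frames
    spike_frames = set()
    if params.n_motion_spikes > 0 and n > 1:
        k = min(params.n_motion_spikes, n - 1)
        spike_frames = set(int(s) for s in rng.choice(np.arange(1, n), size=k, replace=False))
    spike_shifts = {s: int(rng.choice([-2, 2])) for s in sorted(spike_frames)}

    frames = []
    for k in range(n):
        breath = 1.0 + params.breathing_depth * math.sin(2 * math.pi * 0.25 * k / 10.0)
        f = base * breath + fold_img
        if k in spike_shifts:
            f = np.roll(f, spike_shifts[k], axis=0) * 1.25
        if params.noise_sd > 0:
            f = f + rng.normal(0.0, params.noise_sd, f.shape)
        vals = np.clip(np.rint(f), g.value_min, g.value_max).astype(np.int32)
        frames.append(PressureFrame(values=vals, geometry=g))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # incomplete-recording warning for n < 100
        rec = PressureRecording(frames=frames, subject_meta={"phantom_seed": params.seed})
    return rec, gt


@dataclass
class CohortSpec:
    """A simulated screening cohort with Cobb-coupled deformity parameters.

    Group sizes and Cobb distributions default to the clinical severity
    structure (no/mild/moderate scoliosis, Cobb truncated to [0,10), [10,20)
    and [20,40) degrees).  Coupling slopes map Cobb to phantom parameters;
    a null cohort (all slopes zero) makes every index exchangeable across
    groups.  Supine imaging underestimates the standing curvature, hence the
    default bend slope of 0.75 deg of imprint bend per deg of Cobb.
    """

    group_sizes: tuple = (13, 49, 25)
    cobb_mean: tuple = (7.1, 14.0, 26.2)
    cobb_sd: tuple = (1.9, 2.9, 6.0)
    cobb_bounds: tuple = ((0.0, 10.0), (10.0, 20.0), (20.0, 40.0))
    bend_slope: float = 0.75       # deg imprint bend per deg Cobb
    waist_slope: float = 0.30      # waist-dip row offset per deg Cobb
    hump_slope: float = 0.012      # relative hump amplitude per deg Cobb
    bend_jitter: float = 1.2       # inter-subject sd around the coupling (deg)
    waist_jitter: float = 1.2      # (rows)
    hump_jitter: float = 0.06      # (relative amplitude)
    shoulder_sd: float = 1.5       # uncoupled shoulder-offset sd (rows)
    obliquity_sd: float = 1.2      # uncoupled pelvic-obliquity sd (deg)
    noise_sd: float = 25.0
    n_frames: int = 100
    seed: int = 0

    def null(self) -> "CohortSpec":
        """Copy with all Cobb couplings removed (type-I-error conditions)."""
        return replace(self, bend_slope=0.0, waist_slope=0.0, hump_slope=0.0)


_SEVERITIES = ("none", "mild", "moderate")


def generate_cohort(spec: CohortSpec) -> list:
    """List of (PressureRecording, cobb_angle_deg, severity, GroundTruth)."""
    if any(n <= 0 for n in spec.group_sizes):
        raise ValidationError("every severity group must be non-empty")
    rng = np.random.default_rng(spec.seed)
    out = []
    for g_idx, n in enumerate(spec.group_sizes):
        mu, sd = spec.cobb_mean[g_idx], spec.cobb_sd[g_idx]
        lo, hi = spec.cobb_bounds[g_idx]
        a, b = (lo - mu) / sd, (hi - 1e-6 - mu) / sd
        cobbs = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        for cobb in cobbs:
            bend = float(np.clip(spec.bend_slope * cobb + rng.normal(0, spec.bend_jitter), 0, 38))
            waist = spec.waist_slope * cobb + rng.normal(0, spec.waist_jitter)
            waist *= rng.choice([-1.0, 1.0])
            hump = float(max(0.0, spec.hump_slope * cobb + rng.normal(0, spec.hump_jitter)))
            ts = int(rng.integers(16, 21))
            length = int(rng.integers(108, 117))
            apex_lo = ts + round(0.16 * length) + 16
            apex_hi = ts + round(0.60 * length) - 26
            params = PhantomParams(
                bend_angle_deg=bend,
                bend_direction=int(rng.choice([-1, 1])),
                apex_row=int(rng.integers(apex_lo, apex_hi + 1)),
                shoulder_offset_rows=float(rng.normal(0, spec.shoulder_sd)),
                waist_offset_rows=float(waist),
                pelvic_obliquity_deg=float(rng.normal(0, spec.obliquity_sd)),
                hump_amplitude=min(hump, 0.6),
                hump_side=int(rng.choice([-1, 1])),
                torso_start_row=ts,
                torso_length_rows=length,
                torso_width_cols=int(rng.integers(50, 55)),
                noise_sd=spec.noise_sd,
                breathing_depth=float(rng.uniform(0.04, 0.12)),
                n_fold_artifacts=int(rng.integers(0, 4)),
                n_motion_spikes=int(rng.integers(0, 3)) if spec.n_frames > 4 else 0,
                n_frames=spec.n_frames,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, gt = generate_phantom(params)
            severity = _SEVERITIES[g_idx]
            rec.subject_meta = {"cobb_angle_deg": float(cobb), "severity": severity}
            out.append((rec, float(cobb), severity, gt))
    return out
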