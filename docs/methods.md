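# Methods

This note documents the models, algorithms and numerical choices behind
`torsobaro`, and what the synthetic phantom does and does not emulate.

## Measurement model

A recording is a 10 s, 10 Hz series of 160 × 100 grids of relative pressure
integers in [0, 12000] from a capacitive mat (50.8 cm × 81.2 cm; the
transverse pitch 50.8 cm/100 = 5.08 mm matches the longitudinal pitch
81.2 cm/160 = 5.075 mm within 0.01 mm, so slopes in columns-per-row are
treated as dimensionless). Rows run cranial → caudal; the mat symmetry
axis is column `i_sym = 49` (0-based). On the even 100-column grid the
mirror map i → 2·i_sym − i leaves one border column unpaired; imprints are
required to keep a lateral margin, and mirror-based quantities tolerate
the ±1-column parity ambiguity.

Recordings with fewer than the nominal 100 frames are accepted with a
warning — every stage is defined for ≥ 1 frame — and an empty recording is
an error. Physical calibration to kPa is out of scope; every index is a
ratio or an angle and is invariant under global pressure scaling.

## Preprocessing

1. **Median-frame selection** rejects breathing and motion artifacts: the
   frame whose whole-grid mean pressure is the *lower median* (sorted rank
   ⌈n/2⌉) of all frame means. The lower median is deterministic, defined
   for even counts, and always an actually recorded frame.
2. **Filtering**: a 3 × 3 median filter (removes single-cell clothing-fold
   speckle) followed by Gaussian smoothing with σ = 1 cell (gives the
   continuous surface the landmark detectors assume). Both settings are
   configurable and logged in the provenance record.
3. **Centering**: the frame is shifted by an integer column count so the
   pressure-weighted column centroid lands within 0.5 columns of `i_sym`.
   Integer shifts keep values bit-faithful; no interpolation.
4. **Masking**: support is thresholded at 5% of the frame maximum; the
   8-connected component containing the global pressure maximum is the
   torso, everything else (arms, head, mat folds — components that do not
   contain the maximum) is zeroed. A torso below 800 cells (≈ 20 cm²) is
   rejected as "no torso imprint". After masking, the centroid is
   re-centered once more, since removing satellites can move it.

Thresholds are this package's choices; the acquisition literature states
the steps but not the constants. All are exposed under `PreprocessConfig`.

## Landmarks

*Longitudinal* landmarks come from the mean-pressure curve p̄(j) (mean of
masked cells per row): the torso start `j_ts` (first run of 3 supported
rows), the scapular maximum `j_scap` (first prominent peak), the sacral
maximum `j_sac` (last prominent peak), the lumbar minimum `j_lmin`
(minimum between them), and the thoracolumbar inflection `j_tl` (first
convexity change of the 5-row-smoothed curve after `j_scap`; midpoint
fallback, flagged in diagnostics, if discretization hides the sign
change). Peaks must exceed 10% of the curve maximum in prominence over a
5-row neighborhood. Ω_th = [j_ts, j_tl), Ω_lu = [j_tl, j_lmin], and the
sagittal reference v_p̄ = min p̄ over [j_ts, j_lmin] — this choice makes
both SII sums non-negative; the reference level is otherwise
under-determined. The ordering j_ts < j_scap < j_tl < j_lmin < j_sac is
asserted on every successful detection.

*Pelvic contour*: Canny edges (σ = 1, hysteresis at the 0.5/0.8 gradient
quantiles) of the sub-image below `j_lmin`. The lateral extremes of the
contour give the pelvic edges `i_pl`, `i_pr` — the torso-width reference
for the COP curve. The upper pelvic edge is, per column of the sacral
imprint (columns where the `j_sac` row exceeds half its maximum), the edge
pixel closest to the sacral maximum from above; rows further than 5 from
the chain median are discarded as strays. The chains are split left/right
at the sacral pressure centroid rather than `i_sym`, because a bent thorax
leaves the centered pelvis slightly off-axis; the per-side chain midpoints
are `P_p_l`, `P_p_r`.

*Scapulae*: the highest interior maximum per half-plane within
[j_ts, j_tl). Scapular imprints are broad domes, so the center is refined
to the centroid of the near-peak cap (cells within 3% of the peak over a
13 × 13 window) — a plain 3 × 3 centroid quantizes to the grid on flat
peaks and would alias SAA into ≈ 1.7° steps.

*Waist apices*: per row between `j_scap` and `j_sac`, the flank boundary
is the outermost cell above `waist_threshold_frac` (default 0.5) of the
mean masked pressure. The full mean — the natural first choice — sits
above the envelope amplitude at the waist rows whenever the lumbar trough
is pronounced, leaving no flank there at all; half the mean tracks the
envelope robustly. The apex is the most medial boundary point; since
integer boundaries plateau around the optimum, the apex row is the center
of the first most-medial plateau (half-row ties resolved toward the
smaller row).

## Indices

**COP curve**: COP(j) = Σ i·I(j,i)/Σ I(j,i) over i ∈ [i_pl, i_pr]; rows
with zero pressure are omitted, and rows carrying less than 10% of the
heaviest row's pressure are dropped before differentiation (taper rows
whose COP is dominated by mask quantization). If the pelvic contour fails,
the COP range falls back to the mask's column extent and only PAA is
reported failed.

**TBA**: the COP curve is smoothed with a 7-row moving average; extrema
need a prominence of 0.2 columns; inflections are sign changes of the
central second difference, itself smoothed over 9 rows (mask-quantization
ripple otherwise produces spurious crossings of the same magnitude as a
small bend's curvature, ~0.005 columns/row²); sign is carried through
exact zeros, and crossings within 4 rows of the curve ends are ignored
(moving-average edge distortion). Apexes whose flanking inflections are
closer than 10 rows are rejected: a genuine spinal curve spans tens of
rows, while local pressure structures (an offset scapula) produce kinks an
order of magnitude narrower. Tangent slopes are central differences at the
inflection rows; the apex angle is |arctan s_above − arctan s_below|, and
TBA is the maximum over apexes — 0 if the frontal curve has no interior
extremum (a straight spine is a value, not an error).

**SII** = 100 × Σ_th(p̄ − v_p̄)/Σ_lu(p̄ − v_p̄), in percent; a
non-positive denominator raises an undefined-index error rather than
returning a silent NaN.

**TAI**: rows [j_ts, j_lmin] only (the heavy sacral imprint would dominate
the mirror comparison); cells at or above the band's mean masked pressure
are segmented; TAI = 100 × mean |1 − I/I*| over all cells whose mirror
partner is also segmented. Both members of each mirrored pair contribute
(the normalization counts overlap cells), which fixes the scale of the
index; counting pairs once would halve every value without changing any
ordering. The overlap count is reported in the diagnostics.

**SAA / WAA / PAA**: |arctan(Δrow/Δcolumn)| between the bilateral point
pairs, reported as magnitudes (group means of magnitudes are what the
clinical tables use); the signed angle — positive when the right-side
point is more caudal — is kept in diagnostics for laterality.

`compute_all` aggregates per-index failures: a landmark failure disables
only its dependent indices.

## Statistics

Subjects are clustered by Cobb angle: none < 10° ≤ mild < 20° ≤ moderate
< 40°; ≥ 40° (severe, treated surgically) is outside the studied range and
rejected. Per index: tie-corrected Kruskal–Wallis H with the χ²(k−1)
reference; the six omnibus p-values form one Bonferroni–Holm family.
Indices with adjusted p < 0.05 get Dunn pairwise z-tests (pooled midranks,
tie-corrected variance), Holm-adjusted as a three-pair family, with rank
effect sizes ES = z/√N where N is the size of the two compared groups —
the Dunn z is a pairwise statistic, so the pairwise N is the coherent
choice. ES bands follow Cohen in ascending form (small [0.1, 0.3), medium
[0.3, 0.5), large ≥ 0.5) applied to |ES|. Spearman ρ of each index against
the Cobb angle uses midranks and the two-sided t approximation, with the
clinical bands poor < 0.3 ≤ moderate < 0.6 ≤ good < 0.8 ≤ strong on |ρ|.
All tests are two-sided; at cohort scale (n ≈ 87) the large-sample
approximations are adequate and exact permutation is unnecessary. The rank
statistics are implemented directly (they are part of the reported method)
and are cross-checked in the tests against scipy, statsmodels and an
independently coded Dunn formula to 1e−10 on randomized tied data.

The analysis is invariant to subject ordering, and reports with failed or
undefined index values exclude those subjects pairwise with a logged count.

## Synthetic phantom

The generator emulates the morphology of a supine dorsal imprint: a
super-Gaussian lateral envelope with waist narrowing and pelvic flare (the
hip imprint is the widest structure, so the pelvic contour brackets the
whole torso), bilateral scapular domes, a thoracic ridge along the spine
midline, a lumbar pressure trough, a prominent sacral imprint, and
acquisition artifacts: multiplicative breathing at 0.25 Hz (≈ 15
breaths/min, plausible at rest; default depth 8%), motion-spike frames
(±2-row shift with 25% amplification — which median-frame selection must
reject), static 2 × 2 clothing-fold speckle (+800 units, removed by the
median filter), and white sensor noise (sd 25 on a ≈ 4000-unit imprint).
Peak amplitude ≈ 4000 of 12000 so filtering and breathing never saturate
the range.

Deformities are constructed so each index has a well-posed ground truth:

- the **frontal bend** is a Gaussian lateral deviation of the midline,
  amplitude A = σ·e^½·tan(θ/2) with σ = 18 rows, so the inter-tangent
  angle at its two inflection rows is exactly the programmed θ — the same
  definition TBA measures. A Gaussian bump was preferred over a spline
  midline because its inflections and tangents are closed-form. The
  deviation fades out caudal of the lumbar region (the pelvis is rigid and
  anchors the spine), and the apex row is constrained to keep both
  inflection rows clear of the scapular and pelvic structures;
- every cross-section (envelope, ridge, scapulae, hump) is centered on the
  local midline c(j), so the COP curve of a bend-only phantom equals the
  programmed midline exactly; the sacrum sits at a single column (rigid
  pelvis);
- **shoulder and waist offsets** displace the scapular dome rows and the
  per-side waist-dip rows; **pelvic obliquity** tilts the sacral imprint's
  row center linearly across columns, so the upper-edge midpoint angle
  equals the programmed tilt by symmetry;
- ground-truth scapula centers and waist apices are extracted numerically
  from the clean frame (field peak refinement; the same boundary
  definition the detector uses, after the nominal observation filter),
  because the exact optimum shifts slightly on the sloped envelope
  background — the ground truth is a property of the clean imprint, while
  the pipeline must recover it through noise, breathing, frame selection,
  filtering, centering and masking.

A unilateral hump both raises TAI and curves the COP line — deliberately,
as vertebral rotation does in real scoliosis — so TBA and TAI are
correlated under coupling, as in clinical data.

**Cohorts** sample Cobb angles from truncated normals per severity group
(defaults 13/49/25 subjects; means 7.1/14.0/26.2°, sd 1.9/2.9/6.0°,
truncated to [0,10), [10,20), [20,40)) and couple deformities to Cobb:
bend = 0.75°/° (supine imaging underestimates the standing curvature),
waist offset = 0.30 rows/°, hump amplitude = 0.012/° (capped at 0.6),
each with inter-subject jitter; shoulder offset (sd 1.5 rows) and pelvic
obliquity (sd 1.2°) are *uncoupled*, matching the clinical finding that
SAA and PAA do not separate severities. Torso geometry varies per subject.
The coupling slopes were sized by a design power analysis so a 49-vs-25
contrast is detectable through the rank cascade. `CohortSpec.null()`
removes all couplings, making every index exchangeable across groups — the
type-I-error condition.

What the phantom does **not** model: tissue biomechanics, the soft-pad
transfer function, sagittal spine shape beyond the thoracic/lumbar
amplitude profile, arm/head imprints, or any real subject's imprint.
Passing tests therefore demonstrate that the pipeline recovers programmed
morphology through realistic acquisition artifacts — not clinical
validity on human data.

## Problem sizes and runtime choices

Tests run phantoms at reduced frame counts (1–5 frames) where the
per-frame content is irrelevant to the property under test — the stages
are deterministic per frame, and frame-count behavior is covered
separately. The simulation suites use 120 phantoms for parameter recovery,
50 phantoms for the invariance checks, 200 null cohorts for type-I error
and 50 coupled cohorts for power; the acceptance script's simulated study
uses 25-frame recordings. These sizes give stable estimates (binomial sd
≈ 1.5% at 200 replicates) at desk scale.

## Known limitations

- TBA saturates as a measure of the programmed bend when other asymmetries
  (hump, shoulder offset) contribute comparable COP curvature; recovery is
  specified for single-deformity phantoms.
- PAA inherits Canny's pixel quantization; its recovery tolerance (±1.5°)
  is close to the discretization floor at small obliquities.
- The thoracolumbar inflection `j_tl` is sensitive to the p̄ shape between
  the scapular peak and lumbar minimum; SII should be compared only within
  a fixed configuration.
- Severity boundaries are hard thresholds; Cobb measurement error (±5°
  clinically) near 10° and 20° propagates into group assignment, as it
  does in clinical studies.
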