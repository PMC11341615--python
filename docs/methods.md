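# Methods

## Problem and model

A monoplane C-arm acquires 2D projections of a radio-opaque device marker
while the heart beats and the patient breathes. A 3D reference position of
the same marker (e.g. from postprocedural CMR) is co-registered into the
X-ray frame. The package quantifies how well the marker's 3D position can
be recovered from fluoroscopy, and how that accuracy degrades when the
X-ray frames come from a different cardiac or respiratory phase than the
reference.

### Cone-beam geometry

Patient coordinates are right-handed with the origin at the isocenter:
+x patient-left, +y patient-anterior, +z cranial. The view axis w points
from the source through the isocenter to the detector; at zero angulation
(AP) w = +y, the primary angle rotates w about +z toward +x (LAO positive)
and the secondary angle tilts it toward +z (CRA positive). The source sits
at −SOD·w and the detector centre at (SID−SOD)·w. Detector coordinates are
in mm at the detector plane, origin at the principal point; v points
cranially in the AP view and u is oriented so that a point displaced toward
patient-left projects to positive u — i.e. the image as seen from the
source, the usual radiographic presentation. All quantities in the analysis
are relative distances, so any consistent convention gives the same
results; pixel spacing enters only at I/O.

The default simulation geometry is SID 1200 mm / SOD 800 mm
(magnification 1.5), a typical cardiac C-arm configuration consistent with
the default error budget.

### Marker localization

*Two views.* The detector positions of the marker in two views are
back-projected to rays. Real rays are skew (identification noise,
sequential acquisition), so the marker estimate is the midpoint between the
two Nadir points — the mutually closest points on the rays, obtained from
the 2×2 normal equations. The gap between the Nadir points and the per-view
re-projection error (detector-plane distance between the projection of the
estimate and the identified marker) are reported as consistency measures.
Views closer than 1° are rejected (the normal equations become singular);
below 30° a warning is emitted, just under the 35°–145° range usually
recommended so that shallow-but-usable configurations are not refused.

*One view.* When only one angulation is available, the marker estimate is
the closest point on the single back-projected ray to the co-registered
reference. The resulting distance discards the component of the true error
along the view axis, so it is a provable lower bound on the 3D error —
single-view category statistics systematically underestimate the absolute
error, which is why the package also checks the inequality
single-view distance ≤ pair distance (+ ray gap) on every simulated study.

### Phase assignment and categories

Cardiac phase is the elapsed fraction of the surrounding RR interval,
linearly in time, as a percentage. Frames outside the R-peak span are
excluded and logged, not extrapolated.

The respiratory surrogate (diaphragm position at detector scale) is
low-pass filtered with a Savitzky-Golay filter — defaults 0.7 s window
(rounded to an odd sample count at the run's frame rate) and polynomial
order 3, which passes respiration at ~0.2–0.3 Hz while suppressing
cardiac-frequency contamination and tracking jitter — then divided by the
magnification to isocenter scale. Reference levels are the 5th percentile
(end-expiratory plateau) and 95th percentile (inspiratory extreme) of the
filtered trace, robust to outliers. A frame is *expiration* within 3 mm
above the expiratory level, *inspiration* within 3 mm below the inspiratory
level, otherwise unclassified; if the two levels are closer than twice the
window the run is rejected as shallow respiration (the phases cannot be
separated). Cardiac windows are half-open, [30, 40) and [80, 90) %RR, so
that together with the respiratory label every frame maps to exactly one of
{c1, c2, c3, c4, none}.

### Statistics

Per category the report gives n, AED (arithmetic mean of the Euclidean
distances), sample SD (n−1 denominator; a single sample reports SD 0 with a
logged caveat), a Shapiro–Wilk p-value, and Welch's unequal-variance t-test
against c1 (two-sided, α = 0.05, stars at 0.05/0.01). Welch's test and
Shapiro–Wilk delegate to scipy.stats. Three raw comparisons are reported;
a Holm-adjusted column is additionally emitted and labelled as an
adjustment, not part of the primary analysis. Samples are pooled within a
category across sources, with a per-source breakdown preserved alongside.

### Error budget

Identification error per modality is bounded by half the pixel/voxel
diagonal (2D for the detector, 3D for the reference volume). Defaults:
detector pixel chosen so its half diagonal is 0.2 mm, reference voxel
1.3 mm (half diagonal 1.1 mm), intrinsic X-ray geometry error 0.2 mm,
magnification 1.5. The chain divides the detector error by the
magnification, combines it with the geometry error in root sum square for
the two-view 3D error, re-projects that to the detector plane, and combines
it with the reference-volume error for the total. With
`round_intermediates=True` every chained value is rounded to 0.1 mm before
entering the next formula; this reproduces a display-rounded published
chain (0.2 → 0.1 → 0.2 → 0.3 / 1.1 → 1.1 mm) and is only self-consistent
near magnification 1.5. Full precision is the default for new analyses and
stays within 0.15 mm of the rounded chain at the default inputs.
Single-view localization contributes no term to the total: the total is
defined for the two-view reconstruction.

## Synthetic phantom

The generator emulates the study conditions end to end. The marker position
is baseline + cardiac + respiratory displacement, added linearly with no
hysteresis:

- respiratory: A_r · sin^k(πt/T) along a fixed unit vector; k even
  (default 4) produces the end-expiratory dwell of real breathing; default
  T = 4 s, A_r = 2.5 mm cranio-caudal;
- cardiac: a raised-cosine bump of the phase, centred at 85 %RR with 15 %
  half-width (atrial systole), amplitude 4 mm along the oblique direction
  (1,1,1)/√3 — real atrial motion is not aligned with any view axis, and an
  axis-aligned choice would be invisible to single-view localization in
  that view;
- ECG: R-peaks from truncated-normal RR draws (±3 SD), default
  0.9 ± 0.05 s;
- imaging: 15 fps under one or two angulations (default AP + LAO60),
  isotropic detector identification noise σ = 0.1 mm;
- surrogate: the diaphragm trace shares the respiratory waveform exactly
  (amplitude 12 mm at the isocenter, well above the marker's 2.5 mm, as a
  diaphragm surrogate should be), scaled to detector units plus σ = 0.3 mm
  trace noise — so downstream respiratory misclassification is attributable
  to noise and filtering only;
- reference: the true marker position at 35 %RR in end-expiration plus an
  exactly stored injected co-registration error vector (default zero).

Everything is a deterministic function of the parameters and one seed.

What the phantom does **not** model: hysteresis between inspiration and
expiration, beat-to-beat variability of the cardiac displacement, patient
repositioning or drift between runs, C-arm bending as a function of
angulation, detector distortion, and imperfect surrogate–target correlation.
Passing tests therefore demonstrate the correctness of the geometry, the
classification logic and the statistics under the stated motion model — not
that a clinical study would reach the same numbers.

## Numerical and design choices

- Near-parallel triangulation: hard floor 1°, warning 30°, both
  configurable.
- Pair formation for the two-run pair analysis: the runs are sequential,
  never simultaneous, so reference-phase frames are matched greedily by
  nearest cardiac phase, each frame used at most once.
- Distances are aggregated only in the statistics layer; localization
  returns per-frame/per-pair values.
- Degenerate inputs raise typed errors: points at/behind the source,
  parallel rays, shallow respiration, frames outside the R-peak span,
  constant samples in the normality check.
- Problem sizes in the test and acceptance runs: 90 s runs at 15 fps
  (~1350 frames per view), 10–20 seeds per recovery experiment — enough for
  ≥15 frames per category per run and stable seed-averaged statistics.

## Known limitations

Single-view category AEDs are lower bounds (view-axis blindness). The
respiratory reference levels are per-run percentiles, so a run that never
reaches end-inspiration will stretch the inspiration window toward the
middle of the excursion. The pair analysis assumes negligible marker
displacement between the matched frames of the two runs beyond what the
phase matching controls.
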