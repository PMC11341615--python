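# fluoroacc

Motion-resolved 3D accuracy assessment for monoplane C-arm image guidance.

During image-guided cardiac interventions (for example left atrial appendage
closure), a preprocedural 3D dataset such as CMR is fused with live X-ray
fluoroscopy. Cardiac contraction and respiration move the target between and
during acquisitions, so the accuracy of that fusion depends on *when* the
X-ray frames were acquired relative to the phase at which the 3D reference
was imaged. `fluoroacc` implements the full quantitative pipeline for
studying this effect:

- **Cone-beam view model** — builds the source/detector frame of a C-arm
  view from SID, SOD and the gantry angulation (RAO/LAO, CRA/CAU), projects
  3D points to the detector and back-projects detector points to rays.
- **Marker localization** — two-view triangulation of a device marker as
  the midpoint between the Nadir points of the two back-projected rays
  (P_pair, the mutually closest points on the skew lines), per-view
  re-projection error, and single-view localization as the closest point on
  one ray to a co-registered reference position (P_single).
- **Motion phase assignment** — cardiac phase per frame in %RR from ECG
  R-peaks; respiratory label from a Savitzky-Golay-filtered
  diaphragm-surrogate trace with a 3 mm acceptance window at the isocenter;
  frames binned into c1 (expiration, 30–40 %RR — motion-synchronized),
  c2 (inspiration, 30–40 %RR), c3 (expiration, 80–90 %RR, atrial systole),
  c4 (inspiration, 80–90 %RR).
- **Accuracy statistics** — averaged Euclidean distance (AED ± SD) per
  category, Shapiro–Wilk normality check, and Welch's t-test of c2–c4
  against c1 with significance stars (*p* < 0.05 / *p* < 0.01).
- **Error budget** — the closed-form chain from pixel/voxel half-diagonal
  identification errors through isocenter scaling and root-sum-square
  combination:
  ε_2DXR = pixel·√2/2, ε_CMR = voxel·√3/2, ε_2DXRiso = ε_2DXR/m,
  ε_3DXR = √(ε_2DXRiso² + ε_geo²), ε_2DXRproj = ε_3DXR·m,
  ε_tot = √(ε_3DXR² + ε_CMR²), with m = SID/SOD.
- **Synthetic phantom** — a marker with additive cardiac (raised-cosine
  bump in late RR) and respiratory (sin⁴, end-expiratory dwell) motion,
  imaged at 15 fps in one or two angulations with detector noise, RR
  variability, a correlated diaphragm trace, and a reference position with
  an exactly known injected co-registration error — so every stage is
  testable against ground truth.

## Worked example

```python
import fluoroacc as fa

study = fa.simulate_study(fa.MotionParams(seed=42))      # two views, 90 s at 15 fps
report = fa.run_full_analysis(fa.StudyBundle.from_synthetic(study))
print(report.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

```
category  n  AED_mm  SD_mm  p_vs_c1 stars
      c1 67   0.202  0.175      NaN
      c2 34    2.27  0.242 2.51e-42    **
      c3 67    3.06  0.336 5.34e-81    **
      c4 34    4.86  0.306 4.92e-50    **
```

Each row is one motion category of the first run: `n` frames fell in it,
and `AED_mm` is the mean distance between the reference marker and its
single-view localization on those frames. The motion-synchronized category
c1 (same phase as the reference) is limited only by detector noise
(~0.2 mm here, no co-registration error was injected); c2 picks up the
2.5 mm respiratory marker displacement, and the atrial-systole categories
c3/c4 additionally see the 4 mm cardiac bump — all significantly worse than
c1 by Welch's test (`**` = p < 0.01). The pair block of the same report
(`report.pair_block`) shows the two-view triangulation over matched c1
frame pairs: 67 pairs at 60° separation with a 3D AED of 0.23 ± 0.16 mm.

The same pipeline is scriptable from the shell:

```
fluoroacc simulate --seed 42 --out study/    # writes geometry/run/R-peak/marker files
fluoroacc analyze study/ --out report.json
fluoroacc budget                              # closed-form error budget
```

`fluoroacc budget` prints the default chain (0.2 mm detector pixel
half-diagonal, 1.3 mm CMR voxel, 0.2 mm geometry error, magnification 1.5,
intermediates rounded to 0.1 mm): ε_CMR = 1.1, ε_2DXRiso = 0.1,
ε_3DXR = 0.2, ε_2DXRproj = 0.3, ε_tot = 1.1 mm.

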