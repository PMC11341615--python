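"""Synthetic cardiorespiratory motion phantom.

Generates studies with known ground truth so every pipeline stage can be
exercised without patient data: a single device marker undergoing additive
cardiac motion (a raised-cosine bump in late RR, emulating atrial systole)
and respiratory motion (a sin^(2k) waveform with an end-expiratory dwell),
imaged at a fixed frame rate under one or two C-arm angulations with
additive detector-identification noise; a diaphragm-surrogate trace of
larger amplitude than the marker's respiratory displacement, recorded at
detector scale and sharing the respiratory waveform exactly; R-peak times
with truncated-normal RR variability; and a reference 3D marker position
("postprocedural" marker) taken at a chosen cardiac phase in end-expiration
with a controllable, exactly-known co-registration error vector.

Cardiac and respiratory displacements add linearly; no hysteresis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .carm_geometry import CArmGeometry, DetectorPoint, Point3D, project_point
from .motion_phase import XRFrame, XRRun

logger = logging.getLogger("fluoroacc")

DEFAULT_GEOMETRIES = (
    CArmGeometry(sid_mm=1200.0, sod_mm=800.0, primary_deg=0.0, secondary_deg=0.0, label="AP"),
    CArmGeometry(sid_mm=1200.0, sod_mm=800.0, primary_deg=60.0, secondary_deg=0.0, label="LAO60"),
)


@dataclass(frozen=True)
class MotionParams:
    """Ground-truth motion model parameters.

    Amplitude vectors give both direction and magnitude of the peak
    displacement; ``resp_exponent`` (even) shapes the end-expiratory dwell
    of the breathing waveform. Defaults describe a sedated adult: RR
    0.9 +/- 0.05 s, 4 s breathing period, 12 mm diaphragm excursion at the
    isocenter, 2.5 mm marker respiratory amplitude, 4 mm atrial-systolic
    bump centred at 85% RR with 15% half-width, 0.1 mm detector
    identification noise.
    """

    baseline: Point3D = Point3D(0.0, 0.0, 0.0)
    # oblique atrial-systolic displacement (|.| = 4 mm): real cardiac motion
    # has components along every view axis, so no single view nulls it
    cardiac_amp: tuple = (4.0 / np.sqrt(3),) * 3
    cardiac_center_pct: float = 85.0
    cardiac_width_pct: float = 15.0
    resp_amp: tuple = (0.0, 0.0, 2.5)
    resp_period_s: float = 4.0
    resp_exponent: int = 4
    rr_mean_s: float = 0.9
    rr_sd_s: float = 0.05
    diaphragm_amp_mm: float = 12.0
    detector_noise_sd_mm: float = 0.1
    trace_noise_sd_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resp_exponent % 2 != 0 or self.resp_exponent < 2:
            raise ValueError("resp_exponent must be an even integer >= 2")
        if self.rr_sd_s > 0 and not self.rr_mean_s > 3 * self.rr_sd_s:
            raise ValueError("require rr_mean_s > 3 * rr_sd_s (or rr_sd_s = 0)")
        for v in (self.cardiac_amp, self.resp_amp):
            if not np.all(np.isfinite(v)):
                raise ValueError("amplitude vectors must be finite")


@dataclass(frozen=True)
class StudyTruth:
    """Per-frame ground truth aligned 1:1 with each run's frames."""

    positions: dict  # run label -> (n,3) true 3D marker positions
    cardiac_pct: dict  # run label -> (n,) true cardiac phase
    resp_state: dict  # run label -> (n,) true respiratory label
    registration_error: np.ndarray
    reference_true: Point3D  # reference position before the injected error


@dataclass(frozen=True)
class SyntheticStudy:
    runs: tuple  # XRRun, one per geometry
    cmr_marker: Point3D
    truth: StudyTruth


def respiratory_waveform(t_s, period_s: float, amplitude_mm: float, exponent: int):
    """Breathing displacement ``A * sin^k(pi t / T)`` with even exponent k:
    zero at t = 0 (end-expiration), peak A at t = T/2, with an increasingly
    long expiratory dwell as k grows."""
    if exponent % 2 != 0 or exponent < 2:
        raise ValueError("exponent must be an even integer >= 2")
    return amplitude_mm * np.sin(np.pi * np.asarray(t_s, dtype=float) / period_s) ** exponent


def cardiac_waveform(phase_pct, amplitude_mm: float, center_pct: float, width_pct: float):
    """Raised-cosine displacement bump of half-width ``width_pct`` centred
    at ``center_pct`` %RR (circular in phase), zero elsewhere."""
    if width_pct <= 0:
        raise ValueError("width_pct must be positive")
    phase = np.asarray(phase_pct, dtype=float)
    d = np.remainder(phase - center_pct + 50.0, 100.0) - 50.0  # circular distance
    out = np.where(
        np.abs(d) <= width_pct,
        amplitude_mm * 0.5 * (1.0 + np.cos(np.pi * d / width_pct)),
        0.0,
    )
    return out if out.ndim else float(out)


def simulate_rr(n_beats: int, rr_mean_s: float, rr_sd_s: float, seed: int):
    """R-peak times from truncated-normal RR draws (truncated at +/- 3 SD),
    starting at t = 0."""
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    if rr_sd_s == 0:
        rr = np.full(n_beats - 1, rr_mean_s)
    else:
        rng = np.random.default_rng(seed)
        rr = truncnorm.rvs(
            -3.0, 3.0, loc=rr_mean_s, scale=rr_sd_s, size=n_beats - 1, random_state=rng
        )
    return np.concatenate([[0.0], np.cumsum(rr)])


def _true_cardiac_pct(t: np.ndarray, r_peaks: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(r_peaks, t, side="right") - 1, 0, len(r_peaks) - 2)
    return 100.0 * (t - r_peaks[idx]) / (r_peaks[idx + 1] - r_peaks[idx])


def _unit_and_norm(vec) -> tuple:
    v = np.asarray(vec, dtype=float)
    n = float(np.linalg.norm(v))
    return (v / n if n > 0 else v), n


def simulate_study(
    motion: MotionParams = MotionParams(),
    geometries=DEFAULT_GEOMETRIES,
    fps: float = 15.0,
    duration_s: float = 90.0,
    registration_error=(0.0, 0.0, 0.0),
    reference_cardiac_pct: float = 35.0,
) -> SyntheticStudy:
    """End-to-end synthetic study: one XR run per geometry plus a reference
    marker acquired at ``reference_cardiac_pct`` %RR in end-expiration and
    displaced by the injected ``registration_error``.

    The diaphragm surrogate shares the respiratory waveform with the marker
    by construction, so respiratory misclassification downstream is
    attributable to noise and filtering only. All randomness derives from
    ``motion.seed``; identical parameters yield identical studies.
    """
    if len(geometries) < 1:
        raise ValueError("need at least one geometry")
    if duration_s < 2 * motion.resp_period_s:
        raise ValueError("duration must cover at least two respiratory periods")

    rng = np.random.default_rng(motion.seed)
    n_beats = int(np.ceil(duration_s / max(motion.rr_mean_s - 3 * motion.rr_sd_s, 1e-6))) + 2
    r_peaks = simulate_rr(n_beats, motion.rr_mean_s, motion.rr_sd_s, motion.seed + 1)

    t = np.arange(0.0, duration_s, 1.0 / fps)
    phase = _true_cardiac_pct(t, r_peaks)
    c_hat, c_amp = _unit_and_norm(motion.cardiac_amp)
    r_hat, r_amp = _unit_and_norm(motion.resp_amp)
    resp_shape = respiratory_waveform(t, motion.resp_period_s, 1.0, motion.resp_exponent)
    cardiac_disp = cardiac_waveform(
        phase, c_amp, motion.cardiac_center_pct, motion.cardiac_width_pct
    )
    truth_xyz = (
        motion.baseline.as_array()[None, :]
        + cardiac_disp[:, None] * c_hat[None, :]
        + (r_amp * resp_shape)[:, None] * r_hat[None, :]
    )

    # window-free truth labels from the clean surrogate (3 mm at isocenter)
    dia_iso = motion.diaphragm_amp_mm * resp_shape
    resp_state = np.where(
        dia_iso <= 3.0,
        "expiration",
        np.where(dia_iso >= motion.diaphragm_amp_mm - 3.0, "inspiration", "unclassified"),
    )

    runs, positions, pcts, states = [], {}, {}, {}
    for geom in geometries:
        mag = geom.magnification
        dia_det = dia_iso * mag + rng.normal(0.0, motion.trace_noise_sd_mm, len(t))
        frames = []
        for i, ti in enumerate(t):
            clean = project_point(geom, Point3D.from_array(truth_xyz[i]))
            noise = rng.normal(0.0, motion.detector_noise_sd_mm, 2)
            frames.append(
                XRFrame(
                    index=i,
                    t_s=float(ti),
                    marker=DetectorPoint(clean.u_mm + noise[0], clean.v_mm + noise[1]),
                    diaphragm_mm=float(dia_det[i]),
                )
            )
        label = geom.label or f"view{len(runs)}"
        runs.append(
            XRRun(frames=tuple(frames), r_peaks_s=tuple(r_peaks), fps=fps, geometry=geom)
        )
        positions[label] = truth_xyz.copy()
        pcts[label] = phase.copy()
        states[label] = resp_state.copy()

    # reference marker: end-expiration (zero respiratory displacement) at the
    # requested cardiac phase, plus the injected co-registration error
    reg = np.asarray(registration_error, dtype=float)
    ref_cardiac = cardiac_waveform(
        reference_cardiac_pct, c_amp, motion.cardiac_center_pct, motion.cardiac_width_pct
    )
    ref_true = Point3D.from_array(motion.baseline.as_array() + ref_cardiac * c_hat)
    cmr_marker = Point3D.from_array(ref_true.as_array() + reg)

    truth = StudyTruth(
        positions=positions,
        cardiac_pct=pcts,
        resp_state=states,
        registration_error=reg,
        reference_true=ref_true,
    )
    return SyntheticStudy(runs=tuple(runs), cmr_marker=cmr_marker, truth=truth)
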