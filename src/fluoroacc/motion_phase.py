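"""Cardiac-phase and respiratory-phase assignment of fluoroscopy frames.

Each frame gets a cardiac phase in percent of the surrounding RR interval
(from ECG R-peak times) and a respiratory label obtained by Savitzky-Golay
filtering a diaphragm-surrogate trace, rescaling it from detector to
isocenter, and applying a symmetric acceptance window (default 3 mm at the
isocenter) around the end-expiratory and end-inspiratory reference levels.
Frames are then binned into four motion categories:

    c1  expiration,  30-40% RR   (atrial diastole, motion-synchronized)
    c2  inspiration, 30-40% RR
    c3  expiration,  80-90% RR   (atrial systole)
    c4  inspiration, 80-90% RR

Everything else maps to ``none``. Cardiac windows are half-open so the
categories partition the phase axis cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .carm_geometry import CArmGeometry, DetectorPoint

logger = logging.getLogger("fluoroacc")

EXPIRATION = "expiration"
INSPIRATION = "inspiration"
UNCLASSIFIED = "unclassified"

CATEGORIES = ("c1", "c2", "c3", "c4")


class ShallowRespirationError(ValueError):
    """Respiratory excursion too small to separate expiration from
    inspiration at the requested acceptance window."""


class UnclassifiableFrameError(ValueError):
    """Frame time outside the span of the recorded R-peaks."""


@dataclass(frozen=True)
class XRFrame:
    """One fluoroscopy frame: marker detector position plus the
    cranio-caudal diaphragm-surrogate position at detector scale (mm),
    signed so larger values mean more inspiratory displacement."""

    index: int
    t_s: float
    marker: DetectorPoint
    diaphragm_mm: float


@dataclass(frozen=True)
class XRRun:
    """A timed fluoroscopy run under one geometry with simultaneous ECG."""

    frames: tuple
    r_peaks_s: tuple
    fps: float
    geometry: CArmGeometry

    def __post_init__(self) -> None:
        t = np.array([f.t_s for f in self.frames])
        if len(t) > 1 and np.any(np.diff(t) < 0):
            row = int(np.argmax(np.diff(t) < 0)) + 1
            raise ValueError(f"frame times must be non-decreasing (frame {row})")
        r = np.asarray(self.r_peaks_s, dtype=float)
        if len(r) > 1 and np.any(np.diff(r) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t_s for f in self.frames])

    @property
    def diaphragm_trace(self) -> np.ndarray:
        return np.array([f.diaphragm_mm for f in self.frames])


@dataclass(frozen=True)
class PhaseAssignment:
    cardiac_pct: float
    resp_label: str
    category: str  # c1..c4 or "none"


@dataclass(frozen=True)
class ClassificationConfig:
    """Parameters of the frame classifier.

    window_mm: respiratory acceptance half-band at the isocenter.
    cardiac windows: half-open [lo, hi) percent-RR intervals.
    sg_window_s / sg_polyorder: Savitzky-Golay smoothing of the surrogate
        (0.7 s, order 3 passes ~0.2-0.3 Hz respiration and suppresses
        cardiac-frequency contamination and tracking jitter).
    invert_trace: flip traces recorded with larger = expiratory convention.
    """

    window_mm: float = 3.0
    cardiac_window_a: tuple = (30.0, 40.0)
    cardiac_window_b: tuple = (80.0, 90.0)
    sg_window_s: float = 0.7
    sg_polyorder: int = 3
    invert_trace: bool = False
    ref_exp_percentile: float = 5.0
    ref_insp_percentile: float = 95.0

    def to_dict(self) -> dict:
        return {
            "window_mm": self.window_mm,
            "cardiac_window_a": list(self.cardiac_window_a),
            "cardiac_window_b": list(self.cardiac_window_b),
            "sg_window_s": self.sg_window_s,
            "sg_polyorder": self.sg_polyorder,
            "invert_trace": self.invert_trace,
            "ref_exp_percentile": self.ref_exp_percentile,
            "ref_insp_percentile": self.ref_insp_percentile,
        }

    @staticmethod
    def from_dict(d: dict) -> "ClassificationConfig":
        kw = dict(d)
        for k in ("cardiac_window_a", "cardiac_window_b"):
            if k in kw:
                kw[k] = tuple(kw[k])
        return ClassificationConfig(**kw)


def cardiac_phase_percent(t_s: float, r_peaks_s) -> float:
    """Cardiac phase of a time point as percent of its RR interval.

    With R-peaks ``t_prev <= t_s < t_next`` the phase is
    ``100 * (t_s - t_prev) / (t_next - t_prev)``.

    Raises
    ------
    UnclassifiableFrameError
        If ``t_s`` falls before the first or at/after the last R-peak.
    """
    r = np.asarray(r_peaks_s, dtype=float)
    if len(r) < 2:
        raise UnclassifiableFrameError("need at least two R-peaks")
    i = int(np.searchsorted(r, t_s, side="right")) - 1
    if i < 0 or i >= len(r) - 1:
        raise UnclassifiableFrameError(
            f"time {t_s:.3f}s outside the R-peak span [{r[0]:.3f}, {r[-1]:.3f}]s"
        )
    return float(100.0 * (t_s - r[i]) / (r[i + 1] - r[i]))


def sg_window_samples(window_s: float, fps: float, polyorder: int) -> int:
    """Savitzky-Golay window in samples: nearest odd count >= polyorder + 2."""
    n = int(round(window_s * fps))
    if n % 2 == 0:
        n += 1
    m = polyorder + 2
    if m % 2 == 0:
        m += 1
    return max(n, m)


def smooth_respiratory_trace(
    raw, fps: float, window_s: float = 0.7, polyorder: int = 3
) -> np.ndarray:
    """Low-pass filter a respiratory surrogate trace with a
    Savitzky-Golay filter; edges are handled by the polynomial fit on the
    truncated window (``mode='interp'``)."""
    raw = np.asarray(raw, dtype=float)
    n = sg_window_samples(window_s, fps, polyorder)
    if len(raw) < n:
        raise ValueError(
            f"trace of {len(raw)} samples shorter than the {n}-sample filter window"
        )
    return savgol_filter(raw, window_length=n, polyorder=polyorder, mode="interp")


def respiratory_labels(
    trace_iso_mm,
    window_mm: float = 3.0,
    ref_exp_percentile: float = 5.0,
    ref_insp_percentile: float = 95.0,
):
    """Label each sample of an isocenter-scale respiratory trace.

    Reference levels are the expiratory plateau (low percentile) and the
    inspiratory extreme (high percentile) of the trace itself. A sample is
    ``expiration`` within ``window_mm`` above the expiratory level,
    ``inspiration`` within ``window_mm`` below the inspiratory level, and
    ``unclassified`` in between.

    Raises
    ------
    ShallowRespirationError
        If the two reference levels are less than ``2 * window_mm`` apart:
        the windows overlap and the phases are indistinguishable.
    """
    trace = np.asarray(trace_iso_mm, dtype=float)
    ref_exp = float(np.percentile(trace, ref_exp_percentile))
    ref_insp = float(np.percentile(trace, ref_insp_percentile))
    if ref_insp - ref_exp < 2.0 * window_mm:
        raise ShallowRespirationError(
            f"respiratory excursion {ref_insp - ref_exp:.2f} mm < "
            f"2 x {window_mm:.1f} mm acceptance window: "
            "expiration and inspiration are indistinguishable"
        )
    labels = np.full(len(trace), UNCLASSIFIED, dtype=object)
    labels[trace <= ref_exp + window_mm] = EXPIRATION
    labels[trace >= ref_insp - window_mm] = INSPIRATION
    return list(labels)


def _category(cardiac_pct: float, resp_label: str, cfg: ClassificationConfig) -> str:
    a_lo, a_hi = cfg.cardiac_window_a
    b_lo, b_hi = cfg.cardiac_window_b
    in_a = a_lo <= cardiac_pct < a_hi
    in_b = b_lo <= cardiac_pct < b_hi
    if resp_label == EXPIRATION:
        if in_a:
            return "c1"
        if in_b:
            return "c3"
    elif resp_label == INSPIRATION:
        if in_a:
            return "c2"
        if in_b:
            return "c4"
    return "none"


def categorize_frames(run: XRRun, config: ClassificationConfig | None = None):
    """Assign each frame of a run a cardiac phase, respiratory label and
    motion category.

    Frames before the first or after the last R-peak are excluded
    (``cardiac_pct`` NaN, category ``none``) and logged, not extrapolated.
    Returns a list of :class:`PhaseAssignment`, one per frame.
    """
    cfg = config or ClassificationConfig()
    trace = run.diaphragm_trace
    if cfg.invert_trace:
        trace = -trace
    smooth = smooth_respiratory_trace(trace, run.fps, cfg.sg_window_s, cfg.sg_polyorder)
    iso = smooth / run.geometry.magnification
    labels = respiratory_labels(
        iso, cfg.window_mm, cfg.ref_exp_percentile, cfg.ref_insp_percentile
    )

    out = []
    n_excluded = 0
    for frame, label in zip(run.frames, labels):
        try:
            pct = cardiac_phase_percent(frame.t_s, run.r_peaks_s)
        except UnclassifiableFrameError:
            n_excluded += 1
            out.append(PhaseAssignment(float("nan"), label, "none"))
            continue
        out.append(PhaseAssignment(pct, label, _category(pct, label, cfg)))
    if n_excluded:
        logger.info(
            "excluded %d/%d frames outside the R-peak span", n_excluded, len(run.frames)
        )
    counts = {c: sum(1 for a in out if a.category == c) for c in CATEGORIES}
    logger.info("category counts: %s", counts)
    return out
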