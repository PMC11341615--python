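"""Study I/O and end-to-end orchestration.

A *study* is a plain-text directory: one geometry JSON and one run CSV
(+ R-peak CSV) per view, a reference marker JSON, and optionally the
simulation ground truth and a config JSON. ``run_full_analysis`` reproduces
the two accuracy analyses on a loaded bundle:

(a) motion-synchronized pair triangulation — frames matching the reference
    phase (cardiac reference window in expiration) are selected from two
    runs, paired greedily by nearest cardiac phase, triangulated, and
    compared in 3D against the reference marker, with per-view
    re-projection errors;
(b) single-view category analysis — for every categorized frame of the
    first run, the closest point on the back-projected marker ray to the
    reference marker gives a per-frame distance, pooled into the four
    motion categories and summarized with AED +/- SD, Shapiro-Wilk, and
    Welch's test versus the motion-synchronized category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy_stats import AccuracyReport, DistanceSamples, aed, build_report
from .carm_geometry import CArmGeometry, DetectorPoint, Point3D
from .marker_localization import (
    backproject,
    nadir_on_line,
    reprojection_error,
    triangulate_pair,
)
from .motion_phase import ClassificationConfig, XRFrame, XRRun, categorize_frames
from .synthetic_data import SyntheticStudy

logger = logging.getLogger("fluoroacc")

RUN_COLUMNS = ["frame", "t_s", "marker_u_mm", "marker_v_mm", "diaphragm_mm"]


@dataclass
class StudyBundle:
    """A loaded study: runs (with their geometries), the reference marker,
    optional ground truth, and the classification/analysis config."""

    runs: list
    cmr_marker: Point3D
    config: ClassificationConfig = field(default_factory=ClassificationConfig)
    truth: dict | None = None
    provenance: dict = field(default_factory=dict)

    @staticmethod
    def from_synthetic(
        study: SyntheticStudy, config: ClassificationConfig | None = None
    ) -> "StudyBundle":
        return StudyBundle(
            runs=list(study.runs),
            cmr_marker=study.cmr_marker,
            config=config or ClassificationConfig(),
            provenance={"source": "synthetic"},
        )


def _run_label(run: XRRun, i: int) -> str:
    return run.geometry.label or f"view{i}"


def save_study(bundle: StudyBundle, path) -> None:
    """Write a study directory (geometry/run/R-peak files per view plus the
    reference marker and config)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, run in enumerate(bundle.runs):
        label = _run_label(run, i)
        run.geometry.to_json(path / f"geometry_{label}.json")
        df = pd.DataFrame(
            {
                "frame": [f.index for f in run.frames],
                "t_s": [f.t_s for f in run.frames],
                "marker_u_mm": [f.marker.u_mm for f in run.frames],
                "marker_v_mm": [f.marker.v_mm for f in run.frames],
                "diaphragm_mm": [f.diaphragm_mm for f in run.frames],
            }
        )
        df.to_csv(path / f"run_{label}.csv", index=False, float_format="%.12g")
        pd.DataFrame({"t_s": list(run.r_peaks_s)}).to_csv(
            path / f"rpeaks_{label}.csv", index=False, float_format="%.12g"
        )
    (path / "cmr_marker.json").write_text(
        json.dumps({"x": bundle.cmr_marker.x, "y": bundle.cmr_marker.y, "z": bundle.cmr_marker.z}, indent=2)
        + "\n"
    )
    (path / "config.json").write_text(json.dumps(bundle.config.to_dict(), indent=2) + "\n")


def load_study(path) -> StudyBundle:
    """Load and validate a study directory written by :func:`save_study`.

    Raises descriptive errors for missing files, non-monotone frame times
    (naming the offending row), and invalid geometries.
    """
    path = Path(path)
    geo_files = sorted(path.glob("geometry_*.json"))
    if not geo_files:
        raise FileNotFoundError(f"no geometry_*.json in {path}")
    marker_file = path / "cmr_marker.json"
    if not marker_file.exists():
        raise FileNotFoundError(f"missing {marker_file}")

    runs = []
    for gf in geo_files:
        label = gf.stem.removeprefix("geometry_")
        geom = CArmGeometry.from_json(gf)
        run_file = path / f"run_{label}.csv"
        rpeak_file = path / f"rpeaks_{label}.csv"
        for f in (run_file, rpeak_file):
            if not f.exists():
                raise FileNotFoundError(f"missing {f}")
        df = pd.read_csv(run_file)
        missing = [c for c in RUN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{run_file}: missing columns {missing}")
        dt = np.diff(df["t_s"].to_numpy())
        if np.any(dt < 0):
            row = int(np.argmax(dt < 0)) + 2  # 1-based + header
            raise ValueError(f"{run_file}: t_s decreases at row {row}")
        frames = tuple(
            XRFrame(
                index=int(r.frame),
                t_s=float(r.t_s),
                marker=DetectorPoint(float(r.marker_u_mm), float(r.marker_v_mm)),
                diaphragm_mm=float(r.diaphragm_mm),
            )
            for r in df.itertuples()
        )
        r_peaks = tuple(pd.read_csv(rpeak_file)["t_s"].astype(float))
        dt_med = float(np.median(np.diff(df["t_s"]))) if len(df) > 1 else 1.0
        runs.append(XRRun(frames=frames, r_peaks_s=r_peaks, fps=1.0 / dt_med, geometry=geom))

    m = json.loads(marker_file.read_text())
    cmr_marker = Point3D(float(m["x"]), float(m["y"]), float(m["z"]))
    cfg_file = path / "config.json"
    config = (
        ClassificationConfig.from_dict(json.loads(cfg_file.read_text()))
        if cfg_file.exists()
        else ClassificationConfig()
    )
    return StudyBundle(
        runs=runs, cmr_marker=cmr_marker, config=config, provenance={"path": str(path)}
    )


def _reference_frames(run: XRRun, config: ClassificationConfig):
    """Frames of a run in the reference phase (category c1), with their
    cardiac percentages."""
    assignments = categorize_frames(run, config)
    return [
        (frame, a.cardiac_pct)
        for frame, a in zip(run.frames, assignments)
        if a.category == "c1"
    ]


def _greedy_phase_pairs(ref1, ref2):
    """Match reference-phase frames of two runs greedily by nearest cardiac
    phase, each frame used at most once (the runs are sequential, never
    simultaneous)."""
    candidates = sorted(
        ((abs(p1 - p2), i, j) for i, (_, p1) in enumerate(ref1) for j, (_, p2) in enumerate(ref2)),
        key=lambda c: (c[0], c[1], c[2]),
    )
    used1, used2, pairs = set(), set(), []
    for _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append((ref1[i][0], ref2[j][0]))
    return pairs


def pair_analysis(bundle: StudyBundle) -> dict | None:
    """Motion-synchronized two-view triangulation accuracy (block (a)).

    Returns None (with a warning logged) when fewer than two runs exist,
    the runs share one angulation, or either run has no reference-phase
    frames — mirroring studies where the second angulation run is too short
    to classify.
    """
    if len(bundle.runs) < 2:
        logger.warning("pair analysis skipped: fewer than two runs")
        return None
    run1, run2 = bundle.runs[0], bundle.runs[1]
    if (run1.geometry.primary_deg, run1.geometry.secondary_deg) == (
        run2.geometry.primary_deg,
        run2.geometry.secondary_deg,
    ):
        logger.warning("pair analysis skipped: identical angulations")
        return None
    ref1 = _reference_frames(run1, bundle.config)
    ref2 = _reference_frames(run2, bundle.config)
    if not ref1 or not ref2:
        logger.warning(
            "pair analysis skipped: no motion-synchronized frames (run1: %d, run2: %d)",
            len(ref1),
            len(ref2),
        )
        return None

    pairs = _greedy_phase_pairs(ref1, ref2)
    dist_3d, reproj1, reproj2, gaps, records = [], [], [], [], []
    sep = None
    for f1, f2 in pairs:
        loc = triangulate_pair(run1.geometry, f1.marker, run2.geometry, f2.marker)
        sep = loc.angular_separation_deg
        d = loc.p_pair.distance_to(bundle.cmr_marker)
        e1 = reprojection_error(run1.geometry, loc.p_pair, f1.marker)
        e2 = reprojection_error(run2.geometry, loc.p_pair, f2.marker)
        dist_3d.append(d)
        reproj1.append(e1)
        reproj2.append(e2)
        gaps.append(loc.nadirs.gap_mm)
        records.append(
            {
                "frame_1": f1.index,
                "frame_2": f2.index,
                "p_pair": list(loc.p_pair.as_array()),
                "gap_mm": loc.nadirs.gap_mm,
                "dist_3d_mm": d,
                "reproj_view1_mm": e1,
                "reproj_view2_mm": e2,
            }
        )
    m3, s3 = aed(dist_3d)
    m1, s1 = aed(reproj1)
    m2, s2 = aed(reproj2)
    logger.info("pair analysis: %d pairs, 3D AED %.2f mm", len(pairs), m3)
    return {
        "n_pairs": len(pairs),
        "angular_separation_deg": sep,
        "dist_3d_aed_mm": m3,
        "dist_3d_sd_mm": s3,
        "reproj_aed_mm": {"view1": m1, "view2": m2},
        "reproj_sd_mm": {"view1": s1, "view2": s2},
        "mean_gap_mm": float(np.mean(gaps)),
        "pairs": records,
    }


def category_analysis(bundle: StudyBundle) -> list:
    """Single-view category distances (block (b)) on the first run.

    For every frame in a motion category, back-projects the identified
    marker and takes the perpendicular distance from the reference marker
    to that ray as the accuracy sample.
    """
    run = bundle.runs[0]
    assignments = categorize_frames(run, bundle.config)
    by_cat = {c: ([], []) for c in ("c1", "c2", "c3", "c4")}
    for frame, a in zip(run.frames, assignments):
        if a.category == "none":
            continue
        line = backproject(run.geometry, frame.marker)
        _, dist = nadir_on_line(line, bundle.cmr_marker)
        d, src = by_cat[a.category]
        d.append(dist)
        src.append(f"frame{frame.index}")
    return [
        DistanceSamples(category=c, distances_mm=d, source_ids=src)
        for c, (d, src) in by_cat.items()
    ]


def run_full_analysis(bundle: StudyBundle) -> AccuracyReport:
    """Run both accuracy analyses on a study and assemble the report."""
    pair_block = pair_analysis(bundle)
    samples = category_analysis(bundle)
    report = build_report(samples, pair_block=pair_block)
    return report


def report_to_json(report: AccuracyReport) -> str:
    """Deterministic JSON serialization of a report."""
    return json.dumps(report.to_dict(), indent=2, sort_keys=True)


def plot_category_boxes(report: AccuracyReport, samples, ax=None):
    """Box plot of per-category distances with significance stars — a
    minimal visual companion to the report table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    by_cat = {s.category: s.distances_mm for s in samples}
    names = [c for c in ("c1", "c2", "c3", "c4") if by_cat.get(c)]
    ax.boxplot([by_cat[c] for c in names], tick_labels=names)
    for i, c in enumerate(names):
        stars = report.categories.get(c, {}).get("stars", "")
        if stars:
            ax.annotate(
                stars,
                (i + 1, max(by_cat[c])),
                textcoords="offset points",
                xytext=(0, 4),
                ha="center",
            )
    ax.set_ylabel("distance to reference marker (mm)")
    ax.set_xlabel("motion category")
    return ax
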