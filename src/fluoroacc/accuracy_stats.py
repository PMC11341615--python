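"""Accuracy statistics: averaged Euclidean distance (AED) per motion
category, Shapiro-Wilk normality check, and Welch's unequal-variance t-test
of each non-synchronized category against the motion-synchronized one (c1).

Samples are pooled across runs/patients within a category; a per-source
breakdown is also emitted so provenance is preserved. Welch's test is
two-sided with alpha = 0.05; raw p-values are reported, with an additional
Holm-corrected column clearly labelled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("fluoroacc")

ALPHA = 0.05


@dataclass
class DistanceSamples:
    """Euclidean distance samples for one motion category (or the
    pair-triangulation block), with provenance labels."""

    category: str  # c1..c4 or "pair"
    distances_mm: list
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_mm, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if self.source_ids and len(self.source_ids) != len(d):
            raise ValueError("source_ids must align with distances")

    @property
    def n(self) -> int:
        return len(self.distances_mm)


def aed(distances_mm) -> tuple:
    """Averaged Euclidean distance and sample SD (n-1 denominator).

    A single sample reports SD 0 with a logged caveat.
    """
    d = np.asarray(distances_mm, dtype=float)
    if d.size == 0:
        raise ValueError("cannot average an empty distance list")
    if d.size == 1:
        logger.warning("AED over a single sample: SD reported as 0")
        return float(d[0]), 0.0
    return float(np.mean(d)), float(np.std(d, ddof=1))


def welch_t_test(a, b) -> tuple:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's test needs at least two samples per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) != np.mean(b):
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def normality_check(samples) -> float:
    """Shapiro-Wilk p-value (null: the sample is normal)."""
    s = np.asarray(samples, dtype=float)
    if len(s) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    if np.ptp(s) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    return float(stats.shapiro(s).pvalue)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return ""


def holm_correction(pvalues: dict) -> dict:
    """Holm step-down adjustment of a small family of p-values."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted, running_max = {}, 0.0
    for rank, (key, p) in enumerate(items):
        running_max = max(running_max, min(1.0, (m - rank) * p))
        adjusted[key] = running_max
    return adjusted


@dataclass
class AccuracyReport:
    """Per-category accuracy table plus the pair-triangulation block."""

    categories: dict  # name -> row dict
    pair_block: dict | None = None

    def to_dict(self) -> dict:
        out = {"categories": self.categories}
        if self.pair_block is not None:
            out["pair_block"] = self.pair_block
        return out

    def to_frame(self) -> pd.DataFrame:
        """Table-style view: rows = categories, columns = n, AED, SD, p, stars."""
        rows = []
        for name, row in self.categories.items():
            rows.append(
                {
                    "category": name,
                    "n": row["n"],
                    "AED_mm": row["aed_mm"],
                    "SD_mm": row["sd_mm"],
                    "p_vs_c1": row.get("welch_p_vs_c1"),
                    "stars": row.get("stars", ""),
                }
            )
        return pd.DataFrame(rows)


def build_report(
    by_category: list,
    pair_block: dict | None = None,
    alpha: float = ALPHA,
) -> AccuracyReport:
    """Assemble the accuracy report from per-category distance samples.

    c1 must be present with n >= 2 (it is the reference for Welch's test).
    Categories with too few samples for a given statistic get ``None`` for
    that entry rather than failing the whole report.
    """
    samples = {s.category: s for s in by_category}
    if "c1" not in samples or samples["c1"].n < 2:
        raise ValueError("category c1 with at least 2 samples is required")

    c1 = np.asarray(samples["c1"].distances_mm, dtype=float)
    categories: dict = {}
    raw_p: dict = {}
    for name in ("c1", "c2", "c3", "c4"):
        if name not in samples or samples[name].n == 0:
            categories[name] = {"n": 0, "aed_mm": None, "sd_mm": None}
            continue
        s = samples[name]
        mean, sd = aed(s.distances_mm)
        row = {"n": s.n, "aed_mm": mean, "sd_mm": sd}
        d = np.asarray(s.distances_mm, dtype=float)
        try:
            row["normality_p"] = normality_check(d)
        except ValueError:
            row["normality_p"] = None
        if name != "c1" and s.n >= 2:
            t, df, p = welch_t_test(d, c1)
            row.update(welch_t_vs_c1=t, welch_df_vs_c1=df, welch_p_vs_c1=p)
            row["stars"] = significance_stars(p)
            raw_p[name] = p
        if s.source_ids:
            per_source = (
                pd.DataFrame({"src": s.source_ids, "d": s.distances_mm})
                .groupby("src")["d"]
                .agg(["count", "mean", "std"])
            )
            row["per_source"] = {
                str(k): {
                    "n": int(v["count"]),
                    "aed_mm": float(v["mean"]),
                    "sd_mm": float(v["std"]) if np.isfinite(v["std"]) else 0.0,
                }
                for k, v in per_source.iterrows()
            }
        categories[name] = row

    if raw_p:
        adjusted = holm_correction(raw_p)
        for name, p_adj in adjusted.items():
            categories[name]["welch_p_vs_c1_holm"] = p_adj

    return AccuracyReport(categories=categories, pair_block=pair_block)
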