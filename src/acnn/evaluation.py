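"""Sensitivity and FROC analysis with per-scan false-positive operating points.

A scored candidate is a true positive when it lies within one nodule radius
of an annotated centre (the LUNA16 hit convention); each annotation is
claimed once, by its highest-scoring matching candidate, and further
candidates inside an already-claimed annotation are ignored — neither TP
nor FP.  Sweeping the score threshold over all candidate scores yields the
free-response ROC curve: mean false positives per scan on the horizontal
axis against sensitivity SEN = TP / (TP + FN) on the vertical axis.
Detection quality is summarized by the sensitivities at 0.125, 0.25, 0.5,
1, 2, 4 and 8 FPs/scan and their mean (the CPM-style average).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_ct import Annotation, Candidate

__all__ = [
    "STANDARD_FPS",
    "HitCriterion",
    "FrocCurve",
    "MatchResult",
    "sensitivity",
    "match_candidates",
    "froc",
    "sensitivity_at",
    "average_sensitivity",
]

STANDARD_FPS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

TP, FP, IGNORED = "TP", "FP", "IGNORED"


@dataclass(frozen=True)
class HitCriterion:
    """Within-radius hit rule: a candidate hits an annotation when its world
    distance to the centre is at most ``factor`` times the nodule radius."""

    factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"factor must be > 0, got {self.factor}")


@dataclass
class FrocCurve:
    """Monotone operating points (FPs/scan, sensitivity) from a threshold sweep."""

    points: list[tuple[float, float]]
    n_scans: int
    n_nodules: int

    def __post_init__(self) -> None:
        fps = [p[0] for p in self.points]
        sens = [p[1] for p in self.points]
        if any(b < a - 1e-12 for a, b in zip(fps, fps[1:])):
            raise ValueError("fp_per_scan must be non-decreasing along the curve")
        if any(b < a - 1e-12 for a, b in zip(sens, sens[1:])):
            raise ValueError("sensitivity must be non-decreasing along the curve")
        if any(not 0 <= s <= 1 for s in sens):
            raise ValueError("sensitivities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fp_per_scan", "sensitivity"])


@dataclass
class MatchResult:
    """Per-candidate TP/FP/IGNORED flags and per-annotation detection state."""

    flags: list[str]
    detected: list[bool]
    claimed_by: list[int | None]  # candidate index that claims each annotation


def sensitivity(tp: int, fn: int) -> float:
    """SEN = TP / (TP + FN)."""
    if tp < 0 or fn < 0:
        raise ValueError("tp and fn must be non-negative")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no positive cases (tp + fn = 0)")
    return tp / (tp + fn)


def match_candidates(
    scored_candidates: Sequence[Candidate],
    annotations: Sequence[Annotation],
    criterion: HitCriterion = HitCriterion(),
) -> MatchResult:
    """Assign TP/FP/IGNORED flags by descending score.

    Candidates are visited from highest to lowest score; a candidate within
    reach of an unclaimed annotation (same series) claims the nearest such
    annotation and becomes a TP.  A candidate whose only reachable
    annotations are already claimed is IGNORED; one reaching none is an FP.
    """
    for a in annotations:
        if not a.diameter_mm > 0:
            raise ValueError(f"annotation with non-positive diameter: {a}")
    order = sorted(
        range(len(scored_candidates)),
        key=lambda i: -(scored_candidates[i].score or 0.0),
    )
    flags = [FP] * len(scored_candidates)
    claimed: list[int | None] = [None] * len(annotations)
    anno_by_series: dict[str, list[int]] = {}
    for j, a in enumerate(annotations):
        anno_by_series.setdefault(a.series_id, []).append(j)
    for i in order:
        cand = scored_candidates[i]
        reachable = []
        for j in anno_by_series.get(cand.series_id, []):
            a = annotations[j]
            dist = float(
                np.linalg.norm(np.subtract(cand.world_xyz, a.world_xyz))
            )
            if dist <= criterion.factor * a.radius_mm:
                reachable.append((dist, j))
        if not reachable:
            continue  # stays FP
        reachable.sort()
        free = [(d, j) for d, j in reachable if claimed[j] is None]
        if free:
            _, j = free[0]
            claimed[j] = i
            flags[i] = TP
        else:
            flags[i] = IGNORED
    detected = [c is not None for c in claimed]
    return MatchResult(flags=flags, detected=detected, claimed_by=claimed)


def froc(
    scored_candidates: Sequence[Candidate],
    annotations: Sequence[Annotation],
    n_scans: int,
    criterion: HitCriterion = HitCriterion(),
) -> FrocCurve:
    """Threshold sweep over all candidate scores.

    At each threshold t the operating point is (#FPs with score >= t per
    scan, #annotations claimed by a TP with score >= t / #annotations).
    Points are ordered by decreasing threshold, hence non-decreasing in both
    coordinates.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if not annotations:
        raise ValueError("froc needs at least one annotation")
    n_nodules = len(annotations)
    if not scored_candidates:
        return FrocCurve(points=[(0.0, 0.0)], n_scans=n_scans, n_nodules=n_nodules)
    if any(c.score is None for c in scored_candidates):
        raise ValueError("all candidates must carry a score")
    result = match_candidates(scored_candidates, annotations, criterion)
    scores = np.array([c.score for c in scored_candidates])
    is_tp = np.array([f == TP for f in result.flags])
    is_fp = np.array([f == FP for f in result.flags])
    points: list[tuple[float, float]] = []
    for t in sorted(set(scores), reverse=True):
        kept = scores >= t
        fp_rate = float(np.sum(kept & is_fp)) / n_scans
        sens = float(np.sum(kept & is_tp)) / n_nodules
        points.append((fp_rate, sens))
    return FrocCurve(points=points, n_scans=n_scans, n_nodules=n_nodules)


def sensitivity_at(
    curve: FrocCurve, fps_list: Sequence[float] = STANDARD_FPS
) -> list[float]:
    """Step-function read-out: the best sensitivity achieved at <= each FP rate."""
    if not curve.points:
        raise ValueError("empty FROC curve")
    out = []
    for fps in fps_list:
        qualifying = [s for f, s in curve.points if f <= fps + 1e-12]
        out.append(max(qualifying) if qualifying else 0.0)
    return out


def average_sensitivity(curve: FrocCurve) -> float:
    """Mean sensitivity over the seven standard operating points (0.125–8 FPs/scan)."""
    return float(np.mean(sensitivity_at(curve, STANDARD_FPS)))


def write_operating_table(curve: FrocCurve, path: str | Path) -> Path:
    path = Path(path)
    sens = sensitivity_at(curve, STANDARD_FPS)
    frame = pd.DataFrame({"fp_per_scan": STANDARD_FPS, "sensitivity": sens})
    frame.loc[len(frame)] = ["average", average_sensitivity(curve)]
    frame.to_csv(path, index=False)
    return path
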