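"""Clone trajectory assembly and classification.

A trajectory is the ordered series of detections of one mutation in one
individual. Mutations detected at three or more timepoints are *traceable*
and are subclassified by the change in VAF between the first and final
detected timepoints:

* growing   — final VAF at least 0.5 percentage points above the first,
* shrinking — final VAF at least 0.5 percentage points below the first,
* static    — absolute change smaller than 0.5 percentage points.

Mutations detected at only one or two timepoints are *events*; events whose
latest detection falls on the individual's final sampled visit at CHIP scale
(VAF >= 2%) are flagged late-appearing, since an abruptly appearing large
clone is plausibly a fast grower the schedule could not trace.

First/final always refer to *detected* timepoints: the VAF is undefined when
the clone is below the calling threshold, so undetected visits inside a
trajectory are gaps, not zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .detection import CHIP_THRESHOLD_PCT
from .errors import CloneDynError, InputError

__all__ = [
    "Trajectory", "TrajectoryPoint", "DominantSelection",
    "build_trajectories", "classify", "select_dominant",
    "TRACEABLE_MIN_TIMEPOINTS", "TRAJECTORY_DELTA_PP",
]

TRACEABLE_MIN_TIMEPOINTS = 3
#: absolute VAF change (percentage points) separating growing/shrinking from static
TRAJECTORY_DELTA_PP = 0.5

Category = Literal["event", "growing", "static", "shrinking"]


@dataclass(frozen=True)
class TrajectoryPoint:
    age_years: float
    timepoint_years: float
    vaf_pct: float


@dataclass(frozen=True)
class Trajectory:
    individual_id: str
    gene: str
    hgvs_p: str
    points: tuple[TrajectoryPoint, ...]
    category: Category
    late_appearing: bool
    reached_chip: bool
    disappeared: bool

    @property
    def n_detected(self) -> int:
        return len(self.points)

    @property
    def traceable(self) -> bool:
        return self.n_detected >= TRACEABLE_MIN_TIMEPOINTS

    @property
    def vaf_first(self) -> float:
        return self.points[0].vaf_pct

    @property
    def vaf_final(self) -> float:
        return self.points[-1].vaf_pct

    @property
    def vaf_max(self) -> float:
        return max(p.vaf_pct for p in self.points)

    @property
    def mutation_id(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_p)


@dataclass(frozen=True)
class DominantSelection:
    """Outcome of dominant-trajectory selection for one individual."""

    individual_id: str
    status: Literal["dominant", "excluded_shrinking", "no_traceable"]
    trajectory: Trajectory | None = None


def classify(
    vafs: Sequence[float] | Trajectory,
    delta_pp: float = TRAJECTORY_DELTA_PP,
) -> Category:
    """Classify a traceable VAF series as growing/shrinking/static.

    Accepts the detected VAF series (ordered by age) or a Trajectory; raises
    on events (fewer than three detections), for which clone dynamics are
    not defined.
    """
    if isinstance(vafs, Trajectory):
        series = [p.vaf_pct for p in vafs.points]
    else:
        series = list(vafs)
    if len(series) < TRACEABLE_MIN_TIMEPOINTS:
        raise CloneDynError(
            f"classification requires >= {TRACEABLE_MIN_TIMEPOINTS} detections, "
            f"got {len(series)} (an event)"
        )
    delta = series[-1] - series[0]
    if delta >= delta_pp:
        return "growing"
    if delta <= -delta_pp:
        return "shrinking"
    return "static"


def build_trajectories(
    observations: pd.DataFrame,
    chip_threshold_pct: float = CHIP_THRESHOLD_PCT,
    delta_pp: float = TRAJECTORY_DELTA_PP,
) -> list[Trajectory]:
    """Assemble one Trajectory per (individual, gene, hgvs_p) with >= 1 detection.

    ``observations`` is a called table (``detected``/``vaf_pct`` columns, as
    produced by :func:`clonedyn.detection.call_table`). Rows where the
    mutation was assayed but not detected still inform each individual's
    final sampled timepoint, which drives the ``disappeared`` and
    ``late_appearing`` flags. Every detected observation belongs to exactly
    one returned trajectory.
    """
    required = {"individual_id", "gene", "hgvs_p", "timepoint_years",
                "age_years", "detected", "vaf_pct"}
    missing = required - set(observations.columns)
    if missing:
        raise InputError(f"observations table missing columns: {sorted(missing)}")

    dup = observations.duplicated(
        subset=["individual_id", "gene", "hgvs_p", "timepoint_years"]
    )
    if dup.any():
        raise InputError(
            f"{int(dup.sum())} duplicate (individual, mutation, timepoint) rows"
        )

    last_sampled = observations.groupby("individual_id")["timepoint_years"].max()

    detected = observations[observations["detected"]]
    trajectories: list[Trajectory] = []
    for (ind, gene, hgvs), grp in detected.groupby(
        ["individual_id", "gene", "hgvs_p"], sort=True
    ):
        grp = grp.sort_values("age_years")
        points = tuple(
            TrajectoryPoint(float(r.age_years), float(r.timepoint_years),
                            float(r.vaf_pct))
            for r in grp.itertuples()
        )
        n = len(points)
        final_tp = float(last_sampled.loc[ind])
        last_detection_tp = points[-1].timepoint_years
        if n >= TRACEABLE_MIN_TIMEPOINTS:
            category: Category = classify([p.vaf_pct for p in points], delta_pp)
            late = False
        else:
            category = "event"
            late = (last_detection_tp == final_tp
                    and points[-1].vaf_pct >= chip_threshold_pct)
        trajectories.append(
            Trajectory(
                individual_id=str(ind), gene=str(gene), hgvs_p=str(hgvs),
                points=points, category=category, late_appearing=late,
                reached_chip=any(p.vaf_pct >= chip_threshold_pct for p in points),
                disappeared=last_detection_tp < final_tp,
            )
        )
    return trajectories


def select_dominant(
    trajectories: Iterable[Trajectory],
    include_shrinking: bool = False,
) -> DominantSelection:
    """Pick one individual's dominant trajectory.

    The dominant trajectory is the traceable one attaining the highest VAF at
    any timepoint (ties: higher final detected VAF, then lexicographic
    mutation id, so the choice is stable under input reordering). Individuals
    whose dominant trajectory is shrinking are excluded from growth analyses
    unless ``include_shrinking`` (the sensitivity analysis) is set.
    """
    trajs = list(trajectories)
    if not trajs:
        raise InputError("select_dominant called with no trajectories")
    ind_ids = {t.individual_id for t in trajs}
    if len(ind_ids) != 1:
        raise InputError(f"trajectories from multiple individuals: {sorted(ind_ids)}")
    ind = next(iter(ind_ids))

    traceable = [t for t in trajs if t.traceable]
    if not traceable:
        return DominantSelection(ind, "no_traceable", None)
    dominant = sorted(
        traceable,
        key=lambda t: (-t.vaf_max, -t.vaf_final, t.gene, t.hgvs_p),
    )[0]
    if dominant.category == "shrinking" and not include_shrinking:
        return DominantSelection(ind, "excluded_shrinking", dominant)
    return DominantSelection(ind, "dominant", dominant)


def trajectories_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Tabular export of trajectories (one row each)."""
    rows = [
        {"individual_id": t.individual_id, "gene": t.gene, "hgvs_p": t.hgvs_p,
         "n_detected": t.n_detected, "category": t.category,
         "late_appearing": t.late_appearing, "reached_chip": t.reached_chip,
         "disappeared": t.disappeared, "vaf_first": t.vaf_first,
         "vaf_final": t.vaf_final, "vaf_max": t.vaf_max}
        for t in trajectories
    ]
    return pd.DataFrame(
        rows,
        columns=["individual_id", "gene", "hgvs_p", "n_detected", "category",
                 "late_appearing", "reached_chip", "disappeared", "vaf_first",
                 "vaf_final", "vaf_max"],
    )
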