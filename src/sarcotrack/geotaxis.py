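"""Negative-geotaxis screen scoring and phenotype-severity classification.

Flies tapped to the bottom of a vial climb upward; a fly is scored a
success if it crosses a 7.5 cm line.  Assays run every three days from
eclosion (day 0) to day 30, with ~10 flies per vial, several vials per
line and five technical replicates per vial and day.  Per-line climbing
trajectories are normalised to day 0, the day of complete (sustained)
loss of climbing is detected, and each gene is assigned a severity class:

========== ======================================
Severe      complete loss within 9 days
Intermediate  loss between day 12 and day 21
Weak        loss at day 24 or later
None        climbing never completely lost
========== ======================================

Because the assay grid runs in 3-day steps, days 10–11 and 22–23 never
occur and the windows partition every possible outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import star_code

__all__ = [
    "DEFAULT_ASSAY_DAYS",
    "SEVERITY_CLASSES",
    "ScreenGene",
    "score_timepoint",
    "line_trajectory",
    "normalize_trajectory",
    "percent_decline",
    "day_of_loss",
    "classify_severity",
    "severity_window_days",
    "compare_to_control",
    "summarize_screen",
    "hit_rate",
]

DEFAULT_ASSAY_DAYS: tuple[int, ...] = tuple(range(0, 31, 3))
SEVERITY_CLASSES: tuple[str, ...] = ("Severe", "Intermediate", "Weak", "None")

_WINDOWS = {"Severe": (0, 9), "Intermediate": (12, 21), "Weak": (24, None)}

_REQUIRED_COLUMNS = ("line", "vial", "day", "rep", "successes", "n_flies")


@dataclass(frozen=True)
class ScreenGene:
    """One screened gene: its normalised trajectory and classification."""

    gene: str
    trajectory: Mapping[int, float]
    day_of_loss: int | None
    severity: str
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_CLASSES:
            raise ValueError(f"severity must be one of {SEVERITY_CLASSES}")
        if 0 in self.trajectory and self.trajectory[0] != 1.0:
            raise ValueError("normalised trajectory must be exactly 1 at day 0")
        if classify_severity(self.day_of_loss, grid=tuple(self.trajectory)) != self.severity:
            raise ValueError("severity inconsistent with day_of_loss window")


def _check_dataset(dataset: pd.DataFrame) -> None:
    missing = set(_REQUIRED_COLUMNS) - set(dataset.columns)
    if missing:
        raise ValueError(f"climbing dataset missing columns: {sorted(missing)}")
    bad = dataset[(dataset["successes"] < 0) | (dataset["successes"] > dataset["n_flies"])]
    if len(bad):
        raise ValueError("successes must lie in [0, n_flies]")


def score_timepoint(records: pd.DataFrame) -> tuple[float, float]:
    """Climbing score for one line and day: (mean fraction, SEM over vials).

    ``records`` holds all (vial, technical replicate) rows for a single
    line and day.  The score is the mean per-(vial, rep) success fraction;
    the SEM is taken across vial means (0 with a single vial).
    """
    _check_dataset(records)
    if len(records) == 0:
        raise ValueError("no records for this timepoint")
    frac = records["successes"] / records["n_flies"]
    vial_means = frac.groupby(records["vial"]).mean()
    sem = float(vial_means.std(ddof=1) / math.sqrt(len(vial_means))) if len(vial_means) > 1 else 0.0
    return float(frac.mean()), sem


def line_trajectory(dataset: pd.DataFrame, line: str | None = None) -> pd.Series:
    """Per-day mean climbing score for one line, indexed by assay day."""
    _check_dataset(dataset)
    sub = dataset if line is None else dataset[dataset["line"] == line]
    if len(sub) == 0:
        raise ValueError(f"no records for line {line!r}")
    frac = sub["successes"] / sub["n_flies"]
    return frac.groupby(sub["day"]).mean().sort_index()


def normalize_trajectory(trajectory: pd.Series) -> pd.Series:
    """Divide every score by the day-0 score (day 0 becomes exactly 1).

    Values above 1 (improvement over day 0) are permitted and not clipped.
    A zero day-0 score makes the line unusable and raises ``ValueError``.
    """
    traj = trajectory.sort_index()
    if 0 not in traj.index:
        raise ValueError("trajectory has no day-0 entry")
    day0 = float(traj.loc[0])
    if day0 <= 0:
        raise ValueError("day-0 score is 0: unusable line")
    return traj / day0


def percent_decline(normalized: pd.Series) -> float:
    """Total percent decline between the first and last assay day."""
    traj = normalized.sort_index()
    if len(traj) < 2:
        raise ValueError("need both day-0 and final-day scores")
    initial, final = float(traj.iloc[0]), float(traj.iloc[-1])
    if initial <= 0:
        raise ValueError("initial score must be positive")
    return 100.0 * (1.0 - final / initial)


def day_of_loss(normalized: pd.Series, tol: float = 0.0) -> int | None:
    """Earliest assay day of *sustained* zero climbing score.

    A day qualifies only when every later assayed day is also zero, so a
    single-timepoint dip to zero followed by recovery does not count.
    Returns ``None`` when climbing is never completely lost.
    """
    traj = normalized.sort_index()
    zero = traj.values <= tol
    for i in range(len(traj)):
        if zero[i:].all():
            return int(traj.index[i])
    return None


def severity_window_days(cls: str, grid: Sequence[int] = DEFAULT_ASSAY_DAYS) -> tuple[int, ...]:
    """Assay-grid days falling inside a severity class window (day 0 excluded)."""
    if cls == "None":
        return ()
    lo, hi = _WINDOWS[cls]
    return tuple(d for d in grid if d > 0 and d >= lo and (hi is None or d <= hi))


def classify_severity(
    day: int | None, grid: Sequence[int] = DEFAULT_ASSAY_DAYS
) -> str:
    """Map a day of loss to its severity class.

    ``day <= 9`` → Severe; ``12 <= day <= 21`` → Intermediate;
    ``day >= 24`` → Weak; ``None`` → None.  A day off the assay grid is an
    error (on the default 3-day grid the three windows are exhaustive).
    """
    if day is None:
        return "None"
    if day not in grid:
        raise ValueError(f"day {day} is not on the assay grid {tuple(grid)}")
    if day <= 9:
        return "Severe"
    if 12 <= day <= 21:
        return "Intermediate"
    if day >= 24:
        return "Weak"
    raise ValueError(f"day {day} falls in no severity window")


def compare_to_control(
    line_data: pd.DataFrame, control_data: pd.DataFrame
) -> pd.DataFrame:
    """Per-day two-sample t-tests of vial-level scores, line vs control.

    Both datasets must share the same assay-day grid and have at least two
    vials per day.  Returns a DataFrame indexed by day with columns
    ``t, p, stars``.
    """
    _check_dataset(line_data)
    _check_dataset(control_data)
    days_a = sorted(line_data["day"].unique())
    days_b = sorted(control_data["day"].unique())
    if days_a != days_b:
        raise ValueError("line and control assay-day grids differ")

    from scipy import stats

    rows = []
    for day in days_a:
        va = _vial_scores(line_data, day)
        vb = _vial_scores(control_data, day)
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"need >= 2 vials per group on day {day}")
        t, p = stats.ttest_ind(va, vb, equal_var=True)
        rows.append({"day": day, "t": float(t), "p": float(p), "stars": star_code(float(p))})
    return pd.DataFrame(rows).set_index("day")


def _vial_scores(dataset: pd.DataFrame, day: int) -> np.ndarray:
    sub = dataset[dataset["day"] == day]
    frac = sub["successes"] / sub["n_flies"]
    return frac.groupby(sub["vial"]).mean().to_numpy()


def summarize_screen(genes: Sequence[ScreenGene]) -> dict:
    """Counts and gene lists per severity class over a whole screen."""
    counts = {cls: 0 for cls in SEVERITY_CLASSES}
    members: dict[str, list[str]] = {cls: [] for cls in SEVERITY_CLASSES}
    for g in genes:
        counts[g.severity] += 1
        members[g.severity].append(g.gene)
    total = len(genes)
    hits = total - counts["None"]
    return {
        "counts": counts,
        "genes": {cls: sorted(v) for cls, v in members.items()},
        "total": total,
        "hits": hits,
    }


def hit_rate(n_hits: int, n_total: int) -> float:
    """Screen hit rate as a percentage."""
    if n_total < 1 or n_hits < 0 or n_hits > n_total:
        raise ValueError("need 0 <= n_hits <= n_total with n_total >= 1")
    return 100.0 * n_hits / n_total
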