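"""Comparative-Ct (2^−ΔΔCt) relative expression analysis.

Relative transcript abundance is computed from qPCR cycle-threshold (Ct)
values with an internal reference gene and a calibrator sample, assuming
an amplification efficiency of 2 per cycle:

    ΔCt   = Ct(target) − Ct(reference)              (per sample)
    ΔΔCt  = ΔCt(sample) − ΔCt(calibrator)
    fold  = 2^−ΔΔCt                                 (calibrator ≡ 1)

Replicates are averaged on the Ct scale before ΔCt.  Knockdown time
courses are reported per genotype arm against that arm's own day-0
calibrator, so both the RNAi and control arms start at fold 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mean_ct",
    "relative_expression",
    "relative_expression_table",
    "percent_knockdown",
    "normalize_to_day0",
]

_CT_COLUMNS = ("genotype", "day", "gene", "replicate", "ct")


def mean_ct(replicates: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of replicate Ct values (cycles)."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("no replicates")
    return float(reps.mean())


def relative_expression(
    target_ct: float,
    ref_ct: float,
    calib_target_ct: float,
    calib_ref_ct: float,
) -> float:
    """Fold change 2^−ΔΔCt of a sample relative to the calibrator."""
    ddct = (target_ct - ref_ct) - (calib_target_ct - calib_ref_ct)
    return float(2.0 ** -ddct)


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference: str = "GAPDH",
    calibrator_day: int = 0,
) -> pd.DataFrame:
    """Per-(gene, genotype, day) fold changes from a tidy Ct table.

    ``ct_table`` needs columns ``genotype, day, gene, replicate, ct``.
    Replicates are averaged on the Ct scale; each genotype is calibrated
    against its own ``calibrator_day`` sample (genotype-matched
    calibration).  Returns columns ``gene, genotype, day, fold_change``.
    """
    missing = set(_CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    means = (
        ct_table.groupby(["genotype", "day", "gene"])["ct"].mean().rename("ct").reset_index()
    )
    ref = means[means["gene"] == reference].set_index(["genotype", "day"])["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference!r} absent from the table")

    rows = []
    for (genotype, gene), grp in means[means["gene"] != reference].groupby(
        ["genotype", "gene"]
    ):
        grp = grp.sort_values("day")
        if calibrator_day not in set(grp["day"]):
            raise ValueError(
                f"no day-{calibrator_day} calibrator for {gene!r} in {genotype!r}"
            )
        calib_ct = float(grp.loc[grp["day"] == calibrator_day, "ct"].iloc[0])
        calib_ref = float(ref.loc[(genotype, calibrator_day)])
        for _, rec in grp.iterrows():
            day = rec["day"]
            if (genotype, day) not in ref.index:
                raise ValueError(f"reference gene missing for {genotype!r} day {day}")
            fold = relative_expression(
                float(rec["ct"]), float(ref.loc[(genotype, day)]), calib_ct, calib_ref
            )
            rows.append(
                {"gene": gene, "genotype": genotype, "day": int(day), "fold_change": fold}
            )
    return pd.DataFrame(rows).sort_values(["gene", "genotype", "day"]).reset_index(drop=True)


def percent_knockdown(
    fold_kd: float, fold_control: float | None = None
) -> float | tuple[float, float]:
    """Percent reduction 100·(1 − fold) relative to the day-0 calibrator.

    With ``fold_control`` given, returns the pair ``(knockdown arm,
    control arm)``, each arm measured against its own calibrator.
    """
    if fold_kd <= 0 or (fold_control is not None and fold_control <= 0):
        raise ValueError("fold changes must be positive")
    kd = 100.0 * (1.0 - fold_kd)
    if fold_control is None:
        return kd
    return kd, 100.0 * (1.0 - fold_control)


def normalize_to_day0(series: pd.DataFrame) -> pd.DataFrame:
    """Re-normalise fold changes so day 0 is exactly 1 per (gene, genotype).

    ``series`` must carry columns ``gene, genotype, day, fold_change``
    with a day-0 entry for every (gene, genotype) pair.
    """
    required = {"gene", "genotype", "day", "fold_change"}
    if not required <= set(series.columns):
        raise ValueError(f"series missing columns: {sorted(required - set(series.columns))}")
    out = series.copy()
    for (gene, genotype), grp in out.groupby(["gene", "genotype"]):
        day0 = grp.loc[grp["day"] == 0, "fold_change"]
        if day0.empty:
            raise ValueError(f"no day-0 entry for {gene!r} in {genotype!r}")
        out.loc[grp.index, "fold_change"] = grp["fold_change"] / float(day0.iloc[0])
    return out
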