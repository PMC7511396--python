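"""Inhibitor-based ATP partitioning between OXPHOS and glycolysis.

Cells are assayed for ATP after 30 min with oligomycin (blocks OXPHOS),
2-deoxyglucose (blocks glycolysis), both, or vehicle.  With condition means
U (untreated), O (oligomycin), D (2DG) and B (both), and untreated set to
100 %:

    %OXPHOS     = 100 · (U − O) / U
    %glycolysis = 100 · (U − D) / U
    %residual   = 100 · B / U

The partition is invariant to uniform rescaling of the luminescence values.
The three percentages need not sum to 100; the deviation is flagged, never
silently corrected.  Negative inhibition (treated mean above untreated) is
reported as a negative percentage with a warning — it is diagnostic, not an
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("untreated", "oligomycin", "2DG", "both")


@dataclass
class ATPPlate:
    """Luminescence wells of one plate at one differentiation day."""

    wells: pd.DataFrame  # columns: well_id, condition, luminescence
    day: int | None = None
    group: str = "control"

    def __post_init__(self) -> None:
        required = {"condition", "luminescence"}
        if not required.issubset(self.wells.columns):
            raise ValueError(f"wells table needs columns {sorted(required)}")
        unknown = set(self.wells["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}; allowed: {CONDITIONS}")
        if (self.wells["luminescence"] < 0).any():
            raise ValueError("luminescence must be >= 0")
        if "untreated" not in set(self.wells["condition"]):
            raise ValueError("at least one untreated well is required")

    def condition_means(self, robust: bool = False) -> pd.Series:
        agg = "median" if robust else "mean"
        return self.wells.groupby("condition")["luminescence"].agg(agg)

    @classmethod
    def from_csv(cls, path, day=None, group="control") -> "ATPPlate":
        return cls(wells=pd.read_csv(path), day=day, group=group)


@dataclass
class MetabolicPartition:
    """Derived %OXPHOS / %glycolysis split for one plate."""

    untreated_mean: float
    pct_oxphos: float | None = None
    pct_glycolysis: float | None = None
    pct_residual_both: float | None = None
    day: int | None = None
    group: str = "control"
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "day": self.day,
            "group": self.group,
            "untreated_mean": self.untreated_mean,
            "pct_oxphos": self.pct_oxphos,
            "pct_glycolysis": self.pct_glycolysis,
            "pct_residual_both": self.pct_residual_both,
            "flags": ";".join(self.flags),
        }


def atp_partition(plate: ATPPlate, robust: bool = False) -> MetabolicPartition:
    """Partition ATP production from one inhibitor plate.

    Condition means are arithmetic means of wells (median with
    ``robust=True``; off by default, as no outlier handling is assumed).
    Missing conditions leave the corresponding percentage as None, not 0.
    """
    means = plate.condition_means(robust=robust)
    u = float(means["untreated"])
    if u <= 0:
        raise ValueError(f"untreated mean must be > 0, got {u}")
    part = MetabolicPartition(untreated_mean=u, day=plate.day, group=plate.group)
    if "oligomycin" in means:
        part.pct_oxphos = 100.0 * (u - float(means["oligomycin"])) / u
        if part.pct_oxphos < 0:
            warnings.warn(
                "oligomycin wells exceed untreated — negative %OXPHOS reported",
                stacklevel=2,
            )
            part.flags.append("negative_oxphos")
    if "2DG" in means:
        part.pct_glycolysis = 100.0 * (u - float(means["2DG"])) / u
        if part.pct_glycolysis < 0:
            warnings.warn(
                "2DG wells exceed untreated — negative %glycolysis reported",
                stacklevel=2,
            )
            part.flags.append("negative_glycolysis")
    if "both" in means:
        part.pct_residual_both = 100.0 * float(means["both"]) / u
    known = [p for p in (part.pct_oxphos, part.pct_glycolysis, part.pct_residual_both) if p is not None]
    if len(known) == 3 and abs(sum(known) - 100.0) > 1e-9:
        part.flags.append(f"sum_not_100:{sum(known):.1f}")
    return part


def normalize_atp(
    plates: list[ATPPlate], control_group: str = "control"
) -> pd.DataFrame:
    """Untreated ATP level per group as % of the control-group mean.

    SD is propagated as 100·sd_group/mean_control (the control mean is
    treated as the reference constant, matching bar-chart normalisation).
    """
    groups = {p.group for p in plates}
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not among plates: {sorted(groups)}")
    per_group: dict[str, np.ndarray] = {}
    for p in plates:
        vals = p.wells.loc[p.wells["condition"] == "untreated", "luminescence"].to_numpy()
        per_group[p.group] = np.concatenate([per_group.get(p.group, np.empty(0)), vals])
    ctrl_mean = per_group[control_group].mean()
    if not ctrl_mean > 0:
        raise ValueError(f"control mean must be > 0, got {ctrl_mean}")
    rows = []
    for g, vals in sorted(per_group.items()):
        rows.append(
            {
                "group": g,
                "pct_of_control": 100.0 * vals.mean() / ctrl_mean,
                "sd": 100.0 * vals.std(ddof=1) / ctrl_mean if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def metabolic_switch_timecourse(partitions: list[MetabolicPartition]) -> pd.DataFrame:
    """Order partitions by differentiation day and locate the metabolic switch.

    Returns the per-day table with a ``switch`` column marking the first day
    at which %OXPHOS exceeds %glycolysis; no day is marked when the ordering
    never flips.  Unordered input is sorted with a warning.
    """
    if len(partitions) < 2:
        raise ValueError("need >= 2 timepoints")
    days = [p.day for p in partitions]
    if any(d is None for d in days):
        raise ValueError("every partition needs a day for a time course")
    if days != sorted(days):
        warnings.warn("timepoints out of order; sorting by day", stacklevel=2)
        partitions = sorted(partitions, key=lambda p: p.day)
    df = pd.DataFrame([p.as_dict() for p in partitions])
    df["switch"] = False
    ox_gt = (df["pct_oxphos"] > df["pct_glycolysis"]).fillna(False)
    if ox_gt.any():
        df.loc[ox_gt.idxmax(), "switch"] = True
    return df


def switch_day(timecourse: pd.DataFrame) -> int | None:
    """Day of the metabolic switch from a :func:`metabolic_switch_timecourse`
    table, or None when no switch occurs."""
    hits = timecourse.loc[timecourse["switch"], "day"]
    return int(hits.iloc[0]) if len(hits) else None
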