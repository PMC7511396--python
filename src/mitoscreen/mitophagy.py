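"""The 100 %-overlap mitophagy assay and its fixed-stain validations.

A mitophagy event is scored on the binarised maximum-projection label maps:
a mitochondrion is "in mitophagy" in a frame when the fraction of its pixels
lying inside a single lysosome label reaches the overlap threshold (default
1.0, i.e. full containment).  Each frame is scored independently — the assay
reports per-time-point cross-sectional fractions, not cumulative flux, so no
object tracking is performed.

The fixed-assay validations reuse the same containment rule (Tomm20 objects
inside LC3 puncta) and the per-cell integrated Tomm20 signal (more Tomm20 =
less mitophagic clearance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .datatypes import LabelMap
from .segment import SegmentationConfig, assign_to_cells, get_channel, segment_organelles

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["cell_id", "mito_label", "lyso_label", "frame_index", "overlap_fraction"]


def overlap_fractions(
    mito: LabelMap, lyso: LabelMap, mode: str = "single"
) -> pd.DataFrame:
    """Per-mitochondrion overlap with the lysosome map.

    ``mode="single"``: the best overlap with any one lysosome label (an event
    requires containment within a single lysosome).  ``mode="union"``:
    overlap with the lysosome class as a whole.  Returns mito_label,
    lyso_label (0 when no lysosome touches it, or in union mode), and
    overlap_fraction in [0, 1].
    """
    if mito.labels.shape != lyso.labels.shape:
        raise ValueError("mitochondria and lysosome maps must share the grid")
    if mode not in ("single", "union"):
        raise ValueError("mode must be 'single' or 'union'")
    m = mito.labels.ravel()
    sel = m > 0
    if not sel.any():
        return pd.DataFrame(columns=["mito_label", "lyso_label", "overlap_fraction"])
    m = m[sel]
    l = lyso.labels.ravel()[sel]
    areas = pd.Series(m).value_counts()
    if mode == "union":
        inside = pd.Series(m[l > 0]).value_counts()
        frac = (inside.reindex(areas.index).fillna(0) / areas).astype(float)
        return pd.DataFrame(
            {
                "mito_label": areas.index,
                "lyso_label": 0,
                "overlap_fraction": frac.to_numpy(),
            }
        ).sort_values("mito_label", ignore_index=True)
    pairs = pd.DataFrame({"mito": m, "lyso": l})
    pairs = pairs[pairs["lyso"] > 0]
    if pairs.empty:
        best = pd.DataFrame({"mito": areas.index, "lyso": 0, "n": 0})
    else:
        counts = pairs.value_counts().reset_index(name="n")
        best = counts.sort_values("n", ascending=False).drop_duplicates("mito")
        missing = areas.index.difference(best["mito"])
        if len(missing):
            best = pd.concat(
                [best, pd.DataFrame({"mito": missing, "lyso": 0, "n": 0})],
                ignore_index=True,
            )
    best["overlap_fraction"] = best["n"] / best["mito"].map(areas)
    return (
        best.rename(columns={"mito": "mito_label", "lyso": "lyso_label"})[
            ["mito_label", "lyso_label", "overlap_fraction"]
        ]
        .sort_values("mito_label")
        .reset_index(drop=True)
    )


def detect_mitophagy_events(
    mito: LabelMap,
    lyso: LabelMap,
    cells: LabelMap | None = None,
    overlap_threshold: float = 1.0,
    mode: str = "single",
) -> pd.DataFrame:
    """Score mitophagy events on one frame.

    One row per engulfed mitochondrion (at most one event per mitochondrion
    per frame): cell_id (0 if no cell map given), mito_label, lyso_label,
    frame_index, overlap_fraction.  Empty maps yield an empty table.
    """
    if not 0.0 < overlap_threshold <= 1.0:
        raise ValueError("overlap_threshold must be in (0, 1]")
    frac = overlap_fractions(mito, lyso, mode=mode)
    events = frac[frac["overlap_fraction"] >= overlap_threshold - 1e-12].copy()
    if cells is not None and len(events):
        owner = assign_to_cells(mito, cells)
        events["cell_id"] = events["mito_label"].map(owner).fillna(0).astype(int)
    else:
        events["cell_id"] = 0
    events["frame_index"] = mito.frame_index
    return events[EVENT_COLUMNS].reset_index(drop=True)


def mitophagy_fraction_per_cell(
    events: pd.DataFrame, mito_counts: pd.Series
) -> pd.Series:
    """Fraction m = distinct engulfed mitochondria / mitochondria count.

    ``mito_counts`` is indexed by cell_id.  Cells with zero mitochondria are
    excluded (logged), not reported as 0.
    """
    mito_counts = pd.Series(mito_counts)
    zero = mito_counts[mito_counts <= 0]
    if len(zero):
        logger.info(
            "excluding %d cell(s) with zero mitochondria: %s",
            len(zero),
            list(zero.index[:10]),
        )
    valid = mito_counts[mito_counts > 0]
    if len(events):
        engulfed = events.groupby("cell_id")["mito_label"].nunique()
    else:
        engulfed = pd.Series(dtype=np.int64)
    m = (engulfed.reindex(valid.index).fillna(0) / valid).astype(float)
    m.name = "m"
    m.index.name = "cell_id"
    return m


@dataclass
class MitophagyTimeCourse:
    """Per-cell, per-frame engulfed fractions with assay metadata."""

    table: pd.DataFrame  # columns: cell_id, frame, minutes, m, induced
    condition: str  # basal | induced
    frame_interval: float = 18.0
    group: str = "control"

    def mean_series(self) -> pd.DataFrame:
        g = self.table.groupby(["frame", "minutes"])["m"]
        out = g.agg(mean_m="mean", sd="std", n="count").reset_index()
        out["condition"] = self.condition
        out["group"] = self.group
        return out


def assemble_timecourse(
    per_frame_fractions: list[pd.Series],
    condition: str = "basal",
    frame_interval: float = 18.0,
    induction_time: float | None = None,
    group: str = "control",
) -> MitophagyTimeCourse:
    """Stack per-frame per-cell fractions into an ordered time course.

    Frames are aligned by acquisition index (no registration).  When the
    inputs disagree in cell sets the intersection is kept; a single frame is
    an error — a time course needs at least two points.  ``induction_time``
    (minutes from start) flags frames at or after induction.
    """
    if len(per_frame_fractions) < 2:
        raise ValueError("a time course needs >= 2 frames")
    if condition not in ("basal", "induced"):
        raise ValueError("condition must be 'basal' or 'induced'")
    common = per_frame_fractions[0].index
    for s in per_frame_fractions[1:]:
        common = common.intersection(s.index)
    if any(len(s) != len(common) for s in per_frame_fractions):
        warnings.warn(
            "cell sets differ across frames; truncating to the "
            f"{len(common)} cells present in every frame",
            stacklevel=2,
        )
    rows = []
    for t, s in enumerate(per_frame_fractions):
        minutes = t * frame_interval
        for cid, m in s.loc[common].items():
            rows.append(
                {
                    "cell_id": cid,
                    "frame": t,
                    "minutes": minutes,
                    "m": float(m),
                    "induced": induction_time is not None and minutes >= induction_time,
                }
            )
    return MitophagyTimeCourse(
        table=pd.DataFrame(rows),
        condition=condition,
        frame_interval=frame_interval,
        group=group,
    )


def tomm20_loss_readout(
    projection: np.ndarray,
    channel_names: list[str],
    cells: LabelMap,
    channel: str = "mitochondria",
) -> pd.Series:
    """Integrated background-subtracted Tomm20 intensity per cell.

    Higher amount means less mitophagic clearance (the readout direction is
    inverted relative to the live assay).  Background is the median non-cell
    intensity.
    """
    img = get_channel(projection, channel_names, channel).astype(np.float64)
    bg = float(np.median(img[cells.labels == 0])) if (cells.labels == 0).any() else 0.0
    cell_ids = cells.ids
    if len(cell_ids) == 0:
        return pd.Series(dtype=np.float64, name="tomm20_amount")
    sums = ndi.sum_labels(img - bg, labels=cells.labels, index=cell_ids)
    return pd.Series(sums, index=pd.Index(cell_ids, name="cell_id"), name="tomm20_amount")


def lc3_tomm20_colocalization(
    projection: np.ndarray,
    channel_names: list[str],
    cells: LabelMap,
    tomm20_channel: str = "mitochondria",
    lc3_channel: str = "lysosomes",
    overlap_threshold: float = 1.0,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Fixed-assay validation: Tomm20 objects contained in LC3 puncta.

    Segments both channels with the organelle detector and applies the same
    containment rule as the live assay.  Returns per-cell counts of Tomm20
    objects, colocalised objects and their fraction.
    """
    tomm = segment_organelles(
        projection, channel_names, cells, "mitochondrion", config=config, channel=tomm20_channel
    )
    lc3 = segment_organelles(
        projection, channel_names, cells, "lysosome", config=config, channel=lc3_channel
    )
    events = detect_mitophagy_events(
        tomm, lc3, cells=cells, overlap_threshold=overlap_threshold
    )
    owner = assign_to_cells(tomm, cells)
    totals = owner.value_counts()
    cell_ids = cells.ids
    out = pd.DataFrame({"cell_id": cell_ids}).set_index("cell_id")
    out["tomm20_objects"] = totals.reindex(cell_ids).fillna(0).astype(int)
    if len(events):
        coloc = events.groupby("cell_id")["mito_label"].nunique()
    else:
        coloc = pd.Series(dtype=np.int64)
    out["colocalized"] = coloc.reindex(cell_ids).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        out["fraction"] = out["colocalized"] / out["tomm20_objects"].replace(0, np.nan)
    return out.reset_index()
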