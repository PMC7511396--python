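"""Per-cell and per-organelle shape and intensity statistics.

Definitions used throughout (circle = 1 for both shape scores):

* roundness  ``R = P² / (4π A)`` — boundary complexity; elongated or spiky
  outlines score higher.  Some screening platforms report the reciprocal
  convention (elongated < 1); ``convention="inverse"`` switches to ``1/R``.
* elongation ``E`` — major/minor axis ratio of the second-moment ellipse.
* interconnectivity ``I`` — mean mitochondrial area/perimeter in µm, the
  convention popularised by the ImageJ mitochondrial-morphology macros.
  Fragmented networks (many small organelles) score lower; for a disc of
  radius r the continuum value is r/2.

Perimeters use the Crofton approximation, which has lower rasterisation bias
than boundary-pixel counting.  Areas are converted to µm² via pixel_size².
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table

from .datatypes import LabelMap
from .segment import assign_to_cells, border_cell_ids


def cell_shape(
    cells: LabelMap,
    pixel_size: float = 1.0,
    convention: str = "spiky_high",
    exclude_border: bool = False,
) -> pd.DataFrame:
    """Roundness and elongation per cell.

    Returns a table with area (µm²), perimeter (µm), roundness, elongation
    and a ``degenerate`` flag for regions too thin for a second-moment
    ellipse.  ``convention="inverse"`` reports 1/roundness (circle = 1,
    elongated < 1).
    """
    if convention not in ("spiky_high", "inverse"):
        raise ValueError("convention must be 'spiky_high' or 'inverse'")
    if cells.n_objects == 0:
        return pd.DataFrame(
            columns=["cell_id", "area_um2", "perimeter_um", "roundness", "elongation",
                     "degenerate", "border"]
        )
    props = regionprops_table(
        cells.labels,
        properties=(
            "label", "area", "perimeter_crofton", "axis_major_length", "axis_minor_length",
        ),
    )
    df = pd.DataFrame(props).rename(columns={"label": "cell_id"})
    small = df["area"] < 10
    if small.any():
        warnings.warn(
            f"{int(small.sum())} cell(s) below 10 px — shape metrics unreliable",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        roundness = df["perimeter_crofton"] ** 2 / (4.0 * np.pi * df["area"])
        elong = df["axis_major_length"] / df["axis_minor_length"]
    degenerate = (df["axis_minor_length"] <= 1e-9) | small
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate (1-px-wide or tiny) region(s); "
            "metrics flagged",
            stacklevel=2,
        )
    if convention == "inverse":
        roundness = 1.0 / roundness
    border = border_cell_ids(cells)
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"],
            "area_um2": df["area"] * pixel_size**2,
            "perimeter_um": df["perimeter_crofton"] * pixel_size,
            "roundness": roundness,
            "elongation": elong,
            "degenerate": degenerate,
            "border": df["cell_id"].isin(border),
        }
    )
    if exclude_border:
        out = out[~out["border"]].reset_index(drop=True)
    return out


def mito_stats_per_cell(
    mito: LabelMap,
    cells: LabelMap,
    intensity: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Mitochondrial number, size, intensity and interconnectivity per cell.

    One row per cell: ``mito_count`` N, ``mito_mean_area_um2``,
    ``mito_mean_intensity`` (if an intensity image is given) and
    ``interconnectivity_um`` I = mean over the cell's mitochondria of
    area/perimeter in µm.  Cells with N = 0 get NaN for the per-mitochondrion
    means (excluded from group averages rather than counted as zero).
    """
    if mito.labels.shape != cells.labels.shape:
        raise ValueError("mitochondria and cell maps must share the grid")
    cell_ids = cells.ids
    base = pd.DataFrame({"cell_id": cell_ids}).set_index("cell_id")
    base["mito_count"] = 0
    base["mito_mean_area_um2"] = np.nan
    base["interconnectivity_um"] = np.nan
    base["mito_mean_intensity"] = np.nan
    if mito.n_objects == 0:
        return base.reset_index()
    props = ["label", "area", "perimeter_crofton"]
    kwargs = {}
    if intensity is not None:
        props.append("intensity_mean")
        kwargs["intensity_image"] = np.asarray(intensity, dtype=np.float64)
    df = pd.DataFrame(regionprops_table(mito.labels, properties=tuple(props), **kwargs))
    owner = assign_to_cells(mito, cells)
    df["cell_id"] = df["label"].map(owner)
    df = df.dropna(subset=["cell_id"])
    df["area_um2"] = df["area"] * pixel_size**2
    with np.errstate(divide="ignore"):
        df["ap_um"] = df["area_um2"] / (df["perimeter_crofton"] * pixel_size)
    grouped = df.groupby("cell_id")
    base.loc[grouped.size().index, "mito_count"] = grouped.size()
    base.loc[grouped.size().index, "mito_mean_area_um2"] = grouped["area_um2"].mean()
    base.loc[grouped.size().index, "interconnectivity_um"] = grouped["ap_um"].mean()
    if intensity is not None:
        base.loc[grouped.size().index, "mito_mean_intensity"] = grouped["intensity_mean"].mean()
    return base.reset_index()


def intensity_readout_per_cell(
    projection: np.ndarray,
    channel_names: list[str],
    cells: LabelMap,
    mito: LabelMap,
    channel: str,
) -> pd.Series:
    """Mean in-mitochondria intensity per cell, background subtracted.

    Background is the median intensity of non-cell pixels.  With the TMRM
    channel this is the membrane-potential proxy; with the redox-probe
    channel it is the mitochondrial ROS proxy.  Cells without mitochondria
    get NaN.
    """
    from .segment import get_channel

    img = get_channel(projection, channel_names, channel).astype(np.float64)
    bg = float(np.median(img[cells.labels == 0])) if (cells.labels == 0).any() else 0.0
    cell_ids = cells.ids
    out = pd.Series(np.nan, index=pd.Index(cell_ids, name="cell_id"), name=channel)
    if mito.n_objects == 0:
        return out
    owner = assign_to_cells(mito, cells)
    means = ndi.mean(img - bg, labels=mito.labels, index=owner.index.to_numpy())
    per_mito = pd.DataFrame({"cell_id": owner.to_numpy(), "value": means})
    agg = per_mito.groupby("cell_id")["value"].mean()
    out.loc[agg.index] = agg
    return out


def normalize_to_control(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    control_group: str,
) -> pd.Series:
    """Express each value as a percentage of the control-group mean.

    The control group maps to mean 100 by construction.  Raises if the
    control mean is not positive.
    """
    values = pd.Series(np.asarray(values, dtype=np.float64))
    groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} not present")
    ctrl_mean = values[groups == control_group].mean()
    if not ctrl_mean > 0:
        raise ValueError(f"control mean must be > 0, got {ctrl_mean}")
    return 100.0 * values / ctrl_mean


def group_summary(per_cell: pd.DataFrame, by: str, value: str) -> pd.DataFrame:
    """Mean, SD and n of one per-cell column by group, skipping NaN."""
    g = per_cell.groupby(by)[value]
    return g.agg(mean="mean", sd="std", n="count").reset_index()
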