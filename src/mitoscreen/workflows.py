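"""End-to-end assay runs and parameter-recovery experiments.

``run_live_mitophagy``, ``run_morphology`` and ``run_metabolics`` tie the
stages together for real or simulated inputs, with provenance (resolved
config, package version, seeds) written next to every output.  The
``*_recovery`` helpers run the full generate → render → segment → measure
loop used to validate the pipeline against known ground truth.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import InputSpec, RunConfig
from .datatypes import ImageStack, LabelMap
from .metabolics import ATPPlate, atp_partition, metabolic_switch_timecourse, normalize_atp
from .mitophagy import (
    assemble_timecourse,
    detect_mitophagy_events,
    mitophagy_fraction_per_cell,
)
from .morphometrics import cell_shape, group_summary, mito_stats_per_cell, normalize_to_control
from .segment import max_project, segment_cells, segment_nuclei, segment_organelles
from .synthgen import SceneParams, generate_atp_plate, generate_scene, render_timelapse

logger = logging.getLogger(__name__)

CSV_FLOAT = "%.10g"


def _load_stack(spec: InputSpec, cfg: RunConfig) -> ImageStack:
    if spec.simulate is not None:
        scene = generate_scene(SceneParams(**spec.simulate))
        return render_timelapse(scene)
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(f"input stack not found: {path}")
    return ImageStack.from_tiff(path)


def _require_channels(stack: ImageStack, roles: list[str], cfg: RunConfig, name: str) -> None:
    for role in roles:
        ch = cfg.channel(role)
        if ch not in stack.channel_names:
            raise ValueError(
                f"input {name!r}: channel {ch!r} (role {role!r}) missing; "
                f"stack has {stack.channel_names}"
            )


def segment_frame(
    stack: ImageStack, frame: int, cfg: RunConfig
) -> dict[str, LabelMap | np.ndarray]:
    """Project one frame and segment nuclei, cells, mitochondria, lysosomes."""
    proj = max_project(stack, frame)
    names = stack.channel_names
    nuclei = segment_nuclei(proj, names, cfg.segmentation, channel=cfg.channel("nuclei"))
    nuclei.frame_index = frame
    cells = segment_cells(
        proj,
        names,
        nuclei,
        cfg.segmentation,
        proxy_channels=(cfg.channel("mitochondria"), cfg.channel("lysosomes")),
    )
    mito = segment_organelles(
        proj, names, cells, "mitochondrion", cfg.segmentation, channel=cfg.channel("mitochondria")
    )
    lyso = segment_organelles(
        proj, names, cells, "lysosome", cfg.segmentation, channel=cfg.channel("lysosomes")
    )
    return {"projection": proj, "nuclei": nuclei, "cells": cells, "mito": mito, "lyso": lyso}


def analyze_live_stack(stack: ImageStack, cfg: RunConfig):
    """Per-frame mitophagy scoring of one time-lapse stack.

    Returns (events table, list of per-frame per-cell fraction Series).
    """
    all_events = []
    fractions = []
    for t in range(stack.n_frames):
        t0 = time.perf_counter()
        maps = segment_frame(stack, t, cfg)
        events = detect_mitophagy_events(
            maps["mito"],
            maps["lyso"],
            cells=maps["cells"],
            overlap_threshold=cfg.overlap_threshold,
            mode=cfg.containment_mode,
        )
        counts = (
            mito_stats_per_cell(maps["mito"], maps["cells"], pixel_size=stack.pixel_size)
            .set_index("cell_id")["mito_count"]
        )
        fractions.append(mitophagy_fraction_per_cell(events, counts))
        all_events.append(events)
        logger.info(
            "frame %d: %d cells, %d mitochondria, %d events (%.2f s)",
            t,
            maps["cells"].n_objects,
            maps["mito"].n_objects,
            len(events),
            time.perf_counter() - t0,
        )
    return pd.concat(all_events, ignore_index=True), fractions


def _write_provenance(outdir: Path, cfg: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config_resolved.yaml")
    (outdir / "provenance.json").write_text(
        json.dumps({"tool": "mitoscreen", "version": __version__, "seed": cfg.seed}, indent=1)
    )


def run_live_mitophagy(cfg: RunConfig) -> dict:
    """Live assay end-to-end: stacks → events, time courses, summary CSVs.

    Deterministic for a fixed config: rerunning writes byte-identical CSVs.
    """
    outdir = Path(cfg.outdir)
    _write_provenance(outdir, cfg)
    events_all, series_rows, percell_rows = [], [], []
    for spec in cfg.inputs:
        stack = _load_stack(spec, cfg)
        _require_channels(stack, ["nuclei", "mitochondria", "lysosomes"], cfg, spec.name)
        events, fractions = analyze_live_stack(stack, cfg)
        events["input"] = spec.name
        events_all.append(events)
        tc = assemble_timecourse(
            fractions,
            condition=spec.condition,
            frame_interval=stack.frame_interval,
            induction_time=spec.induction_time,
            group=spec.group,
        )
        tab = tc.table.copy()
        tab["input"] = spec.name
        tab["group"] = spec.group
        tab["condition"] = spec.condition
        percell_rows.append(tab)
        mean = tc.mean_series()
        mean["input"] = spec.name
        series_rows.append(mean)
    events_df = pd.concat(events_all, ignore_index=True)
    percell = pd.concat(percell_rows, ignore_index=True)
    series = pd.concat(series_rows, ignore_index=True)
    events_df.to_csv(outdir / "events.csv", index=False, float_format=CSV_FLOAT)
    percell.to_csv(outdir / "timecourse_per_cell.csv", index=False, float_format=CSV_FLOAT)
    series.to_csv(outdir / "timecourse.csv", index=False, float_format=CSV_FLOAT)

    stats_df = _maybe_group_stats(percell)
    if stats_df is not None:
        stats_df.to_csv(outdir / "stats.csv", index=False, float_format=CSV_FLOAT)
    return {"events": events_df, "timecourse": series, "per_cell": percell, "stats": stats_df}


def _maybe_group_stats(percell: pd.DataFrame) -> pd.DataFrame | None:
    """Repeated-measures comparison when >= 2 groups have >= 2 inputs each."""
    from .stats import repeated_measures_anova

    counts = percell.groupby("group")["input"].nunique()
    if len(counts) < 2 or (counts < 2).any():
        return None
    per_subject = percell.groupby(["group", "input", "frame"], as_index=False)["m"].mean()
    per_subject = per_subject.rename(columns={"input": "subject"})
    cmp = repeated_measures_anova(per_subject, value="m", subject="subject")
    return cmp.anova


def run_morphology(cfg: RunConfig) -> dict:
    """Morphology assay: per-cell shape + mitochondrial morphometrics CSVs."""
    outdir = Path(cfg.outdir)
    _write_provenance(outdir, cfg)
    if not cfg.inputs:
        raise ValueError("no inputs configured")
    percell_rows = []
    for spec in cfg.inputs:
        stack = _load_stack(spec, cfg)
        _require_channels(stack, ["nuclei", "mitochondria"], cfg, spec.name)
        maps = segment_frame(stack, 0, cfg)
        mito_ch = cfg.channel("mitochondria")
        intensity = maps["projection"][stack.channel_names.index(mito_ch)]
        stats = mito_stats_per_cell(
            maps["mito"], maps["cells"], intensity=intensity, pixel_size=stack.pixel_size
        )
        shape = cell_shape(
            maps["cells"],
            pixel_size=stack.pixel_size,
            exclude_border=cfg.segmentation.exclude_border_cells,
        )
        merged = shape.merge(stats, on="cell_id", how="left")
        merged["input"] = spec.name
        merged["group"] = spec.group
        percell_rows.append(merged)
    percell = pd.concat(percell_rows, ignore_index=True)
    percell.to_csv(outdir / "per_cell.csv", index=False, float_format=CSV_FLOAT)
    summaries = []
    for col in ("mito_count", "mito_mean_area_um2", "interconnectivity_um", "roundness", "elongation"):
        s = group_summary(percell, "group", col)
        s.insert(0, "metric", col)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    groups = set(percell["group"])
    if cfg.control_group in groups and len(groups) > 1:
        norm = normalize_to_control(
            percell["mito_count"].to_numpy(), percell["group"].to_numpy(), cfg.control_group
        )
        percell["mito_count_pct_control"] = norm.to_numpy()
        norm_summary = group_summary(percell, "group", "mito_count_pct_control")
        norm_summary.insert(0, "metric", "mito_count_pct_control")
        summary = pd.concat([summary, norm_summary], ignore_index=True)
    summary.to_csv(outdir / "group_summary.csv", index=False, float_format=CSV_FLOAT)
    return {"per_cell": percell, "summary": summary}


def run_metabolics(cfg: RunConfig, plates: list[ATPPlate] | None = None) -> dict:
    """ATP partitioning per plate plus switch-day and normalisation tables.

    Plates come either from ``plates`` directly, or from input specs whose
    ``path`` points at a well CSV (columns well_id, condition, luminescence).
    """
    outdir = Path(cfg.outdir)
    _write_provenance(outdir, cfg)
    if plates is None:
        plates = []
        for spec in cfg.inputs:
            if spec.path is None:
                raise ValueError(f"metabolics input {spec.name!r} needs a CSV path")
            plates.append(ATPPlate.from_csv(spec.path, day=spec.day, group=spec.group))
    if not plates:
        raise ValueError("no plates to analyse")
    partitions = [atp_partition(p) for p in plates]
    part_df = pd.DataFrame([p.as_dict() for p in partitions])
    part_df.to_csv(outdir / "partitions.csv", index=False, float_format=CSV_FLOAT)
    result = {"partitions": part_df}
    for group in sorted({p.group for p in partitions}):
        sub = [p for p in partitions if p.group == group and p.day is not None]
        if len(sub) >= 2:
            tc = metabolic_switch_timecourse(sub)
            tc.to_csv(outdir / f"switch_{group}.csv", index=False, float_format=CSV_FLOAT)
            result[f"switch_{group}"] = tc
    if len({p.group for p in plates}) > 1:
        norm = normalize_atp(plates, control_group=cfg.control_group)
        norm.to_csv(outdir / "atp_normalized.csv", index=False, float_format=CSV_FLOAT)
        result["normalized"] = norm
    return result


# ---------------------------------------------------------------------------
# parameter-recovery experiments (generate → render → segment → measure)
# ---------------------------------------------------------------------------


def _measure_scene_fractions(params: SceneParams, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Run the full pipeline on one simulated scene; tidy per-cell per-frame m."""
    cfg = cfg or RunConfig()
    scene = generate_scene(params)
    stack = render_timelapse(scene)
    _, fractions = analyze_live_stack(stack, cfg)
    rows = []
    for t, s in enumerate(fractions):
        for cid, m in s.items():
            rows.append({"frame": t, "cell_id": cid, "m": float(m)})
    return pd.DataFrame(rows)


def basal_mitophagy_recovery(
    rate: float,
    n_seeds: int = 3,
    base_seed: int = 0,
    n_cells: int = 50,
    mito_per_cell_mean: float = 20.0,
    n_frames: int = 10,
    cfg: RunConfig | None = None,
) -> dict:
    """Recover a basal engulfment rate from rendered scenes.

    Generates ``n_seeds`` replicate scenes at the given per-mitochondrion
    per-frame engulfment probability, runs segmentation and the
    100 %-overlap assay, and reports the grand mean per-cell fraction with
    its binomial standard error (computed from the number of mitochondrion ×
    frame Bernoulli draws).
    """
    tables, n_draws = [], 0
    for i in range(n_seeds):
        params = SceneParams(
            n_cells=n_cells,
            mito_per_cell_mean=mito_per_cell_mean,
            n_frames=n_frames,
            basal_engulf_prob=rate,
            seed=base_seed + i,
        )
        scene = generate_scene(params)
        n_draws += sum(c.n_mito for c in scene.cells) * n_frames
        stack = render_timelapse(scene)
        _, fractions = analyze_live_stack(stack, cfg or RunConfig())
        df = pd.concat(fractions).rename("m").reset_index()
        df["seed"] = params.seed
        tables.append(df)
    all_m = pd.concat(tables, ignore_index=True)
    grand = float(all_m["m"].mean())
    se = float(np.sqrt(rate * (1.0 - rate) / n_draws)) if n_draws else np.nan
    return {
        "grand_mean": grand,
        "binomial_se": se,
        "n_draws": n_draws,
        "n_cells_frames": len(all_m),
        "per_seed": all_m.groupby("seed")["m"].mean().to_dict(),
    }


def induced_mitophagy_recovery(
    plateau: float,
    n_seeds: int = 3,
    base_seed: int = 0,
    n_cells: int = 50,
    mito_per_cell_mean: float = 20.0,
    n_frames: int = 10,
    pre_frames: int = 2,
    basal: float = 0.09,
    cfg: RunConfig | None = None,
) -> dict:
    """Recover the post-induction plateau of an induced time course.

    The engulfment probability is ``basal`` for ``pre_frames`` frames and
    jumps to ``plateau`` at induction (sustained response, control-like).
    The plateau grand mean is measured over post-induction frames.
    """
    curve = tuple([basal] * pre_frames + [plateau] * (n_frames - pre_frames))
    tables, n_draws = [], 0
    for i in range(n_seeds):
        params = SceneParams(
            n_cells=n_cells,
            mito_per_cell_mean=mito_per_cell_mean,
            n_frames=n_frames,
            condition="induced",
            induced_engulf_curve=curve,
            seed=base_seed + i,
        )
        scene = generate_scene(params)
        n_draws += sum(c.n_mito for c in scene.cells) * (n_frames - pre_frames)
        stack = render_timelapse(scene)
        _, fractions = analyze_live_stack(stack, cfg or RunConfig())
        df = pd.concat(
            [s.rename("m").reset_index().assign(frame=t) for t, s in enumerate(fractions)],
            ignore_index=True,
        )
        df["seed"] = params.seed
        tables.append(df)
    all_m = pd.concat(tables, ignore_index=True)
    post = all_m[all_m["frame"] >= pre_frames]
    grand = float(post["m"].mean())
    se = float(np.sqrt(plateau * (1.0 - plateau) / n_draws)) if n_draws else np.nan
    frame_means = all_m.groupby("frame")["m"].mean()
    return {
        "plateau_grand_mean": grand,
        "binomial_se": se,
        "n_draws": n_draws,
        "frame_means": frame_means.to_dict(),
    }


def mito_number_normalization_recovery(
    ratio: float,
    control_mean: float = 10.0,
    n_cells: int = 50,
    n_seeds: int = 3,
    base_seed: int = 0,
    cfg: RunConfig | None = None,
) -> dict:
    """Recover a mitochondria-per-cell count ratio as percent of control.

    Control scenes use ``control_mean`` mitochondria per cell; mutant-like
    scenes scale that by ``ratio``.  Single-frame scenes are segmented and
    per-cell counts normalised to the measured control mean.
    """
    counts = {"control": [], "mutant": []}
    for i in range(n_seeds):
        for group, mean in (("control", control_mean), ("mutant", control_mean * ratio)):
            params = SceneParams(
                n_cells=n_cells,
                mito_per_cell_mean=mean,
                n_frames=1,
                basal_engulf_prob=0.0,
                seed=base_seed + 2 * i + (group == "mutant"),
            )
            scene = generate_scene(params)
            stack = render_timelapse(scene)
            maps = segment_frame(stack, 0, cfg or RunConfig())
            stats = mito_stats_per_cell(maps["mito"], maps["cells"], pixel_size=stack.pixel_size)
            counts[group].append(stats["mito_count"].to_numpy())
    ctrl = np.concatenate(counts["control"])
    mut = np.concatenate(counts["mutant"])
    values = np.concatenate([ctrl, mut]).astype(float)
    groups = np.array(["control"] * len(ctrl) + ["mutant"] * len(mut))
    norm = normalize_to_control(values, groups, "control")
    return {
        "mutant_pct_of_control": float(norm[groups == "mutant"].mean()),
        "control_pct_of_control": float(norm[groups == "control"].mean()),
        "control_mean_count": float(ctrl.mean()),
        "mutant_mean_count": float(mut.mean()),
    }


def atp_normalization_recovery(
    ratio: float,
    control_mean: float = 10.0,
    cv: float = 0.05,
    n_wells: int = 12,
    seed: int = 0,
) -> float:
    """Recover a group ATP ratio from simulated plates, as % of control."""
    ctrl = generate_atp_plate({"untreated": control_mean}, cv, n_wells, seed, group="control")
    mut = generate_atp_plate(
        {"untreated": control_mean * ratio}, cv, n_wells, seed + 1, group="mutant"
    )
    norm = normalize_atp([ctrl, mut], control_group="control")
    return float(norm.loc[norm["group"] == "mutant", "pct_of_control"].iloc[0])
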