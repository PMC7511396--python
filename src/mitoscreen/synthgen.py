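"""Ground-truthed synthetic fluorescence scenes, time-lapses and ATP plates.

The generator emulates the live high-content assay this package quantifies:
fields of neurons stained for nuclei (Hoechst), mitochondria (TMRM) and
lysosomes (Lysotracker), imaged in seven z-planes every 18 minutes.  Cells are
smoothed star-convex polygons whose elongation and spikiness are controlled by
``SceneParams``; each cell carries a set of small elliptical-to-round
mitochondria and a few constitutive lysosomes.  Mitophagy is modelled per
mitochondrion per frame: in a frame where a mitochondrion is engulfed, a
lysosome envelops it in place, so its mask is wholly contained in a lysosome
mask — exactly the event the 100 %-overlap assay scores.  Engulfment is
reversible between frames (lysosomal turnover), which keeps the per-frame
cross-sectional engulfed fraction equal to the engulfment probability.

Every scene records its own ground truth (object geometry, per-frame engulfed
states, per-cell engulfed fractions), so downstream segmentation and assay
code can be validated without real images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from scipy.ndimage import binary_erosion

from .datatypes import ImageStack

ATP_CONDITIONS = ("untreated", "oligomycin", "2DG", "both")


class GeometryError(ValueError):
    """Requested object density cannot be realised in the field."""


@dataclass
class NoiseModel:
    """Additive Gaussian read noise plus Poisson shot noise.

    ``poisson_scale`` is the photon gain (photons per intensity unit); 0
    disables shot noise.  ``gaussian_sd`` is in intensity units.
    """

    gaussian_sd: float = 40.0
    poisson_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SceneParams:
    """Parameters of one synthetic field.

    Defaults describe a day-27 control-like field: 50 cells with ~20
    mitochondria each, basal engulfment probability 0.09 per mitochondrion per
    frame, 10 frames at 18-minute spacing, 7 z-planes, 0.3 µm pixels.
    """

    n_cells: int = 50
    cell_roundness_target: float = 1.4
    cell_elongation_ratio: float = 1.7
    cell_radius_um: float = 9.0
    mito_per_cell_mean: float = 20.0
    mito_area_mean: float = 0.9  # µm²
    mito_intensity_mean: float = 3000.0
    mito_intensity_cv: float = 0.1
    lyso_per_cell_mean: float = 4.0
    basal_engulf_prob: float = 0.09
    induced_engulf_curve: tuple[float, ...] | None = None
    condition: str = "basal"
    n_frames: int = 10
    frame_interval: float = 18.0
    n_z: int = 7
    pixel_size: float = 0.3  # µm / pixel
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # secondary stains (rendered as extra channels when set)
    nuclei_intensity: float = 2000.0
    lyso_intensity: float = 3000.0
    cytoplasm_intensity_frac: float = 0.08
    ros_intensity_mean: float | None = None
    marker_positive_fraction: float | None = None
    marker_intensity: float = 1500.0
    spot_positive_fraction: float | None = None
    spots_per_positive_cell: float = 2.0
    spot_intensity: float = 4000.0

    def __post_init__(self) -> None:
        if isinstance(self.noise_model, dict):
            self.noise_model = NoiseModel(**self.noise_model)
        if self.n_cells < 0 or self.mito_per_cell_mean < 0 or self.lyso_per_cell_mean < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.basal_engulf_prob <= 1.0:
            raise ValueError("basal_engulf_prob must be in [0, 1]")
        if self.cell_roundness_target < 1 or self.cell_elongation_ratio < 1:
            raise ValueError("roundness and elongation targets must be >= 1")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if self.n_frames < 1 or self.n_z < 1:
            raise ValueError("n_frames and n_z must be >= 1")
        if self.condition not in ("basal", "induced"):
            raise ValueError("condition must be 'basal' or 'induced'")
        if self.condition == "induced":
            if self.induced_engulf_curve is None:
                raise ValueError("induced condition requires induced_engulf_curve")
            curve = tuple(float(p) for p in self.induced_engulf_curve)
            if len(curve) != self.n_frames:
                raise ValueError(
                    f"induced_engulf_curve has {len(curve)} entries for "
                    f"{self.n_frames} frames"
                )
            if min(curve) < 0 or max(curve) > 1:
                raise ValueError("engulfment probabilities must be in [0, 1]")
            self.induced_engulf_curve = curve
        for frac in (self.marker_positive_fraction, self.spot_positive_fraction):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")

    def engulf_prob(self, frame: int) -> float:
        if self.condition == "induced":
            return self.induced_engulf_curve[frame]
        return self.basal_engulf_prob


@dataclass
class CellTruth:
    """Ground-truth geometry and state of one synthetic cell."""

    cell_id: int
    center: tuple[float, float]
    z_focus: int
    polygon: np.ndarray  # (n_vertices, 2) row/col
    mito_centers: np.ndarray  # (n_mito, 2)
    mito_intensities: np.ndarray  # (n_mito,)
    lyso_centers: np.ndarray  # (n_lyso, 2)
    engulfed: np.ndarray  # (n_mito, n_frames) bool
    marker_positive: bool = False
    spot_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @property
    def n_mito(self) -> int:
        return len(self.mito_centers)


@dataclass
class SyntheticScene:
    """A generated field with full ground truth."""

    params: SceneParams
    field_shape: tuple[int, int]
    mito_radius_px: float
    lyso_radius_px: float
    nucleus_radii_px: tuple[float, float]
    cells: list[CellTruth]
    cell_labels: np.ndarray  # (Y, X) ground-truth cell label map
    nucleus_labels: np.ndarray
    ground_truth_fractions: np.ndarray  # (n_cells, n_frames), NaN for 0-mito cells

    def ground_truth_table(self):
        """Tidy per-cell per-frame ground truth (mito and engulfed counts)."""
        import pandas as pd

        rows = []
        for cell in self.cells:
            for t in range(self.params.n_frames):
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "frame": t,
                        "minutes": t * self.params.frame_interval,
                        "mito_count": cell.n_mito,
                        "engulfed_count": int(cell.engulfed[:, t].sum()),
                    }
                )
        return pd.DataFrame(rows)


def _star_polygon(
    rng: np.random.Generator,
    radius_px: float,
    elongation: float,
    roundness_target: float,
    n_vertices: int = 48,
) -> np.ndarray:
    """Smoothed star-convex polygon with exact second-moment elongation.

    The base boundary is a unit circle modulated by low-order random
    harmonics whose amplitude grows with the requested roundness (spikier =
    less round).  The polygon is whitened by its own second-moment matrix and
    rescaled so the final shape has exactly the requested second-moment axis
    ratio and an area close to a disk of ``radius_px``.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    amp = _spike_amplitude(roundness_target, elongation)
    r = np.ones_like(theta)
    for k in (3, 4, 5, 6):
        a, b = rng.normal(0.0, 1.0, 2)
        r += amp * (a * np.cos(k * theta) + b * np.sin(k * theta)) / 4.0
    r = np.clip(r, 0.35, None)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    cen, cov = _polygon_moments(pts)
    pts -= cen
    evals, evecs = np.linalg.eigh(cov)
    white = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    pts = pts @ white.T
    # unit-covariance shape has disk-equivalent radius 2 (disk cov = r²/4 · I)
    sa = radius_px * np.sqrt(elongation) / 2.0
    sb = radius_px / np.sqrt(elongation) / 2.0
    pts = pts @ np.diag([sa, sb])
    ang = rng.uniform(0.0, np.pi)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return pts @ rot.T


def _spike_amplitude(roundness_target: float, elongation: float) -> float:
    """Monotone mapping from requested boundary roundness to harmonic amplitude.

    An ellipse of the requested elongation already has roundness
    P²/(4πA) > 1; spikes only add to it, so targets at or below the ellipse
    value yield a smooth boundary.
    """
    a, b = np.sqrt(elongation), 1.0 / np.sqrt(elongation)
    h = ((a - b) / (a + b)) ** 2
    perim = np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    r_ellipse = perim**2 / (4.0 * np.pi * np.pi * a * b)
    return float(np.clip(0.3 * np.sqrt(max(roundness_target - r_ellipse, 0.0)), 0.0, 0.35))


def _polygon_moments(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and area-normalised second-moment matrix of a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    x, y = x - cx, y - cy
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    ixx = ((x**2 + x * xn + xn**2) * cross).sum() / 12.0
    iyy = ((y**2 + y * yn + yn**2) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    cov = np.array([[ixx, ixy], [ixy, iyy]]) / area
    return np.array([cx, cy]), cov


def _place_points(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_sep: float = 0.0,
    max_attempts: int = 4000,
) -> np.ndarray:
    """Sample ``n`` points on True pixels of ``allowed`` with pairwise
    separation ``min_sep`` and distance ``avoid_sep`` from ``avoid`` points."""
    coords = np.argwhere(allowed)
    if len(coords) == 0 and n > 0:
        raise GeometryError(
            "no admissible pixels: objects plus their clearance do not fit "
            "inside the cell at the requested size"
        )
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise GeometryError(
                f"could only place {len(placed)}/{n} objects at minimum "
                f"separation {min_sep:.1f} px — requested density too high"
            )
        attempts += 1
        p = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, 2)
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < min_sep:
            continue
        if avoid is not None and len(avoid) and (
            np.min(np.linalg.norm(avoid - p, axis=1)) < avoid_sep
        ):
            continue
        placed.append(p)
    return np.array(placed).reshape(n, 2)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate the ground-truth geometry and engulfment dynamics of a field.

    Deterministic for a fixed ``params.seed``; geometry and engulfment use RNG
    sub-streams separate from rendering noise, so scenes are stable when only
    the noise model changes.
    """
    seq = np.random.SeedSequence(params.seed)
    geom_rng, engulf_rng, _ = [np.random.default_rng(s) for s in seq.spawn(3)]

    r_cell = params.cell_radius_um / params.pixel_size
    r_mito = float(np.sqrt(params.mito_area_mean / np.pi) / params.pixel_size)
    r_lyso = r_mito + 3.0
    mito_sep = 2.0 * r_mito + 2.0  # disjoint masks with a 1-px guard band
    amp = _spike_amplitude(params.cell_roundness_target, params.cell_elongation_ratio)
    bound = r_cell * np.sqrt(params.cell_elongation_ratio) * (1.0 + 2.5 * amp) + 2.0
    spacing = int(np.ceil(2.0 * bound + 6.0))

    n_cols = int(np.ceil(np.sqrt(max(params.n_cells, 1))))
    n_rows = int(np.ceil(max(params.n_cells, 1) / n_cols))
    shape = (n_rows * spacing, n_cols * spacing)

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    erode_px = int(np.ceil(r_lyso)) + 1
    erode_fp = _disk_footprint(erode_px)
    cells: list[CellTruth] = []

    for idx in range(params.n_cells):
        cid = idx + 1
        row, col = divmod(idx, n_cols)
        center = np.array(
            [row * spacing + spacing / 2.0, col * spacing + spacing / 2.0]
        ) + geom_rng.uniform(-2.0, 2.0, 2)
        poly = _star_polygon(
            geom_rng, r_cell, params.cell_elongation_ratio, params.cell_roundness_target
        ) + center
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
        if len(rr) < 10:
            raise GeometryError("degenerate cell polygon — cell radius too small")
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        if (cell_labels[mask] != 0).any():
            raise GeometryError("cells overlap — requested cell size too large for the grid")
        cell_labels[mask] = cid

        # nucleus: ellipse-ish disk at the cell centre
        rn = max(0.3 * r_cell, 3.0)
        nrr, ncc = draw_disk(tuple(center), rn, shape=shape)
        nucleus_labels[nrr, ncc] = cid

        sub = mask[
            max(int(center[0] - bound) - 1, 0) : int(center[0] + bound) + 2,
            max(int(center[1] - bound) - 1, 0) : int(center[1] + bound) + 2,
        ]
        off = np.array(
            [max(int(center[0] - bound) - 1, 0), max(int(center[1] - bound) - 1, 0)]
        )
        allowed = binary_erosion(sub, structure=erode_fp)

        n_mito = _truncated_poisson(geom_rng, params.mito_per_cell_mean, allowed, mito_sep)
        mito = _place_points(geom_rng, allowed, n_mito, mito_sep) + off if n_mito else np.zeros((0, 2))
        n_lyso = int(geom_rng.poisson(params.lyso_per_cell_mean))
        lyso = (
            _place_points(
                geom_rng,
                allowed,
                n_lyso,
                min_sep=2.0,
                # a constitutive lysosome may touch a mitochondrion but must
                # never fully contain one (that would fake an event)
                avoid=mito - off if n_mito else None,
                avoid_sep=(r_lyso - r_mito) + 1.5,
            )
            + off
            if n_lyso
            else np.zeros((0, 2))
        )

        intens = params.mito_intensity_mean * np.clip(
            1.0 + params.mito_intensity_cv * geom_rng.standard_normal(n_mito), 0.2, None
        )
        marker_pos = (
            bool(geom_rng.random() < params.marker_positive_fraction)
            if params.marker_positive_fraction is not None
            else False
        )
        spots = np.zeros((0, 2))
        if params.spot_positive_fraction is not None and geom_rng.random() < params.spot_positive_fraction:
            n_spots = max(1, int(geom_rng.poisson(params.spots_per_positive_cell)))
            spots = _place_points(geom_rng, allowed, n_spots, min_sep=6.0) + off

        cells.append(
            CellTruth(
                cell_id=cid,
                center=tuple(center),
                z_focus=int(geom_rng.integers(1, max(params.n_z - 1, 2))),
                polygon=poly,
                mito_centers=mito,
                mito_intensities=intens,
                lyso_centers=lyso,
                engulfed=np.zeros((n_mito, params.n_frames), dtype=bool),
                marker_positive=marker_pos,
                spot_centers=spots,
            )
        )

    # engulfment dynamics: independent Bernoulli per mitochondrion per frame
    fractions = np.full((params.n_cells, params.n_frames), np.nan)
    for i, cell in enumerate(cells):
        for t in range(params.n_frames):
            p = params.engulf_prob(t)
            if cell.n_mito:
                cell.engulfed[:, t] = engulf_rng.random(cell.n_mito) < p
                fractions[i, t] = cell.engulfed[:, t].mean()

    return SyntheticScene(
        params=params,
        field_shape=shape,
        mito_radius_px=r_mito,
        lyso_radius_px=r_lyso,
        nucleus_radii_px=(max(0.3 * r_cell, 3.0),) * 2,
        cells=cells,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        ground_truth_fractions=fractions,
    )


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _truncated_poisson(
    rng: np.random.Generator, mean: float, allowed: np.ndarray, min_sep: float
) -> int:
    """Poisson count truncated to what provably packs into the allowed region."""
    cap = int(0.62 * allowed.sum() / (0.866 * min_sep**2))
    n = int(rng.poisson(mean))
    if mean > 0 and cap < mean + np.sqrt(mean):
        raise GeometryError(
            f"cell can hold at most ~{cap} mitochondria at separation "
            f"{min_sep:.1f} px but {mean:.1f} per cell were requested"
        )
    return min(n, cap)


def render_frame(scene: SyntheticScene, frame: int) -> tuple[np.ndarray, list[str]]:
    """Noise-free in-focus multichannel image ``(C, Y, X)`` of one frame."""
    p = scene.params
    shape = scene.field_shape
    chans: dict[str, np.ndarray] = {}

    nuc = np.zeros(shape, dtype=np.float64)
    nuc[scene.nucleus_labels > 0] = p.nuclei_intensity
    chans["nuclei"] = nuc

    mito_img = np.zeros(shape, dtype=np.float64)
    mito_img[scene.cell_labels > 0] = p.cytoplasm_intensity_frac * p.mito_intensity_mean
    lyso_img = np.zeros(shape, dtype=np.float64)
    ros_img = np.zeros(shape, dtype=np.float64) if p.ros_intensity_mean is not None else None
    marker_img = (
        np.zeros(shape, dtype=np.float64) if p.marker_positive_fraction is not None else None
    )
    spots_img = (
        np.zeros(shape, dtype=np.float64) if p.spot_positive_fraction is not None else None
    )

    for cell in scene.cells:
        for j in range(cell.n_mito):
            rr, cc = draw_disk(tuple(cell.mito_centers[j]), scene.mito_radius_px, shape=shape)
            mito_img[rr, cc] = np.maximum(mito_img[rr, cc], cell.mito_intensities[j])
            if ros_img is not None:
                ros_img[rr, cc] = np.maximum(ros_img[rr, cc], p.ros_intensity_mean)
            if cell.engulfed[j, frame]:
                lr, lc = draw_disk(
                    tuple(cell.mito_centers[j]), scene.lyso_radius_px, shape=shape
                )
                lyso_img[lr, lc] = p.lyso_intensity
        for k in range(len(cell.lyso_centers)):
            lr, lc = draw_disk(tuple(cell.lyso_centers[k]), scene.lyso_radius_px, shape=shape)
            lyso_img[lr, lc] = p.lyso_intensity
        if marker_img is not None and cell.marker_positive:
            marker_img[scene.cell_labels == cell.cell_id] = p.marker_intensity
        if spots_img is not None:
            for s in cell.spot_centers:
                sr, sc = draw_disk(tuple(s), 1.6, shape=shape)
                spots_img[sr, sc] = p.spot_intensity

    chans["mitochondria"] = mito_img
    chans["lysosomes"] = lyso_img
    if ros_img is not None:
        chans["ros"] = ros_img
    if marker_img is not None:
        chans["marker"] = marker_img
    if spots_img is not None:
        chans["spots"] = spots_img
    names = list(chans)
    return np.stack([chans[n] for n in names]), names


def _render_lysosomes(scene: SyntheticScene, frame: int) -> np.ndarray:
    """Noise-free in-focus lysosome channel of one frame."""
    p = scene.params
    lyso_img = np.zeros(scene.field_shape, dtype=np.float64)
    for cell in scene.cells:
        for j in range(cell.n_mito):
            if cell.engulfed[j, frame]:
                lr, lc = draw_disk(
                    tuple(cell.mito_centers[j]), scene.lyso_radius_px, shape=scene.field_shape
                )
                lyso_img[lr, lc] = p.lyso_intensity
        for k in range(len(cell.lyso_centers)):
            lr, lc = draw_disk(
                tuple(cell.lyso_centers[k]), scene.lyso_radius_px, shape=scene.field_shape
            )
            lyso_img[lr, lc] = p.lyso_intensity
    return lyso_img


def render_timelapse(scene: SyntheticScene) -> ImageStack:
    """Render the scene to a noisy 16-bit ``[T, Z, C, Y, X]`` stack.

    Object intensity is spread across z with a Gaussian focus profile whose
    peak plane (weight 1) is each cell's focal plane, so a per-pixel maximum
    over Z recovers the in-focus image exactly.  Noise (Poisson shot noise
    then Gaussian read noise) is applied after rendering, from an RNG
    sub-stream independent of the geometry, and values are clipped to the
    16-bit range with a warning on saturation.
    """
    p = scene.params
    seq = np.random.SeedSequence(p.seed)
    noise_rng = np.random.default_rng(seq.spawn(3)[2])
    shape = scene.field_shape

    z_focus = np.zeros(shape, dtype=np.float64)
    for cell in scene.cells:
        z_focus[scene.cell_labels == cell.cell_id] = cell.z_focus
    sigma_z = 1.5
    zw = np.empty((p.n_z,) + shape, dtype=np.float64)
    for z in range(p.n_z):
        zw[z] = np.exp(-((z - z_focus) ** 2) / (2.0 * sigma_z**2))

    frame0, names = render_frame(scene, 0)
    n_c = frame0.shape[0]
    lyso_c = names.index("lysosomes")
    out = np.empty((p.n_frames, p.n_z, n_c, *shape), dtype=np.uint16)
    nm = p.noise_model
    focus = frame0
    saturated = False
    for t in range(p.n_frames):  # noise applied per frame to bound memory
        if t > 0:  # only the lysosome channel changes between frames
            focus[lyso_c] = _render_lysosomes(scene, t)
        planes = focus[None, :, :, :] * zw[:, None, :, :]
        if nm.poisson_scale > 0:
            planes = noise_rng.poisson(planes * nm.poisson_scale) / nm.poisson_scale
        if nm.gaussian_sd > 0:
            planes = planes + noise_rng.normal(0.0, nm.gaussian_sd, size=planes.shape)
        np.rint(planes, out=planes)
        saturated |= bool(planes.max() > 65535)
        np.clip(planes, 0, 65535, out=planes)
        out[t] = planes.astype(np.uint16)
    if saturated:
        warnings.warn("rendered intensities exceed 16-bit range; clipping", stacklevel=2)
    return ImageStack(
        pixels=out,
        pixel_size=p.pixel_size,
        frame_interval=p.frame_interval,
        channel_names=names,
    )


def generate_atp_plate(
    group_means: dict[str, float],
    cv: float,
    n_wells: int,
    seed: int,
    day: int | None = None,
    group: str = "control",
):
    """Simulate an inhibitor-assay luminescence plate.

    Wells are drawn from a Gamma distribution with mean equal to the
    condition mean and coefficient of variation ``cv`` (positive-valued by
    construction; ``cv = 0`` gives wells exactly at the means).
    """
    from .metabolics import ATPPlate

    unknown = set(group_means) - set(ATP_CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}; allowed: {ATP_CONDITIONS}")
    if "untreated" not in group_means:
        raise ValueError("untreated condition is required — the partition is undefined without it")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ATP_CONDITIONS:
        if cond not in group_means:
            continue
        mean = float(group_means[cond])
        if cv == 0 or mean == 0:
            values = np.full(n_wells, mean)
        else:
            shape_k = 1.0 / cv**2
            values = rng.gamma(shape_k, mean / shape_k, size=n_wells)
        for i, v in enumerate(values):
            rows.append({"well_id": f"{cond}_{i:02d}", "condition": cond, "luminescence": v})
    import pandas as pd

    return ATPPlate(wells=pd.DataFrame(rows), day=day, group=group)


def scene_params_dict(params: SceneParams) -> dict:
    """JSON/YAML-serialisable copy of the generator parameters."""
    d = asdict(params)
    if d.get("induced_engulf_curve") is not None:
        d["induced_engulf_curve"] = list(d["induced_engulf_curve"])
    return d
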