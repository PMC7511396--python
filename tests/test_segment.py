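"""Segmentation stack: projection oracle, round trips against generator
ground truth, invariances, and the marker/spot readouts."""

import numpy as np
import pytest

import mitoscreen as ms
from mitoscreen.config import RunConfig
from mitoscreen.datatypes import ImageStack, LabelMap
from mitoscreen.segment import (
    detect_spots,
    marker_positive_fraction,
    max_project,
    segment_cells,
    segment_nuclei,
    segment_organelles,
)
from mitoscreen.workflows import segment_frame


def as_stack(planes, channels=1):
    """Z-stack of one frame/channel from a list of 2-D planes."""
    arr = np.asarray(planes, dtype=np.float64)[None, :, None, :, :]
    arr = np.repeat(arr, channels, axis=2)
    return ImageStack(pixels=arr, pixel_size=1.0, channel_names=[f"c{i}" for i in range(channels)])


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        img = rng.random((1, 6, 6))
        stack = as_stack(img)
        assert np.array_equal(max_project(stack, 0)[0], img[0])

    def test_pixelwise_maximum(self):
        planes = np.zeros((3, 2, 2))
        planes[:, 0, 0] = [0, 5, 3]
        assert max_project(as_stack(planes), 0)[0][0, 0] == 5

    def test_dominates_every_plane(self, rng):
        planes = rng.random((7, 16, 16))
        proj = max_project(as_stack(planes), 0)[0]
        assert (proj[None] >= planes).all()
        # exhaustive oracle: elementwise max equals reduce over planes
        assert np.array_equal(proj, np.maximum.reduce(planes))

    def test_commutes_with_monotone_transform(self, rng):
        planes = rng.random((4, 8, 8))
        f = np.sqrt
        assert np.allclose(
            f(max_project(as_stack(planes), 0)[0]), max_project(as_stack(f(planes)), 0)[0]
        )

    def test_frame_out_of_range(self, rng):
        with pytest.raises(IndexError):
            max_project(as_stack(rng.random((2, 4, 4))), 3)


class TestNuclei:
    def test_noise_free_scene_exact_count(self, clean_scene, clean_stack, run_config):
        proj = max_project(clean_stack, 0)
        nm = segment_nuclei(proj, clean_stack.channel_names, run_config.segmentation)
        assert nm.n_objects == clean_scene.params.n_cells

    def test_blank_image_zero_labels(self):
        proj = np.zeros((1, 64, 64))
        nm = segment_nuclei(proj, ["nuclei"])
        assert nm.n_objects == 0

    def test_noisy_count_within_five_percent(self):
        """Nucleus counts across replicate noisy scenes stay within 5 % of truth."""
        errs = []
        for seed in range(20):
            scene = ms.generate_scene(ms.SceneParams(n_cells=6, n_frames=1, seed=100 + seed))
            stack = ms.render_timelapse(scene)
            nm = segment_nuclei(max_project(stack, 0), stack.channel_names)
            errs.append(nm.n_objects - 6)
        assert abs(np.mean(errs)) / 6 <= 0.05


class TestCells:
    def test_isolated_cell_mask_covers_ground_truth(self, run_config):
        scene = ms.generate_scene(ms.SceneParams(n_cells=1, n_frames=1, seed=9))
        stack = ms.render_timelapse(scene)
        maps = segment_frame(stack, 0, run_config)
        gt = scene.cell_labels > 0
        seg = maps["cells"].labels > 0
        iou = (gt & seg).sum() / (gt | seg).sum()
        assert iou >= 0.90

    def test_two_cells_disjoint_each_containing_nucleus(self, small_maps):
        cells, nuclei = small_maps["cells"], small_maps["nuclei"]
        assert cells.n_objects == nuclei.n_objects
        for nid in nuclei.ids:
            owners = cells.labels[nuclei.labels == nid]
            assert (owners == owners[0]).all() and owners[0] > 0

    def test_nucleus_label_permutation_invariance(self, clean_stack, run_config):
        proj = max_project(clean_stack, 0)
        names = clean_stack.channel_names
        nuclei = segment_nuclei(proj, names, run_config.segmentation)
        perm = np.zeros(nuclei.n_objects + 1, dtype=nuclei.labels.dtype)
        perm[1:] = np.roll(np.arange(1, nuclei.n_objects + 1), 1)
        permuted = LabelMap(perm[nuclei.labels], "nucleus")
        a = segment_cells(proj, names, nuclei, run_config.segmentation)
        b = segment_cells(proj, names, permuted, run_config.segmentation)
        assert np.array_equal(a.labels > 0, b.labels > 0)
        assert np.array_equal(perm[a.labels], b.labels)

    def test_no_nuclei_empty_map(self):
        proj = np.zeros((3, 32, 32))
        names = ["nuclei", "mitochondria", "lysosomes"]
        nuclei = segment_nuclei(proj, names)
        cells = segment_cells(proj, names, nuclei)
        assert cells.n_objects == 0


class TestOrganelles:
    def test_noise_free_counts_exact_per_cell(self, clean_scene, clean_maps):
        from mitoscreen.morphometrics import mito_stats_per_cell

        stats = mito_stats_per_cell(clean_maps["mito"], clean_maps["cells"])
        truth = {c.cell_id: c.n_mito for c in clean_scene.cells}
        seg_cells = clean_maps["cells"]
        # map segmented cell ids to ground-truth ids by nucleus position
        for _, row in stats.iterrows():
            gt_ids = clean_scene.cell_labels[seg_cells.labels == row["cell_id"]]
            gt_id = np.bincount(gt_ids[gt_ids > 0]).argmax()
            assert row["mito_count"] == truth[gt_id]

    def test_min_area_filter_excludes_small_objects(self):
        proj = np.zeros((3, 40, 40))
        names = ["nuclei", "mitochondria", "lysosomes"]
        cells = LabelMap(np.ones((40, 40), dtype=np.int32), "cell")
        proj[1, 10, 10] = 1000.0  # single pixel < min_area 3
        proj[1, 25:28, 25:28] = 1000.0  # 9 px object
        lm = segment_organelles(proj, names, cells, "mitochondrion")
        assert lm.n_objects == 1
        assert lm.labels[10, 10] == 0 and lm.labels[26, 26] == 1

    def test_unknown_class_rejected(self, small_maps, small_stack):
        proj = max_project(small_stack, 0)
        with pytest.raises(ValueError, match="organelle"):
            segment_organelles(proj, small_stack.channel_names, small_maps["cells"], "peroxisome")

    def test_labels_never_cross_cell_boundaries(self, small_maps):
        for key in ("mito", "lyso"):
            org = small_maps[key]
            cells = small_maps["cells"]
            for oid in org.ids:
                owners = cells.labels[org.labels == oid]
                assert (owners > 0).all() and len(np.unique(owners)) == 1

    def test_noisy_counts_within_five_percent_on_average(self):
        rel = []
        for seed in range(10):
            scene = ms.generate_scene(
                ms.SceneParams(n_cells=4, n_frames=1, basal_engulf_prob=0.0, seed=300 + seed)
            )
            stack = ms.render_timelapse(scene)
            maps = segment_frame(stack, 0, RunConfig())
            truth = sum(c.n_mito for c in scene.cells)
            rel.append((maps["mito"].n_objects - truth) / truth)
        assert abs(np.mean(rel)) <= 0.05


class TestTranslationEquivariance:
    def test_shifted_input_gives_shifted_masks(self, clean_stack, run_config):
        proj = max_project(clean_stack, 0)
        names = clean_stack.channel_names
        base = segment_nuclei(proj, names, run_config.segmentation)
        dy, dx = 7, -5
        shifted = np.roll(proj, (dy, dx), axis=(1, 2))
        moved = segment_nuclei(shifted, names, run_config.segmentation)
        assert np.array_equal(np.roll(base.labels > 0, (dy, dx), axis=(0, 1)), moved.labels > 0)


@pytest.fixture(scope="module")
def marker_scene():
    params = ms.SceneParams(
        n_cells=36,
        n_frames=1,
        seed=13,
        marker_positive_fraction=0.899,
        spot_positive_fraction=0.15,
    )
    scene = ms.generate_scene(params)
    stack = ms.render_timelapse(scene)
    maps = segment_frame(stack, 0, RunConfig())
    return scene, stack, maps


class TestSpotsAndMarkers:
    def test_spot_counts_exact_on_clean_channel(self):
        params = ms.SceneParams(
            n_cells=4, n_frames=1, seed=17, spot_positive_fraction=1.0,
            noise_model=ms.NoiseModel(0.0, 0.0),
        )
        scene = ms.generate_scene(params)
        stack = ms.render_timelapse(scene)
        maps = segment_frame(stack, 0, RunConfig())
        proj = stack.pixels[0].max(axis=0)
        table = detect_spots(proj, stack.channel_names, maps["cells"])
        truth = {c.cell_id: len(c.spot_centers) for c in scene.cells}
        for _, row in table.iterrows():
            gt_ids = scene.cell_labels[maps["cells"].labels == row["cell_id"]]
            gt_id = np.bincount(gt_ids[gt_ids > 0]).argmax()
            assert row["spot_count"] == truth[gt_id]

    def test_blank_channel_zero_spots(self, small_maps, small_stack):
        proj = np.concatenate([small_stack.pixels[0].max(axis=0), np.zeros((1, *small_maps["cells"].labels.shape))])
        names = small_stack.channel_names + ["spots"]
        table = detect_spots(proj, names, small_maps["cells"])
        assert (table["spot_count"] == 0).all()

    def test_spot_positivity_fraction_recovered(self, marker_scene):
        scene, stack, maps = marker_scene
        proj = stack.pixels[0].max(axis=0)
        table = detect_spots(proj, stack.channel_names, maps["cells"])
        truth_frac = np.mean([len(c.spot_centers) > 0 for c in scene.cells])
        se = np.sqrt(0.15 * 0.85 / len(scene.cells))
        assert abs(table["positive"].mean() - truth_frac) <= 2 * se

    def test_marker_positive_percentage_recovered(self, marker_scene):
        scene, stack, maps = marker_scene
        proj = stack.pixels[0].max(axis=0)
        pct, _ = marker_positive_fraction(proj, stack.channel_names, maps["cells"])
        truth_pct = 100.0 * np.mean([c.marker_positive for c in scene.cells])
        assert pct == pytest.approx(truth_pct, abs=1e-9)
        se = 100.0 * np.sqrt(0.899 * 0.101 / len(scene.cells))
        assert abs(pct - 89.9) <= 2 * se

    def test_all_or_none_marker(self, clean_stack, clean_maps):
        cells = clean_maps["cells"]
        proj = clean_stack.pixels[0].max(axis=0)
        on = np.concatenate([proj, np.where(cells.labels > 0, 900.0, 0.0)[None]])
        names = clean_stack.channel_names + ["marker"]
        pct_on, _ = marker_positive_fraction(on, names, cells)
        assert pct_on == 100.0
        off = np.concatenate([proj, np.zeros_like(proj[:1])])
        pct_off, _ = marker_positive_fraction(off, names, cells)
        assert pct_off == 0.0

    def test_zero_cells_is_an_error_not_zero_percent(self):
        cells = LabelMap(np.zeros((8, 8), dtype=np.int32), "cell")
        with pytest.raises(ValueError, match="no cells"):
            marker_positive_fraction(np.zeros((1, 8, 8)), ["marker"], cells)
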