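"""The 100 %-overlap event rule (with a brute-force containment oracle),
per-cell fractions, time-course assembly and fixed-assay validations."""

import numpy as np
import pandas as pd
import pytest

import mitoscreen as ms
from mitoscreen.datatypes import LabelMap
from mitoscreen.mitophagy import (
    assemble_timecourse,
    detect_mitophagy_events,
    lc3_tomm20_colocalization,
    mitophagy_fraction_per_cell,
    overlap_fractions,
    tomm20_loss_readout,
)


def lm(arr, cls):
    return LabelMap(np.asarray(arr, dtype=np.int32), cls)


class TestContainmentRule:
    def test_full_containment_is_one_event(self):
        mito = np.zeros((10, 10), dtype=int)
        mito[4:6, 4:6] = 1
        lyso = np.zeros((10, 10), dtype=int)
        lyso[3:7, 3:7] = 1
        ev = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(lyso, "lysosome"))
        assert len(ev) == 1
        assert ev["overlap_fraction"].iloc[0] == 1.0

    def test_half_overlap_is_no_event_at_default_threshold(self):
        mito = np.zeros((10, 10), dtype=int)
        mito[4:6, 4:6] = 1
        lyso = np.zeros((10, 10), dtype=int)
        lyso[4:6, 5:8] = 1  # covers 2 of 4 mito pixels
        ev = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(lyso, "lysosome"))
        assert len(ev) == 0

    def test_empty_maps_empty_list(self):
        z = np.zeros((5, 5), dtype=int)
        ev = detect_mitophagy_events(lm(z, "mitochondrion"), lm(z, "lysosome"))
        assert len(ev) == 0

    def test_brute_force_oracle_all_3x3_masks(self):
        """All 2^9 binary 3x3 mitochondrion patterns against a fixed
        lysosome map must agree with pixel-set containment."""
        lyso = np.zeros((7, 7), dtype=int)
        lyso[1:4, 1:4] = 1  # one lysosome covering rows/cols 1..3
        lyso[4:6, 4:6] = 2  # a second, separate lysosome
        lyso_map = lm(lyso, "lysosome")
        for bits in range(1, 2**9):
            patch = np.array([(bits >> k) & 1 for k in range(9)]).reshape(3, 3)
            mito = np.zeros((7, 7), dtype=int)
            mito[1:4, 1:4] = patch
            pixels = set(zip(*np.nonzero(mito)))
            contained = any(
                pixels <= set(zip(*np.nonzero(lyso == lab))) for lab in (1, 2)
            )
            ev = detect_mitophagy_events(lm(mito, "mitochondrion"), lyso_map)
            assert (len(ev) == 1) == contained, f"pattern {bits}"

    def test_single_lysosome_vs_union_mode(self):
        # mito straddles two touching lysosomes: union contains it, no single one does
        mito = np.zeros((5, 8), dtype=int)
        mito[2, 2:6] = 1
        lyso = np.zeros((5, 8), dtype=int)
        lyso[1:4, 1:4] = 1
        lyso[1:4, 4:7] = 2
        single = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(lyso, "lysosome"), mode="single")
        union = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(lyso, "lysosome"), mode="union")
        assert len(single) == 0 and len(union) == 1

    def test_at_most_one_event_per_mito_per_frame(self, small_maps):
        ev = detect_mitophagy_events(small_maps["mito"], small_maps["lyso"], cells=small_maps["cells"])
        assert ev["mito_label"].is_unique

    def test_event_count_monotone_in_threshold(self, small_maps):
        counts = [
            len(
                detect_mitophagy_events(
                    small_maps["mito"], small_maps["lyso"], overlap_threshold=thr
                )
            )
            for thr in (1.0, 0.8, 0.5, 0.2, 0.05)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_overlap_fraction_bounds(self, small_maps):
        frac = overlap_fractions(small_maps["mito"], small_maps["lyso"])
        assert frac["overlap_fraction"].between(0, 1).all()

    def test_invalid_threshold_rejected(self, small_maps):
        with pytest.raises(ValueError):
            detect_mitophagy_events(small_maps["mito"], small_maps["lyso"], overlap_threshold=0.0)


class TestPerCellFraction:
    def test_zero_events_zero_fraction(self):
        m = mitophagy_fraction_per_cell(
            pd.DataFrame(columns=["cell_id", "mito_label"]), pd.Series({1: 20})
        )
        assert m[1] == 0.0

    def test_all_engulfed_fraction_one(self):
        events = pd.DataFrame({"cell_id": [1] * 20, "mito_label": range(20)})
        m = mitophagy_fraction_per_cell(events, pd.Series({1: 20}))
        assert m[1] == 1.0

    def test_zero_mito_cells_excluded(self, caplog):
        m = mitophagy_fraction_per_cell(
            pd.DataFrame(columns=["cell_id", "mito_label"]), pd.Series({1: 10, 2: 0})
        )
        assert list(m.index) == [1]

    def test_fraction_in_unit_interval_on_pipeline_output(self, small_maps):
        from mitoscreen.morphometrics import mito_stats_per_cell

        ev = detect_mitophagy_events(
            small_maps["mito"], small_maps["lyso"], cells=small_maps["cells"]
        )
        counts = mito_stats_per_cell(small_maps["mito"], small_maps["cells"]).set_index(
            "cell_id"
        )["mito_count"]
        m = mitophagy_fraction_per_cell(ev, counts)
        assert m.between(0, 1).all()
        per_cell_events = ev.groupby("cell_id")["mito_label"].nunique()
        assert (per_cell_events.reindex(counts.index).fillna(0) <= counts).all()


class TestTimecourse:
    def test_constant_fractions_flat_series(self):
        frames = [pd.Series({1: 0.1, 2: 0.2}) for _ in range(5)]
        tc = assemble_timecourse(frames, frame_interval=18.0)
        means = tc.mean_series()
        assert np.allclose(means["mean_m"], 0.15)
        assert list(means["minutes"]) == [0.0, 18.0, 36.0, 54.0, 72.0]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            assemble_timecourse([pd.Series({1: 0.1})])

    def test_mismatched_cells_truncated_with_warning(self):
        frames = [pd.Series({1: 0.1, 2: 0.2}), pd.Series({1: 0.3})]
        with pytest.warns(UserWarning, match="cell sets"):
            tc = assemble_timecourse(frames)
        assert set(tc.table["cell_id"]) == {1}

    def test_induction_flag_from_time(self):
        frames = [pd.Series({1: 0.1})] * 4
        tc = assemble_timecourse(frames, condition="induced", induction_time=36.0)
        flags = tc.table.groupby("frame")["induced"].first()
        assert list(flags) == [False, False, True, True]

    def test_induced_rise_then_fall_ordering_recovered(self):
        """An unsustained induced response (step up then decay) keeps its
        rise-then-fall ordering through the generator ground truth."""
        curve = (0.05, 0.05, 0.45, 0.35, 0.25, 0.15, 0.10, 0.10)
        scene = ms.generate_scene(
            ms.SceneParams(
                n_cells=30, n_frames=8, condition="induced",
                induced_engulf_curve=curve, seed=31,
            )
        )
        frame_means = np.nanmean(scene.ground_truth_fractions, axis=0)
        pre, peak, tail = frame_means[:2].mean(), frame_means[2:4].mean(), frame_means[6:].mean()
        assert pre < peak and tail < peak


class TestFixedAssays:
    def test_blank_channel_zero_tomm20(self, clean_maps):
        cells = clean_maps["cells"]
        proj = np.zeros((1, *cells.labels.shape))
        out = tomm20_loss_readout(proj, ["mitochondria"], cells)
        assert (out == 0).all()

    def test_tomm20_linear_in_intensity_scale(self, clean_stack, clean_maps):
        proj = clean_stack.pixels[0].max(axis=0).astype(np.float64)
        names = clean_stack.channel_names
        one = tomm20_loss_readout(proj, names, clean_maps["cells"])
        two = tomm20_loss_readout(2.0 * proj, names, clean_maps["cells"])
        assert np.allclose(two, 2.0 * one)

    def test_group_ratio_recovered_within_ten_percent(self):
        """Two groups rendered at 1x and 1.5x Tomm20 content."""
        from mitoscreen.config import RunConfig
        from mitoscreen.workflows import segment_frame

        totals = {}
        for group, scale in (("lo", 1.0), ("hi", 1.5)):
            params = ms.SceneParams(
                n_cells=4, n_frames=1, seed=29, mito_intensity_mean=3000.0 * scale
            )
            scene = ms.generate_scene(params)
            stack = ms.render_timelapse(scene)
            maps = segment_frame(stack, 0, RunConfig())
            out = tomm20_loss_readout(maps["projection"], stack.channel_names, maps["cells"])
            totals[group] = out.mean()
        assert totals["hi"] / totals["lo"] == pytest.approx(1.5, rel=0.10)

    def test_constructed_colocalization_counts(self):
        mito = np.zeros((20, 20), dtype=int)
        lyso = np.zeros((20, 20), dtype=int)
        for i, (y, x) in enumerate([(3, 3), (3, 12), (12, 3)], start=1):
            mito[y : y + 2, x : x + 2] = i
            lyso[y - 1 : y + 3, x - 1 : x + 3] = i
        mito[12:14, 12:14] = 4  # no matching punctum
        ev = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(lyso, "lysosome"))
        assert len(ev) == 3
        far = np.zeros((20, 20), dtype=int)
        far[7:10, 7:10] = 1  # punctum touching no Tomm20 object
        disjoint = detect_mitophagy_events(lm(mito, "mitochondrion"), lm(far, "lysosome"))
        assert len(disjoint) == 0

    def test_live_and_fixed_assays_rank_groups_identically(self):
        """Higher- vs lower-mitophagy scenes keep their ordering under both
        the live per-frame assay and the fixed colocalization count."""
        from mitoscreen.config import RunConfig
        from mitoscreen.workflows import segment_frame

        live, fixed = {}, {}
        for group, rate in (("high", 0.25), ("low", 0.04)):
            scene = ms.generate_scene(
                ms.SceneParams(n_cells=6, n_frames=1, basal_engulf_prob=rate, seed=37)
            )
            stack = ms.render_timelapse(scene)
            maps = segment_frame(stack, 0, RunConfig())
            from mitoscreen.morphometrics import mito_stats_per_cell

            ev = detect_mitophagy_events(
                maps["mito"], maps["lyso"], cells=maps["cells"]
            )
            counts = mito_stats_per_cell(maps["mito"], maps["cells"]).set_index("cell_id")[
                "mito_count"
            ]
            live[group] = mitophagy_fraction_per_cell(ev, counts).mean()
            coloc = lc3_tomm20_colocalization(
                maps["projection"], stack.channel_names, maps["cells"]
            )
            fixed[group] = coloc["fraction"].mean()
        assert live["high"] > live["low"]
        assert fixed["high"] > fixed["low"]
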