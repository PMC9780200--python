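"""Background thresholding, cell/Golgi segmentation and partitioning."""

import numpy as np
import pytest

from moequant._exceptions import ValidationError
from moequant.io import FluorescenceField
from moequant.segmentation import (
    ThresholdModel,
    ThresholdRule,
    derive_background_threshold,
    foreground_mask,
    partition_cell,
    partition_field,
    segment_cells,
    segment_golgi,
)
from moequant.synth import SceneParams, generate_control_scene, generate_scene

ROLES = {"nuclei": 0, "golgi_marker": 1, "reporter": 2}


def _field(reporter, golgi=None, nuclei=None, is_control=False, condition="c1"):
    H, W = reporter.shape
    px = np.stack(
        [
            nuclei if nuclei is not None else np.zeros((H, W)),
            golgi if golgi is not None else np.zeros((H, W)),
            reporter,
        ]
    )
    return FluorescenceField(
        px, ROLES, {"is_control": is_control, "condition_id": condition}
    )


def _threshold(cutoff, condition="c1"):
    return ThresholdModel(condition, cutoff, ThresholdRule(), n_control_pixels=1)


class TestDeriveThreshold:
    def test_constant_control_mean_plus_ksd(self):
        ctl = _field(np.full((32, 32), 10.0), is_control=True)
        model = derive_background_threshold(
            [ctl], ThresholdRule("mean_plus_ksd", 3.0)
        )
        assert model.cutoff == pytest.approx(10.0)
        assert model.n_control_pixels == 32 * 32

    def test_percentile_matches_sort_based_oracle(self):
        """Pixels 0..1023 each once; the cutoff is the order statistic at
        ceil(q*(n-1)) — checked against an independent sort-and-index
        computation — so at most 0.5% of control pixels can exceed it."""
        values = np.arange(1024, dtype=float)
        rng = np.random.default_rng(1)
        reporter = rng.permutation(values).reshape(32, 32)
        ctl = _field(reporter, is_control=True)
        model = derive_background_threshold([ctl], ThresholdRule("percentile", 99.5))

        srt = np.sort(values)
        oracle = srt[int(np.ceil(0.995 * (srt.size - 1)))]
        assert model.cutoff == oracle
        assert (reporter > model.cutoff).mean() <= 0.005

    def test_pooled_gaussian_controls_mean_plus_3sd(self):
        rng = np.random.default_rng(11)
        fields = [
            _field(rng.normal(100, 10, (256, 256)).clip(0), is_control=True)
            for _ in range(2)
        ]
        model = derive_background_threshold(fields, ThresholdRule("mean_plus_ksd", 3.0))
        pooled = np.concatenate([f.channel("reporter").ravel() for f in fields])
        assert model.cutoff == pytest.approx(pooled.mean() + 3 * pooled.std(), rel=1e-12)
        assert 128 <= model.cutoff <= 132
        assert model.n_control_pixels == 2 * 256 * 256

    def test_empty_control_list_rejected(self):
        with pytest.raises(ValidationError):
            derive_background_threshold([], ThresholdRule())

    def test_non_control_field_rejected(self):
        labeled = _field(np.zeros((32, 32)), is_control=False)
        with pytest.raises(ValidationError):
            derive_background_threshold([labeled])

    def test_mixed_conditions_rejected(self):
        a = _field(np.zeros((32, 32)), is_control=True, condition="a")
        b = _field(np.zeros((32, 32)), is_control=True, condition="b")
        with pytest.raises(ValidationError):
            derive_background_threshold([a, b])


class TestSegmentCells:
    def test_all_background_gives_zero_objects(self):
        field = _field(np.full((64, 64), 5.0))
        cells = segment_cells(field, _threshold(10.0))
        assert cells.n_cells == 0

    def test_single_square_geometry(self):
        reporter = np.zeros((100, 100))
        reporter[30:70, 30:70] = 110.0  # cutoff + 100
        field = _field(reporter)
        cells = segment_cells(field, _threshold(10.0), min_area_px=500)
        assert cells.n_cells == 1
        assert int((cells.labels == 1).sum()) == 1600

    def test_condition_mismatch_rejected(self):
        field = _field(np.zeros((32, 32)), condition="a")
        with pytest.raises(ValidationError):
            segment_cells(field, _threshold(1.0, condition="b"))

    def test_planted_cells_recovered_one_to_one(self, small_scene_params):
        """Each planted cell mask overlaps exactly one label at J >= 0.8."""
        field, truth = generate_scene(small_scene_params)
        ctl, _ = generate_control_scene(small_scene_params)
        model = derive_background_threshold([ctl])
        cells = segment_cells(field, model, min_area_px=400)
        assert cells.n_cells == small_scene_params.n_cells
        matched = set()
        for cid in truth.cell_ids:
            tm = truth.cell_mask(cid)
            jaccards = {
                k: np.logical_and(tm, cells.labels == k).sum()
                / np.logical_or(tm, cells.labels == k).sum()
                for k in cells.cell_ids
            }
            best = max(jaccards, key=jaccards.get)
            assert jaccards[best] >= 0.8
            assert best not in matched
            matched.add(best)

    def test_monotone_in_cutoff_before_size_filter(self):
        rng = np.random.default_rng(4)
        field = _field(rng.uniform(0, 100, (64, 64)))
        areas = [
            int(foreground_mask(field, _threshold(c)).sum()) for c in (10, 30, 50, 70)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_deterministic_label_maps(self, small_scene_params):
        field, _ = generate_scene(small_scene_params)
        model = _threshold(8.0, condition=field.condition_id)
        a = segment_cells(field, model, min_area_px=400)
        b = segment_cells(field, model, min_area_px=400)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSegmentGolgi:
    def test_zero_marker_gives_empty_mask(self):
        reporter = np.zeros((64, 64))
        reporter[10:40, 10:40] = 50.0
        field = _field(reporter)
        cells = segment_cells(field, _threshold(10.0))
        golgi = segment_golgi(field, cells)
        assert not golgi.any()

    def test_bimodal_marker_recovers_square(self):
        reporter = np.zeros((64, 64))
        reporter[5:55, 5:55] = 50.0
        marker = np.zeros((64, 64))
        marker[20:30, 20:30] = 200.0
        field = _field(reporter, golgi=marker)
        cells = segment_cells(field, _threshold(10.0))
        golgi = segment_golgi(field, cells)
        expected = np.zeros((64, 64), dtype=bool)
        expected[20:30, 20:30] = True
        np.testing.assert_array_equal(golgi, expected)

    def test_zero_cells_give_empty_mask_not_error(self):
        field = _field(np.zeros((32, 32)))
        cells = segment_cells(field, _threshold(10.0))
        assert not segment_golgi(field, cells).any()

    def test_planted_golgi_recovered(self, small_scene_params):
        field, truth = generate_scene(small_scene_params)
        model = _threshold(8.0, condition=field.condition_id)
        cells = segment_cells(field, model, min_area_px=400)
        golgi = segment_golgi(field, cells)
        for cid in truth.cell_ids:
            gm = truth.golgi_mask(cid)
            got = golgi & truth.cell_mask(cid)
            j = np.logical_and(gm, got).sum() / np.logical_or(gm, got).sum()
            assert j >= 0.6


class TestPartition:
    def _one_cell(self):
        reporter = np.zeros((64, 64))
        reporter[10:50, 10:50] = 50.0
        field = _field(reporter)
        return field, segment_cells(field, _threshold(10.0))

    def test_empty_golgi_limit(self):
        field, cells = self._one_cell()
        part = partition_cell(cells, np.zeros((64, 64), dtype=bool), 1)
        assert not part.in_golgi.any()
        np.testing.assert_array_equal(part.out_golgi, cells.labels == 1)

    def test_all_golgi_limit(self):
        field, cells = self._one_cell()
        part = partition_cell(cells, np.ones((64, 64), dtype=bool), 1)
        assert not part.out_golgi.any()
        np.testing.assert_array_equal(part.in_golgi, cells.labels == 1)

    def test_unknown_cell_id_is_lookup_error(self):
        _, cells = self._one_cell()
        with pytest.raises(KeyError):
            partition_cell(cells, np.zeros((64, 64), dtype=bool), 99)

    def test_random_masks_partition_set_algebra(self):
        """Disjointness and exact union for arbitrary golgi masks."""
        rng = np.random.default_rng(9)
        _, cells = self._one_cell()
        cell_mask = cells.labels == 1
        for _ in range(20):
            golgi = rng.random((64, 64)) < 0.3
            part = partition_cell(cells, golgi, 1)
            assert not np.any(part.in_golgi & part.out_golgi)
            np.testing.assert_array_equal(part.in_golgi | part.out_golgi, cell_mask)
            assert part.in_golgi.sum() + part.out_golgi.sum() == cell_mask.sum()

    def test_partition_field_covers_all_cells(self, small_scene_params):
        field, _ = generate_scene(small_scene_params)
        model = _threshold(8.0, condition=field.condition_id)
        cells = segment_cells(field, model, min_area_px=400)
        golgi = segment_golgi(field, cells)
        parts = partition_field(cells, golgi)
        assert [p.cell_id for p in parts] == cells.cell_ids


class TestControlSelfConsistency:
    def test_control_threshold_leaves_under_half_percent_foreground(
        self, small_scene_params
    ):
        ctl, _ = generate_control_scene(small_scene_params)
        model = derive_background_threshold([ctl], ThresholdRule("percentile", 99.5))
        frac = foreground_mask(ctl, model).mean()
        assert frac <= 0.005
        cells = segment_cells(ctl, model, min_area_px=400)
        assert cells.n_cells == 0
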