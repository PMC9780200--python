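"""Region measurements, per-condition aggregation and fraction recovery."""

import numpy as np
import pandas as pd
import pytest

from moequant._exceptions import (
    DomainError,
    UndefinedFractionError,
    ValidationError,
)
from moequant.io import FluorescenceField
from moequant.quantify import (
    ConditionSummary,
    estimate_golgi_fraction,
    measure_mask,
    quantify_field,
    summaries_to_frame,
    summarize_condition,
)
from moequant.segmentation import (
    ThresholdModel,
    ThresholdRule,
    partition_cell,
    partition_field,
    segment_cells,
    segment_golgi,
)
from moequant.synth import SceneParams, generate_scene

ROLES = {"nuclei": 0, "golgi_marker": 1, "reporter": 2}


def brute_force_summary(channel, mask):
    """Independent per-pixel loop oracle for measure_mask."""
    vals = []
    for r in range(channel.shape[0]):
        for c in range(channel.shape[1]):
            if mask[r, c]:
                vals.append(channel[r, c])
    return min(vals), max(vals), sum(vals) / len(vals), sum(vals), len(vals)


class TestMeasureMask:
    def test_uniform_channel(self):
        channel = np.full((16, 16), 7.0)
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:6, 2:6] = True
        s = measure_mask(channel, mask)
        assert (s.min, s.max, s.mean) == (7.0, 7.0, 7.0)
        assert s.intden == 7.0 * 16
        assert s.area_px == 16

    def test_single_zero_pixel(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[0, 0] = True
        s = measure_mask(np.zeros((16, 16)), mask)
        assert (s.min, s.max, s.mean, s.intden, s.area_px) == (0, 0, 0, 0, 1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        channel = rng.integers(0, 255, (8, 8)).astype(float)
        mask = rng.random((8, 8)) < 0.5
        mask[0, 0] = True  # nonempty
        s = measure_mask(channel, mask)
        mn, mx, mean, total, n = brute_force_summary(channel, mask)
        assert s.min == mn and s.max == mx
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.intden == pytest.approx(total, rel=1e-12)
        assert s.area_px == n

    def test_empty_mask_is_domain_error(self):
        with pytest.raises(DomainError):
            measure_mask(np.zeros((16, 16)), np.zeros((16, 16), dtype=bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            measure_mask(np.zeros((16, 16)), np.ones((8, 8), dtype=bool))

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(6)
        channel = rng.uniform(0, 50, (16, 16))
        mask = rng.random((16, 16)) < 0.4
        mask[0, 0] = True
        s1 = measure_mask(channel, mask)
        s2 = measure_mask(3.0 * channel, mask)
        for attr in ("min", "max", "mean", "intden"):
            assert getattr(s2, attr) == pytest.approx(3.0 * getattr(s1, attr))


def _scene_tables(params):
    field, truth = generate_scene(params)
    model = ThresholdModel(
        field.condition_id, 8.0, ThresholdRule(), n_control_pixels=1
    )
    cells = segment_cells(field, model, min_area_px=400)
    golgi = segment_golgi(field, cells)
    table = quantify_field(field, partition_field(cells, golgi), field_id="f0")
    return field, truth, cells, table


class TestQuantifyField:
    def test_empty_golgi_gives_identical_whole_and_out_rows(self):
        reporter = np.zeros((64, 64))
        reporter[10:50, 10:50] = 20.0
        field = FluorescenceField(
            np.stack([np.zeros((64, 64)), np.zeros((64, 64)), reporter]),
            ROLES,
            {"condition_id": "c"},
        )
        model = ThresholdModel("c", 5.0, ThresholdRule(), 1)
        cells = segment_cells(field, model)
        part = partition_cell(cells, np.zeros((64, 64), dtype=bool), 1)
        table = quantify_field(field, [part], field_id="f")
        assert set(table["region"]) == {"whole_cell", "out_golgi"}
        whole = table[table.region == "whole_cell"].iloc[0]
        out = table[table.region == "out_golgi"].iloc[0]
        for col in ("min", "max", "mean", "intden", "area_px"):
            assert whole[col] == out[col]

    def test_full_golgi_in_row_equals_whole_cell(self):
        reporter = np.zeros((64, 64))
        reporter[10:50, 10:50] = 20.0
        field = FluorescenceField(
            np.stack([np.zeros((64, 64)), np.zeros((64, 64)), reporter]),
            ROLES,
            {"condition_id": "c"},
        )
        model = ThresholdModel("c", 5.0, ThresholdRule(), 1)
        cells = segment_cells(field, model)
        part = partition_cell(cells, np.ones((64, 64), dtype=bool), 1)
        table = quantify_field(field, [part], field_id="f")
        whole = table[table.region == "whole_cell"].iloc[0]
        ing = table[table.region == "in_golgi"].iloc[0]
        for col in ("min", "max", "mean", "intden", "area_px"):
            assert whole[col] == ing[col]
        assert table[table.region == "out_golgi"].iloc[0]["area_px"] == 0

    def test_intden_conservation_per_cell(self, small_scene_params):
        _, _, cells, table = _scene_tables(small_scene_params)
        for cid in cells.cell_ids:
            sub = table[table.cell_id == cid].set_index("region")
            assert sub.loc["in_golgi", "intden"] + sub.loc[
                "out_golgi", "intden"
            ] == pytest.approx(sub.loc["whole_cell", "intden"], rel=1e-12)
            assert (
                sub.loc["in_golgi", "area_px"] + sub.loc["out_golgi", "area_px"]
                == sub.loc["whole_cell", "area_px"]
            )


class TestSummarizeCondition:
    @staticmethod
    def _table(field_id, intdens):
        rows = []
        for i, v in enumerate(intdens):
            for region in ("whole_cell", "in_golgi", "out_golgi"):
                rows.append(
                    {
                        "field_id": field_id,
                        "cell_id": i,
                        "region": region,
                        "min": 0,
                        "max": v,
                        "mean": v,
                        "intden": v,
                        "area_px": 1,
                    }
                )
        return pd.DataFrame(rows)

    def test_equal_images_zero_sd(self):
        meta = {"condition_id": "c"}
        out = summarize_condition(
            [(meta, self._table("a", [100.0])), (meta, self._table("b", [100.0]))]
        )
        s = {x.region: x for x in out}["in_golgi"]
        assert s.mean_intden == 100.0
        assert s.sd_intden == 0.0
        assert s.n_images == 2

    def test_two_point_sample_sd(self):
        meta = {"condition_id": "c"}
        out = summarize_condition(
            [(meta, self._table("a", [10.0])), (meta, self._table("b", [30.0]))]
        )
        s = {x.region: x for x in out}["out_golgi"]
        assert s.mean_intden == pytest.approx(20.0)
        assert s.sd_intden == pytest.approx(np.std([10.0, 30.0], ddof=1))
        assert s.sd_intden == pytest.approx(14.1421356, rel=1e-6)

    def test_matches_independent_aggregation(self):
        """Four synthetic images: summarize_condition equals a direct
        groupby re-aggregation of the same measured tables."""
        tables = []
        for seed in (1, 2, 3, 4):
            params = SceneParams(
                shape=(256, 256), n_cells=3, cell_radius_px=(20, 26), seed=seed
            )
            field, _, _, table = (
                lambda r: (r[0], r[1], r[2], r[3].assign(field_id=f"f{seed}"))
            )(_scene_tables(params))
            tables.append(({"condition_id": "c"}, table))
        out = {s.region: s for s in summarize_condition(tables)}
        for region in ("in_golgi", "out_golgi"):
            img_means = [
                t[t.region == region]["intden"].mean() for _, t in tables
            ]
            assert out[region].mean_intden == pytest.approx(np.mean(img_means))
            assert out[region].sd_intden == pytest.approx(np.std(img_means, ddof=1))
            assert out[region].n_images == 4

    def test_zero_cells_flagged_not_zero(self):
        from moequant.io import empty_table

        out = summarize_condition([({"condition_id": "c"}, empty_table())])
        for s in out:
            assert s.n_cells == 0
            assert np.isnan(s.mean_intden)
        frame = summaries_to_frame(out)
        assert frame["n_cells"].tolist() == [0, 0]


class TestGolgiFraction:
    @staticmethod
    def _summary(region, mean_intden):
        return ConditionSummary("c", region, mean_intden, 0.0, 2, 4)

    def test_symmetric_signals_give_half(self):
        f = estimate_golgi_fraction(
            self._summary("in_golgi", 500.0),
            self._summary("out_golgi", 500.0),
            background_per_px=0.0,
            mean_area_in=10,
            mean_area_out=10,
        )
        assert f == pytest.approx(0.5)

    def test_out_region_at_background_gives_one(self):
        f = estimate_golgi_fraction(
            self._summary("in_golgi", 500.0),
            self._summary("out_golgi", 100.0),
            background_per_px=1.0,
            mean_area_in=10,
            mean_area_out=100,
        )
        assert f == 1.0

    def test_both_zero_after_correction_undefined(self):
        with pytest.raises(UndefinedFractionError):
            estimate_golgi_fraction(
                self._summary("in_golgi", 10.0),
                self._summary("out_golgi", 10.0),
                background_per_px=1.0,
                mean_area_in=10,
                mean_area_out=10,
            )

    def test_scale_invariance(self):
        a = estimate_golgi_fraction(
            self._summary("in_golgi", 300.0),
            self._summary("out_golgi", 700.0),
            background_per_px=2.0,
            mean_area_in=20,
            mean_area_out=80,
        )
        b = estimate_golgi_fraction(
            self._summary("in_golgi", 3000.0),
            self._summary("out_golgi", 7000.0),
            background_per_px=20.0,
            mean_area_in=20,
            mean_area_out=80,
        )
        assert a == pytest.approx(b)

    def test_planted_fraction_recovered(self, small_scene_params):
        """Measured f within 0.05 of the planted 0.6 on one scene."""
        params = small_scene_params
        _, _, _, table = _scene_tables(params)
        summaries = {
            s.region: s
            for s in summarize_condition([({"condition_id": "c"}, table)])
        }
        f = estimate_golgi_fraction(
            summaries["in_golgi"],
            summaries["out_golgi"],
            background_per_px=params.background_level,
            mean_area_in=table[table.region == "in_golgi"]["area_px"].mean(),
            mean_area_out=table[table.region == "out_golgi"]["area_px"].mean(),
        )
        assert f == pytest.approx(params.f_golgi, abs=0.05)
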