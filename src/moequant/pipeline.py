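"""End-to-end orchestration from a single config mapping.

A run config is a YAML mapping (see ``RunConfig``) that declares, per
condition, the labeled images and their negative-control images, plus
all segmentation / threshold / gating / statistics parameters.  Every
stage writes plain CSV plus a JSON *manifest* echoing every effective
parameter and the seed, so identical manifests imply byte-identical
outputs and "default drift" between versions is detectable.

Stages
------
``simulate``         generate synthetic fields / event tables / lanes
``run_imaging``      threshold -> segment -> partition -> quantify ->
                     summarize -> analog-vs-control t-tests
``run_cytometry``    gate -> MFI -> relative MFI per condition
``run_densitometry`` lane Rel. Int. normalisation

Conventions: a field in which no cell survives the background threshold
contributes an image-level integrated density of zero — the operational
meaning of "no signal above control background".  When both groups of a
t-test are then constant (zero pooled variance), the comparison is
recorded with p = NaN and label "ns": identical data cannot show a
difference.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import DegenerateVarianceError, ValidationError
from .cytometry import gated_mfi, read_events, relative_mfi, write_events_csv
from .densitometry import lanes_to_frame, read_lanes_csv
from .io import FluorescenceField, load_field, save_field, save_table
from .quantify import (
    estimate_golgi_fraction,
    quantify_field,
    summaries_to_frame,
    summarize_condition,
)
from .segmentation import (
    ThresholdRule,
    derive_background_threshold,
    partition_field,
    segment_cells,
    segment_golgi,
)
from .stats import t_test_two_sample
from .synth import (
    DEFAULT_CHANNEL_ROLES,
    EventParams,
    SceneParams,
    generate_control_scene,
    generate_event_table,
    generate_lane_table,
    generate_scene,
)

logger = logging.getLogger(__name__)

DEFAULT_GATE = {"fsc_floor_quantile": 0.02, "robust_z_max": 2.5}
DEFAULT_SEGMENTATION = {
    "min_area_px": 500,
    "closing_radius_px": 2,
    "use_nuclei_seeds": False,
}
DEFAULT_GOLGI = {"method": "otsu", "min_golgi_area_px": 20}
DEFAULT_THRESHOLD = {"method": "percentile", "parameter": 99.5}


@dataclass
class RunConfig:
    """Validated run configuration; see module docstring for layout."""

    raw: dict
    base_dir: Path = dc_field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(raw=raw, base_dir=Path(path).resolve().parent)
        cfg.validate()
        return cfg

    # -- accessors with echoed defaults ------------------------------------
    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out_dir(self) -> Path:
        out = Path(self.raw.get("out_dir", "moequant_out"))
        return out if out.is_absolute() else self.base_dir / out

    @property
    def channel_roles(self) -> dict:
        return dict(
            self.raw.get("imaging", {}).get("channel_roles", DEFAULT_CHANNEL_ROLES)
        )

    @property
    def threshold_rule(self) -> ThresholdRule:
        d = {**DEFAULT_THRESHOLD, **self.raw.get("imaging", {}).get("threshold_rule", {})}
        return ThresholdRule(method=d["method"], parameter=float(d["parameter"]))

    @property
    def segmentation_params(self) -> dict:
        return {**DEFAULT_SEGMENTATION, **self.raw.get("imaging", {}).get("segmentation", {})}

    @property
    def golgi_params(self) -> dict:
        return {**DEFAULT_GOLGI, **self.raw.get("imaging", {}).get("golgi", {})}

    @property
    def gate_params(self) -> dict:
        return {**DEFAULT_GATE, **self.raw.get("cytometry", {}).get("gate", {})}

    @property
    def stats_variant(self) -> str:
        return self.raw.get("stats", {}).get("variant", "student")

    @property
    def imaging_conditions(self) -> dict:
        return dict(self.raw.get("imaging", {}).get("conditions", {}))

    @property
    def cytometry_conditions(self) -> dict:
        return dict(self.raw.get("cytometry", {}).get("conditions", {}))

    def resolve(self, p: str | os.PathLike) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        for cid, spec in self.imaging_conditions.items():
            controls = spec.get("controls", [])
            if not controls:
                raise ValidationError(
                    f"imaging condition {cid!r} declares no control images"
                )
            for p in list(spec.get("images", [])) + list(controls):
                if not self.resolve(p).exists():
                    raise ValidationError(f"condition {cid!r}: missing file {p}")
        for cid, spec in self.cytometry_conditions.items():
            if "control" not in spec:
                raise ValidationError(
                    f"cytometry condition {cid!r} declares no control table"
                )
            for key in ("events", "control"):
                p = spec.get(key)
                if p is None or not self.resolve(p).exists():
                    raise ValidationError(f"condition {cid!r}: missing file {p}")
        self.threshold_rule  # constructor validates


def _child_seed(base: int, *keys) -> int:
    """Deterministic sub-seed below 2**31 for a labelled stream."""
    import zlib

    h = zlib.crc32("/".join(str(k) for k in keys).encode())
    return int((base * 2654435761 + h) % (2**31))


def _manifest(config: RunConfig, stage: str, extras: dict | None = None) -> dict:
    import scipy
    import skimage

    return {
        "stage": stage,
        "seed": config.seed,
        "moequant_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "imaging": {
            "channel_roles": config.channel_roles,
            "threshold_rule": {
                "method": config.threshold_rule.method,
                "parameter": config.threshold_rule.parameter,
            },
            "segmentation": config.segmentation_params,
            "golgi": config.golgi_params,
        },
        "cytometry": {"gate": config.gate_params},
        "stats": {"variant": config.stats_variant},
        **(extras or {}),
    }


def _write_manifest(config: RunConfig, stage: str, extras: dict | None = None) -> None:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    path = config.out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(_manifest(config, stage, extras), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate(config: RunConfig) -> dict:
    """Generate the synthetic inputs declared under ``simulate`` and
    return a layout mapping usable by the quantification stages."""
    sim = config.raw.get("simulate", {})
    out = config.out_dir / "sim"
    out.mkdir(parents=True, exist_ok=True)
    layout: dict = {"imaging": {}, "cytometry": {}, "densitometry": None}

    for cid, spec in sim.get("imaging", {}).get("conditions", {}).items():
        scene_kwargs = dict(spec.get("scene", {}))
        if "shape" in scene_kwargs:
            scene_kwargs["shape"] = tuple(scene_kwargs["shape"])
        if "cell_radius_px" in scene_kwargs:
            scene_kwargs["cell_radius_px"] = tuple(scene_kwargs["cell_radius_px"])
        n_images = int(spec.get("n_images", 2))
        n_controls = int(spec.get("n_controls", 1))
        images, controls, truths = [], [], []
        for i in range(n_images):
            params = SceneParams(**scene_kwargs, seed=_child_seed(config.seed, cid, "img", i))
            field, truth = generate_scene(params, meta={"condition_id": cid})
            p = out / f"{cid}_img{i}.tif"
            save_field(field, p)
            truths.append(truth.expected.assign(field_id=p.name))
            images.append(str(p))
        for i in range(n_controls):
            params = SceneParams(**scene_kwargs, seed=_child_seed(config.seed, cid, "ctl", i))
            field, _ = generate_control_scene(params, meta={"condition_id": cid})
            p = out / f"{cid}_control{i}.tif"
            save_field(field, p)
            controls.append(str(p))
        if truths:
            pd.concat(truths, ignore_index=True).to_csv(
                out / f"{cid}_truth.csv", index=False
            )
        layout["imaging"][cid] = {"images": images, "controls": controls}

    for cid, spec in sim.get("cytometry", {}).get("conditions", {}).items():
        channel = spec.get("channel", "FL1A")
        ev_kwargs = {
            k: spec[k]
            for k in ("n_main", "n_debris", "n_doublets", "fold_over_control")
            if k in spec
        }
        events, _ = generate_event_table(
            EventParams(**ev_kwargs, seed=_child_seed(config.seed, cid, "events")),
            condition_id=cid,
            fluorescence_channel=channel,
        )
        control, _ = generate_event_table(
            EventParams(
                **{k: v for k, v in ev_kwargs.items() if k != "fold_over_control"},
                fold_over_control=1.0,
                seed=_child_seed(config.seed, cid, "events-control"),
            ),
            condition_id=cid,
            fluorescence_channel=channel,
            is_control=True,
        )
        ep = out / f"{cid}_events.csv"
        cp = out / f"{cid}_events_control.csv"
        write_events_csv(events, ep)
        write_events_csv(control, cp)
        layout["cytometry"][cid] = {
            "events": str(ep),
            "control": str(cp),
            "channel": channel,
        }

    dens = sim.get("densitometry")
    if dens:
        lanes = generate_lane_table(
            ratios=dens["ratios"],
            noise_cv=float(dens.get("noise_cv", 0.0)),
            seed=_child_seed(config.seed, "lanes"),
        )
        lp = out / "lanes.csv"
        frame = pd.DataFrame(
            [
                {
                    "blot_id": l.blot_id,
                    "lane_id": l.lane_id,
                    "biotin_density": l.biotin_density,
                    "ponceau_density": l.ponceau_density,
                    "is_reference": l.is_reference,
                }
                for l in lanes
            ]
        )
        frame.to_csv(lp, index=False)
        layout["densitometry"] = str(lp)

    _write_manifest(config, "simulate")
    return layout


# ---------------------------------------------------------------------------
# imaging quantification
# ---------------------------------------------------------------------------


def _load_condition_fields(
    config: RunConfig, cid: str, spec: dict
) -> tuple[list[FluorescenceField], list[FluorescenceField]]:
    roles = config.channel_roles
    labeled = [
        load_field(
            config.resolve(p),
            roles,
            meta={
                "condition_id": cid,
                "is_control": False,
                "field_id": Path(p).name,
            },
        )
        for p in spec.get("images", [])
    ]
    controls = [
        load_field(
            config.resolve(p),
            roles,
            meta={
                "condition_id": cid,
                "is_control": True,
                "field_id": Path(p).name,
            },
        )
        for p in spec.get("controls", [])
    ]
    return labeled, controls


def _measure_fields(
    config: RunConfig, fields, threshold
) -> list[tuple[dict, pd.DataFrame]]:
    seg = config.segmentation_params
    gol = config.golgi_params
    out = []
    for field in fields:
        try:
            cells = segment_cells(
                field,
                threshold,
                min_area_px=int(seg["min_area_px"]),
                closing_radius_px=int(seg["closing_radius_px"]),
                use_nuclei_seeds=bool(seg["use_nuclei_seeds"]),
            )
            golgi = segment_golgi(
                field,
                cells,
                method=gol["method"],
                min_golgi_area_px=int(gol["min_golgi_area_px"]),
            )
            table = quantify_field(
                field, partition_field(cells, golgi), field_id=field.meta["field_id"]
            )
        except Exception:
            logger.exception("field %s failed; skipped", field.meta.get("field_id"))
            table = quantify_field(field, [], field_id=field.meta.get("field_id"))
        out.append((dict(field.meta), table))
    return out


def _image_values(measured, region: str) -> list[float]:
    """Per-image mean of per-cell IntDen; 0.0 for images without cells."""
    values = []
    for _, table in measured:
        sub = table[table["region"] == region] if len(table) else table
        values.append(float(sub["intden"].mean()) if len(sub) else 0.0)
    return values


def run_imaging(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Threshold, segment, quantify and compare every imaging condition.

    Writes ``measurements.csv``, ``condition_summaries.csv``,
    ``golgi_fractions.csv`` and ``imaging_tests.csv`` under the run's
    output directory and returns the frames keyed by those names.
    """
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    all_measurements = []
    all_summaries = []
    test_rows = []
    fraction_rows = []

    for cid, spec in config.imaging_conditions.items():
        labeled, controls = _load_condition_fields(config, cid, spec)
        threshold = derive_background_threshold(controls, config.threshold_rule)
        measured = _measure_fields(config, labeled, threshold)
        measured_ctl = _measure_fields(config, controls, threshold)

        for meta, table in measured + measured_ctl:
            if len(table):
                t = table.copy()
                t.insert(0, "condition_id", cid)
                t.insert(1, "is_control", meta["is_control"])
                all_measurements.append(t)

        summaries = summarize_condition(measured)
        all_summaries.extend(summaries)

        # background per pixel for the recovery statistic: pooled mean of
        # the control reporter channel (flat background plus the small
        # in-cell nonspecific excess)
        bg = float(
            np.mean([c.channel("reporter").mean() for c in controls])
        )
        by_region = {s.region: s for s in summaries}
        areas = {}
        for region in ("in_golgi", "out_golgi"):
            rows = pd.concat(
                [t[t["region"] == region] for _, t in measured if len(t)],
                ignore_index=True,
            ) if any(len(t) for _, t in measured) else pd.DataFrame(columns=["area_px"])
            areas[region] = float(rows["area_px"].mean()) if len(rows) else float("nan")
        try:
            frac = estimate_golgi_fraction(
                by_region["in_golgi"],
                by_region["out_golgi"],
                background_per_px=bg,
                mean_area_in=areas["in_golgi"],
                mean_area_out=areas["out_golgi"],
            )
        except Exception:
            frac = float("nan")
        fraction_rows.append(
            {
                "condition_id": cid,
                "f_golgi_hat": frac,
                "background_per_px": bg,
                "mean_area_in": areas["in_golgi"],
                "mean_area_out": areas["out_golgi"],
                "threshold_cutoff": threshold.cutoff,
            }
        )

        for region in ("in_golgi", "out_golgi"):
            a = _image_values(measured, region)
            b = _image_values(measured_ctl, region)
            row = {
                "comparison_id": f"{cid}:{region}",
                "group_a": cid,
                "group_b": f"{cid}_control",
                "region": region,
                "n_a": len(a),
                "n_b": len(b),
                "variant": config.stats_variant,
            }
            try:
                res = t_test_two_sample(a, b, variant=config.stats_variant)
                row.update(t=res.t_stat, df=res.df, p=res.p_value, label=res.label)
            except (DegenerateVarianceError, ValidationError) as exc:
                logger.warning("comparison %s degenerate: %s", row["comparison_id"], exc)
                row.update(t=float("nan"), df=float("nan"), p=float("nan"), label="ns")
            test_rows.append(row)

    measurements = (
        pd.concat(all_measurements, ignore_index=True)
        if all_measurements
        else pd.DataFrame()
    )
    summaries_frame = summaries_to_frame(all_summaries)
    tests_frame = pd.DataFrame(
        test_rows,
        columns=[
            "comparison_id",
            "group_a",
            "group_b",
            "region",
            "n_a",
            "n_b",
            "t",
            "df",
            "p",
            "label",
            "variant",
        ],
    )
    fractions_frame = pd.DataFrame(fraction_rows)

    measurements.to_csv(out_dir / "measurements.csv", index=False)
    summaries_frame.to_csv(out_dir / "condition_summaries.csv", index=False)
    tests_frame.to_csv(out_dir / "imaging_tests.csv", index=False)
    fractions_frame.to_csv(out_dir / "golgi_fractions.csv", index=False)
    _write_manifest(config, "imaging")
    return {
        "measurements": measurements,
        "condition_summaries": summaries_frame,
        "imaging_tests": tests_frame,
        "golgi_fractions": fractions_frame,
    }


# ---------------------------------------------------------------------------
# cytometry
# ---------------------------------------------------------------------------


def run_cytometry(config: RunConfig) -> pd.DataFrame:
    """Gate, compute MFIs and relative MFIs for every condition."""
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cid, spec in config.cytometry_conditions.items():
        channel = spec.get("channel", "FL1A")
        events = read_events(
            config.resolve(spec["events"]), channel, condition_id=cid
        )
        control = read_events(
            config.resolve(spec["control"]), channel, condition_id=cid, is_control=True
        )
        mfi, gate = gated_mfi(events, **config.gate_params)
        mfi_ctl, gate_ctl = gated_mfi(control, **config.gate_params)
        rows.append(
            {
                "condition_id": cid,
                "channel": channel,
                "n_total": gate.n_total,
                "n_in": gate.n_in,
                "n_total_control": gate_ctl.n_total,
                "n_in_control": gate_ctl.n_in,
                "mfi": mfi,
                "mfi_control": mfi_ctl,
                "relative_mfi": relative_mfi(mfi, mfi_ctl),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "condition_id",
            "channel",
            "n_total",
            "n_in",
            "n_total_control",
            "n_in_control",
            "mfi",
            "mfi_control",
            "relative_mfi",
        ],
    )
    frame.to_csv(out_dir / "relative_mfi.csv", index=False)
    _write_manifest(config, "cytometry")
    return frame


# ---------------------------------------------------------------------------
# densitometry + run-all
# ---------------------------------------------------------------------------


def run_densitometry(config: RunConfig, lanes_path: str | os.PathLike | None = None) -> pd.DataFrame:
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    path = lanes_path or config.raw.get("densitometry", {}).get("lanes")
    if path is None:
        return pd.DataFrame()
    lanes = read_lanes_csv(config.resolve(path))
    frame = lanes_to_frame(lanes)
    frame.to_csv(out_dir / "lane_rel_int.csv", index=False)
    _write_manifest(config, "densitometry")
    return frame


def run_all(config: RunConfig) -> dict:
    """simulate (if declared) -> imaging -> cytometry -> densitometry."""
    results: dict = {}
    if "simulate" in config.raw:
        layout = simulate(config)
        raw = dict(config.raw)
        if layout["imaging"]:
            raw.setdefault("imaging", {})
            raw["imaging"] = {**raw["imaging"], "conditions": layout["imaging"]}
        if layout["cytometry"]:
            raw.setdefault("cytometry", {})
            raw["cytometry"] = {**raw["cytometry"], "conditions": layout["cytometry"]}
        if layout["densitometry"]:
            raw.setdefault("densitometry", {})
            raw["densitometry"] = {**raw["densitometry"], "lanes": layout["densitometry"]}
        config = RunConfig(raw=raw, base_dir=config.base_dir)
        config.validate()
    if config.imaging_conditions:
        results.update(run_imaging(config))
    if config.cytometry_conditions:
        results["relative_mfi"] = run_cytometry(config)
    if config.raw.get("densitometry", {}).get("lanes"):
        results["lane_rel_int"] = run_densitometry(config)
    return results
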