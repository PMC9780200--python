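"""Signal summaries on region masks and per-condition aggregation.

Integrated density (IntDen) is the raw sum of pixel grey values over a
region — equivalently mean x area at pixel calibration 1 (RawIntDen).
Measurements are always taken on the *raw, unthresholded* reporter
channel: the background threshold only defines geometry.  Thresholding
the values as well would bias min/mean and break the additivity
``intden(in) + intden(out) = intden(whole cell)``.

Aggregation treats the *image* as the replication unit: per image the
per-cell IntDen values are averaged, then mean and sample SD are taken
over images of a condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DomainError, UndefinedFractionError, ValidationError
from .io import TABLE_COLUMNS, FluorescenceField, empty_table
from .segmentation import ROIPartition

logger = logging.getLogger(__name__)

_REL_TOL = 1e-6


@dataclass(frozen=True)
class SignalSummary:
    """min / max / mean grey value, integrated density and area of one region."""

    min: float
    max: float
    mean: float
    intden: float
    area_px: int

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValidationError("area_px must be >= 1")
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("expected min <= mean <= max")
        if not math.isclose(
            self.intden, self.mean * self.area_px, rel_tol=_REL_TOL, abs_tol=1e-9
        ):
            raise ValidationError("intden must equal mean * area_px")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition, per-region IntDen mean over images.

    ``sd_intden`` is the sample SD (ddof=1) over image-level values and
    is NaN when fewer than two images contributed.  ``mean_intden`` is
    NaN (flagged, never silently zero) when no cell was measured.
    """

    condition_id: str
    region: str
    mean_intden: float
    sd_intden: float
    n_images: int
    n_cells: int


def measure_mask(channel: np.ndarray, mask: np.ndarray) -> SignalSummary:
    """Summaries of the raw channel over a boolean mask.

    Raises :class:`DomainError` for an empty mask — the caller decides
    whether that means "record nothing" or "record zero".
    """
    channel = np.asarray(channel)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValidationError(
            f"channel shape {channel.shape} != mask shape {mask.shape}"
        )
    values = channel[mask]
    if values.size == 0:
        raise DomainError("empty mask")
    return SignalSummary(
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        intden=float(values.sum()),
        area_px=int(values.size),
    )


def quantify_field(
    field: FluorescenceField,
    partitions: Sequence[ROIPartition],
    field_id: str | None = None,
) -> pd.DataFrame:
    """Per-cell whole_cell / in_golgi / out_golgi rows on the reporter channel.

    The ``in_golgi`` row is omitted (and logged) for cells whose Golgi
    mask is empty; ``out_golgi`` likewise if the Golgi covers the whole
    cell.  The reporter channel is always the measured channel.
    """
    fid = field_id if field_id is not None else field.meta.get("field_id", "field")
    reporter = field.channel("reporter")
    rows: list[dict] = []
    for part in partitions:
        if part.in_golgi.shape != field.shape:
            raise ValidationError("partition shape does not match field")
        cell_mask = part.cell_mask
        whole = measure_mask(reporter, cell_mask)
        rows.append(_row(fid, part.cell_id, "whole_cell", whole))
        if part.in_golgi.any():
            rows.append(
                _row(fid, part.cell_id, "in_golgi", measure_mask(reporter, part.in_golgi))
            )
        else:
            logger.warning(
                "field %s cell %d: empty Golgi mask, in_golgi row omitted",
                fid,
                part.cell_id,
            )
        if part.out_golgi.any():
            rows.append(
                _row(
                    fid, part.cell_id, "out_golgi", measure_mask(reporter, part.out_golgi)
                )
            )
        else:
            # all-Golgi cell: keep the invariant "out_golgi iff whole_cell"
            # with an explicit zero-area row
            rows.append(
                {
                    "field_id": fid,
                    "cell_id": part.cell_id,
                    "region": "out_golgi",
                    "min": 0.0,
                    "max": 0.0,
                    "mean": 0.0,
                    "intden": 0.0,
                    "area_px": 0,
                }
            )
    if not rows:
        return empty_table()
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _row(fid, cid: int, region: str, s: SignalSummary) -> dict:
    return {
        "field_id": fid,
        "cell_id": cid,
        "region": region,
        "min": s.min,
        "max": s.max,
        "mean": s.mean,
        "intden": s.intden,
        "area_px": s.area_px,
    }


def summarize_condition(
    tables: Iterable[tuple[dict, pd.DataFrame]],
    regions: Sequence[str] = ("in_golgi", "out_golgi"),
) -> list[ConditionSummary]:
    """Aggregate measurement tables into per-condition region summaries.

    Parameters
    ----------
    tables:
        pairs of (field meta, measurement table).  The meta must allow a
        condition id (explicit ``condition_id`` key or cell_line/analog/
        timepoint_h); each table should carry a unique ``field_id``.
    regions:
        which regions to report; image-level value = mean of per-cell
        intden within the image, condition value = mean over images,
        SD = sample SD (ddof=1) over images, NaN below two images.
    """
    by_condition: dict[str, list[pd.DataFrame]] = {}
    for meta, table in tables:
        cid = _condition_of(meta)
        by_condition.setdefault(cid, []).append(table)
    out: list[ConditionSummary] = []
    for cid, tbls in by_condition.items():
        for region in regions:
            image_values: list[float] = []
            n_cells = 0
            for tbl in tbls:
                sub = tbl[tbl["region"] == region] if len(tbl) else tbl
                if len(sub) == 0:
                    # an image without measurable cells contributes no
                    # image-level value for this region
                    continue
                image_values.append(float(sub["intden"].mean()))
                n_cells += len(sub)
            n_images = len(image_values)
            if n_images == 0:
                logger.warning(
                    "condition %s region %s: zero measured cells", cid, region
                )
                out.append(
                    ConditionSummary(cid, region, float("nan"), float("nan"), 0, 0)
                )
                continue
            mean = float(np.mean(image_values))
            sd = float(np.std(image_values, ddof=1)) if n_images >= 2 else float("nan")
            out.append(ConditionSummary(cid, region, mean, sd, n_images, n_cells))
    return out


def _condition_of(meta: dict) -> str:
    if "condition_id" in meta:
        return str(meta["condition_id"])
    return "{}:{}:{}h".format(
        meta.get("cell_line", "?"), meta.get("analog", "?"), meta.get("timepoint_h", "?")
    )


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Condition summaries as a CSV-ready frame."""
    return pd.DataFrame(
        [
            {
                "condition_id": s.condition_id,
                "region": s.region,
                "mean_intden": s.mean_intden,
                "sd_intden": s.sd_intden,
                "n_images": s.n_images,
                "n_cells": s.n_cells,
            }
            for s in summaries
        ],
        columns=[
            "condition_id",
            "region",
            "mean_intden",
            "sd_intden",
            "n_images",
            "n_cells",
        ],
    )


def estimate_golgi_fraction(
    summary_in: ConditionSummary,
    summary_out: ConditionSummary,
    background_per_px: float,
    mean_area_in: float,
    mean_area_out: float,
) -> float:
    """Background-corrected share of reporter signal inside the Golgi.

    ``B_region = max(0, mean_intden - background_per_px * mean_area)``;
    the returned fraction is ``B_in / (B_in + B_out)``.  Used to check
    recovery of a planted in-Golgi fraction from synthetic scenes.
    """
    if summary_in.condition_id != summary_out.condition_id:
        raise ValidationError("summaries belong to different conditions")
    if background_per_px < 0:
        raise ValidationError("background_per_px must be >= 0")
    b_in = max(0.0, summary_in.mean_intden - background_per_px * mean_area_in)
    b_out = max(0.0, summary_out.mean_intden - background_per_px * mean_area_out)
    total = b_in + b_out
    if total == 0 or math.isnan(total):
        raise UndefinedFractionError(
            "both regions are at background level; fraction undefined"
        )
    return b_in / total
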