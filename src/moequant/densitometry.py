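"""Relative lane intensity for blot densitometry.

Each lane's biotin signal is normalised to its Ponceau (total-protein)
loading stain, then to a designated reference lane:

    rel_int(lane) = (biotin/ponceau)_lane / (biotin/ponceau)_reference

so the reference lane is 1 exactly, and the statistic is invariant to
rescaling all biotin densities by one constant and all Ponceau densities
by another (exposure time, stain batch).  Band extraction from gel scans
is out of scope: densities enter as numbers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from ._exceptions import ValidationError

LANE_COLUMNS = ["blot_id", "lane_id", "biotin_density", "ponceau_density", "is_reference"]


@dataclass(frozen=True)
class LaneRecord:
    lane_id: str
    biotin_density: float
    ponceau_density: float
    is_reference: bool = False
    blot_id: str = "blot"

    def __post_init__(self) -> None:
        if self.biotin_density < 0:
            raise ValidationError(f"lane {self.lane_id}: biotin density must be >= 0")
        if not self.ponceau_density > 0:
            raise ValidationError(f"lane {self.lane_id}: Ponceau density must be > 0")


def relative_lane_intensity(lanes: list[LaneRecord]) -> dict[str, float]:
    """Map lane_id -> Rel. Int. relative to the single reference lane."""
    refs = [l for l in lanes if l.is_reference]
    if len(refs) != 1:
        raise ValidationError(
            f"exactly one reference lane required, found {len(refs)}"
        )
    ref = refs[0]
    if not ref.biotin_density > 0:
        raise ValidationError("reference lane biotin density must be > 0")
    ref_ratio = ref.biotin_density / ref.ponceau_density
    out = {
        lane.lane_id: (lane.biotin_density / lane.ponceau_density) / ref_ratio
        for lane in lanes
    }
    out[ref.lane_id] = 1.0  # exact by definition, immune to rounding
    return out


def read_lanes_csv(path: str | os.PathLike) -> list[LaneRecord]:
    df = pd.read_csv(path)
    missing = [c for c in LANE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing lane column(s) {missing}")
    return [
        LaneRecord(
            lane_id=str(r.lane_id),
            biotin_density=float(r.biotin_density),
            ponceau_density=float(r.ponceau_density),
            is_reference=bool(r.is_reference),
            blot_id=str(r.blot_id),
        )
        for r in df.itertuples()
    ]


def lanes_to_frame(lanes: list[LaneRecord]) -> pd.DataFrame:
    """Lane records plus their Rel. Int. column, one blot group at a time."""
    by_blot: dict[str, list[LaneRecord]] = {}
    for lane in lanes:
        by_blot.setdefault(lane.blot_id, []).append(lane)
    rows = []
    for blot_id, group in by_blot.items():
        rel = relative_lane_intensity(group)
        for lane in group:
            rows.append(
                {
                    "blot_id": blot_id,
                    "lane_id": lane.lane_id,
                    "biotin_density": lane.biotin_density,
                    "ponceau_density": lane.ponceau_density,
                    "is_reference": lane.is_reference,
                    "rel_int": rel[lane.lane_id],
                }
            )
    return pd.DataFrame(rows, columns=LANE_COLUMNS + ["rel_int"])
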