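"""Reading multi-channel fluorescence fields and writing measurement tables.

A *field* is one acquired multi-channel 2D image together with the mapping
from biological role (nuclei stain, Golgi marker, reporter) to channel
index, and the experimental metadata needed to group fields into
conditions.  Grey values are never rescaled on load: integrated densities
are sums of raw pixel values, so any normalisation here would silently
change every downstream number.

Conventions used throughout the package
---------------------------------------
* pixel coordinates are 0-based ``(row, column)``, row-major;
* boolean masks share the ``(H, W)`` shape of a single channel;
* channel-first storage: ``pixels[c, r, col]``;
* pixel calibration is 1 unit/px, so IntDen == RawIntDen.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from ._exceptions import FormatError, ValidationError

ROLES = ("nuclei", "golgi_marker", "reporter")

REGIONS = ("whole_cell", "in_golgi", "out_golgi")

#: fixed column order of every measurement CSV written by this package
TABLE_COLUMNS = [
    "field_id",
    "cell_id",
    "region",
    "min",
    "max",
    "mean",
    "intden",
    "area_px",
]

MIN_DIM = 16


@dataclass
class FluorescenceField:
    """One multi-channel 2D image plus condition metadata.

    Parameters
    ----------
    pixels:
        ``(C, H, W)`` non-negative array, arbitrary fluorescence units.
        8/16-bit unsigned inputs are accepted and held as float64.
    channel_roles:
        maps each of ``nuclei``, ``golgi_marker``, ``reporter`` to a
        distinct channel index.
    meta:
        ``cell_line``, ``analog``, ``timepoint_h``, ``replicate``,
        ``is_control`` and optionally an explicit ``condition_id`` that
        ties labeled fields to their negative controls.
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3:
            raise ValidationError(
                f"expected (C, H, W) pixels, got ndim={px.ndim}"
            )
        if px.shape[1] < MIN_DIM or px.shape[2] < MIN_DIM:
            raise ValidationError(
                f"spatial dimensions must be >= {MIN_DIM}, got {px.shape[1:]}"
            )
        if np.any(px < 0):
            raise ValidationError("pixel values must be non-negative")
        missing = [r for r in ROLES if r not in self.channel_roles]
        if missing:
            raise ValidationError(f"channel roles not mapped: {missing}")
        idx = [int(self.channel_roles[r]) for r in ROLES]
        if len(set(idx)) != len(idx):
            raise ValidationError(f"duplicate channel indices in role map: {idx}")
        if max(idx) >= px.shape[0]:
            raise FormatError(
                f"role map references channel {max(idx)} but image has "
                f"{px.shape[0]} channels"
            )
        self.pixels = px
        self.channel_roles = {r: int(self.channel_roles[r]) for r in ROLES}

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def is_control(self) -> bool:
        return bool(self.meta.get("is_control", False))

    @property
    def condition_id(self) -> str:
        """Explicit ``meta['condition_id']``, else derived from
        cell line / analog / timepoint."""
        if "condition_id" in self.meta:
            return str(self.meta["condition_id"])
        return "{}:{}:{}h".format(
            self.meta.get("cell_line", "?"),
            self.meta.get("analog", "?"),
            self.meta.get("timepoint_h", "?"),
        )

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D channel for a role (a view, not a copy)."""
        if role not in self.channel_roles:
            raise ValidationError(f"unknown channel role {role!r}")
        return self.pixels[self.channel_roles[role]]


def load_field(
    path: str | os.PathLike,
    channel_roles: Mapping[str, int],
    meta: dict | None = None,
) -> FluorescenceField:
    """Read a single-plane multi-channel TIFF/OME-TIFF as a field.

    Grey values are returned exactly as stored (no rescaling, no gamma).
    Channel-first ``(C, H, W)`` and channel-last ``(H, W, C)`` layouts are
    both accepted; the latter is recognised by a trailing axis of length
    <= 4 and transposed.  Z-stacks (4D arrays) are rejected rather than
    projected, because the projection policy would alter measured values.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError(f"{path}: single-channel image, 3 channels required")
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a single-plane multi-channel image, "
            f"got ndim={arr.ndim} (z-stacks are not supported)"
        )
    if arr.shape[-1] <= 4 < arr.shape[0]:
        arr = np.moveaxis(arr, -1, 0)
    return FluorescenceField(arr, channel_roles, dict(meta or {}))


def save_field(field_: FluorescenceField, path: str | os.PathLike) -> None:
    """Write a field channel-first as TIFF, preserving grey values.

    Integer-valued data is stored as uint16 when it fits, else float32/64
    as needed for exact round-tripping.
    """
    px = field_.pixels
    if np.all(px == np.round(px)) and px.max(initial=0) < 2**16:
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float64)
    tifffile.imwrite(path, data, photometric="minisblack", planarconfig="separate")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check measurement-table invariants and return the table.

    ``area_px`` must be non-negative; for every (field_id, cell_id) an
    ``out_golgi`` row exists iff a ``whole_cell`` row exists.  The
    ``in_golgi`` row may be absent for cells whose Golgi mask was empty.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns: {missing}")
    if len(table) == 0:
        return table
    if (table["area_px"] < 0).any():
        raise ValidationError("area_px must be >= 0")
    bad = set(table["region"]) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown regions: {sorted(bad)}")
    for (fid, cid), grp in table.groupby(["field_id", "cell_id"], sort=False):
        regions = set(grp["region"])
        if ("whole_cell" in regions) != ("out_golgi" in regions):
            raise ValidationError(
                f"cell ({fid}, {cid}): whole_cell and out_golgi rows must "
                "appear together"
            )
    return table


def save_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a measurement table as CSV with the fixed column header."""
    validate_table(table)
    out = table.loc[:, TABLE_COLUMNS] if len(table) else pd.DataFrame(
        columns=TABLE_COLUMNS
    )
    out.to_csv(path, index=False)


def load_table(path: str | os.PathLike) -> pd.DataFrame:
    """Reload a measurement CSV written by :func:`save_table`."""
    table = pd.read_csv(path)
    return validate_table(table)


def empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS)
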