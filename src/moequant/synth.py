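"""Ground-truthed synthetic inputs for every pipeline stage.

No imaging dataset accompanies the study design this package targets, so
validation runs on simulated data with planted, recoverable parameters:

* **fields** — 3-channel fluorescence scenes (nuclei / Golgi marker /
  reporter) containing non-overlapping round cells, each with a nucleus,
  a perinuclear Golgi blob, a 2-px plasma-membrane annulus and diffuse
  cytoplasm.  Each cell's expected reporter signal is a fixed photon
  budget split ``f_golgi : membrane_frac : nuclear_frac : remainder``
  over Golgi / membrane / nucleus / cytoplasm pixel sets (uniform within
  each set), on top of a flat background.  Matched *control* fields keep
  identical geometry but replace the reporter with uniform nonspecific
  signal inside cells — the negative-control condition from which the
  background threshold is derived.
* **event tables** — a main cytometry population with lognormal
  fluorescence at a planted fold over control, plus low-FSC debris and
  2x-scatter doublets.
* **lane tables** — blot lanes with planted biotin/Ponceau ratios under
  multiplicative noise.

Noise model for images: observed = Poisson(expected) + N(0, read_noise),
clipped at zero — shot noise plus camera read noise.  Every generator is
a pure function of (params, seed); geometry and noise use separate
child streams of the seed so a scene and its control share geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import PlacementError, ValidationError
from .cytometry import EventTable
from .densitometry import LaneRecord
from .io import FluorescenceField

DEFAULT_CHANNEL_ROLES = {"nuclei": 0, "golgi_marker": 1, "reporter": 2}

_REGIONS = ("in_golgi", "out_golgi", "whole_cell")


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the image simulator; defaults define the study conditions.

    ``reporter_budget`` is the expected total reporter count per cell
    (arbitrary fluorescence units at unit pixel calibration);
    ``f_golgi`` the planted in-Golgi fraction the pipeline must recover;
    ``nonspecific_level`` the per-pixel in-cell signal of control fields.
    """

    shape: tuple[int, int] = (512, 512)
    n_cells: int = 6
    cell_radius_px: tuple[float, float] = (25.0, 40.0)
    nucleus_radius_frac: float = 0.4
    golgi_area_frac: float = 0.05
    reporter_budget: float = 1e5
    f_golgi: float = 0.5
    membrane_frac: float = 0.1
    nuclear_frac: float = 0.0
    background_level: float = 2.0
    read_noise_sd: float = 1.0
    nonspecific_level: float = 4.0
    nuclei_level: float = 150.0
    golgi_marker_level: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_golgi + self.membrane_frac + self.nuclear_frac > 1.0 + 1e-12:
            raise ValidationError(
                "f_golgi + membrane_frac + nuclear_frac must be <= 1"
            )
        for name in (
            "golgi_area_frac",
            "reporter_budget",
            "f_golgi",
            "membrane_frac",
            "nuclear_frac",
            "background_level",
            "read_noise_sd",
            "nonspecific_level",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


def ac4_like_params(**overrides) -> SceneParams:
    """Preset mimicking a diffusely localising peracetylated reporter:
    low Golgi fraction, strong nuclear + cytosolic component.  Intended
    for qualitative pipeline demos only."""
    base = dict(f_golgi=0.05, membrane_frac=0.05, nuclear_frac=0.4)
    base.update(overrides)
    return SceneParams(**base)


@dataclass
class SceneTruth:
    """Planted geometry and expected signals of one synthetic field.

    Label images use 0 = background and k = cell k; the truth table has
    one row per (cell, region) with the expected reporter IntDen
    (including the flat background contribution) and the region area.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    golgi_labels: np.ndarray
    f_golgi: float
    expected: pd.DataFrame

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.cell_labels)
        return [int(i) for i in ids if i != 0]

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def golgi_mask(self, cell_id: int) -> np.ndarray:
        return self.golgi_labels == cell_id

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id


def _place_cells(params: SceneParams, rng: np.random.Generator):
    """Non-overlapping cell centres/radii by rejection sampling."""
    H, W = params.shape
    lo, hi = params.cell_radius_px
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < params.n_cells:
        attempts += 1
        if attempts > 1000 * params.n_cells:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping cells of "
                f"radius {params.cell_radius_px} in a {params.shape} field; "
                "use fewer or smaller cells"
            )
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r + 1, H - r - 1)
        cx = rng.uniform(r + 1, W - r - 1)
        if all(
            (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def _scene_geometry(params: SceneParams, rng: np.random.Generator):
    """Cell / nucleus / membrane / golgi label images for one scene."""
    H, W = params.shape
    rows, cols = np.mgrid[0:H, 0:W]
    cell_labels = np.zeros((H, W), dtype=np.int32)
    nucleus_labels = np.zeros_like(cell_labels)
    golgi_labels = np.zeros_like(cell_labels)
    membrane_labels = np.zeros_like(cell_labels)

    for k, (cy, cx, r) in enumerate(_place_cells(params, rng), start=1):
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        cell = d2 <= r**2
        cell_labels[cell] = k

        rn = params.nucleus_radius_frac * r
        max_off = max(0.0, r - rn - 3.0)
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off * 0.5)
        ny, nx = cy + off * np.sin(ang), cx + off * np.cos(ang)
        nucleus = (rows - ny) ** 2 + (cols - nx) ** 2 <= rn**2
        nucleus &= cell
        nucleus_labels[nucleus] = k

        membrane = cell & (d2 > (r - 2.0) ** 2)
        membrane_labels[membrane] = k

        # perinuclear Golgi blob: a disk seated on the nucleus boundary,
        # sized to hit golgi_area_frac of the free cytoplasm
        free = cell & ~nucleus & ~membrane
        target = params.golgi_area_frac * int(free.sum())
        rg = max(3.0, np.sqrt(target / np.pi))
        gang = rng.uniform(0, 2 * np.pi)
        gy = ny + (rn + 0.8 * rg) * np.sin(gang)
        gx = nx + (rn + 0.8 * rg) * np.cos(gang)
        golgi = (rows - gy) ** 2 + (cols - gx) ** 2 <= rg**2
        golgi &= free
        if not golgi.any():  # degenerate geometry: fall back to any free px
            golgi = free & (d2 <= (rn + 3.0) ** 2)
        golgi_labels[golgi] = k

    return cell_labels, nucleus_labels, membrane_labels, golgi_labels


def _expected_reporter(
    params: SceneParams,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    membrane_labels: np.ndarray,
    golgi_labels: np.ndarray,
) -> np.ndarray:
    """Per-pixel expected reporter signal (before background)."""
    expected = np.zeros(params.shape, dtype=np.float64)
    cyto_frac = 1.0 - params.f_golgi - params.membrane_frac - params.nuclear_frac
    for k in np.unique(cell_labels):
        if k == 0:
            continue
        cell = cell_labels == k
        golgi = golgi_labels == k
        membrane = membrane_labels == k
        nucleus = (nucleus_labels == k) & ~golgi & ~membrane
        cyto = cell & ~golgi & ~membrane & ~nucleus
        for mask, frac in (
            (golgi, params.f_golgi),
            (membrane, params.membrane_frac),
            (nucleus, params.nuclear_frac),
            (cyto, cyto_frac),
        ):
            n = int(mask.sum())
            if n and frac > 0:
                expected[mask] += frac * params.reporter_budget / n
    return expected


def _observe(expected: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    noisy = rng.poisson(expected).astype(np.float64)
    if params.read_noise_sd > 0:
        noisy += rng.normal(0.0, params.read_noise_sd, size=expected.shape)
    return np.clip(noisy, 0.0, None)


def _truth_table(
    params: SceneParams,
    cell_labels: np.ndarray,
    golgi_labels: np.ndarray,
    expected_reporter: np.ndarray,
) -> pd.DataFrame:
    rows = []
    full_expected = expected_reporter + params.background_level
    for k in np.unique(cell_labels):
        if k == 0:
            continue
        cell = cell_labels == k
        golgi = golgi_labels == k
        for region, mask in (
            ("whole_cell", cell),
            ("in_golgi", golgi),
            ("out_golgi", cell & ~golgi),
        ):
            rows.append(
                {
                    "cell_id": int(k),
                    "region": region,
                    "expected_intden": float(full_expected[mask].sum()),
                    "area_px": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "region", "expected_intden", "area_px"])


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    geom_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(geom_ss), np.random.default_rng(noise_ss)


def _assemble(
    params: SceneParams,
    expected_reporter: np.ndarray,
    geometry,
    noise_rng: np.random.Generator,
    meta: dict,
) -> tuple[FluorescenceField, SceneTruth]:
    cell_labels, nucleus_labels, membrane_labels, golgi_labels = geometry
    bg = params.background_level
    exp_nuclei = bg + params.nuclei_level * (nucleus_labels > 0)
    exp_golgi = bg + params.golgi_marker_level * (golgi_labels > 0)
    channels = np.stack(
        [
            _observe(exp_nuclei, params, noise_rng),
            _observe(exp_golgi, params, noise_rng),
            _observe(expected_reporter + bg, params, noise_rng),
        ]
    )
    field = FluorescenceField(channels, DEFAULT_CHANNEL_ROLES, meta)
    truth = SceneTruth(
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        golgi_labels=golgi_labels,
        f_golgi=params.f_golgi,
        expected=_truth_table(params, cell_labels, golgi_labels, expected_reporter),
    )
    return field, truth


def generate_scene(
    params: SceneParams, meta: dict | None = None
) -> tuple[FluorescenceField, SceneTruth]:
    """One labeled synthetic field plus its ground truth."""
    geom_rng, noise_rng = _streams(params.seed)
    geometry = _scene_geometry(params, geom_rng)
    expected = _expected_reporter(params, *geometry)
    base_meta = {
        "cell_line": "synthetic",
        "analog": "labeled",
        "timepoint_h": 24,
        "replicate": 1,
        "is_control": False,
        "condition_id": "synthetic",
    }
    base_meta.update(meta or {})
    return _assemble(params, expected, geometry, noise_rng, base_meta)


def generate_control_scene(
    params: SceneParams, meta: dict | None = None
) -> tuple[FluorescenceField, SceneTruth]:
    """Matched negative-control field: identical geometry (same seed),
    reporter replaced by uniform nonspecific signal inside cells."""
    geom_rng, noise_rng = _streams(params.seed)
    geometry = _scene_geometry(params, geom_rng)
    cell_labels = geometry[0]
    inside = cell_labels > 0
    # expected = nonspecific inside cells, background outside; expressed
    # here relative to the flat background added in _assemble
    expected = np.where(
        inside, max(0.0, params.nonspecific_level - params.background_level), 0.0
    )
    base_meta = {
        "cell_line": "synthetic",
        "analog": "ManNAc",
        "timepoint_h": 24,
        "replicate": 1,
        "is_control": True,
        "condition_id": "synthetic",
    }
    base_meta.update(meta or {})
    return _assemble(params, expected, geometry, noise_rng, base_meta)


# ---------------------------------------------------------------------------
# Cytometry event tables
# ---------------------------------------------------------------------------

#: main-population scatter cluster (arbitrary instrument units)
FSC_MAIN = (5e4, 5e3)
SSC_MAIN = (3e4, 4e3)
DEBRIS_SCALE = 2e3


@dataclass(frozen=True)
class EventParams:
    """Planted cytometry population mixture.

    ``main_fl_lognormal`` are the (mu, sigma) of the control-level log
    fluorescence; a condition at ``fold_over_control`` shifts mu by
    ln(fold), so the population mean scales by exactly the fold.
    """

    n_main: int = 10_000
    n_debris: int = 300
    n_doublets: int = 200
    main_fl_lognormal: tuple[float, float] = (np.log(500.0), 0.5)
    fold_over_control: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_main < 100:
            raise ValidationError("n_main must be >= 100")
        if self.main_fl_lognormal[1] <= 0:
            raise ValidationError("lognormal sigma must be > 0")
        if self.fold_over_control <= 0:
            raise ValidationError("fold_over_control must be > 0")


def generate_event_table(
    params: EventParams,
    condition_id: str = "condition",
    fluorescence_channel: str = "FL1A",
    is_control: bool = False,
) -> tuple[EventTable, np.ndarray]:
    """Synthetic event table plus per-event population labels
    (``main`` / ``debris`` / ``doublet``), shuffled into one stream."""
    rng = np.random.default_rng(params.seed)
    mu, sigma = params.main_fl_lognormal
    mu = mu + np.log(params.fold_over_control)

    fsc_m = rng.normal(*FSC_MAIN, size=params.n_main)
    ssc_m = rng.normal(*SSC_MAIN, size=params.n_main)
    fl_m = rng.lognormal(mu, sigma, size=params.n_main)

    fsc_d = np.abs(rng.normal(DEBRIS_SCALE, DEBRIS_SCALE / 2, size=params.n_debris))
    ssc_d = np.abs(rng.normal(DEBRIS_SCALE, DEBRIS_SCALE / 2, size=params.n_debris))
    fl_d = rng.lognormal(mu - 2.0, sigma, size=params.n_debris)

    fsc_2 = 2.0 * rng.normal(*FSC_MAIN, size=params.n_doublets)
    ssc_2 = 2.0 * rng.normal(*SSC_MAIN, size=params.n_doublets)
    fl_2 = 2.0 * rng.lognormal(mu, sigma, size=params.n_doublets)

    fsc = np.concatenate([fsc_m, fsc_d, fsc_2])
    ssc = np.concatenate([ssc_m, ssc_d, ssc_2])
    fl = np.concatenate([fl_m, fl_d, fl_2])
    labels = np.array(
        ["main"] * params.n_main
        + ["debris"] * params.n_debris
        + ["doublet"] * params.n_doublets
    )
    order = rng.permutation(fsc.size)
    events = EventTable(
        fsc_a=np.clip(fsc[order], 0.0, None),
        ssc_a=np.clip(ssc[order], 0.0, None),
        fl_a=fl[order],
        condition_id=condition_id,
        fluorescence_channel=fluorescence_channel,
        is_control=is_control,
    )
    return events, labels[order]


# ---------------------------------------------------------------------------
# Blot lane tables
# ---------------------------------------------------------------------------


def generate_lane_table(
    ratios: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    blot_id: str = "blot",
    base_ponceau: float = 1000.0,
) -> list[LaneRecord]:
    """Lanes with planted biotin/Ponceau ratios; lane 0 is the reference.

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` (mean-one) perturbs biotin and Ponceau independently.
    """
    ratios = list(ratios)
    if len(ratios) < 2:
        raise ValidationError("need at least two lanes (reference + one)")
    if any(r <= 0 for r in ratios):
        raise ValidationError("planted ratios must be > 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))

    def _noise() -> float:
        if sigma == 0:
            return 1.0
        return float(rng.lognormal(-sigma**2 / 2, sigma))  # mean-one

    lanes = []
    for i, ratio in enumerate(ratios):
        ponceau = base_ponceau * _noise()
        biotin = ratio * base_ponceau * _noise()
        lanes.append(
            LaneRecord(
                lane_id=f"lane{i}",
                biotin_density=biotin,
                ponceau_density=ponceau,
                is_reference=(i == 0),
                blot_id=blot_id,
            )
        )
    return lanes
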