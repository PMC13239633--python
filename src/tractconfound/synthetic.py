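"""Synthetic QA phantoms, tract templates and cohorts.

The generator emulates the data the tract-strength pipeline consumes: a
standard-space grid holding two descending motor bundles per hemisphere
(CRST medial, CST lateral) as straight vertical tubes with Gaussian
streamline-density cross-sections, a background white-matter sheet whose
mid-plane joins the bundle cores to form the skeleton, and a ventricular CSF
compartment.  Participant volumes add multiplicative scanner gain, voxel
noise, optional rigid misalignment and an optional spherical lesion.

Cohorts encode the hypothesized causal structure of post-stroke motor
plasticity: a latent ipsilesional corticomotor deficit D (in control-SD
units) drives both attenuation of the ipsilesional tracts and upregulation of
the contralesional tracts, and independently reduces six-minute walk distance
(6MWD).  With no direct effect of contralesional CRST strength on walking
(``beta_direct = 0``), any observed cCRST-6MWD association is pure
confounding by D — the null the confounding analysis must detect.

Control tract values follow tract_nQA = mean + slope * (global_nQA - 2.658)
+ noise with structural slopes 1.186 (CRST) and 2.702 (CST); the default
global-nQA SD (0.25) and tract noise SDs (0.25 / 0.35 per side) put the
control regression r-squared near 0.74 and 0.88 for the two families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tracts import SIDES, TRACTS, TractTemplate
from .volumes import GridSpec, MaskSet, Volume, save_mask, save_volume

__all__ = [
    "PhantomParams",
    "CohortParams",
    "ParticipantRecord",
    "make_templates",
    "make_participant_volume",
    "make_cohort",
    "make_tabular_cohort",
    "write_cohort_csv",
    "STRUCTURAL_SLOPES",
    "GLOBAL_NQA_MEAN",
    "TRACT_MEAN_NQA",
]

# structural constants of the control population the generator emulates
GLOBAL_NQA_MEAN = 2.658
STRUCTURAL_SLOPES = {"CRST": 1.186, "CST": 2.702}
TRACT_MEAN_NQA = {"CRST": 3.25, "CST": 4.98}

# phantom geometry (voxel offsets from the grid center)
_CRST_X_OFF = 5
_CST_X_OFF = 11
_TUBE_RADIUS = {"CRST": 2, "CST": 3}
_TUBE_PEAK_COUNT = {"CRST": 50.0, "CST": 150.0}
_SHEET_Y_OFF = 8  # background sheet plane, offset from center in y
_SHEET_X_MARGIN = 4
_CSF_Y_OFF = -11  # CSF box center offset
_MIN_XY = 32
_Z_MARGIN = 2  # bundles and masks stay clear of the volume edge


@dataclass
class PhantomParams:
    """Parameters of one participant's synthetic QA volume.

    ``tract_attenuation`` / ``tract_elevation`` are keyed by (tract, side);
    missing keys mean factor 1.  ``tract_levels`` override the core nQA level
    of individual bundles and, with ``target_global_nqa``, let the cohort
    generator plant an exact global/tract regression structure; both default
    to the structural control constants.
    """

    global_scale: float = 1.0
    tract_attenuation: dict = field(default_factory=dict)
    tract_elevation: dict = field(default_factory=dict)
    scanner_gain: float = 1.0
    noise_sd: float = 0.0
    misalignment_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesion_center: tuple[int, int, int] | None = None
    lesion_radius_mm: float = 0.0
    seed: int = 0
    base_csf: float = 1.0
    tract_levels: dict = field(default_factory=dict)
    target_global_nqa: float | None = None

    def __post_init__(self) -> None:
        if self.scanner_gain <= 0:
            raise ValueError("scanner_gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for key, a in self.tract_attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation for {key} must be in [0, 1], got {a}")
        for key, e in self.tract_elevation.items():
            if e < 1.0:
                raise ValueError(f"elevation for {key} must be >= 1, got {e}")


def _tube_center(grid: GridSpec, name: str, side: str) -> tuple[int, int]:
    cx, cy = grid.dims[0] // 2, grid.dims[1] // 2
    off = _CRST_X_OFF if name == "CRST" else _CST_X_OFF
    x = cx - off if side == "left" else cx + off
    return x, cy


def make_templates(
    grid: GridSpec, seed: int = 0
) -> tuple[dict[tuple[str, str], TractTemplate], MaskSet]:
    """Build the four normative tract templates and the mask set.

    Each bundle is a straight vertical tube whose streamline count falls off
    as a Gaussian of in-plane distance from the core; the CST tube is wider
    (larger normative volume) and denser than the CRST tube.  The skeleton is
    the one-voxel core line of each tube plus the mid-plane of a background
    white-matter sheet.  Deterministic given (grid, seed).
    """
    nx, ny, nz = grid.dims
    z = grid.z_coords()
    if z.min() > -5.0 or z.max() < 12.0:
        raise ValueError(
            "grid z range [{:.1f}, {:.1f}] mm does not cover the internal-capsule "
            "slab z = [-5, 12] mm".format(z.min(), z.max())
        )
    if nx < _MIN_XY or ny < _MIN_XY:
        raise ValueError(f"grid x/y dims must be >= {_MIN_XY} to hold the bundles")
    rng = np.random.default_rng(seed)

    xs = np.arange(nx)[:, None]
    ys = np.arange(ny)[None, :]
    templates: dict[tuple[str, str], TractTemplate] = {}
    tube_support = np.zeros((nx, ny, nz), dtype=bool)
    skeleton = np.zeros((nx, ny, nz), dtype=bool)
    for name in TRACTS:
        for side in SIDES:
            tx, ty = _tube_center(grid, name, side)
            r = _TUBE_RADIUS[name]
            d2 = (xs - tx) ** 2 + (ys - ty) ** 2
            sigma = r / 1.5
            peak = _TUBE_PEAK_COUNT[name] * (1.0 + 0.05 * rng.standard_normal())
            plane = np.where(d2 <= r**2, peak * np.exp(-d2 / (2 * sigma**2)), 0.0)
            counts = np.repeat(plane[:, :, None], nz, axis=2)
            counts[:, :, :_Z_MARGIN] = 0.0
            counts[:, :, nz - _Z_MARGIN :] = 0.0
            vol = Volume(values=counts, grid=grid)
            templates[(name, side)] = TractTemplate(
                name=name,
                side=side,
                streamline_counts=vol,
                normative_volume=float(np.count_nonzero(counts)),
            )
            tube_support |= counts > 0
            skeleton[tx, ty, _Z_MARGIN : nz - _Z_MARGIN] = True

    cx, cy = nx // 2, ny // 2
    sheet = np.zeros((nx, ny, nz), dtype=bool)
    zsl = slice(_Z_MARGIN, nz - _Z_MARGIN)
    sheet[_SHEET_X_MARGIN : nx - _SHEET_X_MARGIN, cy + _SHEET_Y_OFF - 1 : cy + _SHEET_Y_OFF + 2, zsl] = True
    skeleton[_SHEET_X_MARGIN : nx - _SHEET_X_MARGIN, cy + _SHEET_Y_OFF, zsl] = True

    white_matter = tube_support | sheet

    csf = np.zeros((nx, ny, nz), dtype=bool)
    csf[cx - 6 : cx + 7, cy + _CSF_Y_OFF - 1 : cy + _CSF_Y_OFF + 2, zsl] = True

    masks = MaskSet(csf=csf, skeleton=skeleton, white_matter=white_matter, grid=grid)
    return templates, masks


def _integer_shift(arr: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Rigid integer-voxel shift with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for ax, s in enumerate(shift):
        n = arr.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def make_participant_volume(
    templates: dict[tuple[str, str], TractTemplate],
    masks: MaskSet,
    params: PhantomParams,
) -> Volume:
    """Render one participant's raw QA volume from the phantom parameters.

    Compartments before gain and noise: CSF at ``base_csf``; background sheet
    at the sheet level (solved from ``target_global_nqa`` when given,
    otherwise ``global_scale * GLOBAL_NQA_MEAN``); each bundle at its core
    level times the normalized streamline-density profile times its
    attenuation and elevation factors.  A lesion sphere zeroes QA before the
    scanner gain is applied; the rigid misalignment shift is applied before
    gain and noise.
    """
    grid = masks.grid
    signal = np.zeros(grid.dims)

    tube_support = np.zeros(grid.dims, dtype=bool)
    core_factor_one = 0.0  # sum of factor-1 core values over tube skeleton voxels
    n_tube_skel = 0
    tube_values = np.zeros(grid.dims)
    for (name, side), tpl in templates.items():
        counts = tpl.streamline_counts.values
        support = counts > 0
        profile = counts / counts.max()
        level = params.tract_levels.get((name, side), TRACT_MEAN_NQA[name])
        att = params.tract_attenuation.get((name, side), 1.0)
        elev = params.tract_elevation.get((name, side), 1.0)
        tube_values[support] += (
            params.global_scale * level * att * elev * profile[support]
        )
        tube_support |= support
        n_core = int(np.count_nonzero(support & masks.skeleton))
        core_factor_one += params.global_scale * level * n_core
        n_tube_skel += n_core

    sheet = masks.white_matter & ~tube_support
    sheet_skel = masks.skeleton & sheet
    if params.target_global_nqa is not None:
        n_sheet = int(np.count_nonzero(sheet_skel))
        n_total = n_sheet + n_tube_skel
        sheet_level = (params.target_global_nqa * n_total - core_factor_one) / n_sheet
        if sheet_level <= 0:
            raise ValueError("target_global_nqa is too low for the bundle levels")
    else:
        sheet_level = params.global_scale * GLOBAL_NQA_MEAN

    signal[sheet] = sheet_level
    signal[tube_support] = tube_values[tube_support]
    # the CSF compartment extends beyond the sampling mask so that a small
    # rigid misalignment cannot move non-CSF tissue under the mask
    from scipy import ndimage

    csf_compartment = ndimage.binary_dilation(
        masks.csf, structure=np.ones((3, 3, 3), dtype=bool), iterations=2
    )
    if np.any(csf_compartment & masks.white_matter):
        raise ValueError("CSF compartment would overlap white matter")
    signal[csf_compartment] = params.base_csf

    if params.lesion_center is not None and params.lesion_radius_mm > 0:
        ii, jj, kk = np.indices(grid.dims)
        r_vox = params.lesion_radius_mm / grid.voxel_size_mm
        d2 = (
            (ii - params.lesion_center[0]) ** 2
            + (jj - params.lesion_center[1]) ** 2
            + (kk - params.lesion_center[2]) ** 2
        )
        signal[d2 <= r_vox**2] = 0.0

    shift_vox = tuple(
        int(round(m / grid.voxel_size_mm)) for m in params.misalignment_mm
    )
    if any(shift_vox):
        signal = _integer_shift(signal, shift_vox)

    signal = signal * params.scanner_gain
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
        signal = np.clip(signal, 0.0, None)
    return Volume(values=signal, grid=grid)


@dataclass
class CohortParams:
    """Population parameters of the synthetic stroke/control cohort.

    ``damage_mean``/``damage_sd`` describe the latent ipsilesional deficit D
    (control-SD units of corticomotor strength, truncated at 0);
    ``delta_upreg`` maps D to the contralesional CRST elevation factor;
    ``gamma_walk`` is meters of 6MWD per control-SD of actual ipsilesional
    corticomotor strength; ``beta_direct`` is the direct effect (m per SD) of
    cCRST strength on 6MWD, zero under the confounded null.
    """

    n_pairs: int = 10
    damage_mean: float = 8.0
    damage_sd: float = 2.5
    delta_upreg: float = 0.02
    gamma_walk: float = 40.0
    beta_direct: float = 0.0
    walk_intercept_m: float = 500.0
    walk_noise_sd_m: float = 60.0
    upreg_noise_sd: float = 0.04
    seed: int = 0
    # volume-level structure
    global_nqa_sd: float = 0.25
    crst_noise_sd: float = 0.25
    cst_noise_sd: float = 0.35
    voxel_noise_sd: float = 0.02
    scanner_gain_log_sd: float = 0.3
    misalign_vox: int = 1
    att_per_damage_sd: float | None = None  # default: one control SD per unit D
    z_measurement_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        for name in ("walk_noise_sd_m", "upreg_noise_sd", "damage_sd",
                     "global_nqa_sd", "voxel_noise_sd", "z_measurement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ParticipantRecord:
    id: str
    group: str  # stroke | control
    pair_id: str
    lesion_side: str  # left | right | none
    six_mwd_m: float
    true_damage: float


def _pair_rng(seed: int, pair: int, stream: int) -> np.random.Generator:
    # per-pair substreams keyed by counter, so cohorts are reproducible
    # under reordering and the tabular path can reuse the same latents
    return np.random.default_rng([seed & 0x7FFFFFFF, pair, stream])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at >= 0, by rejection."""
    if sd == 0:
        return max(0.0, mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


# integer-lattice cross-section areas of the two tube supports; the
# normative-volume composite weights follow as 13/42 and 29/42
_SUPPORT_AREA = {"CRST": 13, "CST": 29}
COMPOSITE_WEIGHTS = (
    _SUPPORT_AREA["CRST"] / (_SUPPORT_AREA["CRST"] + _SUPPORT_AREA["CST"]),
    _SUPPORT_AREA["CST"] / (_SUPPORT_AREA["CRST"] + _SUPPORT_AREA["CST"]),
)

# control SDs of adjusted tract nQA implied by the default structural noise;
# these define the z-score unit of the generator regardless of the noise
# levels actually simulated
_Z_DENOM = {"CRST": 0.25, "CST": 0.35}
_Z_DENOM_COMPOSITE = float(
    np.sqrt((COMPOSITE_WEIGHTS[0] * _Z_DENOM["CRST"]) ** 2
            + (COMPOSITE_WEIGHTS[1] * _Z_DENOM["CST"]) ** 2)
)
_MEAN_COMPOSITE = float(
    COMPOSITE_WEIGHTS[0] * TRACT_MEAN_NQA["CRST"]
    + COMPOSITE_WEIGHTS[1] * TRACT_MEAN_NQA["CST"]
)


def _default_att_per_sd() -> float:
    # attenuation slope such that one unit of D costs one control SD of
    # composite corticomotor strength
    return _Z_DENOM_COMPOSITE / _MEAN_COMPOSITE


def _adjusted_z(levels: dict, factors: dict, g: float) -> dict:
    """True role z-scores implied by tract levels, factors and global nQA.

    Mirrors the measurement pipeline arithmetic: the raw bundle value is the
    level times its factor; adjustment subtracts slope * (G - mean); z uses
    the structural control SDs.  Sides are keyed ipsi/contra by the caller
    via the factor dict.
    """
    adj = {}
    for (name, side), level in levels.items():
        actual = level * factors.get((name, side), 1.0)
        adj[(name, side)] = actual - STRUCTURAL_SLOPES[name] * (g - GLOBAL_NQA_MEAN)
    out = {}
    for side in SIDES:
        comp = (COMPOSITE_WEIGHTS[0] * adj[("CRST", side)]
                + COMPOSITE_WEIGHTS[1] * adj[("CST", side)])
        out[("CRST", side)] = (adj[("CRST", side)] - TRACT_MEAN_NQA["CRST"]) / _Z_DENOM["CRST"]
        out[("CST", side)] = (adj[("CST", side)] - TRACT_MEAN_NQA["CST"]) / _Z_DENOM["CST"]
        out[("Corticomotor", side)] = (comp - _MEAN_COMPOSITE) / _Z_DENOM_COMPOSITE
    return out


def _pair_latents(params: CohortParams, i: int) -> dict:
    """Biological latent draws for pair i (shared by both cohort flavours)."""
    rng = _pair_rng(params.seed, i, 0)
    d = _trunc_normal(rng, params.damage_mean, params.damage_sd)
    eps_u_crst = rng.normal(0.0, params.upreg_noise_sd) if params.upreg_noise_sd else 0.0
    eps_u_cst = rng.normal(0.0, params.upreg_noise_sd) if params.upreg_noise_sd else 0.0
    eps_walk_s = rng.normal(0.0, params.walk_noise_sd_m) if params.walk_noise_sd_m else 0.0
    eps_walk_c = rng.normal(0.0, params.walk_noise_sd_m) if params.walk_noise_sd_m else 0.0

    # per-participant global nQA and tract-level deviations (biology, not
    # acquisition): tract_nQA = mean + slope * (G - mean_G) + eps
    levels = {}
    gs = {}
    for tag in ("stroke", "control"):
        g = rng.normal(GLOBAL_NQA_MEAN, params.global_nqa_sd) if params.global_nqa_sd else GLOBAL_NQA_MEAN
        gs[tag] = float(g)
        for name in TRACTS:
            noise_sd = params.crst_noise_sd if name == "CRST" else params.cst_noise_sd
            for side in SIDES:
                eps = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                levels[(tag, name, side)] = (
                    TRACT_MEAN_NQA[name]
                    + STRUCTURAL_SLOPES[name] * (g - GLOBAL_NQA_MEAN)
                    + eps
                )

    elev_crst = max(1.0, 1.0 + params.delta_upreg * d + eps_u_crst)
    elev_cst = max(1.0, 1.0 + 0.8 * params.delta_upreg * d + eps_u_cst)
    a = params.att_per_damage_sd if params.att_per_damage_sd is not None else _default_att_per_sd()
    att = float(np.clip(1.0 - a * d, 0.0, 1.0))

    side = "left" if i % 2 == 0 else "right"
    contra = "right" if side == "left" else "left"
    factors = {
        ("CRST", side): att, ("CST", side): att,
        ("CRST", contra): elev_crst, ("CST", contra): elev_cst,
    }
    z_stroke = _adjusted_z(
        {(n, s): levels[("stroke", n, s)] for n in TRACTS for s in SIDES}, factors, gs["stroke"]
    )
    z_control = _adjusted_z(
        {(n, s): levels[("control", n, s)] for n in TRACTS for s in SIDES}, {}, gs["control"]
    )

    # walking capacity depends on the actual ipsilesional corticomotor
    # strength (and, when beta_direct != 0, on actual cCRST strength)
    walk_s = (
        params.walk_intercept_m
        + params.gamma_walk * z_stroke[("Corticomotor", side)]
        + params.beta_direct * z_stroke[("CRST", contra)]
        + eps_walk_s
    )
    walk_c = (
        params.walk_intercept_m
        + params.gamma_walk * z_control[("Corticomotor", side)]
        + params.beta_direct * z_control[("CRST", contra)]
        + eps_walk_c
    )
    return {
        "damage": d,
        "lesion_side": side,
        "contra_side": contra,
        "elev_crst": elev_crst,
        "elev_cst": elev_cst,
        "attenuation": att,
        "factors": factors,
        "g": gs,
        "levels": levels,
        "z_icm_stroke": z_stroke[("Corticomotor", side)],
        "z_ccrst_stroke": z_stroke[("CRST", contra)],
        "z_icm_control": z_control[("Corticomotor", side)],
        "z_ccrst_control": z_control[("CRST", contra)],
        "walk_stroke": max(0.0, walk_s),
        "walk_control": max(0.0, walk_c),
    }


def _volume_params(
    params: CohortParams, i: int, *, stroke: bool, lat: dict
) -> PhantomParams:
    """Acquisition nuisances (gain, misalignment, voxel noise seed) plus the
    biological levels/factors drawn in :func:`_pair_latents`."""
    rng = _pair_rng(params.seed, i, 2 if stroke else 3)
    tag = "stroke" if stroke else "control"
    gain = float(np.exp(rng.normal(0.0, params.scanner_gain_log_sd))) if params.scanner_gain_log_sd else 1.0
    m = params.misalign_vox
    shift = tuple(float(s) for s in rng.integers(-m, m + 1, size=3)) if m else (0.0, 0.0, 0.0)

    attenuation: dict = {}
    elevation: dict = {}
    if stroke:
        side, contra = lat["lesion_side"], lat["contra_side"]
        attenuation = {("CRST", side): lat["attenuation"], ("CST", side): lat["attenuation"]}
        elevation = {("CRST", contra): lat["elev_crst"], ("CST", contra): lat["elev_cst"]}
    return PhantomParams(
        global_scale=1.0,
        tract_attenuation=attenuation,
        tract_elevation=elevation,
        scanner_gain=gain,
        noise_sd=params.voxel_noise_sd,
        misalignment_mm=shift,  # in voxels here; scaled to mm by make_cohort
        seed=int(rng.integers(0, 2**31 - 1)),
        tract_levels={(n, s): lat["levels"][(tag, n, s)] for n in TRACTS for s in SIDES},
        target_global_nqa=lat["g"][tag],
    )


def make_cohort(
    params: CohortParams, voxel_size_mm: float = 2.0
) -> tuple[list[ParticipantRecord], dict[str, PhantomParams]]:
    """Draw the matched cohort and per-participant phantom parameters.

    Returns the participant records (stroke and matched control per pair,
    lesion sides alternating) and a mapping from participant id to the
    :class:`PhantomParams` that renders that participant's QA volume.
    ``misalignment_mm`` is scaled to ``voxel_size_mm`` so the rigid shift is
    a whole number of voxels.
    """
    records: list[ParticipantRecord] = []
    phantoms: dict[str, PhantomParams] = {}
    for i in range(params.n_pairs):
        lat = _pair_latents(params, i)
        pair = f"P{i:03d}"
        sid, cid = f"S{i:03d}", f"C{i:03d}"
        records.append(
            ParticipantRecord(sid, "stroke", pair, lat["lesion_side"],
                              lat["walk_stroke"], lat["damage"])
        )
        records.append(
            ParticipantRecord(cid, "control", pair, "none", lat["walk_control"], 0.0)
        )
        for pid, is_stroke in ((sid, True), (cid, False)):
            pp = _volume_params(params, i, stroke=is_stroke, lat=lat)
            pp.misalignment_mm = tuple(v * voxel_size_mm for v in pp.misalignment_mm)
            phantoms[pid] = pp
    return records, phantoms


def make_tabular_cohort(params: CohortParams) -> pd.DataFrame:
    """Cohort table with tract-strength z-scores emitted analytically.

    Fast path for exercising the statistics stage without volumes: the same
    per-pair latent draws as :func:`make_cohort`, with the true adjusted
    role z-scores computed in closed form from the drawn tract levels and
    factors.  ``z_measurement_sd`` (default 0) adds optional measurement
    noise on top of the analytic values.
    """
    rows = []
    for i in range(params.n_pairs):
        lat = _pair_latents(params, i)
        rng = _pair_rng(params.seed, i, 4)
        noise = [rng.normal(0.0, params.z_measurement_sd) if params.z_measurement_sd else 0.0
                 for _ in range(4)]
        rows.append(
            {
                "id": f"S{i:03d}", "group": "stroke", "pair_id": f"P{i:03d}",
                "lesion_side": lat["lesion_side"],
                "six_mwd_m": lat["walk_stroke"], "true_damage": lat["damage"],
                "z_icorticomotor": lat["z_icm_stroke"] + noise[0],
                "z_ccrst": lat["z_ccrst_stroke"] + noise[1],
            }
        )
        rows.append(
            {
                "id": f"C{i:03d}", "group": "control", "pair_id": f"P{i:03d}",
                "lesion_side": "none",
                "six_mwd_m": lat["walk_control"], "true_damage": 0.0,
                "z_icorticomotor": lat["z_icm_control"] + noise[2],
                "z_ccrst": lat["z_ccrst_control"] + noise[3],
            }
        )
    return pd.DataFrame(rows)


def write_cohort_csv(
    records: list[ParticipantRecord], path: str | Path, params: CohortParams | None = None
) -> Path:
    """Write the cohort table; generator parameters go to a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame([asdict(r) for r in records])
    df.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(".params.json")
        sidecar.write_text(json.dumps(asdict(params), indent=2))
    return path


def write_templates(
    templates: dict[tuple[str, str], TractTemplate],
    masks: MaskSet,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write templates and masks as NIfTI-1 files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for (name, side), tpl in templates.items():
        p = outdir / f"template_{name.lower()}_{side}.nii.gz"
        save_volume(tpl.streamline_counts, p)
        paths[f"{name}_{side}"] = p
    for mname in ("csf", "skeleton", "white_matter"):
        p = outdir / f"mask_{mname}.nii.gz"
        save_mask(getattr(masks, mname), masks.grid, p)
        paths[mname] = p
    return paths
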