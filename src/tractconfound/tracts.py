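"""Streamline-weighted tract strength: slab means, adjustment, z-scores.

For each participant and each descending motor tract (corticoreticulospinal,
CRST; corticospinal, CST; left and right), strength is the streamline-count
weighted mean of skeletonized nQA over the internal-capsule slab
(z = -5 to 12 mm of standard space).  Each tract value is then adjusted for
the participant's global white-matter nQA using slopes fitted on controls
only,

    adjusted_i = unadjusted_i - slope * (global_i - control_global_mean),

so that a stroke survivor's tract value is compared with the normative
expectation for someone with the same global white matter.  Hemispheres are
relabelled ipsi/contralesional from the lesion side (controls inherit the
side of their matched stroke partner), composite corticomotor strength is the
normative-volume weighted average of the CRST and CST values, and everything
is finally expressed as a z-score against the control mean and SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volumes import MaskSet, Volume

__all__ = [
    "TractTemplate",
    "ReferenceModel",
    "ROLES",
    "tract_mean_nqa",
    "global_wm_nqa",
    "fit_reference",
    "adjust_tract_nqa",
    "composite_corticomotor",
    "zscore",
    "assign_laterality",
    "participant_tract_values",
    "strength_records",
    "published_reference_model",
]

TRACTS = ("CRST", "CST")
SIDES = ("left", "right")
#: per-tract roles plus the volume-weighted corticomotor composites
ROLES = ("iCRST", "cCRST", "iCST", "cCST", "iCorticomotor", "cCorticomotor")

DEFAULT_SLAB_MM = (-5.0, 12.0)


@dataclass
class TractTemplate:
    """Normative template for one tract and side.

    ``streamline_counts`` holds, per voxel, the number of normative
    streamlines passing through it; ``normative_volume`` is the whole-tract
    volume (count of voxels with any streamline), used to weight the
    corticomotor composite.
    """

    name: str
    side: str
    streamline_counts: Volume
    normative_volume: float

    def __post_init__(self) -> None:
        if self.name not in TRACTS:
            raise ValueError(f"tract name must be one of {TRACTS}, got {self.name!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if np.any(self.streamline_counts.values < 0):
            raise ValueError("streamline counts must be non-negative")
        if self.normative_volume <= 0:
            raise ValueError("normative_volume must be positive")


@dataclass
class ReferenceModel:
    """Control-derived constants for adjustment and z-scoring.

    ``slope_crst``/``slope_cst`` regress tract nQA (averaged over sides) on
    global nQA in controls; ``tract_stats`` maps each role to the (mean, SD)
    of control adjusted nQA; ``composite_weights`` is (w_crst, w_cst),
    positive and summing to one.
    """

    slope_crst: float
    slope_cst: float
    r2_crst: float
    r2_cst: float
    control_global_mean: float
    tract_stats: dict[str, tuple[float, float]]
    composite_weights: tuple[float, float]
    n_controls: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.composite_weights, dtype=float)
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("composite weights must be positive and sum to 1")
        for role, (_, sd) in self.tract_stats.items():
            if sd <= 0:
                raise ValueError(f"control SD for {role} must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "slope_crst": self.slope_crst,
            "slope_cst": self.slope_cst,
            "r2_crst": self.r2_crst,
            "r2_cst": self.r2_cst,
            "control_global_mean": self.control_global_mean,
            "tract_stats": {k: list(v) for k, v in self.tract_stats.items()},
            "composite_weights": list(self.composite_weights),
            "n_controls": self.n_controls,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        d = json.loads(Path(path).read_text())
        d["tract_stats"] = {k: tuple(v) for k, v in d["tract_stats"].items()}
        d["composite_weights"] = tuple(d["composite_weights"])
        return cls(**d)


def slab_mask(vol: Volume, slab_mm: tuple[float, float]) -> np.ndarray:
    """Boolean 3-D mask of voxels whose z-center lies in [lo, hi] mm, inclusive."""
    lo, hi = slab_mm
    if lo > hi:
        raise ValueError(f"slab bounds out of order: {slab_mm}")
    z = vol.grid.z_coords()
    in_slab = (z >= lo) & (z <= hi)
    mask = np.zeros(vol.grid.dims, dtype=bool)
    mask[:, :, in_slab] = True
    return mask


def tract_mean_nqa(
    skel_nqa: Volume,
    template: TractTemplate,
    slab_mm: tuple[float, float] = DEFAULT_SLAB_MM,
) -> float:
    """Streamline-weighted mean skeleton nQA over the internal-capsule slab.

    Only voxels carrying a skeleton value (non-NaN), with template streamline
    count > 0 and with z-center inside the inclusive slab contribute; each
    voxel is weighted by its streamline count.
    """
    counts = template.streamline_counts.values
    sel = (counts > 0) & slab_mask(skel_nqa, slab_mm) & np.isfinite(skel_nqa.values)
    w = counts[sel]
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"no weighted skeleton voxels for {template.side} {template.name} "
            f"in slab z = [{slab_mm[0]}, {slab_mm[1]}] mm"
        )
    return float(np.sum(w * skel_nqa.values[sel]) / total)


def global_wm_nqa(skel_nqa: Volume, masks: MaskSet) -> float:
    """Unweighted mean of skeletonized nQA over all skeleton voxels."""
    if not masks.skeleton.any():
        raise ValueError("skeleton mask is empty")
    vals = skel_nqa.values[masks.skeleton]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("skeleton carries no finite nQA values")
    return float(vals.mean())


def adjust_tract_nqa(
    unadjusted: float, global_nqa: float, slope: float, control_global_mean: float
) -> float:
    """Remove the global-white-matter component from a tract nQA value."""
    return float(unadjusted - slope * (global_nqa - control_global_mean))


def composite_corticomotor(
    crst_value: float, cst_value: float, weights: tuple[float, float]
) -> float:
    """Normative-volume weighted average of CRST and CST values."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("composite weights must be positive and sum to 1")
    return float(w[0] * crst_value + w[1] * cst_value)


def zscore(adjusted: float, ref_mean: float, ref_sd: float) -> float:
    """Standardize against the control mean and SD."""
    if ref_sd <= 0:
        raise ValueError(f"reference SD must be positive, got {ref_sd}")
    return float((adjusted - ref_mean) / ref_sd)


def resolve_ipsi_side(cohort: pd.DataFrame) -> pd.Series:
    """Ipsilesional side per participant id.

    Stroke participants use their own lesion side; each control uses the
    lesion side of the stroke participant sharing its ``pair_id``.
    """
    cohort = cohort.set_index("id", drop=False)
    stroke = cohort[cohort["group"] == "stroke"]
    side_by_pair = stroke.set_index("pair_id")["lesion_side"]
    out = {}
    for pid, row in cohort.iterrows():
        if row["group"] == "stroke":
            if row["lesion_side"] not in SIDES:
                raise ValueError(f"stroke participant {pid} has no lesion side")
            out[pid] = row["lesion_side"]
        else:
            if row["pair_id"] not in side_by_pair.index:
                raise ValueError(
                    f"control {pid} has no matched stroke partner for pair "
                    f"{row['pair_id']!r}; cannot assign an ipsilesional side"
                )
            out[pid] = side_by_pair.loc[row["pair_id"]]
    return pd.Series(out, name="ipsi_side")


def assign_laterality(
    side_values: dict[tuple[str, str], float], ipsi_side: str
) -> dict[str, float]:
    """Relabel (tract, side) values as ipsi-/contralesional roles."""
    if ipsi_side not in SIDES:
        raise ValueError(f"ipsi_side must be one of {SIDES}, got {ipsi_side!r}")
    contra = "right" if ipsi_side == "left" else "left"
    return {
        "iCRST": side_values[("CRST", ipsi_side)],
        "cCRST": side_values[("CRST", contra)],
        "iCST": side_values[("CST", ipsi_side)],
        "cCST": side_values[("CST", contra)],
    }


def composite_weights_from_templates(
    templates: dict[tuple[str, str], TractTemplate],
) -> tuple[float, float]:
    """(w_crst, w_cst) from mean normative volumes across sides."""
    v_crst = np.mean([templates[("CRST", s)].normative_volume for s in SIDES])
    v_cst = np.mean([templates[("CST", s)].normative_volume for s in SIDES])
    total = v_crst + v_cst
    return (float(v_crst / total), float(v_cst / total))


def participant_tract_values(
    skel_nqa: Volume,
    templates: dict[tuple[str, str], TractTemplate],
    masks: MaskSet,
    slab_mm: tuple[float, float] = DEFAULT_SLAB_MM,
) -> dict:
    """Per-side slab tract means plus the global skeleton mean."""
    out = {
        (name, side): tract_mean_nqa(skel_nqa, templates[(name, side)], slab_mm)
        for name in TRACTS
        for side in SIDES
    }
    out["global"] = global_wm_nqa(skel_nqa, masks)
    return out


def fit_reference(
    control_values: pd.DataFrame,
    templates: dict[tuple[str, str], TractTemplate] | None = None,
    composite_weights: tuple[float, float] | None = None,
) -> ReferenceModel:
    """Fit the control-only reference model.

    ``control_values`` needs one row per control with columns ``global_nqa``,
    ``crst_left``, ``crst_right``, ``cst_left``, ``cst_right`` and
    ``ipsi_side``.  Per tract family, the mean of the two sides is regressed
    on global nQA; control adjusted values are then computed with the fitted
    slopes, relabelled by laterality, composited, and summarized into per-role
    means and SDs.
    """
    n = len(control_values)
    if n < 3:
        raise ValueError(f"need at least 3 controls to fit the reference, got {n}")
    g = control_values["global_nqa"].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("global nQA has zero variance across controls; cannot fit slopes")
    if composite_weights is None:
        if templates is None:
            raise ValueError("provide templates or explicit composite_weights")
        composite_weights = composite_weights_from_templates(templates)

    fits = {}
    for fam in ("crst", "cst"):
        fam_mean = control_values[[f"{fam}_left", f"{fam}_right"]].mean(axis=1).to_numpy()
        res = sps.linregress(g, fam_mean)
        fits[fam] = (float(res.slope), float(res.rvalue**2))
    g_mean = float(g.mean())

    # adjusted, role-labelled control values -> per-role mean/SD
    per_role: dict[str, list[float]] = {r: [] for r in ROLES}
    slopes = {"CRST": fits["crst"][0], "CST": fits["cst"][0]}
    for _, row in control_values.iterrows():
        adj = {
            (name, side): adjust_tract_nqa(
                row[f"{name.lower()}_{side}"], row["global_nqa"], slopes[name], g_mean
            )
            for name in TRACTS
            for side in SIDES
        }
        roles = assign_laterality(adj, row["ipsi_side"])
        roles["iCorticomotor"] = composite_corticomotor(
            roles["iCRST"], roles["iCST"], composite_weights
        )
        roles["cCorticomotor"] = composite_corticomotor(
            roles["cCRST"], roles["cCST"], composite_weights
        )
        for r in ROLES:
            per_role[r].append(roles[r])

    tract_stats = {}
    for r in ROLES:
        vals = np.asarray(per_role[r])
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"control adjusted values for {r} have zero variance")
        tract_stats[r] = (float(vals.mean()), sd)

    return ReferenceModel(
        slope_crst=fits["crst"][0],
        slope_cst=fits["cst"][0],
        r2_crst=fits["crst"][1],
        r2_cst=fits["cst"][1],
        control_global_mean=g_mean,
        tract_stats=tract_stats,
        composite_weights=composite_weights,
        n_controls=n,
    )


def strength_records(
    values: pd.DataFrame, cohort: pd.DataFrame, reference: ReferenceModel
) -> pd.DataFrame:
    """Tidy tract-strength table: one row per participant and role.

    ``values`` needs columns id, global_nqa, crst_left/right, cst_left/right;
    ``cohort`` supplies group, pair_id and lesion_side for laterality.
    """
    ipsi = resolve_ipsi_side(cohort)
    slopes = {"CRST": reference.slope_crst, "CST": reference.slope_cst}
    rows = []
    for _, row in values.iterrows():
        pid = row["id"]
        raw = {
            (name, side): float(row[f"{name.lower()}_{side}"])
            for name in TRACTS
            for side in SIDES
        }
        adj = {
            key: adjust_tract_nqa(
                val, row["global_nqa"], slopes[key[0]], reference.control_global_mean
            )
            for key, val in raw.items()
        }
        side = ipsi.loc[pid]
        raw_roles = assign_laterality(raw, side)
        adj_roles = assign_laterality(adj, side)
        for pre, post in ((raw_roles, adj_roles),):
            pre["iCorticomotor"] = composite_corticomotor(
                pre["iCRST"], pre["iCST"], reference.composite_weights
            )
            pre["cCorticomotor"] = composite_corticomotor(
                pre["cCRST"], pre["cCST"], reference.composite_weights
            )
            post["iCorticomotor"] = composite_corticomotor(
                post["iCRST"], post["iCST"], reference.composite_weights
            )
            post["cCorticomotor"] = composite_corticomotor(
                post["cCRST"], post["cCST"], reference.composite_weights
            )
        for role in ROLES:
            mean, sd = reference.tract_stats[role]
            rows.append(
                {
                    "id": pid,
                    "role": role,
                    "unadjusted_nqa": raw_roles[role],
                    "global_nqa": float(row["global_nqa"]),
                    "adjusted_nqa": adj_roles[role],
                    "z_score": zscore(adj_roles[role], mean, sd),
                }
            )
    return pd.DataFrame(rows)


#: control constants as printed with the normative templates this package is
#: designed around: regression slopes 1.186 (CRST) / 2.702 (CST), control
#: global mean nQA 2.658, and per-role control means/SDs.
PUBLISHED_CONSTANTS = {
    "slope_crst": 1.186,
    "slope_cst": 2.702,
    "r2_crst": 0.735,
    "r2_cst": 0.883,
    "control_global_mean": 2.658,
    "tract_stats": {
        "iCRST": (3.407, 0.357),
        "cCRST": (3.093, 0.272),
        "iCST": (5.106, 0.718),
        "cCST": (4.862, 0.534),
        "iCorticomotor": (4.023, 0.145),
        "cCorticomotor": (3.734, 0.169),
    },
}


def published_reference_model(
    composite_weights: tuple[float, float] = (0.31, 0.69),
) -> ReferenceModel:
    """Frozen reference model with the published control constants.

    Intended for worked examples and single-participant z-scoring; analysis
    runs refit the reference from their own control cohort.  The published
    record does not include normative tract volumes, so the composite weights
    default to the synthetic-template ratio and can be overridden.
    """
    return ReferenceModel(composite_weights=composite_weights, **PUBLISHED_CONSTANTS)
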