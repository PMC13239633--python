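"""Tract strength arithmetic: slab means, adjustment, composites, z-scores."""

import numpy as np
import pandas as pd
import pytest

from tractconfound.synthetic import make_cohort, make_participant_volume, CohortParams
from tractconfound.tracts import (
    ReferenceModel,
    TractTemplate,
    adjust_tract_nqa,
    assign_laterality,
    composite_corticomotor,
    fit_reference,
    global_wm_nqa,
    participant_tract_values,
    published_reference_model,
    resolve_ipsi_side,
    strength_records,
    tract_mean_nqa,
    zscore,
)
from tractconfound.volumes import (
    GridSpec,
    MaskSet,
    Volume,
    normalize_qa,
    project_to_skeleton,
)


def skel_volume(grid, entries):
    """Sparse skeletonized volume: {(i,j,k): value}."""
    vals = np.full(grid.dims, np.nan)
    for idx, v in entries.items():
        vals[idx] = v
    return Volume(vals, grid, skeletonized=True)


def template_with(grid, counts_entries, name="CRST", side="left"):
    counts = np.zeros(grid.dims)
    for idx, c in counts_entries.items():
        counts[idx] = c
    return TractTemplate(name, side, Volume(counts, grid), float(np.count_nonzero(counts)))


GRID = GridSpec((16, 16, 20), 1.0, -6.0)  # z from -6 to 13 mm


class TestTractMeanNQA:
    def test_uniform_value_for_any_weights(self):
        entries = {(1, 1, k): 2.5 for k in range(3, 10)}
        counts = {(1, 1, k): 10 * k for k in range(3, 10)}
        val = tract_mean_nqa(skel_volume(GRID, entries), template_with(GRID, counts))
        assert val == pytest.approx(2.5)

    def test_two_voxel_hand_arithmetic(self):
        # values (2, 4) with weights (1, 3) -> 3.5
        entries = {(1, 1, 6): 2.0, (1, 2, 6): 4.0}
        counts = {(1, 1, 6): 1.0, (1, 2, 6): 3.0}
        val = tract_mean_nqa(skel_volume(GRID, entries), template_with(GRID, counts))
        assert val == pytest.approx(3.5)

    def test_slab_excludes_out_of_range_voxel(self):
        # k=19 -> z = 13 mm, outside [-5, 12]
        entries = {(1, 1, 6): 2.0, (1, 1, 19): 100.0}
        counts = {(1, 1, 6): 1.0, (1, 1, 19): 50.0}
        val = tract_mean_nqa(skel_volume(GRID, entries), template_with(GRID, counts))
        assert val == pytest.approx(2.0)

    def test_slab_bounds_inclusive(self):
        # k=1 -> z = -5 mm and k=18 -> z = 12 mm are both inside
        entries = {(1, 1, 1): 3.0, (1, 1, 18): 5.0}
        counts = {(1, 1, 1): 1.0, (1, 1, 18): 1.0}
        val = tract_mean_nqa(skel_volume(GRID, entries), template_with(GRID, counts))
        assert val == pytest.approx(4.0)

    def test_zero_weight_in_slab_rejected(self):
        entries = {(1, 1, 19): 1.0}
        counts = {(1, 1, 19): 1.0}
        with pytest.raises(ValueError, match="CRST"):
            tract_mean_nqa(skel_volume(GRID, entries), template_with(GRID, counts))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        entries, counts = {}, {}
        for _ in range(60):
            idx = tuple(rng.integers(0, [16, 16, 20]))
            entries[idx] = float(rng.uniform(1, 5))
            counts[idx] = float(rng.uniform(0, 4))
        vol = skel_volume(GRID, entries)
        tpl = template_with(GRID, counts)
        # independent triple-loop oracle
        num = den = 0.0
        for i in range(16):
            for j in range(16):
                for k in range(20):
                    z = -6.0 + k
                    w = tpl.streamline_counts.values[i, j, k]
                    v = vol.values[i, j, k]
                    if w > 0 and -5 <= z <= 12 and np.isfinite(v):
                        num += w * v
                        den += w
        assert tract_mean_nqa(vol, tpl) == pytest.approx(num / den, abs=1e-12)


class TestGlobalWMnQA:
    def make_masks(self, grid, skeleton_idx):
        skel = np.zeros(grid.dims, dtype=bool)
        for idx in skeleton_idx:
            skel[idx] = True
        return MaskSet(
            csf=np.zeros(grid.dims, dtype=bool),
            skeleton=skel,
            white_matter=skel.copy(),
            grid=grid,
        )

    def test_mean_of_skeleton_values(self):
        masks = self.make_masks(GRID, [(1, 1, 5), (1, 1, 6)])
        vol = skel_volume(GRID, {(1, 1, 5): 1.0, (1, 1, 6): 3.0, (2, 2, 5): 99.0})
        assert global_wm_nqa(vol, masks) == pytest.approx(2.0)

    def test_empty_skeleton_rejected(self):
        masks = self.make_masks(GRID, [(1, 1, 5)])
        masks.skeleton[:] = False
        with pytest.raises(ValueError):
            global_wm_nqa(skel_volume(GRID, {}), masks)


class TestAdjustment:
    def test_at_control_global_mean_is_identity(self):
        assert adjust_tract_nqa(2.9, 2.658, 1.186, 2.658) == pytest.approx(2.9)

    def test_hand_arithmetic(self):
        # 3.0 - 1.186 * (3.0 - 2.658) = 2.594 (3 d.p.)
        assert adjust_tract_nqa(3.0, 3.0, 1.186, 2.658) == pytest.approx(2.594, abs=5e-4)

    def test_zero_slope_is_identity(self):
        assert adjust_tract_nqa(1.7, 9.9, 0.0, 2.658) == 1.7


class TestCompositeAndZ:
    def test_composite_values(self):
        assert composite_corticomotor(2.0, 4.0, (0.5, 0.5)) == pytest.approx(3.0)
        assert composite_corticomotor(2.0, 4.0, (0.25, 0.75)) == pytest.approx(3.5)
        assert composite_corticomotor(7.0, 7.0, (0.31, 0.69)) == pytest.approx(7.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            composite_corticomotor(1.0, 2.0, (0.5, 0.6))

    def test_zscore_identities(self):
        assert zscore(3.093, 3.093, 0.272) == 0.0
        assert zscore(3.365, 3.093, 0.272) == pytest.approx(1.0, abs=1e-12)
        assert zscore(5.0, 3.0, 1.0) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore(1.0, 0.0, 0.0)


class TestLaterality:
    SIDE_VALUES = {
        ("CRST", "left"): 1.0,
        ("CRST", "right"): 2.0,
        ("CST", "left"): 3.0,
        ("CST", "right"): 4.0,
    }

    def test_stroke_right_lesion(self):
        roles = assign_laterality(self.SIDE_VALUES, "right")
        assert roles["iCRST"] == 2.0 and roles["cCRST"] == 1.0
        assert roles["iCST"] == 4.0 and roles["cCST"] == 3.0

    def test_control_inherits_partner_side(self):
        cohort = pd.DataFrame(
            [
                {"id": "S0", "group": "stroke", "pair_id": "P0", "lesion_side": "left"},
                {"id": "C0", "group": "control", "pair_id": "P0", "lesion_side": "none"},
            ]
        )
        ipsi = resolve_ipsi_side(cohort)
        assert ipsi["C0"] == "left"
        roles = assign_laterality(self.SIDE_VALUES, ipsi["C0"])
        assert roles["iCST"] == 3.0  # left CST

    def test_unmatched_control_rejected(self):
        cohort = pd.DataFrame(
            [{"id": "C0", "group": "control", "pair_id": "P9", "lesion_side": "none"}]
        )
        with pytest.raises(ValueError, match="matched"):
            resolve_ipsi_side(cohort)


def control_frame(n, slope_crst=1.2, slope_cst=2.5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(2.658, 0.25, n)
    df = pd.DataFrame({"id": [f"C{i}" for i in range(n)], "global_nqa": g})
    for fam, slope, mean in (("crst", slope_crst, 3.25), ("cst", slope_cst, 4.98)):
        for side in ("left", "right"):
            df[f"{fam}_{side}"] = mean + slope * (g - 2.658) + rng.normal(0, noise, n)
    df["ipsi_side"] = ["left", "right"] * (n // 2) + ["left"] * (n % 2)
    return df


class TestReferenceModel:
    def test_near_noise_free_fit_recovers_planted_slopes(self):
        # vanishing tract noise: slopes exact, r^2 -> 1 (exactly noise-free
        # adjusted values would have zero variance and no usable z-scale)
        df = control_frame(12, noise=1e-6, seed=1)
        ref = fit_reference(df, composite_weights=(0.31, 0.69))
        assert ref.slope_crst == pytest.approx(1.2, abs=1e-3)
        assert ref.slope_cst == pytest.approx(2.5, abs=1e-3)
        assert ref.r2_crst == pytest.approx(1.0, abs=1e-6)

    def test_controls_self_zscore_to_standard_normal_moments(self):
        df = control_frame(20, noise=0.2, seed=3)
        ref = fit_reference(df, composite_weights=(0.31, 0.69))
        cohort = pd.DataFrame(
            {
                "id": df["id"],
                "group": "control",
                "pair_id": [f"P{i}" for i in range(20)],
                "lesion_side": "none",
            }
        )
        # pair each control with a placeholder stroke participant
        strokes = pd.DataFrame(
            {
                "id": [f"S{i}" for i in range(20)],
                "group": "stroke",
                "pair_id": [f"P{i}" for i in range(20)],
                "lesion_side": df["ipsi_side"].to_numpy(),
            }
        )
        records = strength_records(df, pd.concat([cohort, strokes]), ref)
        for role, grp in records.groupby("role"):
            assert grp["z_score"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["z_score"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="controls"):
            fit_reference(control_frame(2), composite_weights=(0.31, 0.69))

    def test_zero_global_variance_rejected(self):
        df = control_frame(6)
        df["global_nqa"] = 2.658
        with pytest.raises(ValueError, match="variance"):
            fit_reference(df, composite_weights=(0.31, 0.69))

    def test_published_preset_constants(self):
        ref = published_reference_model()
        assert ref.slope_crst == 1.186 and ref.slope_cst == 2.702
        assert ref.control_global_mean == 2.658
        assert ref.tract_stats["cCRST"] == (3.093, 0.272)

    def test_json_round_trip(self, tmp_path):
        ref = published_reference_model()
        p = ref.to_json(tmp_path / "ref.json")
        back = ReferenceModel.from_json(p)
        assert back == ref


class TestPipelineMonotonicity:
    def test_icrst_z_strictly_decreases_with_attenuation(self, phantom):
        """More ipsilesional damage always lowers the iCRST z-score."""
        from tractconfound.synthetic import PhantomParams

        templates, masks = phantom
        ref = published_reference_model()
        zs = []
        for att in (1.0, 0.8, 0.6, 0.4, 0.2):
            vol = make_participant_volume(
                templates, masks,
                PhantomParams(tract_attenuation={("CRST", "left"): att}),
            )
            skel = project_to_skeleton(normalize_qa(vol, masks.csf), masks, 2)
            vals = participant_tract_values(skel, templates, masks)
            adj = adjust_tract_nqa(
                vals[("CRST", "left")], vals["global"],
                ref.slope_crst, ref.control_global_mean,
            )
            mean, sd = ref.tract_stats["iCRST"]
            zs.append(zscore(adj, mean, sd))
        assert all(a > b for a, b in zip(zs, zs[1:]))
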