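"""Quantify tract strength for one simulated stroke participant.

Renders a participant with 40% attenuation of the left (ipsilesional) motor
tracts and 15% elevation of the right (contralesional) ones, runs CSF
normalization and skeleton projection, and expresses each tract's
streamline-weighted internal-capsule nQA as a z-score against the published
control constants.
"""

from tractconfound import (
    GridSpec,
    make_templates,
    make_participant_volume,
    normalize_qa,
    project_to_skeleton,
    published_reference_model,
    adjust_tract_nqa,
    zscore,
)
from tractconfound.synthetic import PhantomParams
from tractconfound.tracts import assign_laterality, composite_corticomotor, participant_tract_values

grid = GridSpec((48, 48, 48), 2.0, -40.0)
templates, masks = make_templates(grid, seed=0)

params = PhantomParams(
    tract_attenuation={("CRST", "left"): 0.6, ("CST", "left"): 0.6},
    tract_elevation={("CRST", "right"): 1.15, ("CST", "right"): 1.15},
    scanner_gain=1.2,
)
vol = make_participant_volume(templates, masks, params)
skel = project_to_skeleton(normalize_qa(vol, masks.csf), masks, search_radius_vox=2)
vals = participant_tract_values(skel, templates, masks)

ref = published_reference_model()
slopes = {"CRST": ref.slope_crst, "CST": ref.slope_cst}
adjusted = {
    key: adjust_tract_nqa(v, vals["global"], slopes[key[0]], ref.control_global_mean)
    for key, v in vals.items()
    if key != "global"
}
roles = assign_laterality(adjusted, ipsi_side="left")
roles["iCorticomotor"] = composite_corticomotor(
    roles["iCRST"], roles["iCST"], ref.composite_weights
)
roles["cCorticomotor"] = composite_corticomotor(
    roles["cCRST"], roles["cCST"], ref.composite_weights
)

print(f"global white-matter nQA: {vals['global']:.3f}")
print(f"{'role':<14}{'adjusted nQA':>14}{'z-score':>10}")
for role, adj in roles.items():
    mean, sd = ref.tract_stats[role]
    print(f"{role:<14}{adj:>14.3f}{zscore(adj, mean, sd):>10.2f}")
print("\nNegative ipsilesional z-scores quantify damage; positive")
print("contralesional z-scores quantify upregulation, both in control SDs.")
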