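"""Test whether the cCRST-walking association survives adjustment.

Generates a 10-pair cohort under the confounded null (no direct effect of
contralesional CRST strength on walking), fits the unadjusted and adjusted
walking models, applies the >10% change-in-estimate rule, and screens for
influential observations with Cook's distance.
"""

import pandas as pd

from tractconfound import (
    CohortParams,
    assess_confounding,
    cooks_influence,
    fit_linear,
    make_tabular_cohort,
)

params = CohortParams(n_pairs=10, beta_direct=0.0, seed=42)
df = make_tabular_cohort(params)

upreg = fit_linear(
    df["z_ccrst"], pd.DataFrame({"iCorticomotor": df["z_icorticomotor"]})
)
print("cCRST strength ~ iCorticomotor strength:")
print(f"  slope {upreg.params['iCorticomotor']:.3f} "
      f"(p = {upreg.pvalues['iCorticomotor']:.3g})")

ca = assess_confounding(
    df["six_mwd_m"], df["z_ccrst"], df["z_icorticomotor"],
    exposure_name="cCRST", covariate_name="iCorticomotor",
)
print("\n6MWD ~ cCRST strength (unadjusted vs adjusted):")
print(f"  unadjusted coefficient: {ca.unadjusted_coef:8.2f} m per SD")
print(f"  adjusted coefficient:   {ca.adjusted_coef:8.2f} m per SD")
print(f"  shrinkage: {ca.shrinkage_fraction:.0%}  ->  confounded: {ca.confounded}")

influence = cooks_influence(ca.adjusted_fit)
print(f"\nCook's distance threshold (median F(3, 17)): {influence.threshold:.3f}")
print(f"flagged participants: {influence.flagged_ids or 'none'}")
print("\nA negative unadjusted coefficient that collapses after adjusting for")
print("ipsilesional strength is the hallmark of confounding: upregulation")
print("marks damage severity rather than harming walking itself.")
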