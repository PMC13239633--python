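# tractconfound

Tract-strength quantification from diffusion MRI quantitative anisotropy
(QA) volumes, and a confounding analysis of contralesional
corticoreticulospinal tract (cCRST) upregulation after stroke.

## The problem

After a stroke that damages the descending motor pathways on one side,
imaging often shows *stronger* corticoreticulospinal projections on the
opposite (contralesional) side, and that upregulation correlates with
*worse* walking capacity. Does the upregulated pathway hinder walking, or
does it simply mark the people with the most ipsilesional damage — who both
upregulate more and walk less? This package implements the measurement and
analysis chain needed to ask that question quantitatively, for researchers
in stroke neuroimaging and motor rehabilitation.

## The method

Per participant, starting from a voxel-wise QA volume in standard space:

1. **Normalization** — nQA = QA / mean QA in ventricular CSF, removing
   acquisition gain.
2. **Skeleton projection** — each voxel of the white-matter skeleton
   receives the highest nearby nQA (Chebyshev search radius, default 2
   voxels, restricted to white matter), correcting residual misalignment.
3. **Tract strength** — for each tract *t* (CRST/CST, left/right), the
   streamline-count weighted mean of skeletonized nQA over the
   internal-capsule slab (z = −5 to 12 mm):
   `tract_nQA_t = Σ_v w_v nQA_v / Σ_v w_v`.
4. **Global adjustment** — with slopes β_t fit on controls only
   (tract nQA regressed on global skeleton nQA):
   `adj_t,i = tract_nQA_t,i − β_t (global_i − global_control_mean)`.
5. **Laterality and composites** — sides are relabelled ipsi/contralesional
   by lesion side (controls inherit their matched stroke partner's side);
   corticomotor strength is the normative-volume weighted average of CRST
   and CST.
6. **z-scores** — `z = (adj − control_mean) / control_SD` per role.

Cohort analysis: independent t-tests per role; OLS models
`cCRST ~ iCorticomotor`, `6MWD ~ cCRST`, and `6MWD ~ cCRST + iCorticomotor`;
confounding is declared when adjustment shrinks the cCRST coefficient by
more than 10%; influential observations are flagged where Cook's distance
exceeds the median of F(p, n−p) and probed by leave-one-out refits; minimum
detectable effects come from exact noncentral-t (or bias-corrected Fisher-z)
power at 80% power, two-sided α = 0.05.

A first-class synthetic-data module generates tract templates, masks, QA
phantoms and matched cohorts with the full causal structure (latent
ipsilesional damage driving both upregulation and reduced walking), so every
stage can be validated without any imaging download.

## Worked example

`python examples/confounding_analysis.py` generates a 10-pair cohort in
which contralesional upregulation has *no* direct effect on walking, then
runs the analysis:

```
cCRST strength ~ iCorticomotor strength:
  slope -0.304 (p = 7.4e-05)

6MWD ~ cCRST strength (unadjusted vs adjusted):
  unadjusted coefficient:   -85.56 m per SD
  adjusted coefficient:     -25.16 m per SD
  shrinkage: 71%  ->  confounded: True

Cook's distance threshold (median F(3, 17)): 0.821
flagged participants: none
```

Reading: unadjusted, each control-SD of cCRST strength predicts ~86 m less
walking — yet the effect was planted at zero. Adjusting for ipsilesional
corticomotor strength collapses the coefficient (71% shrinkage, above the
10% rule), correctly exposing the association as confounding by damage
severity. The other examples cover phantom simulation, single-participant
z-scoring, power analysis and the full pipeline; a thin CLI
(`tractconfound simulate|quantify|stats|run`) wraps the same functions for
shell use.

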