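# Methods

This note documents the models, parameter choices and numerical conventions
behind `tractconfound`, and what the synthetic validation does and does not
establish about real data.

## Measurement model

**Normalization.** QA carries an arbitrary scanner- and session-dependent
multiplicative gain. Ventricular CSF is unaffected by white-matter pathology,
so dividing every voxel by the participant's mean QA over a CSF mask yields
nQA values in units of "multiples of CSF QA". The operation is exactly
invariant to any global gain k > 0 (up to float rounding; the property tests
check 1e-12 relative agreement, not bit identity, because the division by
the CSF mean rounds differently at different gains).

**Skeleton projection.** Standard-space registration leaves residual
misalignment of bundle cores, worse after stroke. Each one-voxel-thick
skeleton voxel therefore receives the maximum nQA over nearby white matter.
"Nearby" is a Chebyshev (cube) radius, default 2 voxels, exposed in the
configuration; a perpendicular-to-skeleton search like FSL TBSS's would be
less testable and is deliberately out of scope. Two refinements:

* Donors are white-matter voxels *off* the skeleton plus the skeleton voxel
  itself. Excluding other skeleton voxels prevents search windows from
  chaining along a bundle core, which makes the projection idempotent:
  re-projecting an already skeletonized volume returns it unchanged.
* When a lesion mask is supplied, lesioned voxels are excluded from the
  donor set. Projection corrects misalignment; it must not "rescue"
  necrotic tissue by importing values from healthy neighbours.

Off-skeleton voxels carry NaN, an explicit no-data sentinel. Zero is never
used, so off-skeleton voxels cannot bias downstream means.

**Tract strength.** Per tract and side, strength is the streamline-count
weighted mean of skeletonized nQA over template voxels whose z-center lies
in the internal-capsule slab, z ∈ [−5, 12] mm inclusive at both ends (the
source convention for the endpoints is unstated; inclusive-on-voxel-centers
is ours). z-coordinates come from the volume header (z_origin + k · voxel
size).

**Adjustment and z-scores.** Tract nQA is adjusted for global white-matter
nQA with slopes fit by OLS on controls only, regressing the left/right mean
of each tract family on global nQA. The reference model is always refit
from the supplied control cohort. The published control constants (slopes
1.186 and 2.702, r² 0.735 and 0.883, control global mean 2.658, and the
per-role means/SDs of the published z-score formulas) ship as an explicit
frozen preset (`published_reference_model()`, CLI `--preset published`) for
worked examples and single-participant scoring — never silently as
defaults. Note a discrepancy in the published record itself: the z-formula
denominators (0.357, 0.272, 0.718, 0.534) differ from the tabulated control
SDs (0.14, 0.22, 0.24, 0.24). We do not resolve it; computing SDs from the
control data at hand sidesteps the question for every analysis run, and the
preset reproduces the printed formulas as printed.

The corticomotor composite is the normative-volume weighted average of the
*adjusted* CRST and CST values, z-scored with composite-specific control
statistics (matching the published equation ordering). Normative volume is
the count of voxels with any streamline in the whole template, not the
slab; the published record does not define it, and the whole tract is the
natural reading of "tract volume". Controls inherit the ipsilesional side
of their matched stroke partner.

## Cohort statistics

* **Group contrasts**: pooled-variance independent t-tests by default (the
  published table language suggests a two-group linear-model contrast, which
  the pooled test equals); Welch available. Degenerate zero-variance input
  is guarded: identical groups give p = 1, distinct means with zero
  within-group variance give p → 0.
* **Confounding**: shrinkage = (|b_unadj| − |b_adj|) / |b_unadj|, flagged
  when strictly greater than the 0.10 threshold. Absolute values make the
  rule sign-safe; a sign flip with a larger adjusted magnitude yields
  negative shrinkage, reported but never flagged.
* **Influence**: Cook's distance per observation, threshold the median of
  F(p, n − p) with p counting the intercept — the convention that yields
  0.821 at p = 3, n = 20. Flagged observations trigger leave-one-out
  refits with before/after coefficient tables. Unit leverage raises an
  error (distance undefined).
* **Power**: minimum detectable effects are root-found (Brent's method,
  xtol 1e-10) on exact noncentral-t power for t tests, and on the Fisher-z
  approximation with the r/(2(n−1)) bias correction for correlations — the
  formula that yields r = 0.58 at n = 20. NaN underflow in the far
  noncentral-t tail is clamped to its limit value.
* Two-sided p values, α = 0.05, no multiple-testing correction anywhere.

## Synthetic-data generator

The phantom is deliberately minimal: four straight vertical tubes with
Gaussian streamline-density cross-sections (CRST medial and thin, CST
lateral and wide, so the CST normative volume and composite weight are
larger), a 3-voxel-thick background sheet whose mid-plane joins the tube
cores to form the skeleton, and a ventricular CSF box. Only the
slab-weighted arithmetic matters downstream, so anatomical realism is not
attempted. Geometry stays ≥ 2 voxels clear of the volume edge so that rigid
misalignment never truncates tissue under a mask, and the CSF compartment
extends 2 voxels beyond its sampling mask for the same reason.

Control biology: per participant, global nQA G ~ N(2.658, 0.25); per tract
and side, tract nQA = mean + slope · (G − 2.658) + ε, with means 3.25
(CRST) / 4.98 (CST), structural slopes 1.186 / 2.702, and tract noise SDs
0.25 / 0.35. Those noise SDs were chosen so the control regressions of
side-averaged tract nQA on global nQA have r² near 0.74 and 0.88 — the
published fit quality — since the published record does not report the
underlying spreads. The volume builder solves the background-sheet level in
closed form so that the realized skeleton-mean global nQA equals the drawn
G exactly at factor 1, which is what lets a regression on measured volumes
recover the planted slopes.

Stroke effects: a latent deficit D ≥ 0 (truncated normal, mean 8, SD 2.5,
in control-SD units of composite corticomotor strength) drives

* ipsilesional attenuation a = 1 − c·D (clipped to [0, 1]), with c chosen
  so one unit of D costs one control SD of composite strength;
* contralesional elevation 1 + δ·D + noise (δ = 0.02, noise SD 0.04;
  applied at 0.8 δ to the CST), floored at 1;
* walking capacity 6MWD = 500 + 40 · z(actual iCorticomotor strength)
  + β_direct · z(actual cCRST strength) + N(0, 60) meters, truncated at 0.

Two points matter. First, the outcome depends on the participant's *actual*
tract strength — including their biological tract-level deviations — not on
the latent D alone. Conditioning on measured ipsilesional strength can then
remove the confounding path completely, which is exactly the behaviour the
change-in-estimate analysis is designed to detect; had the outcome depended
on an unobservable latent only, every adjustment would leave residual
confounding by construction. Second, β_direct defaults to 0: the default
cohort is a *confounded null*, where any cCRST–walking association exists
only through damage severity. Truncation of 6MWD at 0 is a deliberate
deviation from the pure linear model; the default noise makes it rare
(affecting only the most damaged few percent) and its bias is verified to
stay within Monte-Carlo error in the replicate tests.

Acquisition nuisances per participant: log-normal scanner gain
(log-SD 0.3), additive voxel noise (SD 0.02, clipped at 0), and a random
rigid integer-voxel shift in {−1, 0, 1}³ — the variabilities that
normalization and projection are designed to absorb. An optional spherical
lesion zeroes QA before gain and noise, mimicking tissue loss rather than
acquisition artifact. Randomness uses one master seed with per-pair
counter-keyed substreams, so cohorts are reproducible under reordering and
the fast tabular path reuses the identical latent draws as the volume path.

`make_tabular_cohort` emits the true adjusted z-scores in closed form
(skipping rendering and measurement), for fast statistical validation; with
all noise at 0 its rows match `make_cohort`'s latent values exactly.

**What the synthetic validation does not show.** The phantom has no real
anatomy, no registration error beyond rigid integer shifts, no
spatially-correlated noise, no partial-volume effects, and lesions that
never overlap CSF or distort geometry. Passing tests demonstrate that the
arithmetic, invariances and decision rules are implemented correctly and
behave as designed under the stated causal structure — not that the
published effect sizes would be recovered from any particular scanner's
data.

## Problem sizes and numerical choices

Default runs use a 48³ grid at 2 mm (z origin −40 mm, so the slab lies well
inside the volume) and 10 matched pairs; the reference-slope validation
uses 200 synthetic controls, and the confounding replicate study 200
cohorts of 10 pairs — sizes at which the whole suite and the acceptance
script each complete in seconds on one CPU. OLS goes through statsmodels
(QR-based); rank deficiency is detected before fitting and reported with
the offending column names. The slab mean raises an error (naming tract and
slab) when no weighted voxel lies in range, rather than returning NaN.
Stage outputs are SHA-256 hashed into a provenance record; a rerun with an
unchanged configuration hash skips stages whose outputs still match their
hashes.

## Known limitations

* The projection search is isotropic; bundles running obliquely to the
  skeleton would be better served by a perpendicular search.
* The change-in-estimate rule is a heuristic, not a causal estimator; no
  mediation or sensitivity analysis beyond leave-one-out is provided.
* Lesion-volume covariates and mixed models are out of scope.
* The published preset's composite weights are not part of the published
  record (tract volumes were not printed); the preset defaults to the
  synthetic-template ratio (0.31/0.69) and accepts overrides.
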