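# Methods

This note documents the statistical model behind `ctdna-mr`, every
default parameter, and the numerical and design decisions.

## 1. Variant origin classification (`variant_origin`)

Each unique plasma variant (keyed by patient, chromosome, position,
ref, alt) is assigned one origin by the first matching rule:

1. **Hotspot → tumor.** Variants matching a curated cancer-hotspot list
   (by genomic key when present, else by gene + protein change; the
   built-in list covers recurrent KRAS/NRAS/BRAF/EGFR/PIK3CA drivers)
   are tumor-derived even when detected in the WBC library, because
   buffy-coat contamination by circulating tumor cells can seed true
   tumor mutations into the WBC sequencing.
2. **WBC-shared, germline-band everywhere → germline.** Non-hotspot
   variants detected in WBC DNA at allele fraction ≥ 0.25 (default
   `germline_maf_threshold`) **and** at ≥ 0.25 in every plasma sample
   where the variant was measured. Timepoints where the variant was not
   called are not measurements of the allele and do not veto the rule.
3. **WBC-shared otherwise → hematopoietic** (clonal hematopoiesis).
   WBC detection requires ≥ 1 mutant read family
   (`DEFAULT_WBC_MIN_READS`).
4. **Everything else → tumor.**

Patients without a WBC sample cannot be filtered: their variants are
labeled tumor with a `wbc_missing` provenance flag. Germline and
hematopoietic variants are excluded from tumor-load computation.
When matched tumor-tissue sequencing exists, tumor-labeled plasma calls
are checked against it (variant-level and patient-level concordance);
discordant calls are reported, never reclassified.

## 2. Tumor load and molecular response (`tumor_load_response`)

Circulating tumor load at each timepoint (C1D1 baseline, C2D1, C3D1) is
the **maximum MAF** over the patient's tumor-derived variants (mean and
median are computed alongside). A tumor variant absent from an
available sample contributes MAF 0 — absence in an adequate library is
an observation of clearance, not missing data.

Response calling, with clearance threshold 0 (exact undetectability):

- **not_evaluable**: no baseline sample, or no on-therapy sample.
- **undetectable**: load 0 at every available timepoint.
- **mR**: load cleared to 0 at the *decision timepoint* — the last
  available on-therapy draw (C3D1, or C2D1 when C3D1 was missed). The
  clearance timepoint reported is the first cleared draw.
- **mPD**: detectable at the decision timepoint. This includes
  *transient clearance* (cleared at C2D1, detectable again at C3D1).

Kinetic patterns: `clearance_C2`, `clearance_C3`, `deep_reduction`
(mPD with best on-therapy reduction strictly > 0.85 of baseline),
`persistence`, `none` (undetectable). Calls are invariant under
rescaling all MAFs, which is verified property-based.

## 3. Concordance statistics (`concordance_stats`)

The 2×2 table crosses molecular status (mR/mPD only) with radiographic
best overall response (responder = CR/PR or iCR/iPR; NE excluded).
Sensitivity = a/(a+b) over responders, specificity = d/(c+d) over
non-responders.

Confidence intervals are exact **Clopper–Pearson**, via the
beta-quantile identity: lower endpoint `Beta(k, n−k+1).ppf(α/2)`, upper
`Beta(k+1, n−k).ppf(1−α/2)`, clamped at k = 0 and k = n. The default
level is two-sided 90%, whose lower endpoint is the **one-sided 95%
lower confidence bound** used as a success criterion against 0.50.
The exact binomial test offers four tail rules: `two-sided`
(minimum-likelihood, scipy's default), `central` (twice the smaller
tail), `lower`, `upper`. The central and two-sided rules can differ
noticeably at small n; both are exposed because published reports do
not always state which rule was used.

`min_responders_for_bound` returns the *smallest* n for which the least
favorable responder count at an assumed sensitivity keeps the CI lower
bound above a threshold. Note the bound is not monotone in n, so the
smallest sufficient n can be below a sample size quoted from a design
that also weighed other constraints.

## 4. Depth of response and ROC (`depth_response_roc`)

Depth d = (m₁ − mₓ)/m₁ for baseline load m₁ and on-therapy load mₓ;
d = 1 is clearance, d < 0 an increase. d is undefined at m₁ = 0; such
patients receive the cohort minimum of the defined depths (the largest
observed increase), flagged `imputed`. The AUC for predicting
radiographic response is computed from the trapezoidal ROC integral,
which equals the normalized Mann–Whitney U with ties counted one half
(asserted against a brute-force pairwise oracle). The default CI is
DeLong's placement-value asymptotic interval; a seeded percentile
bootstrap is available.

## 5. Limit of detection (`lod_model`)

With n error-corrected read families and true allele fraction p, the
mutant count is X ~ Binomial(n, p) and a variant is called when
X ≥ 3 (`DEFAULT_MIN_MUTANT_READS`). Detection probability uses the
binomial survival function (stable where naive tail summation cancels);
assay-level sensitivity at each MAF on the grid (0.1%, 0.2%, 0.3%,
0.5%, 1%) is the **median** detection probability across the loci
carrying tumor-derived variants at baseline, each at its observed
distinct coverage. At coverage ≈ 3000 this gives ≈ 93–94% at 0.2% MAF
and > 99% at 0.3%, matching the Poisson limit
1 − e^(−np)(1 + np + (np)²/2) to ~10⁻³.

## 6. Survival analysis (`survival_analysis`)

Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards
regression (Efron tie handling, Wald CIs) are delegated to lifelines.
Conventions: times in months with 1 month = 30.4375 days; median
survival CIs at 90%, hazard-ratio CIs at 95%; a median that is never
reached is an explicit state (`reached: false`), not a number.
Constant covariates yield HR 1 by construction; monotone-likelihood
fits come back flagged (`converged: false`) rather than raising.
Time to molecular response runs from treatment start to the clearance
draw's collection day for mR patients and is censored at the last
liquid-biopsy draw otherwise.

## 7. Synthetic cohort generator (`synthetic_cohort`)

The generator draws a cohort with the full statistical structure the
pipeline consumes: per-patient plasma draws (C3 missed with probability
0.13, whole on-therapy series missing with probability 0.06), a WBC
sample, radiographic BOR (responder probability 0.32; NE 0.04), latent
molecular state (undetectable 0.20 among evaluable; P(mR | responder) =
0.82, P(mPD | non-responder) = 0.75; clearance at C2 with probability
13/15 given mR), tumor variants (1 + Poisson(0.8) per detectable
patient, log-normal baseline MAFs clipped to [0.001, 0.35]), CHIP and
germline contaminants (17% and 5% of unique plasma variants), binomial
read resampling at Normal(3000, 300) coverage, optional tumor-tissue
sequencing (40% of patients, 10% injected discordance) and exponential
PFS/OS with stratum-specific medians under uniform 2.5–23-month
follow-up. A `design_preset` encodes 45% response rate and 70%
sensitivity/specificity design assumptions.

Scope decisions, so that end-to-end tests can demand *exact* truth
recovery rather than approximate agreement:

- germline allele fractions stay in [0.40, 0.60] and CHIP plasma MAFs
  ≤ 0.05 with WBC MAF ≤ 0.10, keeping every injected variant strictly
  on one side of the 0.25 germline threshold;
- persistence multipliers lie in [0.3, 1.5] and deep-reduction
  multipliers in [0.01, 0.13], so observed reductions stay clear of the
  0.85 deep-reduction boundary after binomial resampling (baselines for
  deep reductions are floored at MAF 0.02);
- where detection is semantically required (baseline observations, the
  load-defining variant of persisting patients, contaminants), binomial
  draws of zero reads are floored at one read (`force_detect`);
  elsewhere variants may drop out naturally.

Rule-edge behavior (values exactly at thresholds) is exercised by
dedicated hand-built fixtures in the test suite, not by the generator.
Every latent assignment is returned in ground-truth tables.

## 8. Numerical and design decisions

- Exact CIs come from scipy beta quantiles; tests verify them against
  an independent binomial-tail root-finding oracle to 10⁻⁹.
- Percentages print with round-half-away-from-zero, matching clinical
  reporting convention rather than banker's rounding.
- All outputs are byte-deterministic for fixed input and seed: sorted
  JSON keys, fixed float format (`%.10g`) in TSVs, no timestamps in
  `manifest.json`, manifest paths relative to the output directory.
- The pipeline runs seven fixed-order stages (validate → origins →
  responses → concordance → depth/ROC → LOD → survival); stages
  short-circuit gracefully with a notice when prerequisites are absent
  (no tumor samples, no evaluable patients, a single response class)
  and any hard failure aborts with the stage name (exit code 3).

## 9. Limitations

- The generator reproduces cohort-level statistical structure, not
  biology: no subclonal phylogenies, no assay-specific error profiles,
  no correlation between tumor burden and survival beyond the response
  strata.
- Patient-level endpoint values from any specific trial (exact survival
  medians, time-to-response medians, AUCs) are not reproducible without
  that trial's per-patient data; the test suite verifies the estimators
  on simulated cohorts with known parameters instead.
- Origin classification is rule-based; it does not model CHIP variants
  absent from the WBC library (misclassified tumor) beyond flagging
  that patients without WBC samples are unfiltered.
- The LOD model assumes independent error-corrected read families and
  ignores polymerase/sequencing error, so it is an upper bound on
  analytical sensitivity at very low MAF.
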