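# ctdna-mr

Molecular-response analysis of serial circulating tumor DNA (ctDNA)
liquid biopsies, for single-arm immunotherapy cohorts with plasma drawn
at baseline and the first days of treatment cycles two and three.

Plasma cell-free DNA carries somatic variants from three sources: the
tumor, clonal hematopoiesis of the white-blood-cell (WBC) compartment,
and germline polymorphisms. This package

1. **classifies the cellular origin** of every plasma variant using
   matched WBC sequencing, without requiring tumor tissue (hotspot
   mutations are tumor-derived regardless of WBC status; WBC-shared
   variants at germline-like allele fraction everywhere are germline;
   other WBC-shared variants are hematopoietic; the rest are tumor);
2. **tracks circulating tumor load** as the maximum mutant allele
   fraction (maxMAF) over the tumor-derived variants and calls each
   patient's **molecular response**: `mR` (clearance to undetectable on
   therapy, sustained through the last available draw), `mPD`
   (persistence, including transient clearance), `undetectable` (no
   ctDNA at any timepoint) or `not_evaluable`;
3. computes **concordance** of molecular with radiographic response
   (RECIST/iRECIST) using exact Clopper–Pearson binomial intervals and
   one-sided lower confidence bounds;
4. evaluates the continuous **depth of molecular response** as a
   predictor of radiographic response via ROC analysis (Mann–Whitney
   AUC, DeLong confidence intervals);
5. models the assay's **limit of detection** with a binomial read-count
   model over the observed per-position coverages;
6. runs **survival analyses** (Kaplan–Meier, log-rank, Cox proportional
   hazards via lifelines) stratified by molecular response, including
   time to molecular response;
7. ships a **seeded synthetic cohort generator** with per-patient and
   per-variant ground truth, so the entire pipeline is exercisable and
   testable end to end without patient data.

## Worked example

Generate a 50-patient synthetic cohort and run the full pipeline:

```sh
$ ctdna-mr simulate --n 50 --seed 1 --out demo
$ ctdna-mr run demo --out demo_out
completed 7 stages; outputs in demo_out
```

Per-patient response calls (`demo_out/response_calls.tsv`, first columns):

```text
patient_id  status  clearance_timepoint  kinetic_pattern  best_on_therapy_reduction
SYN0001     mR      C2D1                 clearance_C2     1
SYN0002     mPD                          persistence      -0.1069325482
SYN0003     mR      C2D1                 clearance_C2     1
```

Molecular response rate with its exact 90% CI
(`demo_out/molecular_response_rate.json`):

```json
{
 "ci": {"k": 21, "level": 0.9, "lower": 0.41988146549594696,
        "n": 37, "upper": 0.7067613375928932},
 "n_evaluable": 37,
 "n_mr": 21,
 "rate": 0.5675675675675675
}
```

Limit-of-detection profile over the cohort's baseline coverages:

```text
$ ctdna-mr lod demo
  maf   median      min      max
0.001 0.564483 0.400549 0.779792
0.002 0.933126 0.834854 0.988748
0.003 0.992946 0.967279 0.999625
```

Progression-free survival by molecular response:

```text
$ ctdna-mr survival demo --endpoint pfs
{
 "log_rank": {"df": 1, "p_value": 0.00246..., "statistic": 9.166...},
 "mPD": {"median": 1.8967, "ci": [1.3478, 3.5717], "n": 16, ...},
 "mR":  {"median": 5.2786, "ci": [2.9043, 11.7134], "n": 21, ...}
}
```

Other subcommands: `validate`, `classify`, `respond`, `concordance`,
`roc`. Exit codes: 0 success, 2 validation failure, 3 stage failure.
Every output tree is byte-reproducible for a fixed input and seed, and
`manifest.json` records per-stage counts and SHA-256 checksums.

## Library use

```python
from ctdna_mr import (annotate_cohort_origins, call_cohort_responses,
                      build_concordance_table, concordance_performance)
from ctdna_mr.synthetic_cohort import br36_preset, generate_cohort

dataset, truth = generate_cohort(br36_preset(n_patients=50, seed=1))
annotated = annotate_cohort_origins(dataset)
calls = call_cohort_responses(annotated, dataset)
perf = concordance_performance(
    build_concordance_table(calls, dataset.patients, "RECIST"))
print(perf["sensitivity"], perf["sensitivity_ci"].lower)
```

## Input format

A cohort directory holds three tab-separated tables — `variants.tsv`
(one row per variant observation per sample; plasma, WBC and optional
tumor compartments), `samples.tsv` (draw schedule and availability) and
`patients.tsv` (radiographic best overall response and survival
endpoints). `ctdna_mr.cohort_io.ingest_sample_vcf` converts per-sample
VCFs into variant-observation rows. MAFs may be fractions (default) or
percentages (`maf_dialect=percent`).

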