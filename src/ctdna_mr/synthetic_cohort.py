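"""Seeded synthetic cohorts with the trial's statistical structure.

The generator emulates a 50-patient serial liquid-biopsy cohort: plasma
draws at baseline and the first days of cycles two and three, a baseline
WBC sample per patient, occasional missed draws, radiographic best
overall response, and plasma variants of three origins — tumor-derived
(log-normal baseline MAFs spanning roughly 0.1-35%, response-conditional
on-therapy kinetics), clonal-hematopoiesis (low-MAF, shared with WBC)
and germline (allele fraction near 50% everywhere).  Latent molecular
response is drawn conditionally on radiographic response so that the
pipeline-recovered sensitivity/specificity converge to the configured
targets, and PFS/OS are exponential with stratum-specific medians.

Every latent assignment is recorded in ground-truth tables so that
end-to-end tests can compare pipeline output against the truth.  To keep
origin classification unambiguous, generated germline allele fractions
stay >= 0.40 and CHIP fractions <= 0.10; rule-edge behavior is exercised
by dedicated fixtures, not by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import (CohortConfig, CohortDataset, TIMEPOINTS,
                        default_hotspots)

PANEL_GENES = ("TP53", "KRAS", "ARID1A", "ATM", "NRAS", "PDGFRA", "STK11",
               "KEAP1", "EGFR", "PIK3CA", "BRAF", "MET", "ERBB2", "RB1")
_BASES = ("A", "C", "G", "T")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the trial-like preset."""

    n_patients: int = 50
    seed: int = 0
    # cohort composition
    p_not_evaluable_plasma: float = 0.06    # missed on-therapy draws
    p_not_evaluable_radiographic: float = 0.04
    p_undetectable: float = 0.20            # among evaluable patients
    p_responder: float = 0.32               # RECIST BOR CR/PR
    p_cr_given_responder: float = 0.2
    p_sd_given_nonresponder: float = 0.3
    p_irecist_upgrade: float = 0.05         # SD -> iPR reclassification
    # molecular response conditional on radiographic response
    sens_target: float = 0.82               # P(mR | responder)
    spec_target: float = 0.75               # P(mPD | non-responder)
    p_clear_at_C2_given_mR: float = 13 / 15
    p_deep_reduction_given_mPD: float = 0.10
    # variants
    tumor_variant_poisson_mean: float = 0.8  # count = 1 + Poisson
    chip_fraction: float = 0.17             # of unique plasma variants
    germline_fraction: float = 0.05
    hotspot_probability: float = 0.10
    p_hotspot_in_wbc: float = 0.3           # buffy-coat contamination
    baseline_log_maf_mean: float = float(np.log(0.02))
    baseline_log_maf_sd: float = 1.2
    maf_floor: float = 0.001
    maf_ceiling: float = 0.35
    deep_reduction_min_baseline: float = 0.02
    # sequencing
    coverage_mean: float = 3000.0
    coverage_sd: float = 300.0
    coverage_floor: int = 500
    # draw schedule and missingness
    cycle_days: float = 21.0
    visit_delay_scale: float = 7.0
    p_missing_C3: float = 0.13
    # tumor-tissue sequencing
    tumor_ngs_fraction: float = 0.4
    tumor_discordance_rate: float = 0.1
    # survival (months; exponential medians per stratum)
    median_pfs_mr: float = 5.03
    median_pfs_mpd: float = 2.6
    median_os_mr: float = 20.0              # effectively "not reached"
    median_os_mpd: float = 7.23
    median_pfs_undetectable: float = 8.31
    median_os_undetectable: float = 16.89
    followup_min_months: float = 2.5
    followup_max_months: float = 23.0

    def validate(self) -> None:
        probs = [self.p_not_evaluable_plasma,
                 self.p_not_evaluable_radiographic, self.p_undetectable,
                 self.p_responder, self.sens_target, self.spec_target,
                 self.p_clear_at_C2_given_mR,
                 self.p_deep_reduction_given_mPD, self.chip_fraction,
                 self.germline_fraction, self.hotspot_probability,
                 self.p_missing_C3]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.chip_fraction + self.germline_fraction >= 1:
            raise ValueError("origin fractions must sum below 1")
        if min(self.median_pfs_mr, self.median_pfs_mpd, self.median_os_mr,
               self.median_os_mpd) <= 0:
            raise ValueError("survival medians must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def br36_preset(**overrides) -> SimulationConfig:
    """Trial-like cohort composition (the default)."""
    return replace(SimulationConfig(), **overrides)


def design_preset(**overrides) -> SimulationConfig:
    """The protocol's design assumptions (45% objective response rate,
    70% sensitivity/specificity)."""
    cfg = SimulationConfig(p_responder=0.45, sens_target=0.70,
                           spec_target=0.70)
    return replace(cfg, **overrides)


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None,
                    ) -> tuple[CohortDataset, dict[str, pd.DataFrame]]:
    """Draw one cohort; returns (dataset, ground truth).

    Ground truth has ``patients`` (latent response assignments) and
    ``variants`` (injected origin per unique plasma variant) tables.
    Output is byte-identical under a fixed seed.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    hotspots = default_hotspots()
    hotspot_pairs = list(zip(hotspots["gene"], hotspots["protein_change"]))
    hotspot_set = set(hotspot_pairs)

    exp_detectable = ((1 - cfg.p_not_evaluable_plasma
                       - cfg.p_not_evaluable_radiographic)
                      * (1 - cfg.p_undetectable))
    exp_tumor_per_patient = exp_detectable * (1 + cfg.tumor_variant_poisson_mean)
    tumor_share = 1 - cfg.chip_fraction - cfg.germline_fraction
    lam_chip = exp_tumor_per_patient * cfg.chip_fraction / tumor_share
    lam_germ = exp_tumor_per_patient * cfg.germline_fraction / tumor_share

    variant_rows, sample_rows, patient_rows = [], [], []
    truth_patients, truth_variants = [], []

    for i in range(cfg.n_patients):
        pid = f"SYN{i + 1:04d}"
        used_pos: set[tuple[str, int]] = set()

        # --- plasma draw schedule -------------------------------------
        ne_plasma = rng.random() < cfg.p_not_evaluable_plasma
        c2_day = cfg.cycle_days + rng.exponential(cfg.visit_delay_scale)
        c3_day = c2_day + cfg.cycle_days + rng.exponential(
            cfg.visit_delay_scale)
        available = {"C1D1": True,
                     "C2D1": not ne_plasma,
                     "C3D1": (not ne_plasma)
                     and rng.random() >= cfg.p_missing_C3}
        days = {"C1D1": 0.0, "C2D1": round(c2_day), "C3D1": round(c3_day)}
        for tp in TIMEPOINTS:
            sample_rows.append({
                "sample_id": f"{pid}-{tp}", "patient_id": pid,
                "timepoint": tp, "compartment": "plasma",
                "collection_day": days[tp], "available": available[tp]})
        sample_rows.append({
            "sample_id": f"{pid}-WBC", "patient_id": pid,
            "timepoint": "C1D1", "compartment": "wbc",
            "collection_day": 0.0, "available": True})

        # --- radiographic response ------------------------------------
        ne_radio = rng.random() < cfg.p_not_evaluable_radiographic
        if ne_radio:
            responder = None
            recist = "NE"
        else:
            responder = bool(rng.random() < cfg.p_responder)
            if responder:
                recist = "CR" if rng.random() < cfg.p_cr_given_responder \
                    else "PR"
            else:
                recist = "SD" if rng.random() < cfg.p_sd_given_nonresponder \
                    else "PD"
        irecist = {"CR": "iCR", "PR": "iPR", "SD": "iSD", "PD": "iPD",
                   "NE": "NE"}[recist]
        if recist == "SD" and rng.random() < cfg.p_irecist_upgrade:
            irecist = "iPR"

        # --- latent molecular state -----------------------------------
        undetectable = rng.random() < cfg.p_undetectable
        if undetectable:
            mr = False
        elif responder is None:
            p_mr = (cfg.p_responder * cfg.sens_target
                    + (1 - cfg.p_responder) * (1 - cfg.spec_target))
            mr = rng.random() < p_mr
        else:
            p_mr = cfg.sens_target if responder else 1 - cfg.spec_target
            mr = rng.random() < p_mr

        clearance_tp = None
        deep = False
        if not undetectable:
            if mr:
                clearance_tp = ("C2D1"
                                if rng.random() < cfg.p_clear_at_C2_given_mR
                                else "C3D1")
                if clearance_tp == "C3D1" and not available["C3D1"]:
                    clearance_tp = "C2D1"
            else:
                deep = rng.random() < cfg.p_deep_reduction_given_mPD

        # --- tumor-derived variants -----------------------------------
        tumor_variants = []
        if not undetectable:
            n_tumor = 1 + rng.poisson(cfg.tumor_variant_poisson_mean)
            base_mafs = np.exp(rng.normal(cfg.baseline_log_maf_mean,
                                          cfg.baseline_log_maf_sd,
                                          size=n_tumor))
            base_mafs = np.clip(base_mafs, cfg.maf_floor, cfg.maf_ceiling)
            if deep:
                # keep the load above noise so the reduction is resolvable
                top = int(np.argmax(base_mafs))
                base_mafs[top] = max(base_mafs[top],
                                     cfg.deep_reduction_min_baseline)
            multipliers = _on_therapy_multipliers(
                rng, mr=mr, clearance_tp=clearance_tp, deep=deep)
            for j, f0 in enumerate(base_mafs):
                is_hot = rng.random() < cfg.hotspot_probability
                gene, pchange = _variant_identity(rng, is_hot, hotspot_pairs,
                                                  hotspot_set)
                key = _genomic_key(rng, used_pos)
                in_wbc = is_hot and rng.random() < cfg.p_hotspot_in_wbc
                tumor_variants.append({
                    "key": key, "gene": gene, "protein_change": pchange,
                    "is_hotspot": is_hot, "in_wbc": in_wbc,
                    "origin": "tumor",
                    "mafs": {tp: float(f0) * multipliers[tp]
                             for tp in TIMEPOINTS},
                    "wbc_maf": float(min(f0, 0.02)) if in_wbc else 0.0,
                })

        # --- CHIP and germline contamination --------------------------
        contaminants = []
        for _ in range(rng.poisson(lam_chip)):
            maf = float(rng.uniform(0.002, 0.05))
            gene, pchange = _variant_identity(rng, False, hotspot_pairs,
                                              hotspot_set)
            contaminants.append({
                "key": _genomic_key(rng, used_pos), "gene": gene,
                "protein_change": pchange, "is_hotspot": False,
                "in_wbc": True, "origin": "hematopoietic",
                "mafs": {tp: maf for tp in TIMEPOINTS},
                "wbc_maf": float(np.clip(maf * rng.uniform(0.7, 1.3),
                                         0.001, 0.10)),
            })
        for _ in range(rng.poisson(lam_germ)):
            maf = float(np.clip(rng.normal(0.5, 0.02), 0.40, 0.60))
            gene, pchange = _variant_identity(rng, False, hotspot_pairs,
                                              hotspot_set)
            contaminants.append({
                "key": _genomic_key(rng, used_pos), "gene": gene,
                "protein_change": pchange, "is_hotspot": False,
                "in_wbc": True, "origin": "germline",
                "mafs": {tp: maf for tp in TIMEPOINTS},
                "wbc_maf": float(np.clip(rng.normal(0.5, 0.02), 0.40,
                                         0.60)),
            })

        # --- sequencing observations ----------------------------------
        top_key = None
        if tumor_variants and not mr:
            top_key = max(tumor_variants,
                          key=lambda v: v["mafs"]["C1D1"])["key"]
        for var in tumor_variants + contaminants:
            chrom, pos, ref, alt = var["key"]
            for tp in TIMEPOINTS:
                if not available[tp]:
                    continue
                true_maf = var["mafs"][tp]
                if true_maf <= 0:
                    continue
                force = (tp == "C1D1") or (var["key"] == top_key) \
                    or var["origin"] != "tumor"
                obs = _observe(rng, cfg, true_maf, force_detect=force)
                if obs is None:
                    continue
                reads, cov = obs
                variant_rows.append({
                    "patient_id": pid, "sample_id": f"{pid}-{tp}",
                    "timepoint": tp, "compartment": "plasma",
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "gene": var["gene"],
                    "protein_change": var["protein_change"],
                    "maf": reads / cov, "mutant_reads": reads,
                    "distinct_coverage": cov})
            if var["in_wbc"]:
                obs = _observe(rng, cfg, var["wbc_maf"], force_detect=True)
                reads, cov = obs
                variant_rows.append({
                    "patient_id": pid, "sample_id": f"{pid}-WBC",
                    "timepoint": "C1D1", "compartment": "wbc",
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "gene": var["gene"],
                    "protein_change": var["protein_change"],
                    "maf": reads / cov, "mutant_reads": reads,
                    "distinct_coverage": cov})
            truth_variants.append({
                "patient_id": pid, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "gene": var["gene"],
                "protein_change": var["protein_change"],
                "origin": var["origin"], "is_hotspot": var["is_hotspot"],
                "in_wbc": var["in_wbc"],
                "baseline_maf": var["mafs"]["C1D1"]})

        # --- tumor-tissue sequencing ----------------------------------
        has_tumor_ngs = rng.random() < cfg.tumor_ngs_fraction
        if has_tumor_ngs:
            sample_rows.append({
                "sample_id": f"{pid}-TUM", "patient_id": pid,
                "timepoint": "C1D1", "compartment": "tumor",
                "collection_day": 0.0, "available": True})
            for var in tumor_variants:
                if rng.random() < cfg.tumor_discordance_rate:
                    continue
                chrom, pos, ref, alt = var["key"]
                cov = int(max(200, rng.normal(1168, 150)))
                maf = float(rng.uniform(0.05, 0.5))
                reads = max(1, int(rng.binomial(cov, maf)))
                variant_rows.append({
                    "patient_id": pid, "sample_id": f"{pid}-TUM",
                    "timepoint": "C1D1", "compartment": "tumor",
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "gene": var["gene"],
                    "protein_change": var["protein_change"],
                    "maf": reads / cov, "mutant_reads": reads,
                    "distinct_coverage": cov})

        # --- survival endpoints ---------------------------------------
        not_evaluable = ne_plasma
        if not_evaluable:
            status_true = "not_evaluable"
        elif undetectable:
            status_true = "undetectable"
        else:
            status_true = "mR" if mr else "mPD"
        if status_true == "mR":
            med_pfs, med_os = cfg.median_pfs_mr, cfg.median_os_mr
        elif status_true == "undetectable":
            med_pfs, med_os = (cfg.median_pfs_undetectable,
                               cfg.median_os_undetectable)
        else:
            med_pfs, med_os = cfg.median_pfs_mpd, cfg.median_os_mpd
        os_t = rng.exponential(med_os / np.log(2))
        pfs_t = min(rng.exponential(med_pfs / np.log(2)), os_t)
        followup = rng.uniform(cfg.followup_min_months,
                               cfg.followup_max_months)
        os_event = os_t <= followup
        pfs_event = pfs_t <= followup
        patient_rows.append({
            "patient_id": pid, "recist_bor": recist,
            "irecist_bor": irecist,
            "pfs_months": round(min(pfs_t, followup), 4),
            "pfs_event": pfs_event,
            "os_months": round(min(os_t, followup), 4),
            "os_event": os_event,
            "first_response_day": 84.0 if recist in ("CR", "PR")
            else np.nan})
        truth_patients.append({
            "patient_id": pid, "status_true": status_true,
            "responder": responder, "undetectable": undetectable,
            "clearance_timepoint_true": clearance_tp or "",
            "deep_reduction_true": deep,
            "has_tumor_ngs": has_tumor_ngs,
            "n_tumor_variants": len(tumor_variants)})

    from .cohort_io import (OPTIONAL_VARIANT_COLUMNS, VARIANT_COLUMNS)
    var_cols = (list(VARIANT_COLUMNS)[:8] + ["gene", "protein_change"]
                + list(VARIANT_COLUMNS)[8:])
    dataset = CohortDataset(
        variants=pd.DataFrame(variant_rows, columns=var_cols),
        samples=pd.DataFrame(sample_rows),
        patients=pd.DataFrame(patient_rows),
        hotspots=hotspots,
        config=CohortConfig(),
    )
    truth = {"patients": pd.DataFrame(truth_patients),
             "variants": pd.DataFrame(truth_variants)}
    return dataset, truth


def _on_therapy_multipliers(rng, *, mr: bool, clearance_tp: str | None,
                            deep: bool) -> dict[str, float]:
    """Per-timepoint scaling of all tumor-variant MAFs for one patient."""
    m = {"C1D1": 1.0}
    if mr:
        if clearance_tp == "C2D1":
            m["C2D1"] = 0.0
            m["C3D1"] = 0.0
        else:
            m["C2D1"] = float(rng.uniform(0.1, 0.6))
            m["C3D1"] = 0.0
    elif deep:
        best = 1.0 - float(rng.uniform(0.87, 0.99))
        other = float(rng.uniform(0.2, 0.6))
        if rng.random() < 0.5:
            m["C2D1"], m["C3D1"] = best, other
        else:
            m["C2D1"], m["C3D1"] = other, best
    else:
        # persistence: best reduction stays clear of the 85% boundary
        m["C2D1"] = float(rng.uniform(0.3, 1.5))
        m["C3D1"] = float(rng.uniform(0.3, 1.5))
    return m


def _observe(rng, cfg: SimulationConfig, true_maf: float, *,
             force_detect: bool) -> tuple[int, int] | None:
    """Draw (mutant_reads, coverage); None if the variant drops out."""
    cov = int(max(cfg.coverage_floor,
                  round(rng.normal(cfg.coverage_mean, cfg.coverage_sd))))
    reads = int(rng.binomial(cov, min(true_maf, 1.0)))
    if reads == 0:
        if not force_detect:
            return None
        reads = 1
    return reads, cov


def _genomic_key(rng, used: set) -> tuple[str, int, str, str]:
    while True:
        chrom = f"chr{rng.integers(1, 23)}"
        pos = int(rng.integers(1_000_000, 50_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            break
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(int(_BASES.index(ref)) + int(rng.integers(1, 4))) % 4]
    return chrom, pos, ref, alt


def _variant_identity(rng, is_hotspot: bool, hotspot_pairs, hotspot_set):
    if is_hotspot:
        gene, pchange = hotspot_pairs[rng.integers(0, len(hotspot_pairs))]
        return gene, pchange
    while True:
        gene = PANEL_GENES[rng.integers(0, len(PANEL_GENES))]
        pchange = (f"{_AA[rng.integers(0, 20)]}"
                   f"{rng.integers(100, 1000)}"
                   f"{_AA[rng.integers(0, 20)]}")
        if (gene, pchange) not in hotspot_set:
            return gene, pchange


def generate_expected_summaries(truth: dict[str, pd.DataFrame]) -> dict:
    """Oracle summaries from the latent assignments.

    Returns true origin counts, true status counts and the true 2x2
    molecular-vs-radiographic table (RECIST) for end-to-end assertions.
    """
    tv, tp = truth["variants"], truth["patients"]
    origin_counts = tv["origin"].value_counts().to_dict()
    status_counts = tp["status_true"].value_counts().to_dict()
    evaluable = tp[tp["status_true"].isin(["mR", "mPD"])
                   & tp["responder"].notna()]
    is_mr = evaluable["status_true"] == "mR"
    is_resp = evaluable["responder"].astype(bool)
    table = {"a": int((is_mr & is_resp).sum()),
             "b": int((~is_mr & is_resp).sum()),
             "c": int((is_mr & ~is_resp).sum()),
             "d": int((~is_mr & ~is_resp).sum())}
    return {"origin_counts": origin_counts, "status_counts": status_counts,
            "concordance_table": table}
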