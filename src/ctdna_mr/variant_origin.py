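"""Cellular-origin classification of plasma variants.

Somatic variants detected in plasma cell-free DNA are a mixture of
tumor-derived mutations, clonal-hematopoiesis (CHIP) mutations shed by
white blood cells, and germline polymorphisms.  Matched white-blood-cell
(WBC) DNA sequencing lets the three be separated without tumor tissue —
the tumor-agnostic, WBC-informed strategy:

1. cancer-hotspot mutations (e.g. KRAS G12C) are tumor derived
   regardless of WBC detection, since buffy-coat contamination by
   circulating tumor cells can place true tumor mutations in the WBC
   library;
2. non-hotspot variants at germline-like allele fraction (>= 25% by
   default) in the WBC sample and in every plasma sample where they were
   measured are germline;
3. other non-hotspot variants detected in WBC DNA are CHIP
   ("hematopoietic");
4. everything else is tumor derived.

Germline and hematopoietic variants are excluded from circulating tumor
load downstream.  When a patient has no WBC sample, rules 2-3 cannot
apply; variants are labeled tumor with a ``wbc_missing`` provenance flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort_io import CohortDataset, TIMEPOINTS, VARIANT_KEY

ORIGINS = ("germline", "hematopoietic", "tumor")

#: Minimum WBC mutant read-family count for "detected in WBC".
DEFAULT_WBC_MIN_READS = 1
DEFAULT_GERMLINE_MAF_THRESHOLD = 0.25


def classify_variant_origin(plasma_mafs: Mapping[str, float] | Iterable[float],
                            *,
                            is_hotspot: bool,
                            wbc_detected: bool,
                            wbc_maf: float = 0.0,
                            wbc_available: bool = True,
                            germline_maf_threshold: float =
                            DEFAULT_GERMLINE_MAF_THRESHOLD,
                            ) -> tuple[str, list[str]]:
    """Assign one origin label to a unique plasma variant.

    ``plasma_mafs`` holds the variant's MAF in each plasma sample where it
    was called; timepoints where it was not called do not veto the
    germline rule (they are simply not measurements of the allele).

    Returns ``(origin, provenance_flags)``.
    """
    mafs = (list(plasma_mafs.values()) if isinstance(plasma_mafs, Mapping)
            else list(plasma_mafs))
    if not mafs:
        raise ValueError("variant has no plasma observation")
    if is_hotspot:
        return "tumor", []
    if not wbc_available:
        return "tumor", ["wbc_missing"]
    if wbc_detected:
        if (wbc_maf >= germline_maf_threshold
                and all(m >= germline_maf_threshold for m in mafs)):
            return "germline", []
        return "hematopoietic", []
    return "tumor", []


def annotate_cohort_origins(dataset: CohortDataset,
                            *,
                            wbc_min_reads: int = DEFAULT_WBC_MIN_READS,
                            germline_maf_threshold: float | None = None,
                            ) -> pd.DataFrame:
    """Classify every unique plasma variant of every patient.

    Returns one row per unique ``(patient_id, chrom, pos, ref, alt)`` with
    any plasma observation: origin, hotspot and WBC-detection flags,
    per-timepoint plasma MAF columns (``maf_C1D1``, ...; NaN where the
    variant was not called), and ``excluded_from_load`` for germline and
    hematopoietic variants.
    """
    if germline_maf_threshold is None:
        germline_maf_threshold = dataset.config.germline_maf_threshold
    plasma = dataset.plasma_variants()
    wbc = dataset.wbc_variants()
    wbc = wbc[wbc["mutant_reads"] >= wbc_min_reads]
    wbc_keys = wbc.set_index(["patient_id"] + VARIANT_KEY)["maf"].to_dict()
    wbc_patients = set(
        dataset.samples.loc[dataset.samples["compartment"] == "wbc",
                            "patient_id"])
    hotspot = _hotspot_matcher(dataset.hotspots)

    rows = []
    for (pid, chrom, pos, ref, alt), grp in plasma.groupby(
            ["patient_id"] + VARIANT_KEY, sort=True):
        gene = grp["gene"].iloc[0] if "gene" in grp else ""
        pchange = grp["protein_change"].iloc[0] if "protein_change" in grp else ""
        maf_map = dict(zip(grp["timepoint"], grp["maf"]))
        is_hot = hotspot(chrom, pos, ref, alt, gene, pchange)
        wbc_maf = wbc_keys.get((pid, chrom, pos, ref, alt))
        origin, flags = classify_variant_origin(
            maf_map,
            is_hotspot=is_hot,
            wbc_detected=wbc_maf is not None,
            wbc_maf=wbc_maf or 0.0,
            wbc_available=pid in wbc_patients,
            germline_maf_threshold=germline_maf_threshold)
        row = {
            "patient_id": pid, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "gene": gene, "protein_change": pchange,
            "origin": origin, "is_hotspot": is_hot,
            "wbc_detected": wbc_maf is not None,
            "excluded_from_load": origin != "tumor",
            "provenance": ";".join(flags),
        }
        for tp in TIMEPOINTS:
            row[f"maf_{tp}"] = maf_map.get(tp, np.nan)
        rows.append(row)
    cols = (["patient_id"] + VARIANT_KEY
            + ["gene", "protein_change", "origin", "is_hotspot",
               "wbc_detected", "excluded_from_load", "provenance"]
            + [f"maf_{tp}" for tp in TIMEPOINTS])
    return pd.DataFrame(rows, columns=cols)


def _hotspot_matcher(hotspots: pd.DataFrame):
    """Matching is by genomic key when the entry has one, else by
    (gene, protein_change)."""
    genomic = set()
    by_protein = set()
    for _, row in hotspots.iterrows():
        key_fields = [row.get(k) for k in VARIANT_KEY]
        if all(pd.notna(k) and k != "" for k in key_fields):
            genomic.add((str(row["chrom"]), int(row["pos"]),
                         str(row["ref"]), str(row["alt"])))
        else:
            by_protein.add((str(row["gene"]), str(row["protein_change"])))

    def match(chrom, pos, ref, alt, gene, protein_change) -> bool:
        if (str(chrom), int(pos), str(ref), str(alt)) in genomic:
            return True
        return (str(gene), str(protein_change)) in by_protein

    return match


def origin_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per origin over unique plasma variants.

    Proportions are reported absent (NaN) for an empty input.
    """
    n = len(annotated)
    counts = {o: int((annotated["origin"] == o).sum()) if n else 0
              for o in ORIGINS}
    return pd.DataFrame({
        "origin": list(ORIGINS),
        "count": [counts[o] for o in ORIGINS],
        "proportion": [counts[o] / n if n else np.nan for o in ORIGINS],
    })


def tumor_plasma_origin_concordance(annotated: pd.DataFrame,
                                    tumor_observations: pd.DataFrame,
                                    ) -> dict:
    """Concordance of WBC-informed tumor calls with matched tumor NGS.

    For patients with tumor-tissue sequencing and at least one
    plasma-called tumor-derived variant, computes the fraction of those
    variants confirmed present in the tumor.  Discordant variants are
    reported, not reclassified.  Returns a dict with ``concordance``
    (NaN if no tumor samples), per-variant table and patient counts.
    """
    if tumor_observations is None or len(tumor_observations) == 0:
        return {"concordance": np.nan, "n_variants": 0, "n_patients": 0,
                "table": pd.DataFrame(), "notice": "no tumor samples"}
    tumor_keys = set(map(tuple, tumor_observations[
        ["patient_id"] + VARIANT_KEY].itertuples(index=False)))
    sequenced = set(tumor_observations["patient_id"])
    calls = annotated[(annotated["origin"] == "tumor")
                      & annotated["patient_id"].isin(sequenced)].copy()
    calls["confirmed_in_tumor"] = [
        (row.patient_id, row.chrom, row.pos, row.ref, row.alt) in tumor_keys
        for row in calls.itertuples()]
    n = len(calls)
    conc = float(calls["confirmed_in_tumor"].mean()) if n else np.nan
    by_patient = calls.groupby("patient_id")["confirmed_in_tumor"].any()
    return {
        "concordance": conc,
        "patient_concordance": (float(by_patient.mean()) if len(by_patient)
                                else np.nan),
        "n_variants": n,
        "n_patients": int(calls["patient_id"].nunique()),
        "table": calls[["patient_id"] + VARIANT_KEY
                       + ["gene", "protein_change", "confirmed_in_tumor"]],
    }
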