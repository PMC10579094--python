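import numpy as np
import pandas as pd
import pytest

from ctdna_mr import CohortConfig, CohortDataset, default_hotspots
from ctdna_mr.synthetic_cohort import br36_preset, generate_cohort


def make_variant(pid, sid, tp, compartment, chrom, pos, ref, alt, maf,
                 coverage=3000, gene="", protein_change=""):
    return {
        "patient_id": pid, "sample_id": sid, "timepoint": tp,
        "compartment": compartment, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "gene": gene,
        "protein_change": protein_change, "maf": maf,
        "mutant_reads": max(1, int(round(maf * coverage))),
        "distinct_coverage": coverage,
    }


def make_sample(pid, tp, compartment="plasma", available=True, day=None):
    suffix = "WBC" if compartment == "wbc" else (
        "TUM" if compartment == "tumor" else tp)
    if day is None:
        day = {"C1D1": 0, "C2D1": 21, "C3D1": 42}.get(tp, 0)
    return {"sample_id": f"{pid}-{suffix}", "patient_id": pid,
            "timepoint": tp, "compartment": compartment,
            "collection_day": day, "available": available}


def make_patient(pid, recist="PR", irecist=None, pfs=5.0, pfs_event=True,
                 os=10.0, os_event=False):
    if irecist is None:
        irecist = {"CR": "iCR", "PR": "iPR", "SD": "iSD", "PD": "iPD",
                   "NE": "NE"}[recist]
    return {"patient_id": pid, "recist_bor": recist, "irecist_bor": irecist,
            "pfs_months": pfs, "pfs_event": pfs_event, "os_months": os,
            "os_event": os_event, "first_response_day": np.nan}


def build_dataset(variants, samples, patients, config=None):
    return CohortDataset(
        variants=pd.DataFrame(variants),
        samples=pd.DataFrame(samples),
        patients=pd.DataFrame(patients),
        hotspots=default_hotspots(),
        config=config or CohortConfig(),
    )


@pytest.fixture
def two_patient_dataset():
    """Two patients, six samples, five plasma variant observations.

    Patient A carries a KRAS G12A hotspot at 0.19% MAF at baseline that
    clears on therapy; patient B carries a persistent TP53 variant plus
    a WBC-shared low-MAF variant.
    """
    samples, variants = [], []
    for pid in ("A", "B"):
        for tp in ("C1D1", "C2D1", "C3D1"):
            samples.append(make_sample(pid, tp))
        samples.append(make_sample(pid, "C1D1", "wbc"))
    variants.append(make_variant("A", "A-C1D1", "C1D1", "plasma", "chr12",
                                 25245350, "C", "G", 0.0019, gene="KRAS",
                                 protein_change="G12A"))
    for tp, maf in (("C1D1", 0.04), ("C2D1", 0.03), ("C3D1", 0.035)):
        variants.append(make_variant("B", f"B-{tp}", tp, "plasma", "chr17",
                                     7675000, "G", "A", maf, gene="TP53",
                                     protein_change="R273H"))
    variants.append(make_variant("B", "B-C1D1", "C1D1", "plasma", "chr11",
                                 533800, "T", "C", 0.02, gene="ATM",
                                 protein_change="Q300H"))
    variants.append(make_variant("B", "B-WBC", "C1D1", "wbc", "chr11",
                                 533800, "T", "C", 0.018, gene="ATM",
                                 protein_change="Q300H"))
    patients = [make_patient("A", "PR"), make_patient("B", "PD")]
    return build_dataset(variants, samples, patients)


@pytest.fixture(scope="session")
def simulated_cohort():
    """A moderate seeded synthetic cohort shared across tests."""
    return generate_cohort(br36_preset(n_patients=120, seed=7))
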