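"""Cohort data model, validation and table I/O.

A cohort is held as four pandas DataFrames bundled in a
:class:`CohortDataset`: per-sample variant observations, a sample
manifest, a patient clinical table and a cancer-hotspot list.  Mutant
allele fractions (MAF) are stored internally as fractions in [0, 1];
percent-dialect input files are converted on read.  Coordinates are
1-based with VCF-convention ref/alt alleles, and a variant is keyed by
``(chrom, pos, ref, alt)`` exactly as written in the calls (indel
left-alignment is assumed to have been done by the upstream caller).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Schema constants
# ---------------------------------------------------------------------------

#: Ordered plasma collection timepoints: pre-treatment baseline, then the
#: first days of treatment cycles two and three (3 and 6 weeks).  Assignment
#: is by collection order/label rather than nominal cycle number, since
#: cycles can be delayed.
TIMEPOINTS: tuple[str, ...] = ("C1D1", "C2D1", "C3D1")
BASELINE: str = TIMEPOINTS[0]
ON_THERAPY: tuple[str, ...] = TIMEPOINTS[1:]

COMPARTMENTS = ("plasma", "wbc", "tumor")

RECIST_RESPONDER = frozenset({"CR", "PR"})
RECIST_NONRESPONDER = frozenset({"SD", "PD"})
IRECIST_RESPONDER = frozenset({"iCR", "iPR"})
IRECIST_NONRESPONDER = frozenset({"iSD", "iPD"})

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

VARIANT_COLUMNS = {
    "patient_id": str,
    "sample_id": str,
    "timepoint": str,
    "compartment": str,
    "chrom": str,
    "pos": int,
    "ref": str,
    "alt": str,
    "maf": float,
    "mutant_reads": int,
    "distinct_coverage": int,
}
OPTIONAL_VARIANT_COLUMNS = {"gene": str, "protein_change": str}

SAMPLE_COLUMNS = {
    "sample_id": str,
    "patient_id": str,
    "timepoint": str,
    "compartment": str,
    "available": bool,
}
OPTIONAL_SAMPLE_COLUMNS = {"collection_day": float}

PATIENT_COLUMNS = {
    "patient_id": str,
    "recist_bor": str,
    "irecist_bor": str,
    "pfs_months": float,
    "pfs_event": bool,
    "os_months": float,
    "os_event": bool,
}
OPTIONAL_PATIENT_COLUMNS = {"first_response_day": float}

HOTSPOT_COLUMNS = {"gene": str, "protein_change": str}
OPTIONAL_HOTSPOT_COLUMNS = {"chrom": str, "pos": float, "ref": str, "alt": str}


class SchemaError(ValueError):
    """A required column is missing or a field violates its domain."""


class CohortValidationError(ValueError):
    """The dataset violates a structural invariant."""


@dataclass
class CohortConfig:
    """Parsing and reporting options.

    Parameters
    ----------
    maf_dialect:
        ``"fraction"`` if MAF columns are already in [0, 1]; ``"percent"``
        if they are percentages to be divided by 100 on read.
    ci_level:
        Two-sided confidence level used by downstream statistics.
    clearance_threshold:
        maxMAF at or below which circulating tumor load counts as cleared
        (0 = assay-undetected).
    reduction_threshold:
        Fractional maxMAF reduction separating "deep reduction" from
        persistence kinetics.
    germline_maf_threshold:
        Minimum MAF (in every measured plasma sample and in WBC) for the
        germline call.
    seed:
        Seed for any stochastic downstream step (bootstraps, simulation).
    """

    maf_dialect: str = "fraction"
    ci_level: float = 0.90
    clearance_threshold: float = 0.0
    reduction_threshold: float = 0.85
    germline_maf_threshold: float = 0.25
    percent_decimals: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf_dialect not in ("fraction", "percent"):
            raise SchemaError(f"unknown maf_dialect {self.maf_dialect!r}")
        if not 0 < self.ci_level < 1:
            raise SchemaError("ci_level must be in (0, 1)")


@dataclass
class CohortDataset:
    """All cohort-level tables, referentially linked."""

    variants: pd.DataFrame
    samples: pd.DataFrame
    patients: pd.DataFrame
    hotspots: pd.DataFrame
    config: CohortConfig = field(default_factory=CohortConfig)

    def plasma_variants(self) -> pd.DataFrame:
        return self.variants[self.variants["compartment"] == "plasma"]

    def wbc_variants(self) -> pd.DataFrame:
        return self.variants[self.variants["compartment"] == "wbc"]

    def tumor_variants(self) -> pd.DataFrame:
        return self.variants[self.variants["compartment"] == "tumor"]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: Path, required: Mapping[str, type],
                optional: Mapping[str, type]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, typ in {**required, **optional}.items():
        if col not in df.columns:
            continue
        if typ is bool:
            df[col] = df[col].map(
                lambda v: str(v).strip().lower() in ("1", "true", "yes"))
        elif typ in (int, float):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if typ is int:
                df[col] = df[col].astype(np.int64)
        else:
            df[col] = df[col].astype("string").astype(object)
    return df


def read_cohort_tables(paths: Mapping[str, str | Path] | str | Path,
                       config: CohortConfig | None = None) -> CohortDataset:
    """Read the four cohort tables and return a validated dataset.

    ``paths`` is either a directory containing ``variants.tsv``,
    ``samples.tsv``, ``patients.tsv`` and ``hotspots.tsv``, or a mapping
    from those names (without extension) to file paths.  Raises
    :class:`CohortValidationError` listing all violations if the dataset
    is not clean.
    """
    config = config or CohortConfig()
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.tsv"
                 for name in ("variants", "samples", "patients", "hotspots")}
    variants = _read_table(Path(paths["variants"]), VARIANT_COLUMNS,
                           OPTIONAL_VARIANT_COLUMNS)
    samples = _read_table(Path(paths["samples"]), SAMPLE_COLUMNS,
                          OPTIONAL_SAMPLE_COLUMNS)
    patients = _read_table(Path(paths["patients"]), PATIENT_COLUMNS,
                           OPTIONAL_PATIENT_COLUMNS)
    hotspot_path = Path(paths["hotspots"])
    if hotspot_path.exists():
        hotspots = _read_table(hotspot_path, HOTSPOT_COLUMNS,
                               OPTIONAL_HOTSPOT_COLUMNS)
    else:
        hotspots = default_hotspots()

    if config.maf_dialect == "percent":
        variants["maf"] = variants["maf"] / 100.0
    bad = variants.index[(variants["maf"] < 0) | (variants["maf"] > 1)]
    if len(bad):
        raise SchemaError(
            f"MAF outside [0, 1] under {config.maf_dialect!r} dialect at "
            f"row(s) {list(bad)}")

    dataset = CohortDataset(variants=variants, samples=samples,
                            patients=patients, hotspots=hotspots,
                            config=config)
    report = validate_cohort(dataset)
    if report:
        raise CohortValidationError(
            "cohort failed validation:\n" + "\n".join(report))
    return dataset


def default_hotspots() -> pd.DataFrame:
    """The hotspot list shipped with the package (editable TSV)."""
    path = Path(__file__).parent / "data" / "hotspots.tsv"
    return _read_table(path, HOTSPOT_COLUMNS, OPTIONAL_HOTSPOT_COLUMNS)


def ingest_sample_vcf(vcf_path: str | Path, sample_id: str, *,
                      patient_id: str, timepoint: str,
                      compartment: str = "plasma",
                      af_field: str = "AF", dp_field: str = "DP",
                      ad_field: str | None = None) -> pd.DataFrame:
    """Extract variant observations from a single-sample VCF.

    Allele fraction and depth are taken from the INFO fields named by
    ``af_field``/``dp_field`` (per-alt mutant read counts from
    ``ad_field`` when given, else reconstructed as ``round(af * dp)``).
    Multiallelic records are decomposed into one observation per
    alternate allele.  Records with AF = 0 are retained; filtering is the
    caller's decision.
    """
    from cyvcf2 import VCF

    rows = []
    for idx, record in enumerate(VCF(str(vcf_path))):
        info = dict(record.INFO)
        if af_field not in info or dp_field not in info:
            raise SchemaError(
                f"{vcf_path}: record {idx} ({record.CHROM}:{record.POS}) "
                f"missing INFO field {af_field!r} or {dp_field!r}")
        afs = info[af_field]
        if not isinstance(afs, tuple):
            afs = (afs,)
        ads = info.get(ad_field) if ad_field else None
        if ads is not None and not isinstance(ads, tuple):
            ads = (ads,)
        dp = int(info[dp_field])
        for alt_i, alt in enumerate(record.ALT):
            af = float(afs[alt_i]) if alt_i < len(afs) else float(afs[0])
            reads = (int(ads[alt_i]) if ads is not None
                     else int(round(af * dp)))
            rows.append({
                "patient_id": patient_id, "sample_id": sample_id,
                "timepoint": timepoint, "compartment": compartment,
                "chrom": record.CHROM, "pos": int(record.POS),
                "ref": record.REF, "alt": alt,
                "gene": info.get("GENE", ""),
                "protein_change": info.get("PCHANGE", ""),
                "maf": af, "mutant_reads": reads, "distinct_coverage": dp,
            })
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)
                        + list(OPTIONAL_VARIANT_COLUMNS))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_cohort(dataset: CohortDataset) -> list[str]:
    """Return a list of human-readable invariant violations (empty = clean)."""
    v, s, p = dataset.variants, dataset.samples, dataset.patients
    problems: list[str] = []

    known_samples = set(s["sample_id"])
    known_patients = set(p["patient_id"])
    for _, row in v.iterrows():
        if row["sample_id"] not in known_samples:
            problems.append(
                f"variant {row['chrom']}:{row['pos']} cites unknown "
                f"sample_id {row['sample_id']!r}")
        if row["patient_id"] not in known_patients:
            problems.append(
                f"variant {row['chrom']}:{row['pos']} cites unknown "
                f"patient_id {row['patient_id']!r}")
    unknown_sample_patients = set(s["patient_id"]) - known_patients
    for pid in sorted(unknown_sample_patients):
        problems.append(f"sample table cites unknown patient_id {pid!r}")

    bad = v[(v["maf"] < 0) | (v["maf"] > 1)]
    for _, row in bad.iterrows():
        problems.append(
            f"MAF {row['maf']} outside [0,1] for {row['chrom']}:{row['pos']} "
            f"in {row['sample_id']}")
    bad = v[v["mutant_reads"] > v["distinct_coverage"]]
    for _, row in bad.iterrows():
        problems.append(
            f"mutant_reads {row['mutant_reads']} exceeds distinct_coverage "
            f"{row['distinct_coverage']} for {row['chrom']}:{row['pos']} "
            f"in {row['sample_id']}")
    bad = v[v["distinct_coverage"] <= 0]
    for _, row in bad.iterrows():
        problems.append(
            f"non-positive distinct_coverage for {row['chrom']}:{row['pos']} "
            f"in {row['sample_id']}")

    dup = v.duplicated(subset=["sample_id"] + VARIANT_KEY, keep=False)
    for key, grp in v[dup].groupby(["sample_id"] + VARIANT_KEY):
        problems.append(f"variant {key[1]}:{key[2]} {key[3]}>{key[4]} "
                        f"duplicated within sample {key[0]}")

    plasma = s[s["compartment"] == "plasma"]
    dup = plasma.duplicated(subset=["patient_id", "timepoint"], keep=False)
    for (pid, tp), _ in plasma[dup].groupby(["patient_id", "timepoint"]):
        problems.append(f"patient {pid} has multiple plasma samples at {tp}")
    wbc = s[s["compartment"] == "wbc"]
    dup = wbc.duplicated(subset=["patient_id"], keep=False)
    for pid in sorted(set(wbc[dup]["patient_id"])):
        problems.append(f"patient {pid} has multiple WBC samples")

    bad_tp = s[(s["compartment"] == "plasma")
               & ~s["timepoint"].isin(TIMEPOINTS)]
    for _, row in bad_tp.iterrows():
        problems.append(
            f"sample {row['sample_id']} has unknown timepoint "
            f"{row['timepoint']!r}")

    both = p.dropna(subset=["pfs_months", "os_months"])
    bad = both[(both["pfs_months"] > both["os_months"]) & both["os_event"]]
    for _, row in bad.iterrows():
        problems.append(
            f"patient {row['patient_id']}: PFS {row['pfs_months']} exceeds "
            f"OS {row['os_months']}")

    return problems


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def format_percent(fraction: float, decimals: int = 0) -> str:
    """Render a fraction as a percent string, half-away-from-zero."""
    x = fraction * 100.0
    q = 10 ** decimals
    rounded = np.floor(np.abs(x) * q + 0.5) / q * np.sign(x)
    if decimals == 0:
        return f"{int(rounded)}%"
    return f"{rounded:.{decimals}f}%"


def write_cohort_tables(dataset: CohortDataset, out_dir: str | Path) -> dict:
    """Write the four cohort tables as TSV; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in (("variants", dataset.variants),
                     ("samples", dataset.samples),
                     ("patients", dataset.patients),
                     ("hotspots", dataset.hotspots)):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest[name] = str(path)
    return manifest


def write_analysis_outputs(results: Mapping[str, object],
                           out_dir: str | Path) -> dict:
    """Write pipeline results to ``out_dir`` and return a file manifest.

    DataFrame values become TSV files; everything else is serialized as
    JSON.  Output is deterministic: re-running on identical inputs (and
    seed) yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(_jsonable(obj), indent=1,
                                       sort_keys=True) + "\n")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        # record the path relative to out_dir so the manifest itself is
        # reproducible regardless of where the output tree lives
        manifest[name] = {"path": path.name, "sha256": digest}
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if np.isfinite(x) else None
    if isinstance(obj, (np.bool_, bool)):   # before int: bool is an int
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if obj is None or isinstance(obj, str):
        return obj
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return str(obj)
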