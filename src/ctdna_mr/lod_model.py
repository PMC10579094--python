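"""Binomial limit-of-detection model for error-corrected sequencing.

At a locus with n distinct (error-corrected) read families, a variant
present at allele fraction p yields mutant read-family counts
X ~ Binomial(n, p).  The assay calls the variant when at least k mutant
families are observed (k = 3 by default), so the per-position detection
probability is P(X >= k), evaluated through the binomial survival
function (numerically stable at large n and small p, where naive
upper-tail summation cancels).  Assay-level sensitivity at each MAF is
summarized as the median detection probability across the baseline
tumor-variant positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_MUTANT_READS = 3
DEFAULT_MAF_GRID = (0.001, 0.002, 0.003, 0.005, 0.01)


@dataclass
class LodProfile:
    """Per-position detection probabilities and assay-level medians."""

    positions: pd.DataFrame          # locus, distinct_coverage
    maf_grid: tuple[float, ...]
    min_mutant_reads: int
    probabilities: pd.DataFrame      # one row per position, col per MAF
    median_sensitivity: dict[float, float] = field(default_factory=dict)


def detection_probability(coverage: int | np.ndarray,
                          maf: float | np.ndarray,
                          min_reads: int = DEFAULT_MIN_MUTANT_READS,
                          ) -> float | np.ndarray:
    """P(X >= min_reads) with X ~ Binomial(coverage, maf)."""
    n = np.asarray(coverage)
    p = np.asarray(maf, dtype=float)
    if np.any(n < 0):
        raise ValueError("coverage must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("maf must be in [0, 1]")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out = stats.binom.sf(min_reads - 1, n, p)
    if np.isscalar(coverage) and np.isscalar(maf):
        return float(out)
    return out


def assay_sensitivity_profile(positions: Sequence[tuple[str, int]] |
                              pd.DataFrame,
                              maf_grid: Sequence[float] = DEFAULT_MAF_GRID,
                              min_reads: int = DEFAULT_MIN_MUTANT_READS,
                              ) -> LodProfile:
    """Detection probability per position and MAF, with cohort medians.

    ``positions`` is a sequence of (locus label, distinct coverage) or a
    DataFrame with ``locus`` and ``distinct_coverage`` columns — in the
    trial's usage, the loci carrying tumor-derived variants at baseline.
    """
    if isinstance(positions, pd.DataFrame):
        pos_df = positions[["locus", "distinct_coverage"]].copy()
    else:
        pos_df = pd.DataFrame(list(positions),
                              columns=["locus", "distinct_coverage"])
    if pos_df.empty:
        raise ValueError("at least one position with coverage is required")
    cov = pos_df["distinct_coverage"].to_numpy()
    probs = {f"p_{maf:g}": detection_probability(cov, maf, min_reads)
             for maf in maf_grid}
    prob_df = pd.concat([pos_df.reset_index(drop=True),
                         pd.DataFrame(probs)], axis=1)
    medians = {maf: float(np.median(probs[f"p_{maf:g}"]))
               for maf in maf_grid}
    return LodProfile(positions=pos_df, maf_grid=tuple(maf_grid),
                      min_mutant_reads=min_reads, probabilities=prob_df,
                      median_sensitivity=medians)


def lod_summary_table(profile: LodProfile) -> pd.DataFrame:
    """Per-MAF quantiles of detection probability across positions."""
    rows = []
    for maf in profile.maf_grid:
        col = profile.probabilities[f"p_{maf:g}"]
        rows.append({"maf": maf, "median": float(col.median()),
                     "min": float(col.min()), "max": float(col.max())})
    return pd.DataFrame(rows)


def baseline_positions_from_calls(annotated: pd.DataFrame,
                                  variants: pd.DataFrame) -> pd.DataFrame:
    """Loci of tumor-derived variants detected at baseline, with their
    error-corrected distinct coverage in the baseline plasma sample."""
    tumor = annotated[annotated["origin"] == "tumor"]
    base = variants[(variants["compartment"] == "plasma")
                    & (variants["timepoint"] == "C1D1")]
    merged = tumor.merge(
        base[["patient_id", "chrom", "pos", "ref", "alt",
              "distinct_coverage"]],
        on=["patient_id", "chrom", "pos", "ref", "alt"])
    merged["locus"] = (merged["patient_id"] + ":" + merged["chrom"] + ":"
                       + merged["pos"].astype(str))
    return merged[["locus", "distinct_coverage"]].reset_index(drop=True)
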