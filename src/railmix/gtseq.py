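"""Genotype calling from per-allele amplicon read counts, plus sample QC.

Calls are made from the allele-1 read fraction: homozygous when it is
extreme, heterozygous inside a central band, missing when total depth is
below the cutoff or the ratio is ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

COUNT_COLUMNS = ["sample_id", "locus_id", "count_allele1", "count_allele2"]


def call_genotypes(
    counts: pd.DataFrame,
    min_depth: int = 10,
    hom_fraction: float = 0.9,
    het_low: float = 0.35,
    het_high: float = 0.65,
) -> pd.DataFrame:
    """Call {0, 1, 2, missing} genotypes from long-form read counts.

    Parameters
    ----------
    counts
        Long-form DataFrame with columns ``sample_id``, ``locus_id``,
        ``count_allele1`` (king-associated allele), ``count_allele2``.
    min_depth
        Cells with total depth below this are not scored.
    hom_fraction
        Allele-1 fraction at or above which the call is homozygous 2 (and,
        mirrored, at or below 1-hom_fraction the call is 0).
    het_low, het_high
        Inclusive allele-1-fraction band for the heterozygous call. Fractions
        falling between the bands are ambiguous and left missing.

    Returns
    -------
    Samples x loci DataFrame (float; NaN = missing), rows and columns in
    first-appearance order.
    """
    if not (0.5 < hom_fraction <= 1):
        raise ParameterError("hom_fraction must lie in (0.5, 1]")
    if not (0 <= het_low < het_high <= 1):
        raise ParameterError("require 0 <= het_low < het_high <= 1")
    missing_cols = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing_cols:
        raise DataError(f"counts table missing columns: {missing_cols}")
    c1 = counts["count_allele1"].to_numpy(dtype=float)
    c2 = counts["count_allele2"].to_numpy(dtype=float)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise DataError("negative read counts")
    if counts.duplicated(subset=["sample_id", "locus_id"]).any():
        raise DataError("duplicate (sample, locus) entries in counts table")

    total = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, c1 / total, np.nan)
    call = np.full(len(counts), np.nan)
    scored = total >= min_depth
    call[scored & (f >= hom_fraction)] = 2.0
    call[scored & (f <= 1 - hom_fraction)] = 0.0
    call[scored & (f >= het_low) & (f <= het_high)] = 1.0

    wide = (
        counts[["sample_id", "locus_id"]]
        .assign(genotype=call)
        .pivot(index="sample_id", columns="locus_id", values="genotype")
    )
    # restore first-appearance order lost by pivot's sorting
    sample_order = counts["sample_id"].drop_duplicates().tolist()
    locus_order = counts["locus_id"].drop_duplicates().tolist()
    wide = wide.reindex(index=sample_order, columns=locus_order)
    wide.index.name = "sample_id"
    wide.columns.name = None
    return wide


def missingness(genotypes: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of loci with missing genotype."""
    return genotypes.isna().mean(axis=1)


def sample_qc(
    genotypes: pd.DataFrame,
    max_missing_fraction: float = 0.30,
    min_scored: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples failing the missingness rules.

    ``min_scored`` (minimum number of scored loci; the paper-analogue value
    is 4) is applied first when given, then samples whose missing fraction
    strictly exceeds ``max_missing_fraction`` are dropped.

    Returns the retained matrix and the list of dropped sample ids.
    """
    if genotypes.shape[0] == 0 or genotypes.shape[1] == 0:
        raise DataError("empty genotype matrix")
    n_loci = genotypes.shape[1]
    scored = n_loci - genotypes.isna().sum(axis=1)
    drop = pd.Series(False, index=genotypes.index)
    if min_scored is not None:
        drop |= scored < min_scored
    drop |= missingness(genotypes) > max_missing_fraction
    dropped = genotypes.index[drop].tolist()
    return genotypes.loc[~drop], dropped


def qc_report(
    genotypes: pd.DataFrame,
    max_missing_fraction: float = 0.30,
    min_scored: int | None = None,
) -> pd.DataFrame:
    """Per-sample QC table: scored loci, missing fraction, drop reason."""
    n_loci = genotypes.shape[1]
    scored = (n_loci - genotypes.isna().sum(axis=1)).astype(int)
    frac = missingness(genotypes)
    reasons = []
    for sid in genotypes.index:
        if min_scored is not None and scored[sid] < min_scored:
            reasons.append(f"scored_loci<{min_scored}")
        elif frac[sid] > max_missing_fraction:
            reasons.append(f"missing>{max_missing_fraction:g}")
        else:
            reasons.append("")
    return pd.DataFrame(
        {
            "sample_id": genotypes.index,
            "n_scored": scored.to_numpy(),
            "missing_fraction": frac.to_numpy(),
            "drop_reason": reasons,
        }
    ).reset_index(drop=True)
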