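"""Readers and writers for the plain-text formats used across the pipeline.

Genotype matrices travel as CSV (rows = samples, columns = loci, NA for
missing), read counts as long-form TSV, sequences as FASTA, and the
STRUCTURE two-rows-per-individual text format is supported for users who
want to cross-check with external software.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .gtseq import COUNT_COLUMNS


def read_genotypes(path) -> pd.DataFrame:
    """Read a samples x loci genotype CSV (values 0/1/2 or NA)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    bad = df.stack().loc[lambda s: ~s.isin([0, 1, 2])]
    if len(bad):
        raise DataError(f"genotype values outside {{0,1,2,NA}}: {bad.head().to_dict()}")
    return df.astype(float)


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    out.index.name = "sample_id"
    # integers with NA, rendered without trailing .0
    out.to_csv(path, na_rep="NA", float_format="%.0f")


def read_read_counts(path) -> pd.DataFrame:
    """Read a long-form read-count TSV (sample, locus, count_allele1, count_allele2)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"read-count TSV missing columns: {missing}")
    return df


def write_read_counts(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered mapping of record id -> uppercase sequence string."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DataError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_structure(genotypes: pd.DataFrame, path, missing_code: int = -9) -> None:
    """Write a two-rows-per-individual STRUCTURE input file.

    Alleles are coded 1 (king-associated) and 2; missing is ``missing_code``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(genotypes.columns.astype(str)) + "\n")
        for sid, row in genotypes.iterrows():
            alleles1, alleles2 = [], []
            for g in row:
                if pd.isna(g):
                    alleles1.append(missing_code)
                    alleles2.append(missing_code)
                else:
                    g = int(g)
                    alleles1.append(1 if g >= 1 else 2)
                    alleles2.append(1 if g == 2 else 2)
            fh.write("\t".join([str(sid)] + [str(a) for a in alleles1]) + "\n")
            fh.write("\t".join([str(sid)] + [str(a) for a in alleles2]) + "\n")


def read_site_membership(path) -> pd.DataFrame:
    """Read a sample -> site TSV with columns sample_id, site_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "site_id"):
        if col not in df.columns:
            raise DataError(f"site membership TSV missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise DataError("duplicate sample ids in site membership")
    return df


def write_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Deterministic TSV writer used for all report outputs."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format, na_rep="NA")
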