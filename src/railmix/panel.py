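"""Diagnostic SNP panel definition.

A panel is a set of biallelic loci, each with a king-associated allele, a
clapper-associated allele, and the frequency of the king-associated allele
in each parental reference population (``p_king``, ``p_clapper``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

PANEL_COLUMNS = ["locus_id", "king_allele", "clapper_allele", "p_king", "p_clapper"]

_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PanelSpec:
    """Ordered collection of diagnostic loci.

    Parameters
    ----------
    loci
        DataFrame with columns ``locus_id``, ``king_allele``,
        ``clapper_allele``, ``p_king``, ``p_clapper``. ``p_king`` and
        ``p_clapper`` are frequencies of the king-associated allele in the
        king and clapper reference populations respectively.
    """

    loci: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.loci
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"panel missing columns: {missing}")
        if df["locus_id"].duplicated().any():
            dupes = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
            raise DataError(f"duplicate locus ids: {dupes}")
        for col in ("p_king", "p_clapper"):
            vals = df[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)) or np.any(~np.isfinite(vals)):
                raise DataError(f"{col} outside [0, 1]")
        object.__setattr__(self, "loci", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["locus_id"].tolist()

    @property
    def p_king(self) -> np.ndarray:
        return self.loci["p_king"].to_numpy(dtype=float)

    @property
    def p_clapper(self) -> np.ndarray:
        return self.loci["p_clapper"].to_numpy(dtype=float)

    @property
    def differentials(self) -> np.ndarray:
        """Per-locus parental allele-frequency differential p_king - p_clapper."""
        return self.p_king - self.p_clapper

    def subset(self, locus_ids: list[str]) -> "PanelSpec":
        """Panel restricted to ``locus_ids`` in the given order."""
        df = self.loci.set_index("locus_id").loc[locus_ids].reset_index()
        return PanelSpec(df)

    def with_frequencies(self, p_king: np.ndarray, p_clapper: np.ndarray) -> "PanelSpec":
        """Same loci with replacement parental frequencies."""
        df = self.loci.copy()
        df["p_king"] = np.asarray(p_king, dtype=float)
        df["p_clapper"] = np.asarray(p_clapper, dtype=float)
        return PanelSpec(df)

    @classmethod
    def fixed_difference(cls, n_loci: int, prefix: str = "locus") -> "PanelSpec":
        """Panel with p_king = 1, p_clapper = 0 at every locus."""
        rows = []
        for i in range(n_loci):
            king, clapper = _NUCLEOTIDES[i % 4], _NUCLEOTIDES[(i + 1) % 4]
            rows.append((f"{prefix}{i + 1:03d}", king, clapper, 1.0, 0.0))
        return cls(pd.DataFrame(rows, columns=PANEL_COLUMNS))

    @classmethod
    def read_tsv(cls, path) -> "PanelSpec":
        return cls(pd.read_csv(path, sep="\t", dtype={"locus_id": str}))

    def write_tsv(self, path) -> None:
        self.loci.to_csv(path, sep="\t", index=False)
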