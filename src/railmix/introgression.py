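"""Hybrid index, interspecific heterozygosity, hybrid classes and summaries.

The hybrid index h is the proportion of an individual's alleles inherited
from king rails (0 = clapper, 1 = king), estimated by maximum likelihood
from parental allele frequencies at the diagnostic loci. Interspecific
heterozygosity is the fraction of scored loci that are heterozygous.
Individuals are assigned to classes by fixed thresholds on (h, het), and
per-site and cyto-nuclear summaries aggregate the records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DataError, ParameterError
from .panel import PanelSpec

PURE_CLAPPER = "PURE_CLAPPER"
BACKCROSS_CLAPPER = "BACKCROSS_CLAPPER"
F1F2 = "F1F2"
BACKCROSS_KING = "BACKCROSS_KING"
PURE_KING = "PURE_KING"
UNASSIGNED = "UNASSIGNED"

HYBRID_CLASSES = (
    PURE_CLAPPER,
    BACKCROSS_CLAPPER,
    F1F2,
    BACKCROSS_KING,
    PURE_KING,
    UNASSIGNED,
)

_TINY = 1e-300


@dataclass(frozen=True)
class ClassThresholds:
    """Thresholds for hybrid classification.

    Defaults: F1/F2 requires intermediate hybrid index (0.25-0.75, closed)
    and heterozygosity > 0.3; backcross covers hybrid index 0.05-0.25
    (half-open at 0.25) and its king-side mirror; pure is < 0.05 (> 0.95 on
    the king side).
    """

    f1f2_h_low: float = 0.25
    f1f2_h_high: float = 0.75
    f1f2_het_min: float = 0.30
    backcross_low: float = 0.05
    pure_max: float = 0.05

    def __post_init__(self) -> None:
        vals = (
            self.f1f2_h_low,
            self.f1f2_h_high,
            self.f1f2_het_min,
            self.backcross_low,
            self.pure_max,
        )
        if any(not (0 <= v <= 1) for v in vals):
            raise ParameterError("thresholds must lie in [0, 1]")
        if not self.f1f2_h_low < self.f1f2_h_high:
            raise ParameterError("f1f2 window is empty")


def _copy_loglik(h: float, n_king: np.ndarray, n_clapper: np.ndarray,
                 p_k: np.ndarray, p_c: np.ndarray) -> float:
    """Log-likelihood of allele-copy counts at mixture proportion h.

    ``n_king``/``n_clapper`` are per-locus counts of king- and clapper-
    associated allele copies (summing to 2 at scored loci).
    """
    pk_copy = h * p_k + (1 - h) * p_c
    pc_copy = 1 - pk_copy
    with np.errstate(divide="ignore"):
        lk = np.log(np.maximum(pk_copy, _TINY))
        lc = np.log(np.maximum(pc_copy, _TINY))
    lk = np.where(pk_copy > 0, lk, -np.inf)
    lc = np.where(pc_copy > 0, lc, -np.inf)
    with np.errstate(invalid="ignore"):
        tk = np.where(n_king > 0, n_king * lk, 0.0)
        tc = np.where(n_clapper > 0, n_clapper * lc, 0.0)
        return float(np.sum(tk) + np.sum(tc))


def _fit_h(n_king: np.ndarray, n_clapper: np.ndarray,
           p_k: np.ndarray, p_c: np.ndarray) -> float:
    opt = minimize_scalar(
        lambda h: -_copy_loglik(h, n_king, n_clapper, p_k, p_c),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    cands = [0.0, float(opt.x), 1.0]
    lls = [_copy_loglik(h, n_king, n_clapper, p_k, p_c) for h in cands]
    return cands[int(np.argmax(lls))]


def _support_interval(h_hat: float, n_king, n_clapper, p_k, p_c,
                      drop: float = 2.0) -> tuple[float, float]:
    """Profile-likelihood interval: h where log-likelihood falls ``drop`` units."""
    ll_max = _copy_loglik(h_hat, n_king, n_clapper, p_k, p_c)

    def deficit(h: float) -> float:
        return ll_max - _copy_loglik(h, n_king, n_clapper, p_k, p_c) - drop

    def boundary(lo: float, hi: float, increasing_deficit_at_lo: bool) -> float:
        # bisection; deficit is monotone on each side of the MLE
        for _ in range(80):
            mid = (lo + hi) / 2
            if (deficit(mid) > 0) == increasing_deficit_at_lo:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo = 0.0 if deficit(0.0) <= 0 else boundary(0.0, h_hat, True)
    hi = 1.0 if deficit(1.0) <= 0 else boundary(h_hat, 1.0, False)
    return lo, hi


def hybrid_index(
    genotypes: pd.DataFrame,
    panel: PanelSpec,
    support_drop: float = 2.0,
) -> pd.DataFrame:
    """Maximum-likelihood hybrid index per individual.

    Returns a DataFrame indexed by sample with columns ``h`` (NaN when no
    loci scored), ``n_scored``, and the ``support_drop``-unit profile-
    likelihood interval (``h_low``, ``h_high``). On a fixed-difference
    panel the estimate equals the king-allele fraction among scored copies.
    """
    cols = [c for c in genotypes.columns if c in set(panel.locus_ids)]
    if not cols:
        raise DataError("no panel loci present in genotype matrix")
    sub = panel.subset(cols)
    p_k, p_c = sub.p_king, sub.p_clapper
    g_all = genotypes[cols].to_numpy(dtype=float)

    records = []
    for i in range(g_all.shape[0]):
        mask = ~np.isnan(g_all[i])
        n_scored = int(mask.sum())
        if n_scored == 0:
            records.append((np.nan, 0, np.nan, np.nan))
            continue
        g = g_all[i, mask]
        n_king, n_clapper = g, 2 - g
        h_hat = _fit_h(n_king, n_clapper, p_k[mask], p_c[mask])
        lo, hi = _support_interval(
            h_hat, n_king, n_clapper, p_k[mask], p_c[mask], drop=support_drop
        )
        records.append((h_hat, n_scored, lo, hi))
    out = pd.DataFrame(
        records, index=genotypes.index.copy(), columns=["h", "n_scored", "h_low", "h_high"]
    )
    out["n_scored"] = out["n_scored"].astype(int)
    return out


def interspecific_het(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Fraction of scored loci heterozygous, per individual (NaN if none scored)."""
    g = genotypes.to_numpy(dtype=float)
    scored = (~np.isnan(g)).sum(axis=1)
    n_het = np.nansum(g == 1, axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(scored > 0, n_het / np.maximum(scored, 1), np.nan)
    return pd.DataFrame(
        {"het": het, "n_scored": scored.astype(int)}, index=genotypes.index.copy()
    )


def classify_hybrid(
    h: float, het: float, thresholds: ClassThresholds | None = None
) -> str:
    """Assign one individual to a hybrid class from (h, het).

    Evaluation order: F1/F2 window first, then backcross windows, then pure
    tails; anything left (e.g. intermediate h with low het) is UNASSIGNED.
    """
    t = thresholds or ClassThresholds()
    if not (0 <= h <= 1) or not (0 <= het <= 1):
        raise ParameterError("h and het must lie in [0, 1]")
    if t.f1f2_h_low <= h <= t.f1f2_h_high and het > t.f1f2_het_min:
        return F1F2
    if t.backcross_low <= h < t.f1f2_h_low:
        return BACKCROSS_CLAPPER
    if t.f1f2_h_high < h <= 1 - t.backcross_low:
        return BACKCROSS_KING
    if h < t.pure_max:
        return PURE_CLAPPER
    if h > 1 - t.pure_max:
        return PURE_KING
    return UNASSIGNED


def classify_records(
    h: pd.DataFrame,
    het: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Join hybrid index and heterozygosity tables into IntrogressionRecords.

    Individuals missing either metric get hybrid_class UNASSIGNED.
    """
    joined = h[["h", "h_low", "h_high"]].join(het[["het"]], how="outer")
    joined["n_scored"] = h["n_scored"].reindex(joined.index).fillna(0).astype(int)
    classes = []
    for _, row in joined.iterrows():
        if np.isnan(row["h"]) or np.isnan(row["het"]):
            classes.append(UNASSIGNED)
        else:
            classes.append(classify_hybrid(row["h"], row["het"], thresholds))
    joined["hybrid_class"] = classes
    joined.index.name = "sample_id"
    return joined.reset_index()


SITE_SUMMARY_COLUMNS = [
    "site_id", "n", "mean_h", "sd_h", "mean_het",
    "n_f1f2", "n_backcrossed", "percent_backcrossed",
]


def site_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site introgression summary (Table-2-style schema).

    ``records`` needs ``site_id`` and ``hybrid_class`` columns; ``h`` and
    ``het`` are averaged over non-missing values when present. The percent
    backcrossed is 100 * n_backcrossed / n rounded to one decimal.
    """
    if "site_id" not in records.columns or "hybrid_class" not in records.columns:
        raise DataError("records need site_id and hybrid_class columns")
    if records.empty:
        raise DataError("no records to summarize")
    rows = []
    for site_id, grp in records.groupby("site_id", sort=False):
        n = len(grp)
        classes = grp["hybrid_class"]
        n_f1f2 = int((classes == F1F2).sum())
        n_bc = int(classes.isin([BACKCROSS_CLAPPER, BACKCROSS_KING]).sum())
        mean_h = float(grp["h"].mean()) if "h" in grp else np.nan
        sd_h = float(grp["h"].std(ddof=1)) if "h" in grp else np.nan
        mean_het = float(grp["het"].mean()) if "het" in grp else np.nan
        rows.append(
            (site_id, n, mean_h, sd_h, mean_het, n_f1f2, n_bc,
             round(100.0 * n_bc / n, 1))
        )
    return pd.DataFrame(rows, columns=SITE_SUMMARY_COLUMNS)


NUCLEAR_STATUS = {
    PURE_CLAPPER: "pure_clapper",
    PURE_KING: "pure_king",
    BACKCROSS_CLAPPER: "mixed",
    BACKCROSS_KING: "mixed",
    F1F2: "mixed",
}


@dataclass
class CytoNuclearTable:
    """Cross-tabulation of mtDNA species by nuclear status.

    ``table`` is indexed by mtDNA species (KING, CLAPPER) with columns
    pure_clapper / mixed / pure_king; samples present in only one assay, or
    with AMBIGUOUS mtDNA or UNASSIGNED nuclear class, are listed in
    ``unjoined`` with a reason.
    """

    table: pd.DataFrame
    unjoined: pd.DataFrame


def cytonuclear_table(
    mtdna_calls: pd.DataFrame, records: pd.DataFrame
) -> CytoNuclearTable:
    """Cross-tab mtDNA species against nuclear introgression status."""
    for df, name in ((mtdna_calls, "mtdna_calls"), (records, "records")):
        if df["sample_id"].duplicated().any():
            raise DataError(f"duplicate sample ids in {name}")
    mt = mtdna_calls.set_index("sample_id")["species"]
    nuc = records.set_index("sample_id")["hybrid_class"]
    statuses = ["pure_clapper", "mixed", "pure_king"]
    table = pd.DataFrame(0, index=["KING", "CLAPPER"], columns=statuses)
    unjoined = []
    for sid in sorted(set(mt.index) | set(nuc.index)):
        if sid not in mt.index:
            unjoined.append((sid, "no_mtdna_call"))
            continue
        if sid not in nuc.index:
            unjoined.append((sid, "no_nuclear_record"))
            continue
        species = mt[sid]
        status = NUCLEAR_STATUS.get(nuc[sid])
        if species not in table.index:
            unjoined.append((sid, "ambiguous_mtdna"))
        elif status is None:
            unjoined.append((sid, "unassigned_nuclear"))
        else:
            table.loc[species, status] += 1
    unjoined_df = pd.DataFrame(unjoined, columns=["sample_id", "reason"])
    return CytoNuclearTable(table=table, unjoined=unjoined_df)


def triangle_data(records: pd.DataFrame) -> pd.DataFrame:
    """Rows of (sample_id, h, het, hybrid_class) for triangle plotting.

    Individuals with missing h or het are excluded.
    """
    cols = ["sample_id", "h", "het", "hybrid_class"]
    out = records[cols].dropna(subset=["h", "het"]).reset_index(drop=True)
    return out
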