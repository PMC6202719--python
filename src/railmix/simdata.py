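"""Synthetic diagnostic panels, pedigree cohorts, amplicon read counts and mtDNA.

Everything downstream of the wet lab can be exercised against cohorts
generated here: genotypes follow explicit Mendelian gamete sampling from
simulated parents, read counts follow an overdispersed depth model with
allele-specific error, and mtDNA fragments carry diagnostic sites inherited
through the (recorded) maternal line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .panel import PANEL_COLUMNS, _NUCLEOTIDES, PanelSpec

KING = "KING"
CLAPPER = "CLAPPER"

PURE_KING = "PURE_KING"
PURE_CLAPPER = "PURE_CLAPPER"
F1 = "F1"
F2 = "F2"

_BC_RE = re.compile(r"^BC(\d+)_(KING|CLAPPER)$")

TRUTH_COLUMNS = ["sample_id", "pedigree", "true_ancestry_fraction", "mtdna_species"]


def pedigree_labels(depth: int = 2) -> list[str]:
    """Closed label set for backcross recursion up to ``depth`` generations."""
    labels = [PURE_KING, PURE_CLAPPER, F1, F2]
    for n in range(1, depth + 1):
        labels += [f"BC{n}_KING", f"BC{n}_CLAPPER"]
    return labels


def true_ancestry_fraction(label: str) -> float:
    """Expected king-ancestry fraction implied by a pedigree label."""
    if label == PURE_KING:
        return 1.0
    if label == PURE_CLAPPER:
        return 0.0
    if label in (F1, F2):
        return 0.5
    m = _BC_RE.match(label)
    if m:
        n, species = int(m.group(1)), m.group(2)
        frac_from_hybrid = 0.5 ** (n + 1)
        return 1.0 - frac_from_hybrid if species == KING else frac_from_hybrid
    raise ParameterError(f"unknown pedigree label: {label!r}")


def make_panel(
    n_loci: int,
    mean_diff: float = 0.96,
    sd_diff: float = 0.08,
    floor: float = 0.7,
    seed: int = 0,
) -> PanelSpec:
    """Draw a diagnostic panel with truncated-normal frequency differentials.

    Differentials are drawn from Normal(``mean_diff``, ``sd_diff``) truncated
    to [``floor``, 1]; parental frequencies are placed symmetrically about
    0.5 (p_king = 0.5 + d/2, p_clapper = 0.5 - d/2).
    """
    if n_loci < 1:
        raise ParameterError("n_loci must be >= 1")
    if not (0 < floor <= mean_diff <= 1):
        raise ParameterError("require 0 < floor <= mean_diff <= 1")
    if sd_diff < 0:
        raise ParameterError("sd_diff must be >= 0")
    rng = np.random.default_rng(seed)
    if sd_diff == 0:
        diffs = np.full(n_loci, float(mean_diff))
    else:
        a = (floor - mean_diff) / sd_diff
        b = (1.0 - mean_diff) / sd_diff
        diffs = stats.truncnorm.rvs(
            a, b, loc=mean_diff, scale=sd_diff, size=n_loci, random_state=rng
        )
    p_king = 0.5 + diffs / 2
    p_clapper = 0.5 - diffs / 2
    rows = []
    for i in range(n_loci):
        king_allele, clapper_allele = rng.choice(_NUCLEOTIDES, size=2, replace=False)
        rows.append(
            (f"locus{i + 1:03d}", king_allele, clapper_allele, p_king[i], p_clapper[i])
        )
    return PanelSpec(pd.DataFrame(rows, columns=PANEL_COLUMNS))


class _Individual:
    """Simulated bird: per-locus king-allele counts plus maternal mtDNA species."""

    __slots__ = ("genotype", "mtdna")

    def __init__(self, genotype: np.ndarray, mtdna: str):
        self.genotype = genotype
        self.mtdna = mtdna


def _pure(species: str, panel: PanelSpec, rng: np.random.Generator) -> _Individual:
    p = panel.p_king if species == KING else panel.p_clapper
    return _Individual(rng.binomial(2, p), species)


def _gamete(ind: _Individual, rng: np.random.Generator) -> np.ndarray:
    """One king-allele indicator per locus, drawn Mendelianly from ``ind``."""
    g = ind.genotype
    het_draw = rng.integers(0, 2, size=g.shape)
    return np.where(g == 2, 1, np.where(g == 0, 0, het_draw))


def _cross(a: _Individual, b: _Individual, rng: np.random.Generator) -> _Individual:
    mother, father = (a, b) if rng.integers(0, 2) == 1 else (b, a)
    genotype = _gamete(mother, rng) + _gamete(father, rng)
    return _Individual(genotype, mother.mtdna)


def _simulate_individual(
    label: str, panel: PanelSpec, rng: np.random.Generator
) -> _Individual:
    if label == PURE_KING:
        return _pure(KING, panel, rng)
    if label == PURE_CLAPPER:
        return _pure(CLAPPER, panel, rng)
    if label == F1:
        return _cross(_pure(KING, panel, rng), _pure(CLAPPER, panel, rng), rng)
    if label == F2:
        return _cross(
            _simulate_individual(F1, panel, rng),
            _simulate_individual(F1, panel, rng),
            rng,
        )
    m = _BC_RE.match(label)
    if m:
        n, species = int(m.group(1)), m.group(2)
        hybrid_label = F1 if n == 1 else f"BC{n - 1}_{species}"
        pure_label = PURE_KING if species == KING else PURE_CLAPPER
        return _cross(
            _simulate_individual(hybrid_label, panel, rng),
            _simulate_individual(pure_label, panel, rng),
            rng,
        )
    raise ParameterError(f"unknown pedigree label: {label!r}")


def simulate_cohort(
    panel: PanelSpec,
    design: dict[str, int],
    seed: int = 0,
    id_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of individuals by pedigree class.

    Parameters
    ----------
    design
        Mapping of pedigree label (e.g. ``"F1"``, ``"BC1_CLAPPER"``) to the
        number of individuals to simulate.

    Returns
    -------
    genotypes
        samples x loci DataFrame of king-allele counts {0, 1, 2}.
    truth
        TruthTable: sample_id, pedigree, true_ancestry_fraction, mtdna_species.
    """
    if not design:
        raise ParameterError("design must be non-empty")
    for label in design:
        true_ancestry_fraction(label)  # validates
    rng = np.random.default_rng(seed)
    rows, truth_rows, sample_ids = [], [], []
    i = 0
    for label, count in design.items():
        if count < 0:
            raise ParameterError("design counts must be >= 0")
        for _ in range(count):
            i += 1
            sid = f"{id_prefix}{i:04d}"
            ind = _simulate_individual(label, panel, rng)
            rows.append(ind.genotype)
            truth_rows.append((sid, label, true_ancestry_fraction(label), ind.mtdna))
            sample_ids.append(sid)
    genotypes = pd.DataFrame(
        np.vstack(rows).astype(float), index=sample_ids, columns=panel.locus_ids
    )
    genotypes.index.name = "sample_id"
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genotypes, truth


def simulate_read_counts(
    genotypes: pd.DataFrame,
    depth_mean: float = 100.0,
    depth_dispersion: float = 5.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """GT-seq-like per-allele read counts for every sample x locus cell.

    Total depth is negative binomial with mean ``depth_mean`` and size
    (dispersion) ``depth_dispersion``; the allele-1 (king-allele) count is
    binomial with success probability 1-e, 0.5 or e for genotypes 2, 1, 0.
    Cells with missing genotype get depth drawn the same way and allele
    ratio 0.5 (the caller, not the simulator, decides scoreability).

    Returns a long-form DataFrame (sample_id, locus_id, count_allele1,
    count_allele2).
    """
    if depth_mean <= 0 or depth_dispersion <= 0:
        raise ParameterError("depth parameters must be positive")
    if not (0 <= error_rate < 0.5):
        raise ParameterError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    g = genotypes.to_numpy(dtype=float)
    n, m = g.shape
    p_nb = depth_dispersion / (depth_dispersion + depth_mean)
    total = rng.negative_binomial(depth_dispersion, p_nb, size=(n, m))
    r = np.where(g == 2, 1.0 - error_rate, np.where(g == 0, error_rate, 0.5))
    r = np.where(np.isnan(g), 0.5, r)
    c1 = rng.binomial(total, r)
    c2 = total - c1
    out = pd.DataFrame(
        {
            "sample_id": np.repeat(genotypes.index.to_numpy(), m),
            "locus_id": np.tile(genotypes.columns.to_numpy(), n),
            "count_allele1": c1.ravel(),
            "count_allele2": c2.ravel(),
        }
    )
    return out


@dataclass(frozen=True)
class MtdnaSimulation:
    """Output bundle of :func:`simulate_mtdna`."""

    sequences: dict[str, str]  # sample_id -> fragment
    positions: np.ndarray  # 0-based diagnostic positions
    king_consensus: str
    clapper_consensus: str


def simulate_mtdna(
    truth: pd.DataFrame,
    fragment_length: int = 620,
    n_sites: int = 8,
    background_divergence: float = 0.0,
    diagnostic_site_noise: float = 0.0,
    seed: int = 0,
) -> MtdnaSimulation:
    """Simulate ND2-like fragments carrying diagnostic sites.

    Two species consensus haplotypes differ at exactly ``n_sites`` positions.
    Each individual inherits its maternal species' consensus, then non-
    diagnostic sites mutate independently at rate ``background_divergence``.
    ``diagnostic_site_noise`` (default 0) flips diagnostic sites to the other
    species' state, for testing the matching rule's tolerance.
    """
    if n_sites > fragment_length:
        raise ParameterError("n_sites must be <= fragment_length")
    if not (0 <= background_divergence < 1 and 0 <= diagnostic_site_noise < 1):
        raise ParameterError("noise rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nts = np.array(_NUCLEOTIDES)
    base = rng.integers(0, 4, size=fragment_length)
    positions = np.sort(rng.choice(fragment_length, size=n_sites, replace=False))
    clapper = base.copy()
    king = base.copy()
    # shift by 1-3 mod 4 guarantees a different nucleotide at each site
    king[positions] = (king[positions] + rng.integers(1, 4, size=n_sites)) % 4
    non_diag = np.setdiff1d(np.arange(fragment_length), positions)

    sequences: dict[str, str] = {}
    for sid, species in zip(truth["sample_id"], truth["mtdna_species"]):
        seq = (king if species == KING else clapper).copy()
        if background_divergence > 0:
            hit = non_diag[rng.random(non_diag.size) < background_divergence]
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=hit.size)) % 4
        if diagnostic_site_noise > 0:
            flip = positions[rng.random(n_sites) < diagnostic_site_noise]
            other = king if species == CLAPPER else clapper
            seq[flip] = other[flip]
        sequences[sid] = "".join(nts[seq])
    return MtdnaSimulation(
        sequences=sequences,
        positions=positions,
        king_consensus="".join(nts[king]),
        clapper_consensus="".join(nts[clapper]),
    )
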