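"""Species identification from a fixed-length mtDNA fragment.

Diagnostic sites are the aligned columns where king and clapper voucher
sets are reciprocally fixed for different nucleotides; a query sequence is
assigned to the species it matches at >= ``min_match`` diagnostic sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, DataError, RailmixError

KING = "KING"
CLAPPER = "CLAPPER"
AMBIGUOUS = "AMBIGUOUS"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # 0-based index into the aligned fragment
    king_state: str
    clapper_state: str

    def __post_init__(self) -> None:
        if self.king_state == self.clapper_state:
            raise DataError("diagnostic site states must differ")


@dataclass(frozen=True)
class DiagnosticSiteSet:
    sites: tuple[DiagnosticSite, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise DataError("diagnostic site positions must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[int, str, str]]) -> "DiagnosticSiteSet":
        return cls(tuple(DiagnosticSite(p, k, c) for p, k, c in tuples))

    def swapped(self) -> "DiagnosticSiteSet":
        """Same sites with the species states exchanged."""
        return DiagnosticSiteSet(
            tuple(
                DiagnosticSite(s.position, s.clapper_state, s.king_state)
                for s in self.sites
            )
        )


@dataclass(frozen=True)
class MtdnaCall:
    sample_id: str
    species: str  # KING | CLAPPER | AMBIGUOUS
    matches_king: int
    matches_clapper: int
    n_scored: int


def derive_diagnostic_sites(
    king_vouchers: Sequence[str],
    clapper_vouchers: Sequence[str],
    expected_count: int | None = None,
) -> DiagnosticSiteSet:
    """Find columns reciprocally fixed for different states between voucher sets.

    All sequences must share one aligned length; columns containing anything
    other than A/C/G/T in either set are never diagnostic. Warns when the
    number of sites found differs from ``expected_count``.
    """
    if not king_vouchers or not clapper_vouchers:
        raise DataError("need at least one voucher per species")
    king_vouchers = [s.upper() for s in king_vouchers]
    clapper_vouchers = [s.upper() for s in clapper_vouchers]
    lengths = {len(s) for s in king_vouchers} | {len(s) for s in clapper_vouchers}
    if len(lengths) != 1:
        raise AlignmentError(f"voucher sequences have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    sites = []
    for pos in range(length):
        king_states = {s[pos] for s in king_vouchers}
        clapper_states = {s[pos] for s in clapper_vouchers}
        if len(king_states) == 1 and len(clapper_states) == 1:
            (k,) = king_states
            (c,) = clapper_states
            if k in _BASES and c in _BASES and k != c:
                sites.append(DiagnosticSite(pos, k, c))
    result = DiagnosticSiteSet(tuple(sites))
    if expected_count is not None and len(result) != expected_count:
        warnings.warn(
            f"found {len(result)} diagnostic sites, expected {expected_count}",
            stacklevel=2,
        )
    if len(result) == 0:
        warnings.warn("no diagnostic sites found between voucher sets", stacklevel=2)
    return result


def classify_mtdna(
    seq: str,
    sites: DiagnosticSiteSet,
    min_match: int = 6,
    sample_id: str = "",
) -> MtdnaCall:
    """Assign a sequence to a species by counting diagnostic-site matches.

    Sites where the sequence carries an N, gap or other non-ACGT character
    are not scored; a scored site matching neither voucher state counts
    toward neither species.
    """
    seq = seq.upper()
    matches_king = matches_clapper = n_scored = 0
    for site in sites:
        if site.position >= len(seq):
            raise AlignmentError("sequence shorter than diagnostic site position")
        base = seq[site.position]
        if base not in _BASES:
            continue
        n_scored += 1
        if base == site.king_state:
            matches_king += 1
        elif base == site.clapper_state:
            matches_clapper += 1
    king_hit = matches_king >= min_match
    clapper_hit = matches_clapper >= min_match
    if king_hit and clapper_hit:
        raise RailmixError(
            "both species reached min_match; inconsistent diagnostic site set"
        )
    species = KING if king_hit else CLAPPER if clapper_hit else AMBIGUOUS
    return MtdnaCall(sample_id, species, matches_king, matches_clapper, n_scored)


def classify_many(
    sequences: Mapping[str, str],
    sites: DiagnosticSiteSet,
    min_match: int = 6,
) -> pd.DataFrame:
    """Classify a mapping of sample_id -> sequence; returns a tidy table."""
    calls = [
        classify_mtdna(seq, sites, min_match=min_match, sample_id=sid)
        for sid, seq in sequences.items()
    ]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "species": [c.species for c in calls],
            "matches_king": [c.matches_king for c in calls],
            "matches_clapper": [c.matches_clapper for c in calls],
            "n_scored": [c.n_scored for c in calls],
        }
    )


def register_sequence(
    seq: str,
    king_consensus: str,
    clapper_consensus: str,
    max_offset: int = 10,
) -> str:
    """Ungapped sliding-offset registration onto the voucher frame.

    Shifts ``seq`` by up to ``max_offset`` positions in either direction,
    pads with N, and returns the shift maximizing identity to the closer
    consensus. A convenience for off-by-k inputs only; indels are out of
    scope.
    """
    length = len(king_consensus)
    if len(clapper_consensus) != length:
        raise AlignmentError("consensus sequences differ in length")
    best_seq, best_score = None, -1
    for offset in range(-max_offset, max_offset + 1):
        if offset >= 0:
            shifted = ("N" * offset + seq)[:length]
        else:
            shifted = seq[-offset:][:length]
        shifted = shifted.ljust(length, "N")
        score = max(
            sum(a == b for a, b in zip(shifted, king_consensus)),
            sum(a == b for a, b in zip(shifted, clapper_consensus)),
        )
        if score > best_score:
            best_seq, best_score = shifted, score
    return best_seq
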