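"""All-vs-all pairwise protein identity and duplication tiers.

Global (Needleman-Wunsch) percent identity is counted over the full
alignment length including terminal-gap columns; local (Smith-Waterman)
identity is counted over the local alignment columns.  Default scoring is
BLOSUM62 with affine gaps (open 11, extend 1, BLASTP defaults); both the
matrix and the gap penalties are configurable.

Tier bins are contiguous half-open intervals on global identity so every
pair receives a label: exact_duplicate at exactly 100, recent_paralog in
[98, 100), diverged_paralog in [70, 98), non_homologous below 70.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import ProteinRecord

__all__ = [
    "AlignmentScoring",
    "PairIdentity",
    "LocalHit",
    "TIER_EDGES",
    "global_identity",
    "local_alignment",
    "all_vs_all",
    "classify_tiers",
    "classify_identity",
]

#: (diverged_min, recent_min, exact) global-identity bin edges in percent
TIER_EDGES = (70.0, 98.0, 100.0)


@dataclass(frozen=True)
class AlignmentScoring:
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of the first residue of a gap
    gap_extend: int = 1  # cost of each further residue


class LocalHit(NamedTuple):
    identity: float
    length: int
    start: int  # 1-based in the first sequence; 0 if empty
    end: int


@dataclass(frozen=True)
class PairIdentity:
    id_a: str
    id_b: str
    global_identity: float
    global_aln_length: int
    local_identity: float
    local_aln_length: int
    query_start: int
    query_end: int
    tier: str


def _aligner(scoring: AlignmentScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = mode
    return aligner


def _identity_over_columns(alignment) -> tuple[int, int]:
    """(identical columns, total columns) walked directly off the alignment."""
    a, b = alignment[0], alignment[1]
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return ident, len(a)


def global_identity(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> tuple[float, int]:
    """Optimal global alignment identity over all columns, terminal gaps included."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner(scoring, "global").align(a.upper(), b.upper())[0]
    ident, cols = _identity_over_columns(aln)
    return 100.0 * ident / cols, cols


def local_alignment(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> LocalHit:
    """Highest-scoring local alignment; empty result when no positive segment."""
    if not a or not b:
        raise ValueError("empty sequence")
    alignments = _aligner(scoring, "local").align(a.upper(), b.upper())
    try:
        aln = alignments[0]
    except IndexError:
        return LocalHit(0.0, 0, 0, 0)
    if aln.score <= 0:
        return LocalHit(0.0, 0, 0, 0)
    ident, cols = _identity_over_columns(aln)
    if cols == 0:
        return LocalHit(0.0, 0, 0, 0)
    start = int(aln.coordinates[0][0]) + 1
    end = int(aln.coordinates[0][-1])
    return LocalHit(100.0 * ident / cols, cols, start, end)


def classify_identity(identity: float, edges: tuple[float, float, float] = TIER_EDGES) -> str:
    diverged, recent, exact = edges
    if identity >= exact:
        return "exact_duplicate"
    if identity >= recent:
        return "recent_paralog"
    if identity >= diverged:
        return "diverged_paralog"
    return "non_homologous"


def all_vs_all(
    proteins: Sequence[ProteinRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """All n(n-1)/2 unordered pairs with global and local metrics.

    Pairs are canonically ordered by id so the table is invariant to input
    order; duplicate ids are an error.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    by_id = {p.protein_id: p.sequence for p in proteins}
    rows = []
    for id_a, id_b in combinations(sorted(ids), 2):
        gid, glen = global_identity(by_id[id_a], by_id[id_b], scoring)
        loc = local_alignment(by_id[id_a], by_id[id_b], scoring)
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "global_identity": gid,
                "global_aln_length": glen,
                "local_identity": loc.identity,
                "local_aln_length": loc.length,
                "query_start": loc.start,
                "query_end": loc.end,
            }
        )
    return pd.DataFrame(rows)


def classify_tiers(
    table: pd.DataFrame, edges: tuple[float, float, float] = TIER_EDGES
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach tier labels and return per-tier counts.

    Counts partition all pairs (every pair gets exactly one tier).  The bin
    edges are recorded in ``table.attrs['tier_edges']``.
    """
    table = table.copy()
    table["tier"] = table["global_identity"].map(lambda x: classify_identity(x, edges))
    table.attrs["tier_edges"] = edges
    counts = table["tier"].value_counts().to_dict()
    for tier in ("exact_duplicate", "recent_paralog", "diverged_paralog", "non_homologous"):
        counts.setdefault(tier, 0)
    return table, counts
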