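"""Fuzzy reactive-center-loop (RCL) matching for serpin discovery.

Candidate serpins are proteins whose C-terminal window harbours a close,
substitution-only copy of a known RCL peptide.  Matching permits a bounded
fraction of mismatches (default 30%, floor-rounded) and forbids runs of two
or more consecutive mismatched positions, which suppresses spurious hits in
low-complexity tails.  Discovery can be iterated: RCLs extracted from hits
are fed back as additional queries until the hit set reaches a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "RCLMatch",
    "hamming_with_run_constraint",
    "mismatch_budget",
    "scan_protein",
    "scan_proteome",
    "iterate_to_fixed_point",
    "read_rcl_seeds",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class ScanParams:
    """Matching parameters for the C-terminal RCL scan."""

    window_len: int = 100
    max_mismatch_fraction: float = 0.30
    forbid_adjacent_mismatches: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatch_fraction < 1):
            raise ValueError("max_mismatch_fraction must be in [0, 1)")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")


@dataclass(frozen=True)
class RCLMatch:
    """Best fuzzy match of one query RCL inside a protein.

    ``start``/``end`` are 0-based half-open offsets within the full protein.
    """

    protein_id: str
    query_rcl_id: str
    start: int
    end: int
    mismatch_count: int
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start


def mismatch_budget(query_len: int, max_mismatch_fraction: float) -> int:
    """Allowed mismatches for a query: floor(fraction x length)."""
    return int(max_mismatch_fraction * query_len)


def _same(a: str, b: str) -> bool:
    # case handled by callers (sequences upper-cased); X never matches
    return a == b and a != "X"


def hamming_with_run_constraint(a: str, b: str, budget: int) -> tuple[int, bool]:
    """Substitution distance with the consecutive-mismatch rule.

    Returns ``(count, admissible)`` where ``count`` is the number of
    differing positions and ``admissible`` requires both ``count <= budget``
    and that no two mismatch positions are adjacent.  Comparison is
    case-insensitive and ``X`` mismatches everything.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    count = 0
    prev_mm = False
    run_ok = True
    for x, y in zip(a, b):
        if _same(x, y):
            prev_mm = False
        else:
            count += 1
            if prev_mm:
                run_ok = False
            prev_mm = True
    return count, count <= budget and run_ok


def _mismatch_positions(a: str, b: str, offset: int = 0) -> tuple[int, ...]:
    return tuple(
        offset + i for i, (x, y) in enumerate(zip(a.upper(), b.upper())) if not _same(x, y)
    )


def scan_protein(
    protein: ProteinRecord,
    queries: dict[str, str],
    params: ScanParams = ScanParams(),
) -> RCLMatch | None:
    """Best admissible RCL match within the protein's C-terminal window.

    Every window of exactly the query's length whose span lies entirely
    within the last ``window_len`` residues (the whole protein if shorter)
    is a candidate.  Among admissible (query, offset) pairs the fewest
    mismatches wins; ties break to the smallest start offset, then to
    sorted query id.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    seq = protein.sequence.upper()
    n = len(seq)
    if n == 0:
        logger.info("empty protein %s skipped", protein.protein_id)
        return None
    win_start = max(0, n - params.window_len)
    best: tuple[int, int, int] | None = None  # (mismatches, start, query rank)
    best_match: RCLMatch | None = None
    for rank, qid in enumerate(sorted(queries)):
        q = queries[qid].upper()
        qlen = len(q)
        if qlen == 0 or qlen > n - win_start:
            continue
        budget = mismatch_budget(qlen, params.max_mismatch_fraction)
        for start in range(win_start, n - qlen + 1):
            count = 0
            prev_mm = False
            ok = True
            for i in range(qlen):
                if _same(seq[start + i], q[i]):
                    prev_mm = False
                else:
                    count += 1
                    if count > budget or (prev_mm and params.forbid_adjacent_mismatches):
                        ok = False
                        break
                    prev_mm = True
            if not ok:
                continue
            key = (count, start, rank)
            if best is None or key < best:
                best = key
                best_match = RCLMatch(
                    protein_id=protein.protein_id,
                    query_rcl_id=qid,
                    start=start,
                    end=start + qlen,
                    mismatch_count=count,
                    mismatch_positions=_mismatch_positions(
                        seq[start : start + qlen], q, offset=start
                    ),
                )
    return best_match


def scan_proteome(
    proteins: list[ProteinRecord],
    seed_rcls: dict[str, str],
    params: ScanParams = ScanParams(),
) -> list[tuple[ProteinRecord, RCLMatch]]:
    """Scan every protein; one entry per protein with an admissible match."""
    if not seed_rcls:
        return []
    hits = []
    for p in proteins:
        m = scan_protein(p, seed_rcls, params)
        if m is not None:
            hits.append((p, m))
    return hits


def iterate_to_fixed_point(
    proteins: list[ProteinRecord],
    seed_rcls: dict[str, str],
    params: ScanParams = ScanParams(),
    max_rounds: int = 5,
    p1_offsets: dict[str, int] | None = None,
) -> tuple[list[tuple[ProteinRecord, RCLMatch]], list[int]]:
    """Iterative re-seeding: hit RCLs become queries for the next round.

    Stops when the set of hit proteins is unchanged or ``max_rounds`` is
    reached.  The hit set is monotone non-decreasing because queries only
    accumulate.  Returns the final hits and the per-round hit counts.

    When ``p1_offsets`` (seed id -> P1 offset within the seed) is supplied it
    is extended in place: a query derived from a hit inherits the P1 offset
    of the query that produced the hit, which is exact because matching is
    substitution-only (positions map one-to-one).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    queries = dict(seed_rcls)
    known_seqs = {s.upper() for s in queries.values()}
    hits: list[tuple[ProteinRecord, RCLMatch]] = []
    counts: list[int] = []
    prev_ids: set[str] | None = None
    for rnd in range(1, max_rounds + 1):
        hits = scan_proteome(proteins, queries, params)
        counts.append(len(hits))
        ids = {p.protein_id for p, _ in hits}
        if prev_ids is not None and ids == prev_ids:
            break
        prev_ids = ids
        for p, m in hits:
            rcl = p.sequence.upper()[m.start : m.end]
            if rcl not in known_seqs:
                known_seqs.add(rcl)
                new_id = f"round{rnd}_{p.protein_id}"
                queries[new_id] = rcl
                if p1_offsets is not None and m.query_rcl_id in p1_offsets:
                    p1_offsets[new_id] = p1_offsets[m.query_rcl_id]
    return hits, counts


def read_rcl_seeds(path: str | Path) -> tuple[dict[str, str], dict[str, int | None]]:
    """Read seed RCL peptides from FASTA.

    A ``p1_offset=<int>`` token in the description records the 0-based offset
    of the P1 residue within the seed (scissile bond follows it); absent
    tokens yield ``None``.
    """
    seqs: dict[str, str] = {}
    p1: dict[str, int | None] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        off = None
        for token in rec.description.split():
            if token.startswith("p1_offset="):
                off = int(token.split("=", 1)[1])
        p1[rec.id] = off
    return seqs, p1


def write_hits_tsv(hits: list[tuple[ProteinRecord, RCLMatch]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tquery_id\tstart\tend\tmismatches\n")
        for _, m in hits:
            fh.write(
                f"{m.protein_id}\t{m.query_rcl_id}\t{m.start}\t{m.end}\t"
                f"{m.mismatch_count}\n"
            )
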