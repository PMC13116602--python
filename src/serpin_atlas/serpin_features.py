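"""Protein-level features of candidate serpins.

Hinge motif location, N-glycosylation sequons, average molecular weight,
Henderson-Hasselbalch isoelectric point, and ingestion of externally
computed signal-peptide calls.  Signal-peptide prediction itself is never
re-implemented; absent calls degrade to "unknown".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd
from Bio.Data.IUPACData import protein_weights

from .rcl_scanner import RCLMatch
from .sequence_io import GeneModel, ProteinRecord, select_representative_transcript

__all__ = [
    "SerpinLocus",
    "HingeHit",
    "HINGE_MOTIF",
    "find_sequons",
    "find_hinge",
    "molecular_weight",
    "isoelectric_point",
    "EMBOSS_PKA",
    "attach_signal_peptides",
    "read_signalp_calls",
    "annotate_locus",
    "atlas_table",
    "feature_summary",
    "assign_serpin_names",
]

#: conserved serpin scaffold signature near the N-terminus
HINGE_MOTIF = "NAVYFKG"

_WATER = 18.0153
_SERPIN_NAME_RE = re.compile(r"S\d+c(\d+|j\d+)")


@dataclass
class SerpinLocus:
    """One row of the serpin atlas: gene + protein + derived features."""

    serpin_name: str
    gene: GeneModel
    protein: ProteinRecord
    rcl_match: RCLMatch | None = None
    hinge_position: int | None = None
    sequon_positions: list[int] = field(default_factory=list)
    molecular_weight: float = 0.0
    isoelectric_point: float = 0.0
    has_signal_peptide: bool | None = None  # None == unknown
    exon_count: int = 1

    def __post_init__(self) -> None:
        if not _SERPIN_NAME_RE.fullmatch(self.serpin_name):
            raise ValueError(f"invalid serpin name {self.serpin_name!r}")

    @property
    def chromosome(self) -> str:
        return self.gene.chromosome

    @property
    def strand(self) -> str:
        return self.gene.strand

    @property
    def span_start(self) -> int:
        return self.gene.span_start

    @property
    def span_end(self) -> int:
        return self.gene.span_end


class HingeHit(NamedTuple):
    offset: int
    mismatches: int


def find_sequons(seq: str) -> list[int]:
    """All N-glycosylation sequon offsets: N-X-S/T with X != P.

    Overlapping occurrences are all reported.
    """
    seq = seq.upper()
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


def find_hinge(
    seq: str, motif: str = HINGE_MOTIF, max_mismatches: int = 1
) -> HingeHit | None:
    """Earliest window in the N-terminal half within the mismatch budget.

    The default budget of 1 reconciles the canonical NAVYFKG signature with
    the NAIYFKG variant common in tick serpins.
    """
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    motif = motif.upper()
    half = len(seq) // 2
    for start in range(0, half - len(motif) + 1):
        mm = sum(
            1 for a, b in zip(seq[start : start + len(motif)], motif) if a != b
        )
        if mm <= max_mismatches:
            return HingeHit(start, mm)
    return None


_MEAN_RESIDUE = sum(protein_weights.values()) / len(protein_weights)


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water.

    ``X`` contributes the mean of the twenty standard residue masses; any
    other non-standard character raises ``ValueError``.
    """
    seq = seq.upper()
    total = _WATER
    for aa in seq:
        if aa == "X":
            total += _MEAN_RESIDUE - _WATER
        elif aa in protein_weights:
            total += protein_weights[aa] - _WATER
        else:
            raise ValueError(f"unknown residue {aa!r}")
    return total


#: EMBOSS pKa values (iep); overridable via the ``pka`` argument
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


def _net_charge(seq: str, ph: float, pka: Mapping[str, float]) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        charge -= seq.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    seq: str, pka: Mapping[str, float] = EMBOSS_PKA, tol: float = 0.01
) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Bisection on (0, 14); the net charge is strictly decreasing in pH so the
    root is unique.  ``tol`` bounds the residual charge at the returned pH.
    """
    seq = seq.upper()
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if _net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    ph = (lo + hi) / 2.0
    assert abs(_net_charge(seq, ph, pka)) < max(tol, 1e-3) or math.isclose(
        ph, 14.0
    ) or math.isclose(ph, 0.0)
    return ph


def read_signalp_calls(path: str | Path) -> dict[str, bool]:
    """Two-column TSV of protein_id -> signal-peptide flag.

    Accepts true/false, 1/0, yes/no, or SignalP's SP/OTHER labels.
    Duplicate conflicting rows raise ``ValueError``.
    """
    truthy = {"true", "1", "yes", "sp", "sp(sec/spi)"}
    falsy = {"false", "0", "no", "other", "none"}
    calls: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("protein_id"):
                continue
            pid, raw = line.split("\t")[:2]
            token = raw.strip().lower()
            if token in truthy:
                flag = True
            elif token in falsy:
                flag = False
            else:
                raise ValueError(f"unrecognized signal-peptide call {raw!r} for {pid}")
            if pid in calls and calls[pid] != flag:
                raise ValueError(f"conflicting signal-peptide calls for {pid}")
            calls[pid] = flag
    return calls


def attach_signal_peptides(
    loci: list[SerpinLocus], calls: Mapping[str, bool]
) -> list[SerpinLocus]:
    """Attach external signal-peptide flags; missing ids stay unknown."""
    if isinstance(calls, dict):
        pass
    else:
        items = list(calls.items()) if hasattr(calls, "items") else list(calls)
        merged: dict[str, bool] = {}
        for pid, flag in items:
            if pid in merged and merged[pid] != flag:
                raise ValueError(f"conflicting signal-peptide calls for {pid}")
            merged[pid] = flag
        calls = merged
    for locus in loci:
        locus.has_signal_peptide = calls.get(locus.protein.protein_id, None)
    return loci


def assign_serpin_names(chromosome_labels: list[str]) -> list[str]:
    """Sequential S<number>c<chromosome> names along the genome.

    The caller supplies chromosome labels in genome order (chromosome, then
    start coordinate); numbering follows that order.
    """
    return [f"S{i + 1}c{label}" for i, label in enumerate(chromosome_labels)]


def annotate_locus(
    serpin_name: str,
    gene: GeneModel,
    protein: ProteinRecord,
    rcl_match: RCLMatch | None,
) -> SerpinLocus:
    """Compute all sequence-derived features for one candidate locus."""
    hinge = find_hinge(protein.sequence)
    t = select_representative_transcript(gene)
    return SerpinLocus(
        serpin_name=serpin_name,
        gene=gene,
        protein=protein,
        rcl_match=rcl_match,
        hinge_position=hinge.offset if hinge else None,
        sequon_positions=find_sequons(protein.sequence),
        molecular_weight=molecular_weight(protein.sequence),
        isoelectric_point=isoelectric_point(protein.sequence),
        exon_count=len(t.exons),
    )


def atlas_table(loci: list[SerpinLocus]) -> pd.DataFrame:
    """One row per locus; the TSV-ready serpin atlas."""
    rows = []
    for l in loci:
        rows.append(
            {
                "serpin_name": l.serpin_name,
                "chromosome": l.chromosome,
                "strand": l.strand,
                "start": l.span_start,
                "end": l.span_end,
                "protein_id": l.protein.protein_id,
                "length_aa": len(l.protein.sequence),
                "exon_count": l.exon_count,
                "rcl_query": l.rcl_match.query_rcl_id if l.rcl_match else None,
                "rcl_start": l.rcl_match.start if l.rcl_match else None,
                "rcl_end": l.rcl_match.end if l.rcl_match else None,
                "rcl_mismatches": l.rcl_match.mismatch_count if l.rcl_match else None,
                "hinge_position": l.hinge_position,
                "n_sequons": len(l.sequon_positions),
                "molecular_weight_da": round(l.molecular_weight, 2),
                "isoelectric_point": round(l.isoelectric_point, 2),
                "signal_peptide": {True: "yes", False: "no", None: "unknown"}[
                    l.has_signal_peptide
                ],
            }
        )
    return pd.DataFrame(rows)


def feature_summary(loci: list[SerpinLocus]) -> dict:
    """Recomputed (never cached) per-atlas ranges and shares."""
    lengths = [len(l.protein.sequence) for l in loci]
    mws = [l.molecular_weight for l in loci]
    pis = [l.isoelectric_point for l in loci]
    known = [l for l in loci if l.has_signal_peptide is not None]
    with_sp = [l for l in known if l.has_signal_peptide]
    multi_exon = [l for l in loci if l.exon_count > 1]
    return {
        "n_loci": len(loci),
        "length_range_aa": (min(lengths), max(lengths)) if lengths else None,
        "mw_range_kda": (min(mws) / 1000, max(mws) / 1000) if mws else None,
        "pi_range": (min(pis), max(pis)) if pis else None,
        "pi_median": float(pd.Series(pis).median()) if pis else None,
        "n_with_sequon": sum(1 for l in loci if l.sequon_positions),
        "n_signal_peptide": len(with_sp),
        "n_signal_peptide_unknown": len(loci) - len(known),
        "pct_signal_peptide": (100.0 * len(with_sp) / len(loci)) if loci else None,
        "n_multi_exon": len(multi_exon),
        "pct_multi_exon_of_all": (
            100.0 * len(multi_exon) / len(loci) if loci else None
        ),
    }
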