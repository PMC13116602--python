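"""Schechter-Berger RCL numbering and P1-based protease-class prediction.

The scissile bond sits between P1 and P1'; Pk counts upstream (toward the
hinge, P15-P9) and Pk' downstream.  The P1 residue predicts the target
protease family: basic P1 (R/K) marks trypsin-like targets (coagulation
factors, kallikrein, trypsin-like complement proteases); hydrophobic or
aromatic P1 marks chymotrypsin-like enzymes (cathepsin G, chymase); small
neutral P1 marks elastase-like enzymes.  Val/Ile P1 with a small P1' is
flagged "dual" (chymotrypsin-like/elastase-like preference).  All
predictions are screening-level: exosites, cofactors and extended RCL
context can shift real specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .rcl_scanner import RCLMatch

logger = logging.getLogger(__name__)

__all__ = [
    "RCLAnnotation",
    "number_rcl",
    "classify_by_p1",
    "annotate_confirmed_targets",
    "load_p1_catalog",
    "load_confirmed_targets",
    "PATHWAY_NOTES",
]

_BASIC = set("RK")
_HYDROPHOBIC_AROMATIC = set("FYWLIVM")
_SMALL = set("ASG")
_SMALL_PRIME = set("ASGT")

PATHWAY_NOTES = {
    "coagulation_complement": (
        "trypsin-like targets: thrombin, factor Xa/XIa, kallikrein, "
        "C1r/C1s/MASP-type complement proteases"
    ),
    "inflammation_control": (
        "chymotrypsin-like targets: cathepsin G, mast-cell chymase, chymotrypsin"
    ),
    "tissue_protection": "elastase-like targets: neutrophil elastase, proteinase 3",
    "dual": (
        "chymotrypsin-like/elastase-like preference (hydrophobic P1 with small P1')"
    ),
    "unknown": "non-canonical P1; no screening-level call",
}

# keyword -> class, used to grade concordance of experimental evidence
_TARGET_KEYWORDS = {
    "thrombin": "coagulation_complement",
    "factor": "coagulation_complement",
    "fxa": "coagulation_complement",
    "fxia": "coagulation_complement",
    "fixa": "coagulation_complement",
    "kallikrein": "coagulation_complement",
    "trypsin": "coagulation_complement",
    "plasmin": "coagulation_complement",
    "complement": "coagulation_complement",
    "c1s": "coagulation_complement",
    "c2": "coagulation_complement",
    "chymotrypsin": "inflammation_control",
    "chymase": "inflammation_control",
    "cathepsin": "inflammation_control",
    "elastase": "tissue_protection",
    "proteinase 3": "tissue_protection",
}


@dataclass
class RCLAnnotation:
    """Numbered RCL residues plus the P1-rule class for one serpin."""

    positions: dict[str, str | None] = field(default_factory=dict)  # "P15".."P4'"
    p1: str | None = None
    p1_prime: str | None = None
    predicted_class: str = "unknown"
    pathway_note: str = ""
    confirmed_targets: str | None = None
    concordant: bool | None = None


def number_rcl(
    rcl_match: RCLMatch, protein_sequence: str, scissile_offset: int
) -> RCLAnnotation:
    """Number residues P15..P1 and P1'..P4' around the scissile bond.

    ``scissile_offset`` is the 0-based offset of the P1 residue within the
    matched RCL (the bond follows it).  Positions outside the protein are
    marked absent (None).
    """
    if not (0 <= scissile_offset < rcl_match.length):
        raise ValueError(
            f"scissile offset {scissile_offset} outside match of length {rcl_match.length}"
        )
    seq = protein_sequence.upper()
    p1_abs = rcl_match.start + scissile_offset
    positions: dict[str, str | None] = {}
    for k in range(15, 0, -1):
        idx = p1_abs - (k - 1)
        positions[f"P{k}"] = seq[idx] if 0 <= idx < len(seq) else None
    for k in range(1, 5):
        idx = p1_abs + k
        positions[f"P{k}'"] = seq[idx] if idx < len(seq) else None
    p1 = positions["P1"]
    p1p = positions["P1'"]
    cls = classify_by_p1(p1, p1p)
    return RCLAnnotation(
        positions=positions,
        p1=p1,
        p1_prime=p1p,
        predicted_class=cls,
        pathway_note="screening-level prediction; " + PATHWAY_NOTES[cls],
    )


def classify_by_p1(p1: str | None, p1_prime: str | None = None) -> str:
    """Total rule table mapping (P1, P1') to a predicted protease class.

    The dual rule strictly precedes the hydrophobic rule: Val/Ile with a
    small P1' is "dual", never "inflammation_control".
    """
    if p1 is None:
        return "unknown"
    p1 = p1.upper()
    p1p = p1_prime.upper() if p1_prime else None
    if p1 in {"V", "I"} and p1p in _SMALL_PRIME:
        return "dual"
    if p1 in _BASIC:
        return "coagulation_complement"
    if p1 in _HYDROPHOBIC_AROMATIC:
        return "inflammation_control"
    if p1 in _SMALL:
        return "tissue_protection"
    return "unknown"


def _evidence_classes(confirmed: str) -> set[str]:
    text = confirmed.lower()
    return {cls for kw, cls in _TARGET_KEYWORDS.items() if kw in text}


def annotate_confirmed_targets(
    annotations: dict[str, RCLAnnotation], evidence: pd.DataFrame
) -> dict[str, RCLAnnotation]:
    """Attach experimentally confirmed targets and a concordance flag.

    ``evidence`` columns: serpin_name, confirmed_targets[, citation].
    Predictions are never overwritten; evidence rows naming unknown serpins
    are skipped with a warning.
    """
    for _, row in evidence.iterrows():
        name = row["serpin_name"]
        ann = annotations.get(name)
        if ann is None:
            logger.warning("evidence for unknown serpin %s skipped", name)
            continue
        ann.confirmed_targets = row["confirmed_targets"]
        classes = _evidence_classes(row["confirmed_targets"])
        effective = {"coagulation_complement"} if ann.predicted_class == "coagulation_complement" else (
            {"inflammation_control", "tissue_protection"}
            if ann.predicted_class == "dual"
            else {ann.predicted_class}
        )
        ann.concordant = bool(classes & effective) if classes else None
    return annotations


def load_p1_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """The published chromosome-resolved P1/P1' catalog (printed table).

    Columns: serpin_name, p1, p1_prime (empty when unreported), reported_class.
    """
    if path is None:
        ref = resources.files("serpin_atlas").joinpath("data/ixodes_p1_catalog.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def load_confirmed_targets(path: str | Path | None = None) -> pd.DataFrame:
    """Published experimentally confirmed targets for a subset of serpins."""
    if path is None:
        ref = resources.files("serpin_atlas").joinpath(
            "data/ixodes_confirmed_targets.tsv"
        )
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", dtype=str).fillna("")
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
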