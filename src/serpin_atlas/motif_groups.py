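"""Motif occurrence matrix and importance-weighted two-step grouping.

Motif hits come either from an external MEME/FIMO run (parsed, never
re-implemented) or from the internal consensus scanner, which reuses the
constrained fuzzy matcher over full-length sequences.  Sequences are then
grouped by a two-step procedure: provisional Ward clustering of the
standardized binary occurrence matrix, a random-forest fit on the
provisional labels to obtain per-motif importances, column re-weighting by
normalized importance, and a final Ward clustering.  The number of groups
is chosen by silhouette over a k range at both steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .rcl_scanner import hamming_with_run_constraint, mismatch_budget

__all__ = [
    "MotifHit",
    "MotifInfo",
    "OccurrenceMatrix",
    "GroupAssignment",
    "entropy_windows",
    "column_entropies",
    "build_occurrence_matrix",
    "two_step_cluster",
    "internal_motif_scan",
    "parse_external_hits",
    "parse_fimo_tsv",
    "parse_meme_text",
    "plot_occurrence_heatmap",
]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    start: int  # 0-based half-open within the protein
    end: int
    score: float | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("motif hit must satisfy start < end")


@dataclass(frozen=True)
class MotifInfo:
    motif_id: str
    width: int
    consensus: str | None = None
    e_value: float | None = None


@dataclass
class OccurrenceMatrix:
    """Binary sequence-by-motif matrix with optional column weights."""

    table: pd.DataFrame  # rows: sequence ids; columns: motif ids; cells 0/1
    weights: pd.Series | None = None

    @property
    def sequence_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class GroupAssignment:
    provisional: dict[str, int]
    final: dict[str, int]
    k_provisional: int
    k_final: int
    importances: pd.Series | None = None

    @property
    def n_groups(self) -> int:
        return len(set(self.final.values()))


# ---------------------------------------------------------------------------
# entropy windows
# ---------------------------------------------------------------------------


def column_entropies(msa: Sequence[str]) -> list[float]:
    """Shannon entropy (bits) per alignment column; gap is a 21st symbol."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows differ in length")
    out = []
    n = len(msa)
    for j in range(width):
        counts: dict[str, int] = {}
        for row in msa:
            c = row[j].upper()
            counts[c] = counts.get(c, 0) + 1
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        out.append(h)
    return out


def entropy_windows(
    msa: Sequence[str], window: int, top_k: int
) -> list[tuple[int, int, float]]:
    """Top non-overlapping high-entropy windows of an alignment.

    Returns (start, end, mean entropy) with 0-based half-open column spans,
    picked greedily by mean entropy with ties to the leftmost window.
    """
    entropies = column_entropies(msa)
    if window > len(entropies) or window < 1:
        raise ValueError("window must be within alignment length")
    means = [
        (sum(entropies[i : i + window]) / window, i)
        for i in range(len(entropies) - window + 1)
    ]
    means.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[tuple[int, int, float]] = []
    for mean, start in means:
        if len(chosen) >= top_k:
            break
        if all(start + window <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, start + window, mean))
    chosen.sort(key=lambda t: t[0])
    return chosen


# ---------------------------------------------------------------------------
# occurrence matrix
# ---------------------------------------------------------------------------


def build_occurrence_matrix(
    hits: Iterable[MotifHit],
    sequence_ids: Sequence[str],
    q_threshold: float | None = 0.05,
) -> OccurrenceMatrix:
    """Cell = 1 iff the sequence has at least one hit passing the threshold.

    All sequences are rows even when all-zero; duplicate hits are idempotent;
    a hit naming an unknown sequence is an error.  Hits without a q-value
    always pass.
    """
    known = set(sequence_ids)
    passing: dict[tuple[str, str], int] = {}
    motif_ids: set[str] = set()
    for h in hits:
        if h.sequence_id not in known:
            raise ValueError(f"hit references unknown sequence {h.sequence_id!r}")
        motif_ids.add(h.motif_id)
        if h.q_value is None or q_threshold is None or h.q_value <= q_threshold:
            passing[(h.sequence_id, h.motif_id)] = 1
    cols = sorted(motif_ids)
    data = np.zeros((len(sequence_ids), len(cols)), dtype=int)
    col_index = {m: j for j, m in enumerate(cols)}
    row_index = {s: i for i, s in enumerate(sequence_ids)}
    for (sid, mid) in passing:
        data[row_index[sid], col_index[mid]] = 1
    return OccurrenceMatrix(
        table=pd.DataFrame(data, index=list(sequence_ids), columns=cols)
    )


# ---------------------------------------------------------------------------
# two-step clustering
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return (x - mean) / std


def _ward_with_silhouette(
    x: np.ndarray, k_range: Sequence[int]
) -> tuple[np.ndarray, int]:
    n = x.shape[0]
    candidates = [k for k in k_range if 2 <= k <= n - 1]
    if not candidates:
        raise ValueError(f"k_range {list(k_range)} unusable for {n} sequences")
    best = None
    for k in candidates:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if best is None or score > best[0]:
            best = (score, k, labels)
    assert best is not None
    return best[2], best[1]


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel groups by order of first appearance (stable across runs)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def two_step_cluster(
    matrix: OccurrenceMatrix,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
) -> GroupAssignment:
    """Provisional Ward groups -> forest importances -> weighted final groups."""
    if matrix.table.shape[0] < 2 or matrix.table.shape[1] < 1:
        raise ValueError("need at least 2 sequences and 1 motif column")
    x = _standardize(matrix.table.to_numpy(dtype=float))
    prov_labels, k_prov = _ward_with_silhouette(x, k_range)
    prov_labels = _canonical(prov_labels)

    forest = RandomForestClassifier(n_estimators=200, random_state=seed)
    forest.fit(x, prov_labels)
    imp = forest.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))

    weighted = x * imp
    final_labels, k_final = _ward_with_silhouette(weighted, k_range)
    final_labels = _canonical(final_labels)

    ids = matrix.sequence_ids
    matrix.weights = pd.Series(imp, index=matrix.motif_ids)
    return GroupAssignment(
        provisional=dict(zip(ids, map(int, prov_labels))),
        final=dict(zip(ids, map(int, final_labels))),
        k_provisional=k_prov,
        k_final=k_final,
        importances=matrix.weights,
    )


# ---------------------------------------------------------------------------
# internal consensus scanner (fallback when no MEME/FIMO run is available)
# ---------------------------------------------------------------------------


def internal_motif_scan(
    sequences: Mapping[str, str],
    motifs: Mapping[str, str],
    max_mismatch_fraction: float = 0.2,
) -> list[MotifHit]:
    """All qualifying fuzzy occurrences of ungapped consensus motifs.

    Reuses the constrained matcher (mismatch budget floor(fraction x width),
    no two adjacent mismatches) over the full sequence, not just the
    C-terminal window; every admissible offset is reported.
    """
    hits: list[MotifHit] = []
    for sid in sequences:
        seq = sequences[sid].upper()
        for mid in sorted(motifs):
            motif = motifs[mid].upper()
            w = len(motif)
            if w == 0 or w > len(seq):
                continue
            budget = mismatch_budget(w, max_mismatch_fraction)
            for start in range(len(seq) - w + 1):
                count, ok = hamming_with_run_constraint(
                    seq[start : start + w], motif, budget
                )
                if ok:
                    hits.append(
                        MotifHit(
                            motif_id=mid,
                            sequence_id=sid,
                            start=start,
                            end=start + w,
                            score=float(w - count),
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# external interfaces: FIMO TSV and MEME text
# ---------------------------------------------------------------------------


def parse_fimo_tsv(path: str | Path) -> list[MotifHit]:
    """FIMO --text TSV: motif_id, motif_alt_id, sequence_name, start, stop, ...

    FIMO coordinates are 1-based inclusive; converted to 0-based half-open.
    """
    hits: list[MotifHit] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"motif_id", "sequence_name", "start", "stop"}
                if not required.issubset(header):
                    raise ValueError(
                        f"{path}: line {lineno}: not a FIMO TSV header: {line!r}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                hits.append(
                    MotifHit(
                        motif_id=row["motif_id"],
                        sequence_id=row["sequence_name"],
                        start=int(row["start"]) - 1,
                        end=int(row["stop"]),
                        score=float(row["score"]) if row.get("score") else None,
                        q_value=float(row["q-value"]) if row.get("q-value") else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed FIMO row: {line!r}") from exc
    if header is None:
        raise ValueError(f"{path}: empty or truncated FIMO file")
    return hits


_MEME_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def parse_meme_text(path: str | Path) -> list[MotifInfo]:
    """Minimal MEME text-format parser: motif ids, widths, consensus.

    Consensus is taken from the letter-probability matrix (per-column argmax)
    when present.
    """
    motifs: list[MotifInfo] = []
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("MEME version"):
        first = lines[0] if lines else "<empty file>"
        raise ValueError(f"{path}: not MEME text format, first line: {first!r}")
    alphabet = _MEME_ALPHABET
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            width = None
            e_value = None
            consensus = None
            j = i + 1
            while j < len(lines) and not lines[j].startswith("MOTIF"):
                if lines[j].startswith("letter-probability matrix"):
                    tokens = lines[j].replace("=", " = ").split()
                    for a, b in zip(tokens, tokens[2:]):
                        if a == "w":
                            width = int(b)
                        if a == "E":
                            e_value = float(b)
                    rows = []
                    k = j + 1
                    while k < len(lines) and lines[k].strip() and not lines[k].startswith(
                        ("MOTIF", "URL", "---")
                    ):
                        rows.append([float(t) for t in lines[k].split()])
                        k += 1
                    if width is None:
                        width = len(rows)
                    if rows:
                        consensus = "".join(
                            alphabet[int(np.argmax(r))] for r in rows
                        )
                    j = k
                    continue
                j += 1
            if width is None:
                raise ValueError(
                    f"{path}: motif {motif_id}: missing letter-probability matrix"
                )
            motifs.append(
                MotifInfo(motif_id=motif_id, width=width, consensus=consensus, e_value=e_value)
            )
            i = j
            continue
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no motifs found in MEME text")
    return motifs


def parse_external_hits(path: str | Path):
    """Sniff and parse a MEME text file or a FIMO TSV.

    Returns ``("meme", list[MotifInfo])`` or ``("fimo", list[MotifHit])``.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("MEME version"):
        return "meme", parse_meme_text(path)
    if "motif_id" in first and "sequence_name" in first:
        return "fimo", parse_fimo_tsv(path)
    raise ValueError(f"{path}: unrecognized motif file, first line: {first!r}")


def plot_occurrence_heatmap(
    matrix: OccurrenceMatrix, groups: GroupAssignment | None, path: str | Path
) -> None:
    """Presence/absence heatmap, rows ordered by final group when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = matrix.table
    if groups is not None:
        order = sorted(table.index, key=lambda s: (groups.final[s], s))
        table = table.loc[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.15 * table.shape[1]), max(3, 0.12 * table.shape[0]))
    )
    ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("motif")
    ax.set_ylabel("sequence")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
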