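"""Genome FASTA / GFF3 / GTF input-output and CDS translation.

All genomic coordinates are 1-based inclusive (GFF3 convention) throughout
the package; any half-open arithmetic is confined to private helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "GenomeSequences",
    "TranscriptModel",
    "GeneModel",
    "ProteinRecord",
    "read_annotation",
    "select_representative_transcript",
    "translate_cds",
    "translate_representative",
    "write_serpin_gff",
    "write_proteins_fasta",
    "read_proteins_fasta",
    "protein_span_to_genome",
    "chromosome_label",
]


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input (with context)."""


class GenomeSequences:
    """Uppercase nucleotide sequences keyed by sequence id.

    Thin mapping wrapper so that per-sequence lengths and 1-based inclusive
    slicing live in one place.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        if len(self._seqs) != len(sequences):
            raise ValueError("duplicate sequence ids in genome")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequences":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence id in FASTA: {rec.id}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for sid, seq in self._seqs.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, sid: str) -> str:
        return self._seqs[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._seqs.items()}

    def fetch(self, sid: str, start: int, end: int) -> str:
        """Return the subsequence [start, end], 1-based inclusive."""
        if start < 1 or end > len(self._seqs[sid]) or start > end:
            raise ValueError(f"coordinates {start}-{end} out of bounds for {sid}")
        return self._seqs[sid][start - 1 : end]


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered exons plus CDS segments with phase."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    # (start, end, phase) sorted by genomic coordinate
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s, e) in self.exons:
            if s > e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] <= a[1]:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons {a} and {b}"
                )

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def intron_lengths(self) -> list[int]:
        return [b[0] - a[1] - 1 for a, b in zip(self.exons, self.exons[1:])]

    @property
    def span(self) -> tuple[int, int]:
        coords = self.exons or [(s, e) for s, e, _ in self.cds]
        return coords[0][0], coords[-1][1]


@dataclass
class GeneModel:
    """A gene locus: chromosome, strand, and its transcript isoforms."""

    gene_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    span_start: int = 0
    span_end: int = 0
    biotype: str = "protein_coding"
    # child features of non-standard types (e.g. RCL annotations), kept for
    # lossless round-tripping: (type, start, end, attributes)
    extra_features: list[tuple[str, int, int, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.transcripts and not (self.span_start and self.span_end):
            starts = [t.span[0] for t in self.transcripts]
            ends = [t.span[1] for t in self.transcripts]
            self.span_start, self.span_end = min(starts), max(ends)


@dataclass
class ProteinRecord:
    """Amino-acid sequence (20-letter alphabet plus X) with provenance."""

    protein_id: str
    sequence: str
    gene_id: str | None = None
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if "*" in self.sequence:
            raise ValueError(f"protein {self.protein_id}: internal stop character")


# ---------------------------------------------------------------------------
# annotation reading
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _prevalidate_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected 9 tab-separated fields"
                )


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Parse a GFF3 or GTF file into :class:`GeneModel` objects.

    Genes are grouped by gene id with transcripts attached; records with an
    unknown strand character are rejected (logged, not fatal).  A CDS or exon
    whose parent transcript cannot be resolved raises
    :class:`AnnotationError` naming the orphan feature.
    """
    if dialect not in {"gff3", "gtf"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    _prevalidate_lines(path)

    infer = dialect == "gtf"
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=not infer,
            disable_infer_transcripts=not infer,
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many errors
        raise AnnotationError(f"{path}: failed to parse as {dialect}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    transcript_gene: dict[str, str] = {}

    for feat in db.features_of_type("gene"):
        if feat.strand not in {"+", "-"}:
            logger.warning("rejected gene %s: unknown strand %r", feat.id, feat.strand)
            continue
        genes[feat.id] = GeneModel(
            gene_id=feat.id,
            chromosome=feat.seqid,
            strand=feat.strand,
            span_start=feat.start,
            span_end=feat.end,
            biotype=feat.attributes.get("biotype", ["protein_coding"])[0],
        )

    for ttype in _TRANSCRIPT_TYPES:
        for feat in db.features_of_type(ttype):
            parents = list(db.parents(feat, featuretype="gene"))
            if not parents:
                raise AnnotationError(
                    f"{path}: transcript {feat.id} has no parent gene"
                )
            gid = parents[0].id
            if gid not in genes:
                continue  # parent rejected (e.g. unknown strand)
            t = TranscriptModel(transcript_id=feat.id)
            transcripts[feat.id] = t
            transcript_gene[feat.id] = gid
            genes[gid].transcripts.append(t)

    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parent_ids = feat.attributes.get("Parent") or feat.attributes.get(
                "transcript_id", []
            )
            if not parent_ids:
                raise AnnotationError(
                    f"{path}: {ftype} at {feat.seqid}:{feat.start}-{feat.end} "
                    "has no Parent attribute"
                )
            attached = False
            for pid in parent_ids:
                if pid in transcripts:
                    t = transcripts[pid]
                    if ftype == "exon":
                        t.exons.append((feat.start, feat.end))
                    else:
                        phase = int(feat.frame) if feat.frame in {"0", "1", "2"} else 0
                        t.cds.append((feat.start, feat.end, phase))
                    attached = True
                elif pid in genes:
                    # tolerated: feature hangs directly off a gene
                    attached = True
            if not attached:
                raise AnnotationError(
                    f"{path}: orphan {ftype} feature "
                    f"{feat.seqid}:{feat.start}-{feat.end} "
                    f"(parent {','.join(parent_ids)!r} not found)"
                )

    # attach any non-standard child features (lossless round-trip support)
    known = {"gene", "exon", "CDS"} | _TRANSCRIPT_TYPES
    for feat in db.all_features():
        if feat.featuretype in known:
            continue
        for parent in db.parents(feat):
            gid = transcript_gene.get(parent.id, parent.id)
            if gid in genes:
                genes[gid].extra_features.append(
                    (feat.featuretype, feat.start, feat.end, dict(feat.attributes))
                )
                break

    out = []
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
        for t in g.transcripts:
            # normalise ordering after incremental appends
            t.exons = sorted(t.exons)
            t.cds = sorted(t.cds)
            if not t.exons and t.cds:
                t.exons = [(s, e) for s, e, _ in t.cds]
        out.append(g)
    out.sort(key=lambda g: (g.chromosome, g.span_start, g.gene_id))
    return out


def select_representative_transcript(gene: GeneModel) -> TranscriptModel:
    """The longest coding transcript; ties broken by lexicographic id."""
    coding = [t for t in gene.transcripts if t.cds]
    if not coding:
        raise AnnotationError(f"gene {gene.gene_id} has no coding transcript")
    return min(coding, key=lambda t: (-t.coding_length, t.transcript_id))


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


class TranslationError(ValueError):
    pass


def translate_cds(
    genome: GenomeSequences,
    chromosome: str,
    cds: Iterable[tuple[int, int, int]],
    strand: str,
) -> str:
    """Translate a CDS (list of (start, end, phase) 1-based segments).

    Minus-strand segments are reverse-complemented; the phase of the first
    segment in transcription order trims incomplete leading codons.  A single
    trailing stop is removed; an internal stop raises
    :class:`TranslationError` (pseudogene-like model).
    """
    segs = sorted(cds)
    if not segs:
        raise TranslationError("empty CDS")
    nt = "".join(genome.fetch(chromosome, s, e) for s, e, _ in segs)
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
        first_phase = segs[-1][2]
    elif strand == "+":
        first_phase = segs[0][2]
    else:
        raise TranslationError(f"unknown strand {strand!r}")
    nt = nt[first_phase:]
    if len(nt) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(nt)} not divisible by 3 after phase adjustment"
        )
    aa = str(Seq(nt).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise TranslationError("internal stop codon (pseudogene-like model)")
    return aa


def translate_representative(
    genome: GenomeSequences, gene: GeneModel
) -> ProteinRecord:
    """Translate the representative (longest-coding) transcript of a gene."""
    t = select_representative_transcript(gene)
    aa = translate_cds(genome, gene.chromosome, t.cds, gene.strand)
    return ProteinRecord(
        protein_id=t.transcript_id,
        sequence=aa,
        gene_id=gene.gene_id,
        transcript_id=t.transcript_id,
    )


def protein_span_to_genome(
    transcript: TranscriptModel, strand: str, aa_start: int, aa_end: int
) -> list[tuple[int, int]]:
    """Map a 0-based half-open protein span onto genomic interval(s).

    Returns 1-based inclusive genomic intervals, possibly split across CDS
    segments (e.g. an RCL crossing the conserved splice junction).
    """
    segs = sorted(transcript.cds)
    total = sum(e - s + 1 for s, e, _ in segs)
    nt_lo, nt_hi = aa_start * 3, aa_end * 3  # half-open in coding nt space
    if nt_hi > total:
        raise ValueError("protein span outside coding region")
    if strand == "-":
        nt_lo, nt_hi = total - nt_hi, total - nt_lo
    out: list[tuple[int, int]] = []
    offset = 0
    for s, e, _ in segs:
        seg_len = e - s + 1
        lo = max(nt_lo, offset)
        hi = min(nt_hi, offset + seg_len)
        if lo < hi:
            out.append((s + (lo - offset), s + (hi - offset) - 1))
        offset += seg_len
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_serpin_gff(loci, path: str | Path) -> None:
    """Write serpin loci as GFF3: gene/mRNA/exon/CDS plus an RCL sub-feature.

    The output round-trips through :func:`read_annotation` (the RCL feature is
    preserved in ``GeneModel.extra_features``).
    """
    lines = ["##gff-version 3"]
    for locus in loci:
        g = locus.gene
        t = select_representative_transcript(g)
        attrs = f"ID={g.gene_id};Name={locus.serpin_name}"
        lines.append(
            "\t".join(
                [g.chromosome, "serpin_atlas", "gene", str(g.span_start),
                 str(g.span_end), ".", g.strand, ".", attrs]
            )
        )
        mid = t.transcript_id
        lines.append(
            "\t".join(
                [g.chromosome, "serpin_atlas", "mRNA", str(t.span[0]),
                 str(t.span[1]), ".", g.strand, ".",
                 f"ID={mid};Parent={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(t.exons, start=1):
            lines.append(
                "\t".join(
                    [g.chromosome, "serpin_atlas", "exon", str(s), str(e), ".",
                     g.strand, ".", f"ID={mid}.exon{i};Parent={mid}"]
                )
            )
        for i, (s, e, ph) in enumerate(t.cds, start=1):
            lines.append(
                "\t".join(
                    [g.chromosome, "serpin_atlas", "CDS", str(s), str(e), ".",
                     g.strand, str(ph), f"ID={mid}.cds{i};Parent={mid}"]
                )
            )
        if locus.rcl_match is not None:
            for j, (s, e) in enumerate(
                protein_span_to_genome(
                    t, g.strand, locus.rcl_match.start, locus.rcl_match.end
                ),
                start=1,
            ):
                lines.append(
                    "\t".join(
                        [g.chromosome, "serpin_atlas", "RCL", str(s), str(e),
                         ".", g.strand, ".",
                         f"ID={mid}.rcl{j};Parent={mid};"
                         f"query={locus.rcl_match.query_rcl_id};"
                         f"mismatches={locus.rcl_match.mismatch_count}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_proteins_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def read_proteins_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def chromosome_label(seqid: str) -> str:
    """Short chromosome label used in serpin names.

    ``chr10``/``Chr10``/``10`` -> ``"10"``; an unplaced scaffold id falls back
    to ``"j"`` plus its final digit group (e.g. ``JAMZAT010000234.1`` ->
    ``j234``, digits read before the version suffix).
    """
    import re

    m = re.fullmatch(r"(?:[Cc]hr)?0*(\d+)", seqid)
    if m:
        return m.group(1)
    stem = seqid.split(".")[0]
    groups = re.findall(r"\d+", stem)
    if groups:
        return "j" + str(int(groups[-1][-6:]))
    return "j0"
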