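"""Synthetic genomes with planted serpin loci and full ground truth.

The generator reverse-engineers serpin proteins into chromosomes so that
every downstream stage (RCL scan, feature annotation, cluster calling,
pairwise tiers, P1 classes) can be validated against a known truth table
without any external data.  Planted proteins carry the canonical anatomy:
an N-terminal hinge signature, at least one N-glycosylation sequon, a
conserved splice-junction motif (for two-exon loci) and a C-terminal RCL at
a planned mismatch distance from one of the seed peptides.  Decoy genes are
guaranteed to carry no within-budget RCL.  Identical seeds reproduce
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .atlas_clusters import ClusterParams
from .pairwise_homology import AlignmentScoring, global_identity
from .rcl_scanner import ScanParams, scan_protein
from .sequence_io import GeneModel, GenomeSequences, ProteinRecord, TranscriptModel
from .serpin_features import HINGE_MOTIF

__all__ = [
    "LocusPlan",
    "DecoyPlan",
    "AtlasSimConfig",
    "SyntheticTruth",
    "SimulatedAtlas",
    "DEFAULT_RCL_SEEDS",
    "JUNCTION_MOTIF",
    "simulate_atlas",
    "mutate_to_identity",
    "study_scale_config",
    "write_atlas_dir",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: protein-level conserved splice-junction consensus; exon 1 ends after the
#: sixth residue of this motif in two-exon loci
JUNCTION_MOTIF = "TVFLPKFKLETKYSL"

#: hinge variant planted in synthetic serpins (one mismatch from NAVYFKG)
PLANTED_HINGE = "NAIYFKG"

_SEED_BODY = "EEGTVAAAATGVA"  # P15..P3 of every synthetic seed RCL

#: synthetic seed RCL catalog: id -> (sequence, 0-based P1 offset).
#: Seeds share a hinge-proximal body and differ in the P2-P1-P1' tail, so
#: the P1 residue (and hence the predicted protease class) is seed-determined.
DEFAULT_RCL_SEEDS: dict[str, tuple[str, int]] = {
    "rcl_R": (_SEED_BODY + "VRS", 14),
    "rcl_K": (_SEED_BODY + "VKS", 14),
    "rcl_L": (_SEED_BODY + "VLE", 14),
    "rcl_Y": (_SEED_BODY + "VYE", 14),
    "rcl_S": (_SEED_BODY + "VSE", 14),
    "rcl_G": (_SEED_BODY + "VGE", 14),
    "rcl_A": (_SEED_BODY + "VAE", 14),
    "rcl_Vdual": (_SEED_BODY + "TVS", 14),
    "rcl_Idual": (_SEED_BODY + "TIS", 14),
    "rcl_E": (_SEED_BODY + "VEE", 14),
    "rcl_N": (_SEED_BODY + "VNE", 14),
}

# fixed protein-layout offsets (0-based); all comfortably inside the
# 372-455 aa length range
_HINGE_AT = 30
_SEQUON_AT = 45
_JUNCTION_AT = 190  # junction motif start; exon 1 ends after _JUNCTION_AT + 6 aa
_RCL_FROM_CTERM = 26  # RCL start measured back from the C-terminus


@dataclass
class LocusPlan:
    """One planted serpin locus."""

    name: str
    chromosome: str
    strand: str
    gap_before: int  # bp between previous feature end (or position 0) and this gene
    architecture: str = "intronless"  # or "two_exon"
    intron_length: int = 1500
    rcl_seed_id: str = "rcl_R"
    rcl_mismatches: int = 0
    parent: str | None = None  # name of a parent locus for identity-mutant copies
    target_identity: float | None = None
    length_aa: int | None = None
    cluster_id: str | None = None


@dataclass
class DecoyPlan:
    """A non-serpin gene (no within-budget RCL)."""

    name: str
    chromosome: str
    gap_before: int
    length_aa: int = 300


@dataclass
class AtlasSimConfig:
    chromosomes: dict[str, int]  # id -> minimum length (0 = sized from layout)
    features: list  # LocusPlan | DecoyPlan, in per-chromosome layout order
    seed: int = 0
    margin: int = 50_000
    intron_length_range: tuple[int, int] = (498, 7613)
    scan_params: ScanParams = field(default_factory=ScanParams)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)


@dataclass
class SyntheticTruth:
    loci: pd.DataFrame
    clusters: dict[str, list[list[str]]]  # chromosome -> ordered member-name lists
    orientations: dict[str, list[list[str]]]  # parallel to clusters
    strand_counts: tuple[int, int]  # (n_plus, n_minus)
    tier_pairs: list[tuple[str, str, str]]


@dataclass
class SimulatedAtlas:
    genome: GenomeSequences
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    seeds: dict[str, str]
    seed_p1_offsets: dict[str, int]
    truth: SyntheticTruth
    config: AtlasSimConfig


# ---------------------------------------------------------------------------
# protein construction
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n)]


def _plant_rcl(rng: np.random.Generator, seed_seq: str, k: int, params: ScanParams) -> str:
    """Mutate a seed RCL at k hinge-side, non-adjacent positions."""
    budget = int(params.max_mismatch_fraction * len(seed_seq))
    if k > budget:
        raise ValueError(f"planned {k} mismatches exceed budget {budget}")
    candidates = list(range(0, len(_SEED_BODY) - 1, 2))  # even, non-adjacent, body-only
    if k > len(candidates):
        raise ValueError("too many planned mismatches for the seed body")
    positions = sorted(rng.choice(candidates, size=k, replace=False))
    rcl = list(seed_seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != rcl[pos]]
        rcl[pos] = choices[rng.integers(0, len(choices))]
    return "".join(rcl)


def _build_serpin_protein(
    rng: np.random.Generator, plan: LocusPlan, seeds: dict[str, tuple[str, int]]
) -> tuple[str, int]:
    """Return (sequence, rcl_start offset) for one planned locus."""
    if plan.length_aa is not None:
        n = plan.length_aa
    else:
        n = int(np.clip(round(rng.normal(396, 11)), 372, 455))
    seq = _random_protein(rng, n)
    seq[0] = "M"
    seq[_HINGE_AT : _HINGE_AT + len(PLANTED_HINGE)] = list(PLANTED_HINGE)
    seq[_SEQUON_AT : _SEQUON_AT + 3] = list("NGT")
    seq[_JUNCTION_AT : _JUNCTION_AT + len(JUNCTION_MOTIF)] = list(JUNCTION_MOTIF)
    seed_seq, _ = seeds[plan.rcl_seed_id]
    rcl = _plant_rcl(rng, seed_seq, plan.rcl_mismatches, ScanParams())
    rcl_start = n - _RCL_FROM_CTERM
    seq[rcl_start : rcl_start + len(rcl)] = list(rcl)
    return "".join(seq), rcl_start


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    rng: np.random.Generator,
    frozen: frozenset[int] = frozenset(),
    scoring: AlignmentScoring = AlignmentScoring(),
    tolerance: float = 0.5,
) -> str:
    """Substitution-only mutant at a planned global identity to the source.

    The achieved identity (under the package's global aligner and the given
    scoring) is verified to be within ``tolerance`` percentage points of the
    target; substitutions are added or reverted until it is.  Positions in
    ``frozen`` are never touched (e.g. RCL and hinge).
    """
    if not (0 < target_identity <= 100):
        raise ValueError("target identity must be in (0, 100]")
    if target_identity == 100:
        return sequence
    n = len(sequence)
    free = [i for i in range(n) if i not in frozen]
    # floor-biased so the achieved identity sits at or just above the target,
    # keeping planted tier labels (e.g. the >=98% bin) on the intended side
    needed = int((1 - target_identity / 100.0) * n)
    if needed > len(free):
        raise ValueError(
            f"target {target_identity}% needs {needed} substitutions but only "
            f"{len(free)} positions are free"
        )
    order = list(rng.permutation(free))
    mutant = list(sequence)
    applied: list[int] = []

    def _sub(pos: int) -> None:
        choices = [a for a in AMINO_ACIDS if a != sequence[pos]]
        mutant[pos] = choices[rng.integers(0, len(choices))]
        applied.append(pos)

    for pos in order[:needed]:
        _sub(pos)
    cursor = needed
    for _ in range(2 * n):
        ident, _cols = global_identity(sequence, "".join(mutant), scoring)
        if abs(ident - target_identity) <= tolerance:
            return "".join(mutant)
        if ident > target_identity:
            if cursor >= len(order):
                break
            _sub(order[cursor])
            cursor += 1
        else:
            if not applied:
                break
            pos = applied.pop()
            mutant[pos] = sequence[pos]
            if order and order[cursor - 1] == pos:
                cursor -= 1
    raise ValueError(
        f"could not reach target identity {target_identity}% within tolerance"
    )


# ---------------------------------------------------------------------------
# reverse translation and embedding
# ---------------------------------------------------------------------------

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS_FOR[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    parts.append("TAA")
    return "".join(parts)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _gene_blocks(
    rng: np.random.Generator, plan: LocusPlan, cds_nt: str
) -> list[tuple[str, str]]:
    """Transcription-order blocks [(seq, 'exon'|'intron'), ...]."""
    if plan.architecture == "intronless":
        return [(cds_nt, "exon")]
    if plan.architecture != "two_exon":
        raise ValueError(f"unknown architecture {plan.architecture!r}")
    junction_aa = _JUNCTION_AT + 6  # exon 1 ends at the conserved junction
    cut = 3 * junction_aa
    intron_len = plan.intron_length
    if intron_len < 4:
        raise ValueError("intron too short for splice sites")
    intron = "GT" + _random_dna(rng, intron_len - 4) + "AG"
    return [(cds_nt[:cut], "exon"), (intron, "intron"), (cds_nt[cut:], "exon")]


def _place_gene(
    blocks: list[tuple[str, str]], strand: str, start: int
) -> tuple[str, list[tuple[int, int]], int]:
    """Physical sequence plus 1-based exon coordinates for a gene at start."""
    physical_blocks = blocks if strand == "+" else [
        (_revcomp(seq), kind) for seq, kind in reversed(blocks)
    ]
    physical = "".join(seq for seq, _ in physical_blocks)
    exons = []
    pos = start
    for seq, kind in physical_blocks:
        if kind == "exon":
            exons.append((pos, pos + len(seq) - 1))
        pos += len(seq)
    return physical, exons, start + len(physical) - 1


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_atlas(config: AtlasSimConfig) -> SimulatedAtlas:
    """Generate genome + annotation + proteome + truth from a plan."""
    rng = np.random.default_rng(config.seed)
    seeds = {k: v[0] for k, v in DEFAULT_RCL_SEEDS.items()}
    p1_offsets = {k: v[1] for k, v in DEFAULT_RCL_SEEDS.items()}

    # 1. proteins (plan order; parents must precede children)
    locus_plans = [f for f in config.features if isinstance(f, LocusPlan)]
    proteins: dict[str, str] = {}
    rcl_starts: dict[str, int] = {}
    for plan in locus_plans:
        if plan.parent is not None:
            if plan.parent not in proteins:
                raise ValueError(f"{plan.name}: parent {plan.parent} not yet generated")
            src = proteins[plan.parent]
            src_rcl = rcl_starts[plan.parent]
            frozen = set(range(src_rcl, src_rcl + 16))
            frozen |= set(range(_HINGE_AT, _HINGE_AT + len(PLANTED_HINGE)))
            frozen |= set(range(_SEQUON_AT, _SEQUON_AT + 3))
            frozen |= set(range(_JUNCTION_AT, _JUNCTION_AT + len(JUNCTION_MOTIF)))
            frozen.add(0)
            target = plan.target_identity if plan.target_identity is not None else 100.0
            proteins[plan.name] = mutate_to_identity(
                src, target, rng, frozen=frozenset(frozen)
            )
            rcl_starts[plan.name] = src_rcl
        else:
            seq, rcl_start = _build_serpin_protein(rng, plan, DEFAULT_RCL_SEEDS)
            proteins[plan.name] = seq
            rcl_starts[plan.name] = rcl_start

    # 2. verify planted discovery guarantees
    for plan in locus_plans:
        rec = ProteinRecord(protein_id=plan.name, sequence=proteins[plan.name])
        m = scan_protein(rec, seeds, config.scan_params)
        if m is None or m.start != rcl_starts[plan.name]:
            raise RuntimeError(f"planted RCL not recoverable in {plan.name}")

    # 3. decoy proteins: guaranteed free of any within-budget RCL, checked
    # against the seeds and against every planted RCL variant
    decoy_plans = [f for f in config.features if isinstance(f, DecoyPlan)]
    all_queries = dict(seeds)
    for plan in locus_plans:
        s = rcl_starts[plan.name]
        all_queries[f"planted_{plan.name}"] = proteins[plan.name][s : s + 16]
    decoys: dict[str, str] = {}
    for plan in decoy_plans:
        for _attempt in range(50):
            seq = "M" + "".join(_random_protein(rng, plan.length_aa - 1))
            rec = ProteinRecord(protein_id=plan.name, sequence=seq)
            if scan_protein(rec, all_queries, config.scan_params) is None:
                decoys[plan.name] = seq
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate clean decoy {plan.name}")

    # 4. lay features onto chromosomes
    by_chrom: dict[str, list] = {c: [] for c in config.chromosomes}
    for feat in config.features:
        if feat.chromosome not in by_chrom:
            raise ValueError(f"feature {feat.name} on unknown chromosome {feat.chromosome}")
        by_chrom[feat.chromosome].append(feat)

    genes: list[GeneModel] = []
    protein_records: list[ProteinRecord] = []
    chrom_seqs: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    loci_rows: list[dict] = []

    for chrom, feats in by_chrom.items():
        pieces: list[str] = []
        pos = 0  # bp laid so far
        for feat in feats:
            if feat.gap_before < 0:
                raise ValueError(f"{feat.name}: negative gap")
            pieces.append(_random_dna(rng, feat.gap_before))
            pos += feat.gap_before
            start = pos + 1
            if isinstance(feat, LocusPlan):
                cds_nt = _reverse_translate(rng, proteins[feat.name])
                blocks = _gene_blocks(rng, feat, cds_nt)
                physical, exons, end = _place_gene(blocks, feat.strand, start)
                t = TranscriptModel(
                    transcript_id=f"t_{feat.name}",
                    exons=exons,
                    cds=[(s, e, 0) for s, e in exons],
                )
                gene = GeneModel(
                    gene_id=f"g_{feat.name}",
                    chromosome=chrom,
                    strand=feat.strand,
                    transcripts=[t],
                    span_start=start,
                    span_end=end,
                )
                genes.append(gene)
                protein_records.append(
                    ProteinRecord(
                        protein_id=feat.name,
                        sequence=proteins[feat.name],
                        gene_id=gene.gene_id,
                        transcript_id=t.transcript_id,
                    )
                )
                seed_seq, p1_off = DEFAULT_RCL_SEEDS[
                    feat.rcl_seed_id if feat.parent is None else _root_seed(feat, locus_plans)
                ]
                rcl_s = rcl_starts[feat.name]
                p1 = proteins[feat.name][rcl_s + p1_off]
                p1_prime_idx = rcl_s + p1_off + 1
                p1_prime = (
                    proteins[feat.name][p1_prime_idx]
                    if p1_prime_idx < len(proteins[feat.name])
                    else None
                )
                from .rcl_classifier import classify_by_p1

                loci_rows.append(
                    {
                        "name": feat.name,
                        "chromosome": chrom,
                        "strand": feat.strand,
                        "start": start,
                        "end": end,
                        "architecture": feat.architecture,
                        "intron_length": (
                            feat.intron_length if feat.architecture == "two_exon" else 0
                        ),
                        "protein_length": len(proteins[feat.name]),
                        "rcl_seed": (
                            feat.rcl_seed_id
                            if feat.parent is None
                            else _root_seed(feat, locus_plans)
                        ),
                        "rcl_mismatches": (
                            feat.rcl_mismatches if feat.parent is None else None
                        ),
                        "rcl_start": rcl_s,
                        "rcl_end": rcl_s + 16,
                        "p1": p1,
                        "p1_prime": p1_prime,
                        "p1_class": classify_by_p1(p1, p1_prime),
                        "parent": feat.parent,
                        "target_identity": feat.target_identity,
                        "cluster_id": feat.cluster_id,
                    }
                )
            else:
                cds_nt = _reverse_translate(rng, decoys[feat.name])
                physical, exons, end = _place_gene([(cds_nt, "exon")], "+", start)
                t = TranscriptModel(
                    transcript_id=f"t_{feat.name}",
                    exons=exons,
                    cds=[(s, e, 0) for s, e in exons],
                )
                genes.append(
                    GeneModel(
                        gene_id=f"g_{feat.name}",
                        chromosome=chrom,
                        strand="+",
                        transcripts=[t],
                        span_start=start,
                        span_end=end,
                        biotype="decoy",
                    )
                )
            spans[feat.name] = (start, end)
            pieces.append(physical)
            pos = end
        tail = max(config.chromosomes[chrom] - pos, config.margin)
        pieces.append(_random_dna(rng, tail))
        chrom_seqs[chrom] = "".join(pieces)

    genome = GenomeSequences(chrom_seqs)

    # 5. truth tables
    truth = _build_truth(config, locus_plans, loci_rows, spans)

    return SimulatedAtlas(
        genome=genome,
        genes=genes,
        proteins=protein_records,
        seeds=seeds,
        seed_p1_offsets=p1_offsets,
        truth=truth,
        config=config,
    )


def _root_seed(plan: LocusPlan, all_plans: list[LocusPlan]) -> str:
    by_name = {p.name: p for p in all_plans}
    while plan.parent is not None:
        plan = by_name[plan.parent]
    return plan.rcl_seed_id


def _orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == right_strand:
        return "head_to_tail"
    return "head_to_head" if left_strand == "-" else "tail_to_tail"


def _build_truth(
    config: AtlasSimConfig,
    locus_plans: list[LocusPlan],
    loci_rows: list[dict],
    spans: dict[str, tuple[int, int]],
) -> SyntheticTruth:
    loci = pd.DataFrame(loci_rows)
    n_plus = int((loci["strand"] == "+").sum())
    n_minus = len(loci) - n_plus

    clusters: dict[str, list[list[str]]] = {}
    orientations: dict[str, list[list[str]]] = {}
    for chrom in loci["chromosome"].unique():
        sub = loci[loci["chromosome"] == chrom].sort_values("start")
        runs: list[list[str]] = []
        labels: list[str | None] = []
        for _, row in sub.iterrows():
            cid = row["cluster_id"]
            if runs and cid is not None and labels[-1] == cid:
                runs[-1].append(row["name"])
            else:
                runs.append([row["name"]])
                labels.append(cid)
        clusters[chrom] = runs
        strand_of = dict(zip(sub["name"], sub["strand"]))
        orientations[chrom] = [
            [
                _orientation(strand_of[a], strand_of[b])
                for a, b in zip(run, run[1:])
            ]
            for run in runs
        ]

    # geometry sanity: planted partitions must be consistent with the
    # cluster rule the pipeline will apply
    params = config.cluster_params
    for chrom, runs in clusters.items():
        for run in runs:
            for a, b in zip(run, run[1:]):
                gap = spans[b][0] - spans[a][1] - 1
                if gap > params.max_distance:
                    raise ValueError(
                        f"planted within-cluster gap {gap} bp between {a} and {b} "
                        f"exceeds max_distance {params.max_distance}"
                    )
        for left, right in zip(runs, runs[1:]):
            a, b = left[-1], right[0]
            gap = spans[b][0] - spans[a][1] - 1
            if gap <= params.max_distance:
                # distance alone would chain them; the intervening-gene rule
                # must then be the separator — require > max_intervening decoys
                n_between = sum(
                    1
                    for f in config.features
                    if isinstance(f, DecoyPlan)
                    and f.chromosome == chrom
                    and spans[f.name][0] > spans[a][1]
                    and spans[f.name][1] < spans[b][0]
                )
                if n_between <= params.max_intervening_genes:
                    raise ValueError(
                        f"planted clusters ending at {a} and starting at {b} "
                        "would merge under the cluster rule"
                    )

    tier_pairs = []
    for plan in locus_plans:
        if plan.parent is None:
            continue
        target = plan.target_identity if plan.target_identity is not None else 100.0
        if target >= 100:
            tier = "exact_duplicate"
        elif target >= 98:
            tier = "recent_paralog"
        elif target >= 70:
            tier = "diverged_paralog"
        else:
            tier = "non_homologous"
        tier_pairs.append((plan.parent, plan.name, tier))

    return SyntheticTruth(
        loci=loci,
        clusters=clusters,
        orientations=orientations,
        strand_counts=(n_plus, n_minus),
        tier_pairs=tier_pairs,
    )


# ---------------------------------------------------------------------------
# the study-scale configuration
# ---------------------------------------------------------------------------


def study_scale_config(seed: int = 0) -> AtlasSimConfig:
    """The default study-scale simulation: 74 serpin loci on a 15-chromosome
    genome plus one unplaced scaffold.

    Chromosome 10 carries 50 loci in 17 tandem clusters (nine singletons,
    three 2-gene, three 3-gene, one 5-gene and one 21-gene array whose
    intergenic gaps span 679-43,544 bp with mean 11,908 bp); strand totals
    are 46 plus / 28 minus; four exact-duplicate pairs, two recent-paralog
    pairs (98%) and two diverged pairs (85%) are planted; 20 loci are
    two-exon with the conserved junction.
    """
    rng = np.random.default_rng(seed)
    features: list = []
    intron_lo, intron_hi = 498, 7613

    def intron() -> int:
        return int(rng.integers(intron_lo, intron_hi + 1))

    def gap() -> int:
        return int(rng.integers(5_000, 40_000))

    counter = [0]

    def locus(chrom_label: str, chromosome: str, strand: str, gap_before: int,
              seed_id: str, cluster_id: str | None, *, mism: int | None = None,
              two_exon: bool = False, parent: str | None = None,
              identity: float | None = None) -> LocusPlan:
        counter[0] += 1
        name = f"S{counter[0]}c{chrom_label}"
        plan = LocusPlan(
            name=name,
            chromosome=chromosome,
            strand=strand,
            gap_before=gap_before,
            architecture="two_exon" if two_exon else "intronless",
            intron_length=intron() if two_exon else 0,
            rcl_seed_id=seed_id,
            rcl_mismatches=int(rng.integers(0, 4)) if mism is None else mism,
            parent=parent,
            target_identity=identity,
            cluster_id=cluster_id,
        )
        features.append(plan)
        return plan

    decoy_n = [0]

    def decoy(chromosome: str, gap_before: int) -> None:
        decoy_n[0] += 1
        features.append(
            DecoyPlan(
                name=f"decoy{decoy_n[0]}",
                chromosome=chromosome,
                gap_before=gap_before,
            )
        )

    def cluster_break(chromosome: str) -> int:
        """Two decoys inside a >100 kb inter-cluster gap; returns final gap."""
        decoy(chromosome, 50_000)
        decoy(chromosome, 20_000)
        return 50_000

    seed_cycle = ["rcl_R", "rcl_S", "rcl_K", "rcl_G", "rcl_L", "rcl_R",
                  "rcl_Y", "rcl_A", "rcl_E", "rcl_R", "rcl_N", "rcl_K",
                  "rcl_Vdual", "rcl_R", "rcl_Idual", "rcl_G"]
    cyc = [0]

    def next_seed() -> str:
        s = seed_cycle[cyc[0] % len(seed_cycle)]
        cyc[0] += 1
        return s

    # chr1: 4 loci, all two-exon, strands + - + -
    for i, strand in enumerate("+-+-"):
        locus("1", "chr1", strand, 30_000 if i == 0 else 140_000,
              next_seed(), cluster_id=None, two_exon=True)
    # chr2: exact-duplicate pair in one 2-gene cluster
    p = locus("2", "chr2", "+", 40_000, "rcl_N", cluster_id="c2_1", mism=1)
    locus("2", "chr2", "+", gap(), p.rcl_seed_id, cluster_id="c2_1",
          parent=p.name, identity=100.0)
    # chr3: 2 two-exon singletons
    locus("3", "chr3", "+", 35_000, next_seed(), cluster_id=None, two_exon=True)
    locus("3", "chr3", "-", 130_000, next_seed(), cluster_id=None, two_exon=True)
    # chr4: 2 singletons
    locus("4", "chr4", "-", 45_000, next_seed(), cluster_id=None)
    locus("4", "chr4", "+", 125_000, next_seed(), cluster_id=None)
    # chr5: 6 loci = two duplicate pairs (each its own cluster) + 2 singletons
    p = locus("5", "chr5", "+", 30_000, "rcl_S", cluster_id="c5_1", mism=2)
    locus("5", "chr5", "+", gap(), p.rcl_seed_id, cluster_id="c5_1",
          parent=p.name, identity=100.0)
    features.append(DecoyPlan(name="decoy_c5", chromosome="chr5", gap_before=60_000))
    p = locus("5", "chr5", "-", 60_000, "rcl_R", cluster_id="c5_2", mism=1)
    locus("5", "chr5", "-", gap(), p.rcl_seed_id, cluster_id="c5_2",
          parent=p.name, identity=100.0)
    locus("5", "chr5", "+", 150_000, next_seed(), cluster_id=None)
    locus("5", "chr5", "-", 150_000, next_seed(), cluster_id=None)

    # chr10: 50 loci in 17 clusters
    chrom = "chr10"

    def c10(strand: str, cluster_id: str | None, gap_before: int | None = None,
            *, two_exon: bool = False, parent: str | None = None,
            identity: float | None = None, seed_id: str | None = None) -> LocusPlan:
        g = gap() if gap_before is None else gap_before
        return locus("10", chrom, strand, g,
                     seed_id or next_seed(), cluster_id,
                     two_exon=two_exon, parent=parent, identity=identity)

    # C1 (2): t2t pair
    c10("+", "10_1", 40_000)
    c10("-", "10_1")
    c10("-", None, cluster_break(chrom))  # C2 singleton
    # C3 (3): recent-paralog pair inside
    a = c10("+", "10_3", cluster_break(chrom))
    c10("+", "10_3", parent=a.name, identity=98.0)
    c10("+", "10_3")
    c10("-", None, cluster_break(chrom))  # C4 singleton
    # C5 (2): h2h
    c10("-", "10_5", cluster_break(chrom))
    c10("+", "10_5")
    # C6 (3): all minus
    c10("-", "10_6", cluster_break(chrom))
    c10("-", "10_6")
    c10("-", "10_6")
    c10("-", None, cluster_break(chrom), two_exon=True)  # C7 singleton
    # C8 (5): includes the chr10 exact-duplicate pair and an 85% mutant
    a = c10("+", "10_8", cluster_break(chrom), seed_id="rcl_K")
    c10("+", "10_8", parent=a.name, identity=100.0)
    b = c10("+", "10_8", seed_id="rcl_Y")
    c10("+", "10_8", parent=b.name, identity=85.0)
    c10("+", "10_8")
    c10("-", None, cluster_break(chrom))  # C9 singleton
    # C10 (3): mixed orientations
    c10("+", "10_10", cluster_break(chrom))
    c10("-", "10_10")
    c10("+", "10_10")
    c10("-", None, cluster_break(chrom), two_exon=True)  # C11 singleton
    # C12 (2)
    c10("+", "10_12", cluster_break(chrom))
    c10("+", "10_12")
    c10("+", None, cluster_break(chrom))  # C13 singleton
    c10("-", None, cluster_break(chrom), two_exon=True)  # C14 singleton
    # C15: the 21-gene array; fixed gaps give mean 11,908 bp, range 679-43,544
    array_gaps = [679] + [10_774] * 17 + [10_779] + [43_544]
    array_strands = ["+"] * 9 + ["-"] + ["+"] * 5 + ["-"] + ["+"] * 5
    first = c10(array_strands[0], "10_15", cluster_break(chrom), seed_id="rcl_R")
    prev = first
    for i, (g, strand) in enumerate(zip(array_gaps, array_strands[1:]), start=1):
        if i == 1:
            prev = c10(strand, "10_15", g, parent=prev.name, identity=98.0)
        elif i == 2:
            prev = c10(strand, "10_15", g, parent=first.name, identity=85.0)
        elif i in (5, 11, 17):
            prev = c10(strand, "10_15", g, two_exon=True)
        else:
            prev = c10(strand, "10_15", g)
    c10("-", None, cluster_break(chrom))  # C16 singleton
    c10("-", None, cluster_break(chrom))  # C17 singleton

    # chr11: 6 singletons, alternating strands, all two-exon
    for i, strand in enumerate("+-+-+-"):
        locus("11", "chr11", strand, 30_000 if i == 0 else 140_000,
              next_seed(), cluster_id=None, two_exon=True)
    # chr13: 1 two-exon singleton
    locus("13", "chr13", "-", 50_000, "rcl_S", cluster_id=None, two_exon=True)
    # unplaced scaffold: 1 two-exon locus
    locus("j234", "scaffold_234", "-", 20_000, "rcl_N", cluster_id=None,
          two_exon=True)

    chromosomes = {f"chr{i}": 300_000 for i in range(1, 16)}
    chromosomes["scaffold_234"] = 60_000
    return AtlasSimConfig(chromosomes=chromosomes, features=features, seed=seed)


# ---------------------------------------------------------------------------
# planted-partition motif matrices (for the grouping stage)
# ---------------------------------------------------------------------------


def planted_motif_matrix(
    n_groups: int = 6,
    per_group: int = 12,
    signature_motifs: int = 8,
    noise_motifs: int = 10,
    noise_rate: float = 0.1,
    overlap: float = 0.0,
    seed: int = 0,
):
    """Binary occurrence matrix with a planted group structure.

    Each group has its own block of signature motifs (present in all its
    members); ``overlap`` is the probability that a member also carries a
    motif from another group's signature, and ``noise_motifs`` columns are
    uninformative Bernoulli(``noise_rate``) noise.  The defaults emulate the
    density of a real serpin motif catalog (roughly fifty motifs resolving
    six groups, i.e. about eight signature motifs per group).  Returns
    ``(OccurrenceMatrix, truth labels dict)``.
    """
    from .motif_groups import OccurrenceMatrix
    import pandas as pd  # local alias to keep the module import list honest

    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    n_cols = n_groups * signature_motifs + noise_motifs
    data = np.zeros((n, n_cols), dtype=int)
    labels: dict[str, int] = {}
    rows = []
    for g in range(n_groups):
        for i in range(per_group):
            sid = f"seq_g{g}_{i}"
            rows.append(sid)
            labels[sid] = g
            r = len(rows) - 1
            block = slice(g * signature_motifs, (g + 1) * signature_motifs)
            data[r, block] = 1
            for other in range(n_groups * signature_motifs):
                if not (block.start <= other < block.stop) and rng.random() < overlap:
                    data[r, other] = 1
            for j in range(noise_motifs):
                if rng.random() < noise_rate:
                    data[r, n_groups * signature_motifs + j] = 1
    cols = [f"motif_{j}" for j in range(n_cols)]
    matrix = OccurrenceMatrix(table=pd.DataFrame(data, index=rows, columns=cols))
    return matrix, labels


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_atlas_dir(sim: SimulatedAtlas, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, GFF3 annotation, proteome FASTA and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "proteins": outdir / "proteins.fa",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "seeds": outdir / "rcl_seeds.fa",
    }
    sim.genome.to_fasta(paths["genome"])
    lines = ["##gff-version 3"]
    for gene in sim.genes:
        lines.append(
            "\t".join(
                [gene.chromosome, "sim", "gene", str(gene.span_start),
                 str(gene.span_end), ".", gene.strand, ".",
                 f"ID={gene.gene_id};biotype={gene.biotype}"]
            )
        )
        for t in gene.transcripts:
            lines.append(
                "\t".join(
                    [gene.chromosome, "sim", "mRNA", str(t.span[0]),
                     str(t.span[1]), ".", gene.strand, ".",
                     f"ID={t.transcript_id};Parent={gene.gene_id}"]
                )
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                lines.append(
                    "\t".join(
                        [gene.chromosome, "sim", "exon", str(s), str(e), ".",
                         gene.strand, ".",
                         f"ID={t.transcript_id}.e{i};Parent={t.transcript_id}"]
                    )
                )
            for i, (s, e, ph) in enumerate(t.cds, start=1):
                lines.append(
                    "\t".join(
                        [gene.chromosome, "sim", "CDS", str(s), str(e), ".",
                         gene.strand, str(ph),
                         f"ID={t.transcript_id}.c{i};Parent={t.transcript_id}"]
                    )
                )
    paths["annotation"].write_text("\n".join(lines) + "\n")
    with open(paths["proteins"], "w") as fh:
        for p in sim.proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    sim.truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    with open(paths["truth_clusters"], "w") as fh:
        fh.write("chromosome\tcluster_index\tmembers\torientations\n")
        for chrom, runs in sim.truth.clusters.items():
            for i, run in enumerate(runs):
                ori = ",".join(sim.truth.orientations[chrom][i]) or "-"
                fh.write(f"{chrom}\t{i}\t{','.join(run)}\t{ori}\n")
    with open(paths["seeds"], "w") as fh:
        for sid, seq in sim.seeds.items():
            fh.write(f">{sid} p1_offset={sim.seed_p1_offsets[sid]}\n{seq}\n")
    return paths
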