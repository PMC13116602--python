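"""End-to-end atlas construction: annotation -> proteins -> scan -> features.

Thin orchestration over the other modules; everything here is also callable
piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import rcl_classifier, serpin_features
from .rcl_scanner import RCLMatch, ScanParams, iterate_to_fixed_point
from .sequence_io import (
    GeneModel,
    GenomeSequences,
    ProteinRecord,
    TranslationError,
    chromosome_label,
    translate_representative,
)
from .serpin_features import SerpinLocus

__all__ = ["AtlasResult", "build_atlas", "chromosome_sort_key"]


def chromosome_sort_key(chromosome: str) -> tuple:
    """Numbered chromosomes first (numerically), then unplaced scaffolds."""
    label = chromosome_label(chromosome)
    if label.startswith("j"):
        return (1, int(label[1:]) if label[1:].isdigit() else 0, chromosome)
    return (0, int(label), chromosome)


@dataclass
class AtlasResult:
    loci: list[SerpinLocus]
    annotations: dict[str, rcl_classifier.RCLAnnotation]
    hits: list[tuple[ProteinRecord, RCLMatch]]
    round_counts: list[int]
    skipped: list[str] = field(default_factory=list)  # untranslatable genes

    @property
    def table(self) -> pd.DataFrame:
        tab = serpin_features.atlas_table(self.loci)
        classes = {
            name: ann.predicted_class for name, ann in self.annotations.items()
        }
        tab["p1_class"] = tab["serpin_name"].map(classes)
        return tab


def build_atlas(
    genome: GenomeSequences,
    genes: list[GeneModel],
    seed_rcls: dict[str, str],
    seed_p1_offsets: dict[str, int] | None = None,
    params: ScanParams = ScanParams(),
    max_rounds: int = 5,
) -> AtlasResult:
    """Discover, name and annotate serpin loci from a genome + annotation.

    Serpin names are assigned sequentially along the genome (numbered
    chromosomes in numeric order, then unplaced scaffolds), matching the
    S<number>c<chromosome> convention.
    """
    proteins: list[ProteinRecord] = []
    gene_by_protein: dict[str, GeneModel] = {}
    skipped: list[str] = []
    for gene in genes:
        try:
            rec = translate_representative(genome, gene)
        except TranslationError:
            skipped.append(gene.gene_id)
            continue
        proteins.append(rec)
        gene_by_protein[rec.protein_id] = gene

    offsets = dict(seed_p1_offsets) if seed_p1_offsets else {}
    hits, round_counts = iterate_to_fixed_point(
        proteins, seed_rcls, params, max_rounds=max_rounds, p1_offsets=offsets
    )

    ordered = sorted(
        hits,
        key=lambda pm: (
            chromosome_sort_key(gene_by_protein[pm[0].protein_id].chromosome),
            gene_by_protein[pm[0].protein_id].span_start,
        ),
    )
    loci: list[SerpinLocus] = []
    annotations: dict[str, rcl_classifier.RCLAnnotation] = {}
    for i, (protein, match) in enumerate(ordered, start=1):
        gene = gene_by_protein[protein.protein_id]
        name = f"S{i}c{chromosome_label(gene.chromosome)}"
        locus = serpin_features.annotate_locus(name, gene, protein, match)
        loci.append(locus)
        off = offsets.get(match.query_rcl_id)
        if off is not None and off < match.length:
            annotations[name] = rcl_classifier.number_rcl(
                match, protein.sequence, off
            )
        else:
            annotations[name] = rcl_classifier.RCLAnnotation(
                predicted_class="unknown",
                pathway_note="no P1 offset available for the matched query",
            )
    return AtlasResult(
        loci=loci,
        annotations=annotations,
        hits=hits,
        round_counts=round_counts,
        skipped=skipped,
    )
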