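"""Tandem-cluster calling, pair orientations, and distribution statistics.

A cluster is a maximal run of serpin loci on one chromosome in which every
neighbouring pair is within a boundary-to-boundary distance threshold
(default 100 kb) and separated by at most a threshold number of intervening
annotated genes (default 10).  Distances use gene spans (outermost
transcript bounds), not CDS.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterParams",
    "Cluster",
    "DensityTest",
    "SpacingStats",
    "call_clusters",
    "sensitivity_sweep",
    "classify_pair_orientation",
    "strand_bias_test",
    "chrom_density_test",
    "cluster_spacing_stats",
    "chromosome_counts",
    "chromosome_share",
]


@dataclass(frozen=True)
class ClusterParams:
    max_distance: int = 100_000
    max_intervening_genes: int = 10

    def __post_init__(self) -> None:
        if self.max_distance <= 0 or self.max_intervening_genes <= 0:
            raise ValueError("cluster thresholds must be positive")


@dataclass
class Cluster:
    """An ordered run of serpin loci on one chromosome.

    Singletons are legitimate clusters with zero adjacent pairs.
    """

    chromosome: str
    members: list = field(default_factory=list)  # SerpinLocus-like, sorted
    pair_orientations: list[str] = field(default_factory=list)
    intergenic_distances: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.members[-1].span_end - self.members[0].span_start + 1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DensityTest:
    observed: dict[str, int]
    lengths: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float


@dataclass
class SpacingStats:
    mean: float | None
    min: int | None
    max: int | None
    span: int


def classify_pair_orientation(left, right) -> str:
    """Orientation label for an adjacent gene pair (left.start <= right.start).

    Same strand -> head_to_tail.  Opposite strands: (-,+) has the two 5'
    ends facing inward -> head_to_head; (+,-) has the 3' ends facing ->
    tail_to_tail.  (Some atlases label the 5'-facing case "convergent";
    here the geometric definition above is authoritative.)
    """
    if left.chromosome != right.chromosome:
        raise ValueError("pair spans two chromosomes")
    if left.span_start > right.span_start:
        raise ValueError("left locus must not start after right locus")
    if left.strand == right.strand:
        return "head_to_tail"
    if left.strand == "-" and right.strand == "+":
        return "head_to_head"
    return "tail_to_tail"


class _GeneIndex:
    """Per-chromosome sorted gene intervals for intervening-gene counts."""

    def __init__(self, genes: Iterable):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append((g.span_start, g.span_end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            self._starts[chrom] = [s for s, _ in spans]
            self._ends[chrom] = [e for _, e in spans]

    def count_strictly_between(self, chrom: str, lo: int, hi: int) -> int:
        """Genes with span entirely inside the open interval (lo, hi)."""
        starts = self._starts.get(chrom, [])
        ends = self._ends.get(chrom, [])
        i = bisect_right(starts, lo)  # first gene with start > lo
        j = bisect_left(starts, hi)  # genes with start < hi
        return sum(1 for k in range(i, j) if ends[k] < hi)


def call_clusters(
    loci: Sequence,
    all_genes: Iterable,
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Chain serpin loci into maximal tandem clusters per chromosome.

    Adjacent loci (sorted by start) are chained when the boundary-to-boundary
    gap (next.start - prev.end - 1) is within ``max_distance`` and at most
    ``max_intervening_genes`` annotated genes lie strictly between them.
    Genes overlapping either serpin span are not counted as intervening.
    """
    genes = list(all_genes)
    gene_chroms = {g.chromosome for g in genes}
    for locus in loci:
        if locus.chromosome not in gene_chroms:
            raise ValueError(f"locus chromosome {locus.chromosome!r} absent from annotation")
    index = _GeneIndex(genes)

    clusters: list[Cluster] = []
    by_chrom: dict[str, list] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda l: (l.span_start, l.span_end))
        current = [members[0]]
        for prev, nxt in zip(members, members[1:]):
            gap = nxt.span_start - prev.span_end - 1
            n_between = index.count_strictly_between(chrom, prev.span_end, nxt.span_start)
            # serpin loci themselves never lie strictly between adjacent
            # serpins, so no self-count correction is needed
            if gap <= params.max_distance and n_between <= params.max_intervening_genes:
                current.append(nxt)
            else:
                clusters.append(_finish_cluster(chrom, current))
                current = [nxt]
        clusters.append(_finish_cluster(chrom, current))
    return clusters


def _finish_cluster(chrom: str, members: list) -> Cluster:
    orientations = [
        classify_pair_orientation(a, b) for a, b in zip(members, members[1:])
    ]
    gaps = [b.span_start - a.span_end - 1 for a, b in zip(members, members[1:])]
    return Cluster(
        chromosome=chrom,
        members=members,
        pair_orientations=orientations,
        intergenic_distances=gaps,
    )


def _partition_signature(clusters: list[Cluster]) -> frozenset:
    return frozenset(
        frozenset(m.serpin_name for m in c.members) for c in clusters
    )


def sensitivity_sweep(
    loci: Sequence,
    all_genes: Iterable,
    grid: Sequence[ClusterParams],
) -> pd.DataFrame:
    """Cluster counts and clustered share across a parameter grid.

    ``plateau_group`` indexes identical partitions, so a run of rows sharing
    one value marks a plateau of the cluster definition.
    """
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    genes = list(all_genes)
    rows = []
    signatures: dict[frozenset, int] = {}
    for params in grid:
        clusters = call_clusters(loci, genes, params)
        multi = [c for c in clusters if c.size >= 2]
        clustered = sum(c.size for c in multi)
        sig = _partition_signature(clusters)
        group = signatures.setdefault(sig, len(signatures))
        rows.append(
            {
                "max_distance": params.max_distance,
                "max_intervening_genes": params.max_intervening_genes,
                "n_clusters_multi": len(multi),
                "n_clusters_total": len(clusters),
                "pct_loci_clustered": 100.0 * clustered / len(loci) if loci else 0.0,
                "plateau_group": group,
            }
        )
    return pd.DataFrame(rows)


def strand_bias_test(loci: Sequence) -> tuple[int, int, float]:
    """Exact two-sided binomial test of + vs - strand counts against 0.5.

    Uses the minimum-likelihood two-sided definition, which at p = 0.5
    equals doubling the smaller tail.
    """
    if not loci:
        raise ValueError("no loci")
    n_plus = sum(1 for l in loci if l.strand == "+")
    n_minus = len(loci) - n_plus
    p = stats.binomtest(n_plus, n_plus + n_minus, 0.5).pvalue
    return n_plus, n_minus, float(p)


def chrom_density_test(
    counts: dict[str, int], lengths: dict[str, int]
) -> DensityTest:
    """Length-weighted chi-square goodness of fit for per-chromosome counts.

    Expected counts are proportional to chromosome length:
    E_i = N x L_i / sum(L).  Every chromosome in ``lengths`` contributes a
    category, including those with zero observed loci; the caller excludes
    unplaced-scaffold loci beforehand.
    """
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
    chroms = sorted(lengths)
    obs = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    L = np.array([lengths[c] for c in chroms], dtype=float)
    n = obs.sum()
    expected = n * L / L.sum()
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return DensityTest(
        observed={c: int(o) for c, o in zip(chroms, obs)},
        lengths=dict(lengths),
        expected={c: float(e) for c, e in zip(chroms, expected)},
        chi2=float(chi2),
        df=len(chroms) - 1,
        p=float(p),
    )


def cluster_spacing_stats(cluster: Cluster) -> SpacingStats:
    """Mean/min/max intergenic gap and total span of one cluster.

    Spacing is undefined (None) for singletons; span is always defined.
    """
    gaps = cluster.intergenic_distances
    if not gaps:
        return SpacingStats(mean=None, min=None, max=None, span=cluster.span)
    return SpacingStats(
        mean=float(np.mean(gaps)),
        min=int(min(gaps)),
        max=int(max(gaps)),
        span=cluster.span,
    )


def chromosome_counts(loci: Sequence) -> dict[str, int]:
    out: dict[str, int] = {}
    for l in loci:
        out[l.chromosome] = out.get(l.chromosome, 0) + 1
    return out


def chromosome_share(counts: dict[str, int], chromosome: str) -> float:
    """Percent of all loci on one chromosome."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no loci counted")
    return 100.0 * counts.get(chromosome, 0) / total
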