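# Methods

This note documents the models, rules and numerical choices behind
`serpin-atlas`, and what its synthetic validation does and does not show.

## Problem setting

Serpins (serine protease inhibitors) are suicide-substrate inhibitors built
on a conserved fold. The exposed reactive center loop (RCL) near the
C-terminus acts as protease bait; its residues — especially P1, the residue
immediately N-terminal of the scissile bond in Schechter–Berger numbering —
largely determine which protease family a serpin inhibits. In
blood-feeding arthropods, serpin genes occur in expanded, tandemly
duplicated families. Given an assembled genome, a gene annotation and a set
of known RCL peptides, the package builds a chromosome-resolved atlas of
serpin loci: where they are, how they are structured and oriented, how they
cluster, how similar they are to each other, and what they likely inhibit.

## Discovery: fuzzy RCL matching (`rcl_scanner`)

A protein is a serpin candidate if a window inside its C-terminal region
(last `window_len = 100` residues; the whole protein if shorter) matches a
known RCL peptide under pure substitution distance, with

* a mismatch budget of `floor(0.30 × query length)` — the floor is the
  conservative reading of "up to 30% mismatches"; for 16-mer RCLs the
  budget is 4;
* no two adjacent mismatched positions (runs of ≥ 2 are inadmissible),
  which suppresses chance matches in low-complexity tails;
* candidate windows of exactly the query's length (no indels — the run
  constraint is positional and gapped matches would make it ill-defined);
* `X` mismatching everything, case-insensitive comparison.

One best match is kept per protein across all queries: fewest mismatches,
then smallest offset, then sorted query id. Discovery iterates: RCLs
extracted from hits are appended to the query set and the scan repeats
until the hit set is stable (it is monotone non-decreasing because queries
only accumulate). Because matching is substitution-only, a derived query
inherits the P1 offset of the query that produced it, position for
position.

## Protein features (`serpin_features`)

* **Hinge.** The conserved scaffold signature NAVYFKG is searched in the
  N-terminal half with a budget of one substitution, which also accepts the
  common NAIYFKG variant. The earliest admissible window wins.
* **Sequons.** N-glycosylation acceptors are all offsets matching
  Asn-X-Ser/Thr with X ≠ Pro, overlapping occurrences included.
* **Molecular weight.** Average (not monoisotopic) residue masses plus one
  water; `X` contributes the mean residue mass. This matches how
  "calculated MW" is conventionally reported.
* **Isoelectric point.** Henderson–Hasselbalch net charge over the termini
  and D, E, C, Y, K, R, H with the EMBOSS pKa table (overridable), solved
  by bisection on pH ∈ (0, 14); the net charge is strictly decreasing in
  pH, so the root is unique. The residual charge at the returned pH is
  below 0.01.
* **Signal peptides** are never predicted internally; externally computed
  calls are ingested from a two-column table, with missing entries
  reported as "unknown" and conflicting duplicates rejected.

Atlas-level summaries (length/MW/pI ranges, multi-exon share) are
recomputed from the loci on every call, never cached, and the multi-exon
share is reported with its numerator and denominator because percentage
conventions differ between atlases.

## Tandem clusters and distribution statistics (`atlas_clusters`)

A cluster is a maximal chain of serpin loci on one chromosome in which
every neighbouring pair satisfies both

* boundary-to-boundary gap (next start − previous end − 1, on gene spans,
  not CDS) ≤ 100 kb, and
* at most 10 annotated genes of any biotype lying strictly between the two
  spans (genes overlapping either serpin are not counted).

Singletons are clusters of size one. A sensitivity sweep reports cluster
counts and the clustered share over a parameter grid and tags identical
partitions, making plateaus visible. Relaxing either threshold can only
merge clusters, never split them.

Adjacent-pair orientation is assigned from strands: same strand →
head-to-tail; (−,+) → head-to-head (the 5′ ends face each other);
(+,−) → tail-to-tail. Note a terminology caveat: some atlases label the
5′-facing arrangement "convergent", though transcription in that geometry
is conventionally called divergent; the geometric definition above is what
the code implements. The label set is invariant under mirroring the
chromosome together with a strand flip (the same molecule read from the
other end); either operation alone exchanges head-to-head and
tail-to-tail.

Strand bias uses the exact binomial test against 0.5 with the
minimum-likelihood two-sided p-value (equal to tail-doubling at p = 0.5).
Chromosomal density uses a χ² goodness-of-fit test with expectations
proportional to chromosome length, E_i = N·L_i/ΣL, over every chromosome
supplied (zero-count chromosomes included; df = #chromosomes − 1). Loci on
unplaced scaffolds are excluded from the density test by the caller but
retained in the strand test — both choices follow how such atlases are
normally tabulated, and both tallies are explicit inputs.

## Pairwise identity and duplication tiers (`pairwise_homology`)

Every unordered protein pair gets a Needleman–Wunsch global alignment and a
Smith–Waterman local alignment under BLOSUM62 with affine gaps (open 11,
extend 1 — BLASTP defaults; configurable). Global percent identity counts
identical aligned pairs over *all* alignment columns including terminal-gap
columns; local identity counts local alignment columns only, with 1-based
query coordinates.

Tiers are contiguous half-open bins on global identity so that every pair
is labelled: exact duplicate at 100, recent paralog in [98, 100), diverged
paralog in [70, 98), non-homologous below 70. The [98, 100) and [70, 98)
bins close the gap left open by prose ranges like "70–97%"/"≥98%"; the bin
edges are recorded in the output table metadata.

## P1 rule engine (`rcl_classifier`)

Schechter–Berger numbering places Pk k−1 positions upstream of the P1
residue and Pk′ k positions downstream; hinge positions P15–P9 and the
specificity core P4–P4′ are reported, with positions beyond the protein
marked absent. The scissile-bond position is not derivable from a match
alone, so each seed RCL carries its known P1 offset, which propagates to
hits (and to iteratively derived queries) by alignment position.

The class rules, applied in order:

1. P1 ∈ {V, I} and P1′ ∈ {A, S, G, T} → **dual**
   (chymotrypsin-like/elastase-like preference);
2. P1 ∈ {R, K} → **coagulation_complement** (trypsin-like targets:
   thrombin, factor Xa/XIa, kallikrein, C1r/C1s/MASP-type proteases);
3. P1 ∈ {F, Y, W, L, I, V, M} → **inflammation_control**
   (chymotrypsin-like: cathepsin G, chymase);
4. P1 ∈ {A, S, G} → **tissue_protection** (elastase-like);
5. otherwise (N, E, …) → **unknown**.

The dual rule strictly precedes the hydrophobic rule. All outputs are
labelled screening-level: extended RCL context, exosites and cofactors can
shift real specificity, and the package's concordance flag against
experimentally confirmed targets exists precisely to surface such
disagreements rather than hide them. The published 70-row P1 catalog and
confirmed-target table ship as package data; the rule table reproduces
every catalog class label.

## Motif occurrence and grouping (`motif_groups`)

Motif hits come from a parsed external MEME/FIMO run (de novo motif
discovery is deliberately not re-implemented) or from an internal consensus
scanner that reuses the constrained fuzzy matcher over full-length
sequences (default mismatch fraction 0.2). The binary sequence-by-motif
occurrence matrix keeps all-zero rows and is idempotent under duplicate
hits; FIMO hits pass at q < 0.05 by default.

Grouping is two-step: (1) columns are standardized and Ward-linkage
agglomerative clustering produces provisional groups, with k chosen by
silhouette over 2–10; (2) a random forest (200 trees, fixed seed) is fit to
the provisional labels, its feature importances are normalized to sum to
one and used to scale columns, and Ward clustering is re-run on the
weighted matrix (k again by silhouette) to give the final groups. Labels
are canonicalized by first appearance, so results are reproducible for a
fixed seed. Column-wise Shannon entropy (gap counted as a 21st symbol)
over an alignment yields high-entropy "variable" windows: sliding means,
top-k non-overlapping, ties to the leftmost.

On planted-partition matrices mimicking a realistic catalog density
(about eight signature motifs per group, cf. ~50 motifs resolving six
groups, plus Bernoulli(0.1) noise columns), the final grouping recovers
the planted partition with adjusted Rand index ≥ 0.9 up to 20%
between-group signature overlap. The importance-weighting step is not
uniformly beneficial at weaker signal — with sparse signatures it can
discard columns a minority group depends on — which is a known property of
importance-reweighted re-clustering, not a defect the tests hide.

## Synthetic atlases (`synthetic_atlas`)

The generator reverse-engineers proteins into chromosomes so each pipeline
stage can be checked against planted truth:

* Planted serpins are 372–455 aa (drawn N(396, 11), clipped — the length
  band of real serpin cores), with M at position 0, the hinge variant
  NAIYFKG at offset 30, a sequon at 45, the conserved splice-junction
  peptide TVFLPK|FKLETKYSL at offset 190 and a 16-mer RCL ending 10
  residues before the C-terminus.
* The RCL is a seed peptide mutated at a planned number of non-adjacent,
  hinge-side positions, so the planned (seed, offset, mismatch count) is
  provably the scan's best match; the generator verifies this before
  emitting anything. Seed RCLs are synthetic 16-mers sharing a
  hinge-proximal body and differing in the P2-P1-P1′ tail, so the planted
  seed determines the P1 class.
* Two-exon loci split the CDS at the junction codon boundary (both CDS
  phases 0), with GT…AG introns of configurable length (default range
  498–7613 bp, the observed intron-length band); minus-strand genes are
  placed as the reverse complement with mirrored exon coordinates.
* Duplicate/paralog pairs are substitution-only mutants at a target global
  identity; the substitution count is floor-biased and the result verified
  with the package's own global aligner (tolerance ±0.5 points), with RCL,
  hinge, sequon and junction frozen. At 100% the copy is exact.
* Decoy genes are random proteins verified to contain no admissible match
  against any seed *or any planted RCL variant* (regenerated until clean),
  so specificity on the simulation is 1 by construction.
* Codons are chosen uniformly at random (no codon-usage model — nothing
  downstream consumes codon bias); intergenic sequence is i.i.d. uniform
  nucleotides. All randomness flows from one seed; identical seeds give
  byte-identical FASTA/GFF3/TSV outputs.

`study_scale_config` is the study-scale default: 74 loci across eight
numbered chromosomes plus one unplaced scaffold (4/2/2/2/6/50/6/1 + 1),
strand totals 46+/28−, 20 two-exon loci, and chromosome 10 carrying 50
loci in 17 clusters — nine singletons, three 2-gene, three 3-gene, one
5-gene and one 21-gene array whose 20 intergenic gaps are fixed to mean
11,908 bp with range 679–43,544 bp. The published chromosome-10 cluster
census counts its 49 unique serpins (with a 4-gene cluster); this
generator plants the 50th locus — the exact-duplicate copy — adjacent to
its partner inside that cluster, which is why the corresponding cluster
has five members here. Four exact-duplicate pairs, two 98% pairs and two
85% pairs are planted. Inter-cluster breaks are >100 kb with two decoy
genes inside, so the distance rule, not luck, separates clusters.

**What the simulation does not emulate:** pseudogenes and partial gene
models, alternative splicing, repeat landscapes, codon bias, sequencing or
annotation error, and RCLs diverged beyond the scan budget. Passing the
recovery tests therefore shows the pipeline is internally correct — it
recovers exactly what its rules define on clean input — not that the scan
budget or cluster thresholds are optimal for any particular real genome.

## Problem sizes and runtime

The test suite and the acceptance script run the full 74-locus simulation
(≈ 8 Mb genome), one all-vs-all pass over the 49 chromosome-10 proteins
(1176 pairs, both aligners), 1000 randomized scan-vs-enumeration trials
and 150 aligner-vs-DP trials on ≤ 30-aa pairs; the whole suite completes
in well under a minute on one CPU. These sizes were chosen as the smallest
that exercise every rule at the study's published scale.

## Known limitations

* The length-weighted χ² reproduces any hand-computed input exactly, but
  reproducing a published genome-scale value requires that assembly's
  chromosome lengths, which are an external input the package does not
  bundle.
* The P1 classes are screening predictions; the concordance flag against
  confirmed targets shows both agreements and disagreements (e.g. a
  small-P1 serpin experimentally inhibiting chymotrypsin-like proteases).
* Indel-tolerant RCL matching and profile/HMM detection are out of scope;
  a serpin whose RCL has internal insertions relative to every seed will
  be missed by design.
* Group recovery guarantees for the motif stage hold under the planted
  model's assumptions (block signatures, independent noise); real
  occurrence matrices with strongly nested motifs may cluster differently.
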