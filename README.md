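# serpin-atlas

Build a chromosome-resolved atlas of serpin (serine protease inhibitor)
genes from an annotated genome assembly.

Serpins inhibit serine proteases by a suicide-substrate mechanism: an
exposed reactive center loop (RCL) near the C-terminus baits the target
protease, and the residue immediately N-terminal of the scissile bond (P1
in Schechter–Berger numbering) largely sets which protease family is
inhibited. In blood-feeding arthropods such as ticks, serpin genes occur
in large tandemly duplicated families injected into the host to defeat
coagulation, complement and inflammation. This package is for genome
scientists who have an assembly, a gene annotation (GFF3/GTF) and a set of
known RCL peptides, and want the family mapped end to end:

* **Discovery** — fuzzy RCL matching in each protein's C-terminal window
  (≤ 30% mismatches, floor-rounded; no two adjacent mismatches; one best
  match per protein), iterated by re-seeding with discovered RCLs until a
  fixed point.
* **Features** — hinge motif (NAVYFKG ± 1), N-glycosylation sequons
  (N-X-S/T, X ≠ P), average molecular weight, Henderson–Hasselbalch
  isoelectric point (EMBOSS pKa, bisection), ingestion of external
  signal-peptide calls.
* **Clusters** — tandem arrays chained by a ≤ 100 kb boundary-to-boundary
  gap and ≤ 10 intervening genes; adjacent-pair orientations
  (head-to-tail / head-to-head / tail-to-tail); exact binomial strand-bias
  test; length-weighted χ² test of chromosomal density
  (E_i = N·L_i / ΣL).
* **Homology** — all-vs-all Needleman–Wunsch and Smith–Waterman under
  BLOSUM62 (gap open 11, extend 1); global identity counted over all
  columns including terminal gaps; duplication tiers: exact duplicate
  (100%), recent paralog [98, 100), diverged paralog [70, 98),
  non-homologous below 70%.
* **Function** — P1/P1′ rule engine: R/K → coagulation/complement
  (trypsin-like targets), F/Y/W/L/I/V/M → inflammation control
  (chymotrypsin-like), A/S/G → tissue protection (elastase-like), V/I with
  small P1′ → dual, non-canonical P1 → unknown; screening-level, with
  concordance flags against experimentally confirmed targets.
* **Motif groups** — binary sequence-by-motif occurrence matrix (parsed
  MEME/FIMO output or an internal consensus scanner) clustered by a
  two-step Ward + random-forest importance-weighting procedure.
* **Synthetic validation** — a generator that reverse-engineers serpin
  proteins into chromosomes with full planted truth (coordinates,
  strands, clusters, identity tiers, P1 classes), so every stage is
  testable without any external download.

## Worked example

The study-scale synthetic atlas plants 74 serpin loci (the published
family size) on a 15-chromosome genome plus an unplaced scaffold, then
runs the full pipeline:

```python
from serpin_atlas import synthetic_atlas as sa, atlas_clusters as ac
from serpin_atlas.pipeline import build_atlas

sim = sa.simulate_atlas(sa.study_scale_config(42))
atlas = build_atlas(sim.genome, sim.genes, sim.seeds, sim.seed_p1_offsets)
print(f"serpin loci discovered: {len(atlas.loci)}")

n_plus, n_minus, p = ac.strand_bias_test(atlas.loci)
print(f"strand bias: {n_plus}+ / {n_minus}-  exact binomial p = {p:.3g}")

clusters = ac.call_clusters(atlas.loci, sim.genes)
chr10 = [c for c in clusters if c.chromosome == "chr10"]
big = max(chr10, key=lambda c: c.size)
stats = ac.cluster_spacing_stats(big)
print(f"chr10: {sum(c.size for c in chr10)} loci in {len(chr10)} clusters; "
      f"largest = {big.size} genes, mean gap {stats.mean:.0f} bp "
      f"(range {stats.min}-{stats.max})")
```

prints

```
serpin loci discovered: 74
strand bias: 46+ / 28-  exact binomial p = 0.0474
chr10: 50 loci in 17 clusters; largest = 21 genes, mean gap 11908 bp (range 679-43544)
```

— every planted locus is rediscovered; the strand split of 46 plus versus
28 minus is significantly biased (p ≈ 0.047, exact two-sided binomial);
chromosome 10 carries 50 of the 74 loci in 17 tandem clusters, the largest
a 21-gene array whose intergenic gaps average 11,908 bp. The atlas table
(`atlas.table`) lists one row per locus with coordinates, exon count, RCL
match, hinge, sequons, MW, pI and predicted P1 class:

```
serpin_name chromosome strand  exon_count               p1_class
       S1c1       chr1      +           2 coagulation_complement
       S2c1       chr1      -           2      tissue_protection
       S3c1       chr1      +           2 coagulation_complement
```

The same steps run from the shell:

```bash
atlas simulate --seed 42 --out simdir/
atlas extract  --genome simdir/genome.fa --annotation simdir/annotation.gff3 --out proteins.fa
atlas scan     --proteins proteins.fa --rcl-seeds simdir/rcl_seeds.fa --out hits.tsv
atlas features --genome simdir/genome.fa --annotation simdir/annotation.gff3 \
               --rcl-seeds simdir/rcl_seeds.fa --out atlas.tsv
atlas clusters --atlas atlas.tsv --annotation simdir/annotation.gff3 --out clusters.tsv
atlas pairwise --proteins proteins.fa --out pairs.tsv
```

## Layout

```
src/serpin_atlas/
  sequence_io.py       FASTA/GFF3/GTF I-O, representative transcripts, translation
  rcl_scanner.py       constrained fuzzy RCL matching, iterative re-seeding
  serpin_features.py   hinge, sequons, MW, pI, signal-peptide ingestion
  atlas_clusters.py    tandem clusters, orientations, strand & density tests
  pairwise_homology.py all-vs-all identity and duplication tiers
  rcl_classifier.py    Schechter-Berger numbering and P1 rule engine
  motif_groups.py      occurrence matrix, two-step grouping, MEME/FIMO parsing
  synthetic_atlas.py   planted-truth genome generator
  pipeline.py          end-to-end orchestration
  cli.py               `atlas` command-line interface
docs/methods.md        models, rules, numerical choices, limitations
```

See `docs/methods.md` for the scientific details and known limitations.
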