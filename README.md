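# baitdesign

Design of hybridization-capture probe (bait) sets for target-enrichment
sequencing from per-gene nucleotide alignments.

Target enrichment (Hyb-Seq) recovers hundreds of nuclear loci from genomic
libraries by hybridizing them to short oligonucleotide probes. A probe set
meant to work across a large, deeply divergent clade cannot be designed from
one reference sequence per gene: hybridization fails beyond roughly 30%
sequence divergence, so each gene must be represented by several sequences
that jointly span the clade's diversity — while keeping the total probe count
(and kit cost) as small as possible. `baitdesign` solves this representative-
selection problem and carries it through to a synthesizable probe set. It is
aimed at phylogeneticists building capture kits from transcriptome or genome
alignments (e.g. per-gene alignments spanning hundreds of taxa).

## Method

For each gene alignment the pipeline:

1. **Cleans the alignment** — optional taxon keep-list filtering, removal of
   gap-only columns, case/U→T normalisation.
2. **Computes p-distances** — for rows *i*, *j* the distance is
   *d(i,j) = m / s*, where *s* counts sites at which both rows have an
   unambiguous nucleotide and *m* counts mismatches among them. Pairs with no
   comparable sites get the maximal distance 1.0.
3. **Selects the minimum number of representatives** — PAM k-medoids
   (BUILD + SWAP) partitions the rows around *k* real sequences, minimising
   Σᵢ min_m d(i, m). For *k* = k_min … k_max (default 5–15), up to 100
   restarts are run per *k*; the first medoid set for which at least 95% of
   the gene's sequences lie within 30% p-distance of a medoid is accepted.
   Genes that cannot meet the criterion by k_max are reported as failed and
   excluded. Medoids are used (rather than k-means centroids) because every
   representative must be a real, synthesizable sequence.
4. **Assembles target instances** — selected rows are degapped; mandatory
   reference orthologs (e.g. well-annotated model-genome rows) are appended
   when the medoids did not pick them.
5. **Tiles probes** — 120-mers at 3× tiling density (40 bp start spacing,
   every interior base covered by three probes), with an end-anchored final
   window. Instances shorter than 120 bp are padded with 3'-Ns; N runs of
   1–10 become Ts, longer runs survive and their windows are dropped.
   Identical 120-mers from different instances are collapsed.
6. **Filters for specificity** — each probe is searched against reference
   genomes (exact 16-mer seeding + ungapped verification, both strands,
   ≥90% identity over the full probe). A probe with two or more hit loci in
   each of two or more genomes is removed as likely paralogous/repetitive.

A synthetic-data module generates alignments with planted divergence clusters
and genomes with planted probe copies, so the whole pipeline is testable
without any external download.

## Worked example

```python
from baitdesign import (generate_clustered_alignment, build_distance_matrix,
                        select_minimal_medoids, SelectionParams,
                        build_target_instances, ProbeSet, mean_target_length)

aln, truth = generate_clustered_alignment(
    n_clusters=8, members_per_cluster=10, length=600, seed=1, gene_id="demo")
dm = build_distance_matrix(aln)
sol = select_minimal_medoids(dm, SelectionParams(seed=1), gene_id="demo")
instances = build_target_instances(aln, list(sol.medoid_ids))
probes = ProbeSet.from_instances(instances)
```

prints, step by step:

```
alignment: 80 sequences x 600 columns
selection: k=8 status=passed coverage=1.000 cost=3.061 restarts=1
targets: 8 instances, mean length 535.8 bp
probes: 96 unique 120-mers (0 duplicates removed, 0 windows dropped)
```

The gene was planted with 8 divergence clusters; the search rejects
k = 5, 6, 7 (their best coverage leaves whole clusters unrepresented) and
accepts k = 8 on the first restart with every sequence within the 30%
threshold of a medoid. Each ~536 bp instance yields 12 tiled 120-mers
(starts 0, 40, …, plus one end-anchored window), 96 in total with no
cross-instance duplicates.

The same run from a shell:

```bash
baitdesign simulate --genes 10 --out sim/ --seed 3
baitdesign design sim/ --out design/ --seed 3 \
    --threshold 0.30 --coverage 0.95 --k-min 5 --k-max 15 --restarts 100
```

which writes `probes.fasta`, `targets.fasta` (HybPiper-style
`SourceID-GeneID` headers) and `report.tsv` with per-gene k, coverage, cost
and probe counts. `baitdesign compare-refs` contrasts medoid coverage with
coverage by fixed genome references, and `baitdesign filter` screens an
existing probe FASTA against genomes.

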