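# Methods

## Problem and model

Given a multiple sequence alignment of one putatively single-copy gene
across a clade, the design task is to pick the smallest set of *target
instances* (real sequences from the alignment) such that nearly every known
sequence of that gene could hybridize to a probe tiled from at least one
instance. Hybridization efficiency decays with sequence divergence, with a
practical capture limit of about 30% mismatch; we therefore use a coverage
criterion rather than a clustering-quality criterion: a candidate set of
representatives is acceptable when at least `coverage_target` of the gene's
sequences lie within `divergence_threshold` of their nearest representative.

Divergence is the p-distance: mismatches divided by comparable sites, where
a site is comparable when both rows carry an unambiguous nucleotide
(A/C/G/T). Gaps never count; by default N and IUPAC ambiguity codes are also
excluded (`ambiguous_as_missing=True`), since an unresolved state is
evidence neither of match nor mismatch. This exclusion is a documented,
switchable choice. A pair of rows with no comparable sites at all is
assigned distance 1.0 with a logged warning: such a pair carries no evidence
that one could represent the other, so the conservative (maximal) distance
keeps the coverage criterion honest. An optional `min_overlap` (default 1
site) extends this treatment to pairs whose overlap is too small to be
meaningful. All distances are ratios of small integers evaluated in floating
point, and threshold comparisons are inclusive (`d <= 0.30` is covered,
`coverage >= 0.95` passes) with no tolerance term.

## Medoid selection

Representatives must be real sequences (they are synthesized as probes), so
selection is k-medoids, not k-means. The solver is PAM: a greedy BUILD phase
seeds k medoids by repeatedly adding the sequence that most reduces total
cost Σᵢ min_m d(i,m); a SWAP phase then exchanges (medoid, non-medoid) pairs
until no exchange lowers the cost. SWAP evaluates all k·(n−k) candidate
exchanges per pass in O(n²) using the FastPAM1 delta decomposition (Schubert
& Rousseeuw 2019), applying the single best exchange per pass; this visits
the same local optima as the classical swap search, which the test suite
confirms by exhaustive enumeration on small instances. The kernel is
numba-compiled with a pure-numpy fallback that implements the identical
update and tie rules.

The minimal-k search runs k from `k_min` (default 5) to `k_max` (default
15). For each k up to `restarts` (default 100) PAM runs are tried: the first
is BUILD-seeded, subsequent restarts start from a uniform random k-subset.
Random restarts are pre-conditioned by a Voronoi (alternating) refinement —
assign each point to its nearest medoid, recentre each cluster on its
cost-minimising member, repeat — before the SWAP polish; this cuts the
number of SWAP passes several-fold without changing what is returned, since
SWAP still runs to convergence and every reported solution is a PAM local
optimum. The first restart whose medoid set meets the coverage target is
accepted (early stop); searching k in ascending order makes the accepted k
minimal within the searched range. If no k qualifies the best solution seen
(highest coverage, then lowest cost) is returned as failed. `k_min=5` is kept
as the procedure's default lower bound even where a smaller k would cover;
it is configurable.

Determinism: every restart's seed is derived as
`crc32(master_seed | gene_id | k | restart)`, so per-gene results are
identical across machines and independent of file-listing order. All ties
(equal-cost swaps, equidistant nearest medoids, equal BUILD gains) break
toward the lowest matrix index.

Coverage counts the representatives themselves in the denominator (they are
sequences of the gene, at distance 0). The companion evaluation of a *fixed*
reference set (e.g. "which fraction of transcripts could available genome
sequences alone represent?") instead scores only the non-reference rows,
since there the references are the probe source and the transcripts the
objects to be captured.

## Targets and probes

Accepted medoids are degapped into target instances; mandatory reference
orthologs (a per-gene id list, e.g. model-genome rows of the same alignment)
are appended when absent from the medoid set, membership judged by sequence
id. Target files use `SourceID-GeneID` headers for direct use as a HybPiper
target file.

Probes are 120-mers tiled at 3× density: start spacing
`probe_length / tiling_density` = 40 bp, so every interior base is covered
by exactly three probes; when the instance length is not start-aligned one
extra window is anchored at the 3' end so the terminus is always covered.
Instances shorter than 120 bp are padded with 3'-terminal Ns; maximal N runs
of 1–10 are then rewritten as Ts (so short ambiguity stretches do not block
synthesis) while longer runs survive, and any window still containing an N
is dropped and counted. Padding with N-then-T, start-anchored tiling and the
end-anchored final window are documented design choices where the procedure
admits alternatives (consensus fill, centred tiling); the probe-count law
`floor((L−120)/40) + 1 (+1 if off-step)` is fixed by them and verified
exhaustively for L up to 1 kb. Deduplication collapses byte-identical probe
sequences across all genes and instances, keeping the first in
(gene, source, start) order; probes are emitted in target-strand orientation
only, since capture enriches both strands regardless.

## Specificity filter

A probe that matches several loci in several genomes is likely to enrich
paralogues or repeats. The filter counts *hit loci* per genome: ungapped
full-length placements at ≥ 90% identity on either strand, found by exact
16-mer seeding against a sorted 2-bit k-mer index and verified
position-by-position; overlapping accepted placements (across strands too)
merge into one locus. A probe is removed iff it has ≥ 2 loci in each of ≥ 2
genomes. The alternative grammatical reading of the removal rule (≥ 2 hits
in total spread over ≥ 2 genomes) would delete probes for genes legitimately
single-copy in every genome and is rejected; both the threshold and the rule
arity are configurable. Seeding at k=16 can in principle miss a 90%-identity
placement whose mismatches are spread so evenly that no 16-mer survives
(pigeonhole bound: 12 mismatches can cap clean stretches at 9 bp); planted
and realistic hits are found, and the matcher is validated against a
brute-force every-offset scan in the tests. Hits aggregate across the
sequences of one genome file; the genome's name is its file stem.

## Synthetic data

The generator emulates the structure of large per-gene transcriptome
alignments. Each of c clusters descends from its own ancestor; ancestors
radiate from a common root at per-lineage substitution rate
m = (3 − √(9 − 12b))/4 so that ancestor pairs sit at expected p-distance b
(`between_divergence`; for b ≥ 0.75, the uniform-substitution saturation
level, ancestors are drawn independently). Members mutate from their
ancestor at per-site rate w/2, giving within-cluster pairwise p-distance
concentrating at w (`within_divergence`). Mutations are substitutions
uniform over the three alternative bases; gaps are inserted as random blocks
(lengths 1–15) until a per-row `gap_fraction` is reached and carry no
divergence signal. Defaults — w = 0.05, b = 0.60, 10 members per cluster,
600 columns, 10% gaps — are the separable regime the selection procedure is
specified against. The preset used for full-scale screens draws row counts
from [12, 655] and column counts from [105, 3498], the observed ranges of
the real per-gene alignments, with c ∈ [5, 15] clusters and multinomial
cluster sizes.

What the generator does **not** emulate: phylogenetic tree structure (all
clusters are star-shaped radiations), rate heterogeneity across sites, codon
structure, indel evolution, alignment error and ambiguity codes. Passing
recovery tests therefore shows the selection machinery is correct under
separable cluster structure, not that real alignments are this separable —
on real data genes genuinely fail the criterion (the pipeline reports them
as failed rather than forcing a representation). Synthetic genomes are
i.i.d. uniform background with probes planted verbatim at non-overlapping
positions on random strands; a 120-mer has vanishing probability of a
spurious ≥ 90% match in ≤ 1 Mb of such background, which the brute-force
oracle confirms.

## Numerical and scale choices

* Distance matrices are built by one-hot float32 matrix products; all counts
  are integers below 2²⁴, so the products are exact.
* A SWAP exchange is applied only if it improves cost by > 1e-12, preventing
  float-noise cycling; PAM passes are capped at 2 + 20k as a safety bound
  never reached in practice.
* The full-scale screen in the tests and acceptance script uses 400 and 80
  synthetic genes respectively at the preset size ranges — large enough that
  every k in [5, 15] and both report outcomes are exercised, while a 400-gene
  screen completes in a few minutes on one CPU.
* Gene processing order, report float formatting (`%.6f`) and the absence of
  timestamps make pipeline outputs byte-reproducible for identical inputs
  and seed.

## Known limitations

* The ungapped seeded matcher is not a general aligner: indel-containing or
  edge-partial matches are not hits by definition.
* Coverage is evaluated on the alignment's own rows; it does not model
  capture chemistry (GC content, melting temperature) or probe synthesis
  constraints beyond fixed length and full specification.
* With unequal planted cluster sizes, clusters holding < 5% of rows can be
  left unrepresented by a passing solution — a property of the coverage
  criterion itself, not a defect of the solver.
* The restart ladder explores uniform random initialisations only; for
  pathological tie-rich matrices the global optimum is guaranteed only on
  the enumerable sizes covered by the exhaustive-oracle tests.
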