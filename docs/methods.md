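# Methods

`virobench` measures how assembly and taxonomic-annotation tools behave on
viral (and mixed viral-bacterial) metagenomes by running them on *simulated*
communities for which every read's origin is known exactly. The package
provides the three pillars such a benchmark needs: a ground-truth-tracked
community simulator, an artifact-free reference ("optimal") assembly to
compare against, and the evaluation machinery (chimera/LCA statistics,
contig scores, classifier sensitivity/specificity under taxon-exclusion
databases).

## The synthetic community

**Taxonomy.** A complete nine-rank hierarchy (root, superkingdom, phylum,
class, order, family, subfamily, genus, species) with every rank present on
every root-to-species path, split between a viral and a bacterial
superkingdom by a configurable viral fraction. Families are grouped into
orders (default 3 per order) and genera into subfamilies (default 2), so
lowest-common-ancestor queries can land on any rank.

**Genomes.** One genome per species. Each *family* ancestor is generated de
novo: its length is drawn from `length_range` (default 5–10 kb, phage-like)
and its sequence from a family-specific random order-2 Markov chain
(Dirichlet(2) transition rows). The Markov kernel gives every clade a
genome-wide oligonucleotide usage signature — the analogue of the
dinucleotide/codon biases of real genomes — which is the feature that
k-mer-composition classifiers exploit; i.i.d. random sequences would lack it
and would make composition-based classification uninformative by
construction. Below the family, sequences are derived hierarchically by
per-site substitution at rank-keyed divergences (defaults: family 0.10,
subfamily 0.07, genus 0.04; substitutions replace a base uniformly by one of
the other three). No indels are introduced between relatives by default so
that coordinates are exact across the clade; two sequences that split at
per-site rate *d* therefore mismatch at an expected proportion
2d(1−d) + (2/3)d².

**Conserved shared segments.** `n_shared_functions` segments (600 bp,
labels such as `terminase_large_subunit`, `portal_protein`, `integrase`)
are copies of community-wide templates inserted at fixed relative positions
in every family and mutated at a low rate (default 0.01, never faster than
the local background). They give otherwise-unrelated genomes a shared
homologous core — the conserved-gene mechanism that makes real assemblers
collapse reads from different taxa into chimeric contigs. Each genome also
carries private ORFs with genome-unique labels, so functional-annotation
accuracy can distinguish correct from transferred labels.

**Abundances.** Per-genome coverages are standardized by the minimum
positive value; expected read counts are proportional to standardized
coverage × genome length (the combination that reproduces the requested
mean depth at fixed read length), and integers are allocated by
largest-remainder rounding so counts sum exactly to the requested total.
The convenience sampler draws coverages from a log-normal (σ = 1), the
canonical shape of metagenomic abundance distributions.

**Reads.** Single-end reads with normal template lengths (default
400 ± 30 bp, truncated at 50 bp and the genome length), uniform start and
strand. The pyrosequencing-style error model applies (a) per-base
substitutions (default 10⁻³) and (b) homopolymer over/under-calls: each run
of length L ≥ 2 gains or loses one base with probability
min(0.5, c·(L−1)), c = 5·10⁻³ by default. These defaults are
order-of-magnitude typical for 454 chemistry and configurable; the
benchmark's logic is insensitive to their exact values. Every error is
recorded, and the read header carries the full provenance
(`read…|gid=…|tid=…|start=…|end=…|strand=…|err=…`), with 1-based inclusive
forward-strand coordinates of the error-free template; homopolymer indels
change the read length but never the template coordinates.

## The optimal assembly

Reads are grouped by source genome, sorted by start (ties: end descending,
then read id), and merged into maximal chains in which every read overlaps
the running span by ≥ 1 bp — strict adjacency is not merged, since a
zero-overlap junction is not assemblable evidence. Each chain becomes a
contig whose consensus is the error-free reference substring it spans;
contigs shorter than 350 bp (the benchmark's analysis floor) are discarded
and their reads reported unassembled. By construction the optimal assembly
contains no chimeras and every consensus is an exact reference substring,
which pins its expected statistics (0% chimeric contigs, median contig
score 100) independent of scale.

## Perturbation fixtures

`perturb_assembly` selects each contig independently with probability
`chimera_rate` and splices into it a block of reads donated by a partner
contig whose source species' LCA with the target's species is exactly
`fusion_rank` (the partner's consensus is appended with a 100 bp junction
overlap so donated reads physically overlap the junction). The partner
*donates* rather than being consumed: the number of chimeric contigs then
equals the number of selected contigs, so the measured chimera percentage
is an unbiased estimate of the injected rate — full pairwise fusion would
halve the chimeric count and shrink the denominator, biasing the recovery
check. Donor search prefers unselected multi-read contigs, falls back to
still-unfused selected ones, and as a last resort absorbs a single-read
partner whole. A fraction `read_drop_rate` of placed reads is moved to the
unassembled pool. The injected chimera list is returned for truth checking.

## Assembly evaluation

* **N statistics** (N30/N50/N90): length of the contig at which contigs
  sorted by decreasing size cumulatively reach the stated fraction of total
  assembled bases (the base-weighted definition; at ties the threshold
  contig's length is returned, which is well defined).
* **Chimeras**: a contig is chimeric when its reads originate from ≥ 2
  source genomes; its LCA rank is the lowest rank at which all source
  lineages share an ancestor, and it is viral-bacterial when the sources
  span both superkingdoms.
* **Contig scores**: score = aligned contig fraction × percent identity, so
  a complete, error-free contig scores 100. Two scoring routes exist. The
  default *truth projection* maps the contig onto each of its source
  genomes through the ground-truth read coordinates and compares sequences
  positionally — exact, linear-time, and free of alignment noise (this is
  why the optimal assembly's reads-on-original-genome is exactly 100% here,
  where an external aligner would introduce a small mapping loss). The
  *align* route runs Smith-Waterman (match +1, mismatch −2, gap open −5,
  gap extend −2) of the consensus against reference genomes and is meant
  for small problems or real data where truth is unavailable.
* **Viral-bacterial hits**: a contig whose best viral and best bacterial
  contig scores are equal within 10⁻⁹ (scores here are floats; the
  historical integer-percent scores made exact ties common).
* **Genome recovery**: a genome counts as recovered when some contig's
  alignment spans 100% of the *genome* length at identity > 95% (the
  whole-genome claim would be vacuous if the span were measured on the
  contig). Under uniform sampling a read starting exactly at base 1 is
  rare, so recovery counts are small at moderate depth — expected, not a
  defect.
* **Reads on original genome**: over contigs whose majority organism equals
  their best-HSP genome, the count of member reads whose own source matches,
  divided by all assembled reads.

## Taxonomic classification

**k-mer KL classifier.** Profiles are frequencies of overlapping k-mers
(k = 4 by default, configurable 2–8) with a +1 pseudocount per cell
(Kullback–Leibler distance is undefined on zeros). A read is compared in
both orientations against every genome profile and the candidate is the
genome minimizing KL(read‖genome). Significance is a calibrated
goodness-of-fit test: at construction, for each genome a gamma distribution
is fitted by maximum likelihood to the KL distances of reads *simulated
from that genome* (same length scale, both strands, the simulator's error
model) — the null distribution of the distance when the read truly comes
from the genome. The candidate is accepted when the upper-tail probability
of its distance under this null exceeds α = 0.05. An outlier test against
the distances to the *other* genomes was considered and rejected: the
candidate is the arg-min and therefore always sits below the others, so any
others-only test is either vacuous (shifted gamma) or weakly powered
(zero-anchored gamma puts lower-tail mass where wrong-genome distances can
never fall, because KL to a wrong genome is bounded away from zero by the
compositional divergence itself). The calibrated null accepts same-source
reads at rate ≈ 1−α and leaves novel-taxon reads unassigned, which is what
the exclusion benchmark needs. With fewer than three reference genomes the
test is skipped (candidate returned, flagged not significant). Exact ties
are left unassigned.

**Best-hit classifier.** The best-alignment-hit decision structure of a
BLAST-style search: the read is scored against every retained genome, the
arg-max wins if its score clears a floor, and ties are left unassigned. The
default engine scores `read_length − edit_distance` with a semi-global
(infix) bit-vector edit-distance alignment over both orientations — fast
enough to run full exclusion benchmarks in seconds; the floor defaults to
0.7 × read length, which separates homologs up to ~25–30% divergence from
the ~50% edit distance of unrelated sequences (standing in for an e-value
cutoff). A Smith-Waterman engine with the contig-scoring parameters is
available for small runs, and a test asserts both engines agree on the
best-hit decision.

**Exclusion databases and confusion counts.** For a query read set, the
Species-/Genera-/Families-excluded databases remove every genome whose
ancestor at the corresponding rank occurs among the query lineages.
Evaluation at rank r (which must be strictly above the excluded rank):
an assigned read is TP when its predicted ancestor at r equals its true
ancestor, else FP; an unassigned read is FN when the true ancestor is still
represented in the database and TN when it is not. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); zero denominators return an undefined marker
(`None`), never 0. In the packaged trend experiment one family is placed
alone in its order and all of its species forced into the query, so that
its whole order is absent from every database — this "truly novel virus"
fraction keeps true negatives (hence specificity) defined in every
database, mirroring the real situation that most virus-like-particle reads
have no database relatives. Classifier-benchmark communities are generated
with `n_shared_functions = 0`: conserved shared segments are the chimera
driver for the assembly analysis, but in a classification benchmark they
create cross-taxon hits that say nothing about the classifier.

## Functional annotation

A read's *true annotation* is the label of the ORF overlapping its genomic
interval best, accepted when the overlap covers ≥ 60% of the read (ties go
to the smaller ORF start). For assembled reads, the contig is projected
onto its majority genome via the ground-truth read coordinates; each
overlapping ORF becomes an annotated contig region, and every member read
with ≥ 1 bp inside a region inherits the region's label with overlap
fraction = bases-inside-region / read length (a read spanning several
regions keeps the best-covered one). Accuracy tables count correct vs
incorrect calls at overlap cutoffs {0.1, 0.3, 0.5, 1.0}. Chimeric
*collapses* are pairwise within-contig overlaps between reads of different
organisms; each records the pair's LCA rank and the function of the overlap
region (mapped through the lower-offset read; `unannotated` when no ORF
covers it). Over-represented collapse functions are labels whose count
exceeds Q3 + 1.5·IQR of the label-count distribution (the standard boxplot
fence) and whose relative abundance among annotated collapses exceeds 1%.

## Cross-assembly reports

Spearman rank correlations over the statistic columns with two-sided
p-values from the t-approximation (constant columns yield undefined
markers); complete-linkage agglomerative clustering on Euclidean distances
between correlation-matrix rows (rows pre-sorted by label for deterministic
tie-breaking); correlation-based PCA (columns standardized, eigenvalues sum
to the number of retained columns, each loading's largest entry made
positive for a reproducible orientation).

## Problem sizes and numerical choices

The packaged experiments run on one CPU in well under a minute each: the
optimal-assembly invariants use 25 genomes × 20,000 reads (~43× depth); the
chimera-recovery fixture uses 300 genomes × 6,000 reads at ~2× depth, which
fragments the optimal assembly into ~800 contigs — enough statistical power
for the ±3σ binomial recovery check; classifier benchmarks use 200-read
query sets against ~20–44 genome databases, the scale of the original
taxon-exclusion protocol. Score-tie tolerance is 10⁻⁹; KL tie tolerance
10⁻¹²; all randomness flows from explicit integer seeds and every simulated
artifact is byte-reproducible.

## What passing does and does not show

The generator emulates ranked lineages, clade-specific composition,
conserved shared genes, log-normal abundances and 454-style errors. It does
not emulate repeats and genome rearrangements, strain-level microdiversity,
horizontal transfer beyond the fixed shared segments, GC-dependent coverage
bias, chimeric *reads*, or database annotation errors. Green results
therefore validate the benchmark machinery (the metrics, the oracle
assembly, the classifier harness) — they do not predict the absolute
performance of any particular assembler or classifier on real virome data,
where those unmodelled features dominate.
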