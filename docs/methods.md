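# Methods

## Scope and model

germtag quantifies mapped chromatin-profiling fragments over genomic
intervals and derives three analyses from those counts: promoter
activation timing across stage-arrest genotypes, germline-enrichment and
expression staging of genes from a cluster-averaged single-nucleus testis
atlas, and chromosome-scale dosage statistics. Read mapping, duplicate
removal and peak calling are upstream concerns: the package consumes
fragment intervals (BED3+), a GTF annotation, a chromosome-sizes table,
and a clusters × genes expression matrix with a germline/somatic cluster
annotation.

## Coordinates and counting

GTF input (1-based inclusive) is converted exactly once to 0-based
half-open coordinates on parse; all internal structures and all BED and
bedGraph output use the half-open convention. A fragment is counted once
in every interval it overlaps by at least one base; abutting half-open
intervals share no fragment. Counting uses a sorted-endpoint identity
(overlaps of [s, e) = #starts < e minus #ends ≤ s), which is exact and
O((n + m) log n); the test suite checks it against an all-pairs
brute-force oracle.

## Promoter table

Each transcript's TSS is its minimum feature coordinate on '+', maximum on
'−'. Within a gene, duplicate TSS coordinates collapse to one promoter;
the same coordinate shared by distinct genes yields one promoter per gene.
The scoring window spans 200 bp upstream through 500 bp downstream of the
TSS inclusive — 701 bp unless clipped at a chromosome end. The window is
strand-oriented by default; the alternative genomic left-to-right reading
is available via `oriented=False`, since either convention is defensible
and the choice is immaterial to downstream statistics as long as it is
fixed. Upstream-neighbor detection finds, for each promoter, the nearest
promoter of a *different* gene lying 5′ in the promoter's own orientation
(a shared coordinate counts at distance 0; ties break on gene id); the
1-kb flag marks promoters whose average profiles would overlap a
neighbor's signal.

Gene bodies for CPKM scoring are union spans (min start, max end over the
gene's transcripts), the simplest multi-isoform convention.

## Scaling and z-scores

CPM = counts × 10⁶ / library size; CPKM = CPM / (interval length in kb);
both exact formulas, no effective-genome-size correction. Binned coverage
uses consecutive fixed-width bins (default 20 kb) from position 0, scaled
CPM-per-bin; library-size scaling suffices for within-genome comparisons,
and in log2 bin ratios it cancels entirely. The log2 ratio of two tracks
adds a pseudocount ρ (default 1 CPM-bin unit) to both terms to keep empty
bins finite.

Cross-genotype z-scores standardize each interval's CPM over the genotype
triple using the population SD (n = 3). With three values the
population/sample choice only rescales z by a constant and cannot change
any ordering, but it is fixed so that results are exactly reproducible;
zero-variance intervals get z = 0.

## Atlas summaries and staging

Cluster averaging is the arithmetic mean of the supplied normalized
expression values per cluster; the normalization of the input matrix is
the caller's responsibility. gexp/sexp are means over germline/somatic
clusters, excluding the unannotated cluster from both. The enrichment
ratio log2((gexp + ε)/(sexp + ε)) uses ε = 0.01 (configurable): the ratio
is undefined at sexp = 0, and the pseudocount keeps it finite without
moving the ≥ 1 decision for well-expressed genes. Genes absent from the
atlas are reported as missing (#N/A in output), never silently dropped.

Staging clusters genes by k-means (k = 10, k-means++ with 50 restarts,
fixed seed) on per-gene z-scored profiles over all annotated clusters,
germline first in developmental order. Row z-scoring is essential: without
it absolute expression level dominates and stage structure is
unrecoverable. Each k-cluster is called germline- or somatic-associated by
comparing its centroid's mean over germline vs somatic columns;
somatic-associated clusters collapse into one group (label 11), and
germline-associated clusters are numbered 1..n by their centroid's peak
position along the germline cluster order — the natural assignment of
k-clusters to developmental stages when no explicit rule is given.
Germline-cluster z-score profiles for display use the population SD per
gene, with zero-variance rows set to zero.

## Dosage statistics

Pipeline order mirrors the display convention: per-gene CPKM per
condition; discard genes with a zero score in any compared condition;
double X- and Y-linked scores to per-copy densities (the fourth chromosome
is diploid and is not doubled, despite its X-derived evolutionary
history); divide by the median per-copy score of second/third-chromosome
genes, making the scaled major-autosome median exactly 1. Doubling raw
counts or doubled CPKM are equivalent under these linear formulas; the
invariant tests assert this scale-invariance. Summaries report median and
linear-interpolation quartiles per chromosome class.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
sequence-level reality: no reads, no mapping, no repeat structure —
fragment intervals are emitted directly.

* Genome: seven scaffolds (four arms of 2 Mb with 120 genes each, a 0.5-Mb
  fourth chromosome with 10 genes, a 1.5-Mb X with 100 single-copy genes,
  a 0.8-Mb Y with 12 long single-copy genes of 55–64 kb, echoing the
  megabase-scale fertility factors so gene bodies tile most 20-kb Y bins).
  Genes are placed without overlap via Dirichlet-distributed gaps and get
  random strands.
* Fragments: per-gene Poisson counts with rate copies × per-copy rate ×
  chromosome factor × genotype stage weight, where the per-copy rate is
  15 fragments/kb of gene body × a lognormal(0, 0.5) per-gene amplitude
  shared with the expression atlas. Fragment midpoints are uniform over
  the gene body ("body" mode, elongating-polymerase-like), uniform over
  the promoter window ("promoter" mode), or a 50:50 TSS-proximal/body
  mixture ("peaked" mode, somatic promoter-proximal accumulation).
  Lengths are normal(250, 100) clipped to [50, 700] bp. A uniform genomic
  background adds 10% of the genic total.
* Condition factors: "wing" (somatic) has X factor 2 (compensated) and Y
  factor 0.05 (heterochromatic); "spermatocyte" has X factor 1
  (uncompensated), Y factor 8 (activated), fourth 0.5. The genotype trio
  (bam/aly/wildtype) instead weights genes by stage: bam 10× on stage-1
  genes, aly on stages 2–3, wildtype on stages 4–5.
* Atlas: 18 ordered germline clusters, 21 somatic, 1 unannotated. A
  germline gene of stage a expresses amplitude × (Gaussian bump_a over the
  germline order, width 2 clusters) plus a 0.02 baseline elsewhere;
  somatic genes mirror this with five archetypes over the somatic
  clusters, so k = 10 resolves the planted partition into five germline
  and five somatic groups. Additive profile noise (SD 0.1 relative to
  amplitude, clipped at zero) keeps archetype separation an order of
  magnitude above noise. Five percent of genes are withheld from the
  atlas to exercise the missing-gene path.

Everything downstream of a fixed seed is byte-reproducible.

What passing synthetic tests does *not* show: robustness to mappability
artifacts, duplicate fragments, repeat-masking edge effects, cluster
misannotation in the atlas, or biological dispersion beyond Poisson; real
libraries also couple expression and chromatin signal far more loosely
than the shared-amplitude model.

## Study scenarios and problem sizes

The scenario module fixes the conditions under which recovery is
measured. The dosage scenario plants one fixed per-copy rate per
chromosome class (amplitude dispersion off): autosomes at 2 copies × r, X
at 1 copy × 2r (compensated) or r (uncompensated), with 500 genes per
class at equal gene density (16 kb/gene, so neighbor-fragment spillover is
symmetric between classes) and ≥ 50 expected fragments per gene copy; the
median scaled X score recovers the planted factor within a few percent
over 10 seeds. The staging scenario uses the default ~600-gene genome and
scores the k-means partition by adjusted Rand index against the planted
stages. The Y-activation scenario compares 20-kb tracks between the
default wing and spermatocyte conditions and reports the fraction of Y
bins with a positive log2 ratio. These sizes keep the full recovery suite
in the tens of seconds while leaving all medians' sampling error well
inside the bands being checked.

## Degenerate inputs and numerical choices

Empty libraries refuse CPM/coverage scaling (no denominator); empty
promoter tables propagate to empty outputs with a warning rather than an
error; k-means on fewer distinct profiles than k reports the empty
clusters; zero-variance rows in any z-score yield zeros; the
autosome-median scaler raises when the median is zero. Chromosome-name
dialects ("2L" vs "chr2L") are normalized to bare names on input. Library
size defaults to the number of accepted fragments; out-of-bounds records
are rejected and counted, never silently dropped.

## Known limitations

Fragment counting is single-unit per template (no per-mate mode yet).
Cluster discovery, UMAP, QC and doublet handling are out of scope —
clusters are taken as given. No statistical test accompanies the dosage
medians (the statistic of interest is the median itself). CIRCOS-style
rendering is not included; the exported bedGraph/TSV layers are the
contract.
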