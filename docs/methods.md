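# Methods

`rpggkit` genotypes variable-number tandem repeats (VNTRs; tandem arrays of
motifs longer than 6 bp, 150 bp–10 kbp total) from short paired-end reads by
aligning them to a *repeat-pangenome graph* (RPGG): a collection of
per-locus bidirectional de Bruijn graphs built from multiple
haplotype-resolved assemblies. This note documents the model, the algorithmic
and numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.

## Locus definition and boundary harmonization

Raw tandem-repeat annotations (e.g. Tandem Repeats Finder output) are
filtered to motif length > 6 bp and total length strictly between 150 bp and
10 kbp, then lifted onto each haplotype through a correspondence table.
Because repeat boundaries are ill-defined and annotation fragments on long
or impure arrays, boundaries are *harmonized* before graph construction:
the invariant sought is that no haplotype's 700 bp flank shares a canonical
k-mer with the union of all haplotypes' VNTR k-mers at that locus. While
violated, the offending haplotype's boundary moves outward to just past the
most distal offending k-mer and the k-mer union is recomputed; haplotypes
are processed in row order, making the fixed point deterministic. The
boundary step lands directly on the offending k-mer rather than advancing
by a fixed increment — fewer iterations, same fixed point. Expansion beyond
10 kbp in either direction marks the haplotype failed; a flank running off
the contig marks it near-breakpoint.

QC then proceeds in a fixed order: (1) drop near-breakpoint/failed
haplotypes and haplotypes whose reference anchor lies more than 1 kb from
the per-locus median (orthology discordance; ties are resolved
conservatively by dropping the discordant rows); (2) drop loci supported by
fewer than 90% of haplotypes; (3) merge loci that come within 700 bp of
each other on any haplotype (union-find over inducing pairs; the merged
interval is the hull; haplotypes whose adjacency call is in the strict
minority — or tied — are dropped from the merged locus); (4) drop loci
supported by fewer than 80%. On clean synthetic data the pipeline returns
the planted intervals exactly.

The flank length of 700 bp approximates the upper bound of the insert size
of typical short-read libraries, so a read pair anchored in a flank can
still reach the repeat.

## Graph model

k-mers are packed two bits per base into 64-bit integers (k ≤ 31; default
k = 21, configurable 17–25 — downstream results are insensitive in this
range). The canonical form is the smaller of a k-mer and its reverse
complement; unsigned comparison of packings equals lexicographic comparison
on ACGT. A locus graph has one vertex per canonical k-mer of the locus
region (VNTR plus 700 bp flanks, over all haplotypes) and one edge per
canonical (k+1)-mer, which deduplicates an edge with its reverse
complement exactly as a bidirectional de Bruijn graph requires. Occurrence
counts are kept separately for VNTR-interval k-mers and flank k-mers; a
k-mer overlapping the VNTR/flank junction is counted as VNTR — the
conservative choice for length estimation (at most k−1 boundary k-mers per
end, a ≤ 2(k−1)-base edge effect on a length estimate).

The RPGG is the set of locus graphs plus a global index from canonical
k-mer to the loci containing it; the same k-mer may live in several locus
graphs, a deliberate departure from a single genome-wide de Bruijn graph.
Pruning deletes k-mers with no support in reads aligned with error
correction disabled (assembly consensus artifacts) together with incident
edges; merging per-genome graphs unions vertices and edges and sums counts.
Pruning never increases a count, merging never decreases one. Graphs
serialize to GFA v1 (one S line per canonical k-mer with a `KC:i:` count
tag, L lines with k−1 overlap).

## Read alignment

Alignment is three-phase and entirely k-mer based:

1. **Locus assignment.** The pair's canonical k-mer multisets are scored
   against the index; the locus with the largest intersection wins if each
   end shares more than `cth = 45` k-mers with it and the shared fraction
   over the pair is at least `rth = 0.5`. Exact ties break to the lower
   locus id.
2. **Threading.** Each mate's k-mers are walked along the locus graph as a
   continuous path/cycle (consecutive k-mers must be vertices joined by an
   observed (k+1)-mer edge). At a failure, the first base that
   distinguishes the failing k-mer (read position `i + k − 1`) is edited:
   3 substitutions, 4 insertions, 1 deletion, in that fixed order, accepting
   the first candidate that extends the path; no backtracking. Each mate
   has an edit budget of 2. A pair is feasible when both mates thread at
   least `thcth` k-mers (default 50; `thcth = ceil((read_len − k + 1) ×
   0.9) = 117` at 150/21 enforces ≥ 90% identity for every aligned pair).
   Because vertices and edges are canonical, threading is strand-symmetric
   and no orientation search is needed.
3. **Counting.** For feasible pairs, canonical k-mers present in the locus'
   VNTR region are counted (never flank k-mers), yielding the per-sample
   per-locus sum `kms` and, optionally, per-k-mer count vectors.

The greedy edit rule is a documented simplification: errors within the
first k−1 bases of a read cannot seed a path and such reads may fail; with
two edits per mate this affects a small minority of error-carrying reads
and no error-free reads.

## Length genotyping

If sample *s* were sequenced uniformly at depth `cov_s`, `kms` would equal
`cov_s × L` with `L` the diploid mean locus length (mean over H haplotypes;
H = 1 for effectively haploid samples). Real coverage deviates per locus by
the locus-specific sampling bias `b_{s,l} = kms / (cov_s × L)`, estimable
only where assembly truth exists. `cov_s` comes from averaging read depth
over repeat-free control regions. For a new sample, the bias vector is
borrowed from the reference sample maximizing squared Pearson correlation
of control-region depth profiles, restricted to the same sequencing run
when labels exist (ties break on sample id); the length estimate is
`kms / (cov_s × b̂)`. Loci with `b̂ = 0` are reported missing, never
infinite. Locus QC first requires mean alignment quality ≥ 0.96, where
aln-r² is the squared correlation between assembly-derived and
read-derived per-k-mer counts over the genotyped individual's k-mer set
(defined as 0 for fewer than two distinct k-mers or zero variance; note r²
is direction-blind, so perfect anticorrelation also scores 1 — kept as
defined). The read-depth baseline divides per-locus aligned bases by
global depth and therefore inherits local sampling bias — the failure mode
the borrowed-bias correction removes. Evaluation uses mean absolute
percentage error (zero-truth loci excluded and counted) and per-genome
accuracy, defined here as squared Pearson correlation of estimates versus
truths across loci. Leave-one-out evaluation rebuilds the reference bias
set without the held-out sample and never touches its truth.

## Population statistics

k-mer dosage `kms/cov` proxies locus length. V_ST partitions dosage
variance: `max(0, (var_all − Σ n_i var_i / n_T) / var_all)`, with
population variances on denominator n (not n−1) so the between-population
form `Σ n_i (μ_i − μ_T)² / (n_T σ_T²)` is an exact identity (tested to
1e-12). Top loci are flagged at mean + 3 SD of V_ST across loci. V_ST
decreases as within-population variance inflates with means held fixed.

The unstable-locus screen works per population and locus: individuals with
dosage < 10 are discarded; the remaining distribution must be strongly
unimodal (Hartigan dip test p > 0.9 against a uniform-sample reference,
B = 200 seeded bootstraps — the uniform is the least-favourable unimodal
reference, so this gate is deliberately strict and also rejects a fraction
of genuinely unimodal loci); individuals at or above mean + 6 SD are
flagged. Candidate loci containing an individual that is an outlier at ≥ 4
other loci are removed (systematically aberrant genomes, not locus
instability). The dip statistic is implemented from the classic
convex-minorant/concave-majorant iteration and validated against a linear-
programming brute force over unimodal CDFs and the closed-form two-point
value of 1/4.

Differential motif usage compares two populations through the *most
informative k-mer* (mi-kmer): a lasso of VNTR length on per-k-mer dosage in
the reference population, penalty scanned 0.9, 0.8, … 0.1 until some
coefficient is positive (both sides z-scored so the penalty scale is
unit-free; untestable if none). Statistics: the difference in population
median mi-kmer counts (usage) and in the proportion of length variance the
mi-kmer explains (expansion). Nulls are built by resampling the reference
population with replacement N_A + N_B times and splitting into pseudo
populations; p = (1 + #{|T*| ≥ |T|}) / (1 + B), B = 1000 by default, RNG
seeded. Under the null, ~1% of loci are flagged at p < 0.01 (calibration
tested within the exact binomial interval).

Sample outliers are removed by DBSCAN on column-standardized control-region
depths concatenated with dosages; `eps` defaults to twice the median
distance to the `min_samples`-th nearest neighbour (adaptive and
deterministic), and a parameterization flagging every sample is rejected.

## eQTL mapping

Genotype is depth- and ploidy-adjusted dosage (divided by 2 for diploids),
z-scored per locus. Expression is residualized against the covariate matrix
(intercept required; rank-deficiency is an error naming the collinear
columns) via least squares — numerically identical to the projection
(I − H)Y′ — then z-scored per gene; genes left with zero residual variance
are dropped with a warning. Residualization is idempotent to 1e-10. Pairs
are tested when the closest-edge gap between the VNTR interval and the gene
body is ≤ 100 kb (gene-body distance chosen over TSS distance; overlap is
distance 0). Simple linear regression per pair gives a slope (equal to the
Pearson correlation on z-scored data), a two-sided t-test p-value, per-gene
Bonferroni adjustment, a lead VNTR per gene (smallest adjusted p; ties by
distance then locus id), and Benjamini–Hochberg at 5% across genes' lead
adjusted p-values — at most one eVNTR per gene. Zero-variance genotypes
are skipped and counted.

## Synthetic data

The generator emulates every input with known truth. Haplotypes are one
contig per haplotype; each locus is a tandem motif array (uniform copy
number in a configurable range) between locus-specific flanks shared by all
haplotypes, drawn i.i.d. over ACGT and redrawn until they share no
canonical k-mer with any repeat array — giving boundary expansion a clean
baseline. Coordinates are 0-based half-open; sequences uppercase ACGT with
no N. A dirty-flank mode plants `ceil((k−1)/|motif|)+1` motif copies 30 bp
into the shared 3′ flank (enough to guarantee a fully periodic shared
k-mer for any motif length), forcing expansion on every haplotype.
Populations differ by copy-number shifts and by per-copy probability of a
fixed two-substitution motif variant. Read pairs are FR with a 600 bp
insert (300 bp gap at 150 bp reads); tiling mode enumerates start positions
(optionally strided), sampled mode draws starts at a target coverage with
per-locus bias multipliers; errors are i.i.d. substitutions only.
Sequencing-run structure: samples in a run share a per-locus bias vector
(uniform in 1.5–2 by default) and a control-region depth profile, each with
multiplicative lognormal noise (1% by default), so nearest-neighbour
selection on control depths recovers run membership. kms matrices can be
drawn directly from the generative model Poisson(cov × bias × length).
Expression is β·z(dosage) + Cγ + standard-normal noise with planted
(gene, locus, β) triples.

One seed fixes all randomness end-to-end; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: assembly errors and phasing
switches, indel sequencing errors, GC-dependent coverage, nested or
degenerate motif structure, mobile-element homology between loci, linkage
between loci, and genome-scale read volumes. Passing tests therefore show
algorithmic correctness and calibration under the modelled noise processes,
not performance on real cohorts.

## Problem sizes used in the bundled experiments

The alignment-fidelity experiment uses 200 loci × 10 diploid genomes
(motifs 7–30 bp, 5–100 copies), error-free tiling pairs strided every 25
start positions (~3×10⁵ pairs), thresholds 45/117/2; it reports the
percentage of aligned pairs at ≥ 90% identity. The leave-one-out
length-prediction experiment uses 50 loci × 12 genomes in 2 runs, coverage
~30×, planted 1.5–2× biases. Calibration runs use 500 null motif loci
(B = 1000), 600 null eQTL pairs at n = 200, and 20 planted effects
(β ≥ 0.3, n = 500) among 500 null genes. These sizes are the package's
reference configuration for desk-scale reproduction; all are parameters.

## Known limitations

Threading reports counts, not traversal paths; repeat dosage is continuous,
so discrete genotypes and linkage disequilibrium are out of reach. The
greedy single-pass edit search can miss repairs near read starts. The dip
p-value uses a uniform reference rather than interpolated lookup tables, so
very small samples are conservative. DBSCAN outlier removal depends on its
scale parameter; the adaptive default is reasonable for homogeneous cohorts
but should be inspected on heterogeneous ones.
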