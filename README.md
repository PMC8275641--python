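# rpggkit

Toolkit for genotyping variable-number tandem repeats (VNTRs) from short
paired-end reads using **repeat-pangenome graphs** (RPGGs).

VNTRs — tandem arrays of motifs longer than 6 bp, here 150 bp to 10 kbp in
total — are hypervariable in both copy number and motif composition, and
reads from them align poorly to a single linear reference. `rpggkit`
instead builds, for every VNTR locus, a bidirectional de Bruijn graph over
the locus and its 700 bp flanks from multiple haplotype-resolved
assemblies; the collection of locus graphs (plus a global k-mer → locus
index) is the RPGG. Short reads are aligned to the RPGG by k-mer threading,
and the resulting per-locus k-mer counts drive length genotyping,
population analyses and eQTL mapping.

The core quantities, for sample *s* and locus *l* with diploid mean truth
length *L*<sub>g,l</sub> (mean over the genome's *H* haplotypes):

- locus-specific sampling bias (LSB):
  *b*<sub>s,l</sub> = kms<sub>s,l</sub> / (cov<sub>s</sub> · *L*<sub>g,l</sub>),
  where kms is the summed VNTR k-mer count mapped by *s* and cov the global
  depth from repeat-free control regions;
- length prediction with a borrowed bias vector:
  *L*<sub>s,l</sub> = kms<sub>s,l</sub> / (cov<sub>s</sub> · *b̂*<sub>l</sub>),
  *b̂* taken from the reference sample whose control-region depth profile
  maximizes r² with the query's (same sequencing run when known);
- k-mer dosage kms/cov as a length proxy for population statistics, with
  stratification measured by
  V<sub>ST</sub> = max(0, (σ²<sub>T</sub> − Σ n<sub>i</sub>σ²<sub>i</sub>/n<sub>T</sub>) / σ²<sub>T</sub>);
- cis-association of z-scored dosage with covariate-residualized expression
  (Y = (I − H)Y′, H = C(CᵀC)⁻¹Cᵀ), per-gene Bonferroni, gene-level
  Benjamini–Hochberg FDR on lead VNTRs.

A synthetic-data module generates complete cohorts — diploid haplotypes
with planted VNTRs, reads with configurable error and per-locus coverage
bias, population structure in length and motif usage, expression with
planted effects — so every stage is testable end-to-end with known truth.

## Worked example

Build an RPGG from a small synthetic cohort and align error-free tiling
read pairs back to it:

```python
from rpggkit.simulate import SimConfig, gen_population, sim_reads, locus_regions
from rpggkit.graph import build_rpgg
from rpggkit.aligner import AlignParams, align_sample, threading_threshold

cfg = SimConfig(n_loci=5, n_genomes=2, copy_number_range=(10, 25), seed=31)
haps, truth, catalog = gen_population(cfg)
rpgg = build_rpgg(catalog.regions(haps), k=21)
print(len(rpgg.loci), rpgg.n_vertices())        # 5 7088

pairs = sim_reads(haps, cfg, mode="tiling", regions=locus_regions(truth), step=10)
params = AlignParams(thcth=threading_threshold())   # ceil(130 * 0.9) = 117
kms, _, stats = align_sample(pairs, rpgg, params)
print(stats.as_dict())
# {'pairs': 2256, 'assigned': 2256, 'feasible': 2256, 'identity_ge_90': 2256}
print(kms)
# {0: 39000, 1: 39208, 2: 41106, 3: 43342, 4: 14456}
```

All 2,256 pairs are assigned to a locus, thread feasibly (at threshold 117
every aligned pair has ≥ 90% identity by construction), and the kms counts
track the planted lengths: locus 4, the shortest (cohort mean 119 bp
versus 355–397 bp for loci 0–3), collects proportionally fewer VNTR
k-mers (14,456 versus ~39,000–43,000). Dividing kms by coverage and a
matched-run bias vector returns length estimates; see
`rpggkit.evaluation.length_prediction_experiment` for the leave-one-out
experiment in which bias correction reaches ~1% mean absolute percentage
error while the naive read-depth baseline, confounded by planted 1.5–2×
sampling bias, errs by ~74%.

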