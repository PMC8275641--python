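"""Synthetic diploid genomes with planted VNTRs, reads, coverage bias and
expression.

The generator emulates the inputs of the repeat-pangenome workflow with
known ground truth: each genome carries two haplotypes (one contig per
haplotype) in which VNTR loci — tandem arrays of a motif longer than 6 bp —
are embedded in random flanking sequence.  Flanks are screened to share no
k-mer with any locus' repeat array so that boundary harmonization has a
clean baseline; a "dirty flank" mode deliberately plants extra motif copies
inside flanks to exercise boundary expansion.  Population structure is
modelled as per-population shifts in mean copy number and per-population
motif variants; sequencing-run structure as shared per-locus sampling-bias
vectors.  All randomness flows from a single seed.

Coordinates are 0-based half-open; sequences are uppercase ACGT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kmers import revcomp, seq_to_canonical_codes

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Motifs must be longer than 6 bases (the VNTR definition); copy numbers
    at least 1.  ``coverage`` is fold genome coverage for sampled reads;
    ``error_rate`` the per-base substitution probability.
    """

    n_loci: int = 20
    n_genomes: int = 4
    motif_pool: Sequence[str] = ()
    copy_number_range: tuple[int, int] = (5, 100)
    flank_len: int = 700
    read_len: int = 150
    insert_len: int = 600
    coverage: float = 30.0
    error_rate: float = 0.0
    k: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.motif_pool:
            if len(m) <= 6:
                raise ValueError(f"motif {m!r} not longer than 6 bp")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise ValueError("copy numbers must be >= 1 and lo <= hi")
        if self.insert_len < self.read_len:
            raise ValueError("insert_len must be >= read_len")


@dataclass
class PopulationSpec:
    """One population's deviation from the base simulation parameters.

    ``copy_shift`` is added to every copy-number draw; ``variant_motif_p``
    is the per-copy probability of using the population's variant motif
    (two fixed substitutions of the locus motif), creating differential
    motif usage between populations.
    """

    name: str
    n_genomes: int
    copy_shift: int = 0
    variant_motif_p: float = 0.0


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def random_motif(rng: np.random.Generator, min_len: int = 7, max_len: int = 30) -> str:
    return random_seq(rng, int(rng.integers(min_len, max_len + 1)))


def _variant_of(motif: str) -> str:
    """A fixed two-substitution variant of a motif (deterministic)."""
    out = list(motif)
    for pos in (0, len(motif) // 2):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + 1) % 4]
    return "".join(out)


def _mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def gen_population(
    config: SimConfig,
    pops: Sequence[PopulationSpec] | None = None,
    dirty_flank: bool = False,
    per_copy_mutation: float = 0.0,
):
    """Generate haplotype sequences, a truth table and a locus catalog.

    Returns ``(haplotypes, truth, catalog)`` where ``haplotypes`` maps
    contig names ``<genome>.<hap>.chr1`` to sequences, ``truth`` is a
    DataFrame with one row per (genome, haplotype, locus) giving the
    planted interval, motif, copy number and true length, and ``catalog``
    is the identity :class:`~rpggkit.annotation.LocusCatalog` built from
    the truth intervals.

    Each locus is a tandem motif array embedded between locus-specific
    flanks shared by all haplotypes (homologous flanks); flanks are
    rejected and redrawn if they share any canonical k-mer with the union
    of repeat arrays.  ``dirty_flank`` plants one extra motif copy 30
    bases into the (shared) 3' flank of every locus, so boundary
    expansion must move every haplotype's boundary outward past it.
    """
    from .annotation import LocusCatalog

    rng = np.random.default_rng(config.seed)
    if pops is None:
        pops = [PopulationSpec("POP", config.n_genomes)]
    if sum(p.n_genomes for p in pops) != config.n_genomes:
        raise ValueError("populations must partition the genomes")

    motifs = [
        config.motif_pool[int(rng.integers(0, len(config.motif_pool)))]
        if config.motif_pool
        else random_motif(rng)
        for _ in range(config.n_loci)
    ]

    genome_pop: list[tuple[str, PopulationSpec]] = []
    gi = 0
    for p in pops:
        for _ in range(p.n_genomes):
            genome_pop.append((f"g{gi}", p))
            gi += 1

    lo, hi = config.copy_number_range
    # draw every repeat array first so flanks can be screened against them
    arrays: dict[tuple[str, int, int], str] = {}
    rows = []
    for genome, pop in genome_pop:
        for hap in (0, 1):
            for lid in range(config.n_loci):
                copies = int(rng.integers(lo, hi + 1)) + pop.copy_shift
                copies = max(1, copies)
                motif = motifs[lid]
                vm = _variant_of(motif)
                parts = []
                for _ in range(copies):
                    m = vm if rng.random() < pop.variant_motif_p else motif
                    parts.append(_mutate_seq(rng, m, per_copy_mutation))
                arr = "".join(parts)
                arrays[(genome, hap, lid)] = arr
                rows.append(
                    {
                        "genome": genome,
                        "population": pop.name,
                        "hap": hap,
                        "locus": lid,
                        "motif": motif,
                        "copies": copies,
                        "length": len(arr),
                    }
                )

    repeat_kmers: set[int] = set()
    for arr in arrays.values():
        repeat_kmers.update(seq_to_canonical_codes(arr, config.k).tolist())

    def clean_flank(length: int) -> str:
        while True:
            s = random_seq(rng, length)
            codes = set(seq_to_canonical_codes(s, config.k).tolist())
            if not codes & repeat_kmers:
                return s

    pad = config.insert_len  # extra sequence at contig ends and between loci
    left_flanks = [clean_flank(config.flank_len + pad) for _ in range(config.n_loci)]
    right_flanks = [clean_flank(config.flank_len + pad) for _ in range(config.n_loci)]
    if dirty_flank:
        for lid in range(config.n_loci):
            gap = clean_flank(30)
            rf = right_flanks[lid]
            right_flanks[lid] = gap + motifs[lid] + rf[len(gap) + len(motifs[lid]) :]

    haplotypes: dict[str, str] = {}
    truth = pd.DataFrame(rows)
    truth["contig"] = ""
    truth["start"] = 0
    truth["end"] = 0
    truth = truth.set_index(["genome", "hap", "locus"])
    for genome, _pop in genome_pop:
        for hap in (0, 1):
            contig = f"{genome}.{hap}.chr1"
            segs: list[str] = []
            offset = 0
            for lid in range(config.n_loci):
                rf = right_flanks[lid]
                arr = arrays[(genome, hap, lid)]
                segs.append(left_flanks[lid])
                offset += len(left_flanks[lid])
                truth.loc[(genome, hap, lid), ["contig", "start", "end"]] = (
                    contig,
                    offset,
                    offset + len(arr),
                )
                segs.append(arr)
                offset += len(arr)
                segs.append(rf)
                offset += len(rf)
            haplotypes[contig] = "".join(segs)
    truth = truth.reset_index()

    catalog = LocusCatalog.from_truth(truth, flank_len=config.flank_len)
    return haplotypes, truth, catalog


def diploid_lengths(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-genome diploid mean VNTR length: mean of the H haplotype lengths
    (H=2 here; effectively haploid genomes would use H=1)."""
    return truth.pivot_table(index="genome", columns="locus", values="length", aggfunc="mean")


# ---------------------------------------------------------------------------
# reads


def sim_reads(
    haplotypes: Mapping[str, str],
    config: SimConfig,
    mode: str = "tiling",
    bias: Mapping[str, float] | None = None,
    bias_regions: Mapping[str, list[tuple[int, int, int]]] | None = None,
    regions: Sequence[tuple[str, int, int, int]] | None = None,
    step: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate FR paired-end reads.

    ``tiling`` emits a pair at every ``step``-th start position of each
    template (deterministic; ``step=1`` covers every k-mer).  ``sampled``
    draws pair start positions at the target coverage, multiplying the
    sampling weight inside a locus by its bias factor (``bias`` keyed by
    locus id via ``bias_regions``: contig -> [(start, end, locus)]).
    Substitution errors are i.i.d. at ``config.error_rate``.

    ``regions`` restricts simulation to (contig, start, end, locus)
    windows; read names encode the template of origin as
    ``<contig>|<start>|<locus>`` for downstream evaluation.

    Returns a list of (name, read1, read2) with read2 reverse-complemented
    (FR orientation, gap = insert - 2*read_len).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl, il = config.read_len, config.insert_len
    templates: list[tuple[str, int, str, int]] = []  # contig, offset, seq, locus
    if regions is not None:
        for contig, s, e, lid in regions:
            templates.append((contig, s, haplotypes[contig][s:e], lid))
    else:
        for contig, seq in haplotypes.items():
            templates.append((contig, 0, seq, -1))

    out: list[tuple[str, str, str]] = []
    for contig, off, seq, lid in templates:
        n = len(seq) - il + 1
        if n <= 0:
            warnings.warn(f"template {contig}:{off} shorter than insert, skipped")
            continue
        if mode == "tiling":
            starts = np.arange(0, n, step)
        elif mode == "sampled":
            n_pairs = int(round(config.coverage * len(seq) / (2 * rl)))
            if bias is not None and bias_regions is not None:
                w = np.ones(n)
                for s, e, b_lid in bias_regions.get(contig, []):
                    s0, e0 = max(0, s - off), min(n, e - off)
                    if e0 > s0:
                        w[s0:e0] *= bias.get(b_lid, 1.0)
                w /= w.sum()
                starts = rng.choice(n, size=n_pairs, p=w)
            else:
                starts = rng.integers(0, n, size=n_pairs)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for i in starts.tolist():
            r1 = seq[i : i + rl]
            r2 = revcomp(seq[i + il - rl : i + il])
            if config.error_rate > 0:
                r1 = _mutate_seq(rng, r1, config.error_rate)
                r2 = _mutate_seq(rng, r2, config.error_rate)
            out.append((f"{contig}|{off + i}|{lid}", r1, r2))
    return out


def locus_regions(
    truth: pd.DataFrame, flank_len: int = 700
) -> list[tuple[str, int, int, int]]:
    """(contig, start, end, locus) windows covering each planted VNTR plus
    its flanks, suitable for the ``regions`` argument of :func:`sim_reads`."""
    out = []
    for row in truth.itertuples():
        out.append(
            (row.contig, max(0, row.start - flank_len), row.end + flank_len, row.locus)
        )
    return out


# ---------------------------------------------------------------------------
# coverage bias and k-mer count matrices


def gen_depth_bias(
    samples: Sequence[str],
    run_labels: Mapping[str, str],
    n_loci: int,
    n_controls: int = 40,
    bias_range: tuple[float, float] = (1.5, 2.0),
    noise_sd: float = 0.01,
    seed: int = 0,
):
    """Per-sample per-locus sampling-bias factors plus control-region depths.

    Samples sharing a sequencing run share the run's locus-bias vector
    (drawn uniformly from ``bias_range``) and control-region depth profile,
    each perturbed by i.i.d. multiplicative lognormal noise of scale
    ``noise_sd``; this makes nearest-neighbour selection on control-region
    depth recover run membership.

    Returns ``(bias, rd)``: DataFrames indexed by sample with locus and
    control-region columns respectively (rd is relative depth, ~1).
    """
    if not set(run_labels) >= set(samples):
        raise ValueError("every sample needs a run label")
    runs = sorted({run_labels[s] for s in samples})
    rng = np.random.default_rng(seed)
    run_bias = {r: rng.uniform(*bias_range, size=n_loci) for r in runs}
    run_rd = {r: rng.uniform(0.7, 1.3, size=n_controls) for r in runs}
    bias_rows, rd_rows = [], []
    for s in samples:
        r = run_labels[s]
        noise_b = rng.lognormal(0.0, noise_sd, size=n_loci)
        noise_d = rng.lognormal(0.0, noise_sd, size=n_controls)
        bias_rows.append(run_bias[r] * noise_b)
        rd_rows.append(run_rd[r] * noise_d)
    bias = pd.DataFrame(bias_rows, index=list(samples))
    rd = pd.DataFrame(rd_rows, index=list(samples))
    return bias, rd


def gen_kms(
    lengths: pd.DataFrame,
    cov: pd.Series,
    bias: pd.DataFrame,
    seed: int = 0,
    poisson: bool = True,
) -> pd.DataFrame:
    """Synthesize a sample x locus k-mer count (kms) matrix from the
    generative model kms = cov * bias * length, optionally with Poisson
    sampling noise.  ``lengths`` rows are aligned to ``bias`` rows."""
    rng = np.random.default_rng(seed)
    lam = lengths.values * bias.values * cov.values[:, None]
    kms = rng.poisson(lam).astype(float) if poisson else lam
    return pd.DataFrame(kms, index=bias.index, columns=lengths.columns)


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    dosage: pd.DataFrame,
    effects: Iterable[tuple[str, object, float]] = (),
    n_genes: int = 100,
    covariates: pd.DataFrame | None = None,
    gamma_scale: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix with planted VNTR effects.

    Y' = beta * z(dosage) + C gamma + noise, with standard-normal noise.
    ``effects`` lists (gene, locus, beta) triples; genes not listed are
    null (beta = 0).  Gene names default to g0..g{n-1}; named genes in
    ``effects`` are added if absent.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    for g, _, _ in effects:
        if g not in genes:
            genes.append(g)
    n = len(dosage)
    expr = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(n, len(genes))),
        index=dosage.index,
        columns=genes,
    )
    if covariates is not None and len(covariates.columns):
        gamma = rng.normal(0.0, gamma_scale, size=(len(covariates.columns), len(genes)))
        expr += covariates.loc[dosage.index].values @ gamma
    for gene, locus, beta in effects:
        x = dosage[locus].values.astype(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"locus {locus} has zero dosage variance")
        expr[gene] += beta * (x - x.mean()) / sd
    return expr
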