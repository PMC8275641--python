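"""Per-locus bidirectional de Bruijn graphs and the repeat-pangenome graph.

A VNTR locus plus its two 700 bp flanks is represented as a bidirectional
de Bruijn graph: one vertex per distinct canonical k-mer, one edge per
distinct canonical (k+1)-mer observed in any source haplotype (an observed
(k+1)-mer and its reverse complement are the same edge).  Vertex counts are
kept separately for k-mers inside the VNTR interval and k-mers wholly in
the flanks; a k-mer overlapping the VNTR/flank junction is counted as a
VNTR k-mer, the conservative choice for length estimation.

A repeat-pangenome graph (RPGG) is a collection of locus graphs plus a
global index mapping each canonical k-mer to the set of loci containing it.
Because every locus has its own graph, a k-mer may occur in several loci —
a deliberate departure from a single genome-wide de Bruijn graph.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmers import (
    canonical_codes,
    decode_kmer,
    revcomp_code,
    seq_to_codes,
)

DEFAULT_K = 21
DEFAULT_FLANK = 700


def _edge_endpoints(edge_code: int, k: int) -> tuple[int, int]:
    """Oriented endpoint k-mers (prefix, suffix) of a packed (k+1)-mer."""
    mask = (1 << (2 * k)) - 1
    return edge_code >> 2, edge_code & mask


@dataclass
class LocusGraph:
    """Bidirectional de Bruijn graph of one VNTR locus plus flanks."""

    locus: int
    k: int = DEFAULT_K
    vntr: Counter = field(default_factory=Counter)  # canonical k-mer -> count
    flank: Counter = field(default_factory=Counter)
    edges: set = field(default_factory=set)  # canonical (k+1)-mer codes

    def vertices(self) -> set:
        return set(self.vntr) | set(self.flank)

    def n_vertices(self) -> int:
        return len(self.vertices())

    def has_vertex(self, code: int) -> bool:
        return code in self.vntr or code in self.flank

    def add_haplotype(self, seq: str, vntr_start: int, vntr_end: int) -> None:
        """Add one haplotype's locus region (flank + VNTR + flank).

        ``vntr_start``/``vntr_end`` are 0-based half-open coordinates of the
        VNTR within ``seq``.  A haplotype shorter than k+1 is skipped.
        """
        k = self.k
        if len(seq) < k + 1:
            warnings.warn(
                f"locus {self.locus}: haplotype of length {len(seq)} < k+1, skipped"
            )
            return
        codes = seq_to_codes(seq, k)
        canon = canonical_codes(codes, k)
        pos = np.arange(len(canon))
        # k-mer at offset i spans [i, i+k); it belongs to the VNTR counter
        # when it overlaps [vntr_start, vntr_end)
        in_vntr = (pos + k > vntr_start) & (pos < vntr_end)
        for counter, sel in ((self.vntr, in_vntr), (self.flank, ~in_vntr)):
            vals, cnts = np.unique(canon[sel], return_counts=True)
            for v, c in zip(vals.tolist(), cnts.tolist()):
                counter[v] += c
        ecodes = canonical_codes(seq_to_codes(seq, k + 1), k + 1)
        self.edges.update(ecodes.tolist())

    def has_edge_code(self, edge_code_canonical: int) -> bool:
        return edge_code_canonical in self.edges

    def edge_pairs(self) -> Iterable[tuple[int, str, int, str]]:
        """Edges as (canonical u, strand, canonical v, strand) tuples."""
        k = self.k
        for e in self.edges:
            u, v = _edge_endpoints(e, k)
            uc, vc = min(u, revcomp_code(u, k)), min(v, revcomp_code(v, k))
            yield uc, "+" if u == uc else "-", vc, "+" if v == vc else "-"

    def prune(self, supported: set) -> None:
        """Remove vertices absent from ``supported`` and incident edges."""
        for counter in (self.vntr, self.flank):
            for code in [c for c in counter if c not in supported]:
                del counter[code]
        keep = self.vertices()
        k = self.k
        dead = set()
        for e in self.edges:
            u, v = _edge_endpoints(e, k)
            if (
                min(u, revcomp_code(u, k)) not in keep
                or min(v, revcomp_code(v, k)) not in keep
            ):
                dead.add(e)
        self.edges -= dead

    def merge(self, other: "LocusGraph") -> None:
        """In-place union with another graph of the same locus: vertex and
        edge sets are united, counts summed."""
        if other.k != self.k:
            raise ValueError("cannot merge graphs with different k")
        self.vntr.update(other.vntr)
        self.flank.update(other.flank)
        self.edges |= other.edges


def build_locus_graph(
    haplotypes: Sequence[tuple[str, int, int]], k: int = DEFAULT_K, locus: int = 0
) -> LocusGraph:
    """Build a locus graph from (sequence, vntr_start, vntr_end) triples,
    aggregating vertices, edges and occurrence counts over haplotypes."""
    g = LocusGraph(locus=locus, k=k)
    for seq, s, e in haplotypes:
        g.add_haplotype(seq, s, e)
    return g


@dataclass
class RPGG:
    """Collection of locus graphs plus the global k-mer -> loci index."""

    k: int = DEFAULT_K
    flank_len: int = DEFAULT_FLANK
    loci: dict = field(default_factory=dict)  # locus id -> LocusGraph
    index: dict = field(default_factory=dict)  # canonical k-mer -> tuple of loci
    genomes: list = field(default_factory=list)

    def rebuild_index(self) -> None:
        idx: dict[int, list] = {}
        for lid in sorted(self.loci):
            for code in self.loci[lid].vertices():
                idx.setdefault(code, []).append(lid)
        self.index = {c: tuple(ls) for c, ls in idx.items()}

    def n_vertices(self) -> int:
        return sum(g.n_vertices() for g in self.loci.values())

    def prune(self, supported_by_locus: Mapping[int, set]) -> "RPGG":
        """Delete k-mers with no read support (graph pruning step).

        ``supported_by_locus`` maps locus id to the set of canonical k-mers
        observed in reads aligned to that locus with error correction
        disabled.  An absent locus means no read support at all there.
        """
        for lid, g in self.loci.items():
            sup = supported_by_locus.get(lid, set())
            if not sup:
                warnings.warn(f"locus {lid}: no read support, graph pruned to empty")
            g.prune(sup)
        self.rebuild_index()
        return self


def build_rpgg(
    regions: Mapping[int, Sequence[tuple[str, int, int]]],
    k: int = DEFAULT_K,
    flank_len: int = DEFAULT_FLANK,
    genomes: Sequence[str] = (),
) -> RPGG:
    """Build an RPGG from per-locus haplotype regions.

    ``regions`` maps locus id to a list of (sequence, vntr_start, vntr_end)
    triples, one per haplotype carrying the locus.
    """
    rpgg = RPGG(k=k, flank_len=flank_len, genomes=list(genomes))
    for lid, haps in regions.items():
        rpgg.loci[lid] = build_locus_graph(haps, k=k, locus=lid)
    rpgg.rebuild_index()
    return rpgg


def merge_rpggs(parts: Sequence[RPGG]) -> RPGG:
    """Merge per-genome RPGGs: per-locus union of vertices and edges, sum of
    counts, index rebuilt.  Loci present in only a subset of inputs are
    still merged (union semantics)."""
    if not parts:
        raise ValueError("nothing to merge")
    k = parts[0].k
    out = RPGG(k=k, flank_len=parts[0].flank_len)
    for p in parts:
        out.genomes.extend(g for g in p.genomes if g not in out.genomes)
        for lid, g in p.loci.items():
            if lid not in out.loci:
                out.loci[lid] = LocusGraph(locus=lid, k=k)
            out.loci[lid].merge(g)
    out.rebuild_index()
    return out


def write_gfa(rpgg: RPGG, path: str) -> None:
    """Serialize as GFA v1: one S line per canonical k-mer with a ``KC:i:``
    total-count tag and a ``LN:i:`` tag, L lines with k-1 overlap.  Segment
    names are ``<locus>.<canonical k-mer>``; loci are independent subgraphs."""
    k = rpgg.k
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for lid in sorted(rpgg.loci):
            g = rpgg.loci[lid]
            for code in sorted(g.vertices()):
                cnt = g.vntr.get(code, 0) + g.flank.get(code, 0)
                fh.write(
                    f"S\t{lid}.{code}\t{decode_kmer(code, k)}\tLN:i:{k}\tKC:i:{cnt}\n"
                )
            for uc, ou, vc, ov in sorted(g.edge_pairs()):
                fh.write(f"L\t{lid}.{uc}\t{ou}\t{lid}.{vc}\t{ov}\t{k - 1}M\n")


def write_counts_tsv(rpgg: RPGG, path: str) -> None:
    """Dump per-locus canonical k-mer counts (VNTR and flank) as TSV."""
    with open(path, "w") as fh:
        fh.write("locus\tkmer\tregion\tcount\n")
        for lid in sorted(rpgg.loci):
            g = rpgg.loci[lid]
            for region, counter in (("vntr", g.vntr), ("flank", g.flank)):
                for code in sorted(counter):
                    fh.write(
                        f"{lid}\t{decode_kmer(code, rpgg.k)}\t{region}\t{counter[code]}\n"
                    )
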