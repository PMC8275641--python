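"""Three-phase alignment of paired-end short reads to the RPGG.

Phase 1 (k-mer set mapping) converts a read pair to canonical k-mer
multisets and picks the locus with the highest number of shared k-mers,
requiring more than ``cth`` shared k-mers in each end and a minimum shared
fraction ``rth`` over the pair.  Phase 2 (threading) walks the read's
k-mers along the locus graph as a continuous path/cycle, editing up to
``edit_budget`` bases per read when no consistent k-mer is found; a pair
is feasible when each read threads at least ``thcth`` k-mers.  Phase 3
counts the canonical k-mers of feasible pairs that exist in the locus'
VNTR region, producing the per-sample "kms" vector used for length
genotyping.

Because vertices are canonical k-mers and edges canonical (k+1)-mers, all
phases are strand-symmetric: threading a read and its reverse complement
give identical results, so no orientation search is needed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .graph import RPGG, LocusGraph
from .kmers import seq_to_canonical_codes

#: default thresholds, named after the corresponding CLI flags
DEFAULT_CTH = 45  # phase-1 shared k-mers per end (exclusive)
DEFAULT_THCTH = 50  # phase-2 matched k-mers per read (inclusive)
DEFAULT_RTH = 0.5  # min fraction of pair k-mers found in assigned locus
DEFAULT_EDITS = 2  # per-read edit budget


def threading_threshold(read_len: int = 150, k: int = 21, identity: float = 0.9) -> int:
    """Matched-k-mer threshold asserting a given alignment identity:
    ceil((read_len - k + 1) * identity).  150/21/0.9 gives 117."""
    import math

    return math.ceil((read_len - k + 1) * identity)


@dataclass
class AlignParams:
    k: int = 21
    cth: int = DEFAULT_CTH
    thcth: int = DEFAULT_THCTH
    rth: float = DEFAULT_RTH
    edit_budget: int = DEFAULT_EDITS


@dataclass
class ReadPairAlignment:
    locus: Optional[int]
    matched: tuple[int, int] = (0, 0)
    edits: int = 0
    feasible: bool = False
    identity: float = 0.0
    #: canonical k-mer codes of the threaded (possibly corrected) reads
    codes: tuple = ()


def assign_locus(
    codes1: np.ndarray, codes2: np.ndarray, rpgg: RPGG, params: AlignParams
) -> Optional[int]:
    """Phase 1: locus with the highest multiset intersection between the
    pair's canonical k-mers and the locus vertex set, requiring > cth
    shared k-mers in each end; exact ties break to the lower locus id."""
    index = rpgg.index
    scores: dict[int, list[int]] = {}
    for endi, codes in enumerate((codes1, codes2)):
        for c in codes.tolist():
            loci = index.get(c)
            if loci is None:
                continue
            for lid in loci:
                scores.setdefault(lid, [0, 0])[endi] += 1
    if not scores:
        return None
    best = min(scores.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0]))
    lid, (c1, c2) = best
    if c1 <= params.cth or c2 <= params.cth:
        return None
    if (c1 + c2) < params.rth * (len(codes1) + len(codes2)):
        return None
    return lid


def _read_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical k-mer codes, canonical (k+1)-mer edge codes) of a read."""
    return seq_to_canonical_codes(seq, k), seq_to_canonical_codes(seq, k + 1)


def _walk(canon: np.ndarray, ecanon: np.ndarray, g: LocusGraph) -> int:
    """Length of the maximal graph-consistent k-mer path from the start of
    the read: consecutive k-mers must be vertices joined by observed
    (k+1)-mer edges."""
    vntr, flank, edges = g.vntr, g.flank, g.edges
    for i, c in enumerate(canon.tolist()):
        if c not in vntr and c not in flank:
            return i
        if i > 0 and int(ecanon[i - 1]) not in edges:
            return i
    return len(canon)


def thread_read(
    seq: str,
    g: LocusGraph,
    params: AlignParams,
    codes: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[int, int, np.ndarray]:
    """Phase 2 for one read: greedy threading with bounded edits.

    On a threading failure at k-mer ``i``, the base that first
    distinguishes the failing k-mer (read position ``i + k - 1``) is
    edited: the 3 substitutions, 4 insertions and 1 deletion are tried in
    that fixed order, accepting the first candidate that extends the path
    by at least one k-mer.  No backtracking.  Returns (matched k-mers,
    edits used, canonical k-mer codes of the threaded read).
    """
    k = params.k
    if codes is None:
        codes = _read_codes(seq, k)
    canon, ecanon = codes
    edits = 0
    cur = seq
    fail = _walk(canon, ecanon, g)
    n = len(seq) - k + 1
    while fail < len(canon) and edits < params.edit_budget:
        pos = fail + k - 1
        candidates = []
        orig = cur[pos] if pos < len(cur) else ""
        for b in "ACGT":  # substitutions
            if b != orig and pos < len(cur):
                candidates.append(cur[:pos] + b + cur[pos + 1 :])
        for b in "ACGT":  # insertions
            candidates.append(cur[:pos] + b + cur[pos:])
        if pos < len(cur):  # deletion
            candidates.append(cur[:pos] + cur[pos + 1 :])
        advanced = False
        for cand in candidates:
            cc = _read_codes(cand, k)
            w = _walk(cc[0], cc[1], g)
            if w > fail:
                cur, (canon, ecanon), fail = cand, cc, w
                edits += 1
                advanced = True
                break
        if not advanced:
            break
    matched = min(fail, n)
    return matched, edits, canon


def thread_read_pair(
    seq1: str,
    seq2: str,
    g: LocusGraph,
    params: AlignParams,
    codes1: tuple[np.ndarray, np.ndarray] | None = None,
    codes2: tuple[np.ndarray, np.ndarray] | None = None,
) -> ReadPairAlignment:
    """Phase 2 for a pair: thread each mate (strand-symmetric, so no
    orientation search), feasible iff both mates match at least ``thcth``
    k-mers with at most ``edit_budget`` edits each."""
    k = params.k
    m1, e1, t1 = thread_read(seq1, g, params, codes=codes1)
    m2, e2, t2 = thread_read(seq2, g, params, codes=codes2)
    n1, n2 = len(seq1) - k + 1, len(seq2) - k + 1
    feasible = m1 >= params.thcth and m2 >= params.thcth
    identity = min(m1 / n1 if n1 > 0 else 0.0, m2 / n2 if n2 > 0 else 0.0)
    return ReadPairAlignment(
        locus=g.locus,
        matched=(m1, m2),
        edits=e1 + e2,
        feasible=feasible,
        identity=min(identity, 1.0),
        codes=(t1, t2),
    )


@dataclass
class AlignStats:
    pairs: int = 0
    assigned: int = 0
    feasible: int = 0
    identity_ge_90: int = 0
    per_locus_pairs: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "pairs": self.pairs,
            "assigned": self.assigned,
            "feasible": self.feasible,
            "identity_ge_90": self.identity_ge_90,
        }


def align_pair(
    seq1: str, seq2: str, rpgg: RPGG, params: AlignParams
) -> ReadPairAlignment:
    """Phases 1+2 for one pair."""
    k = params.k
    codes1 = _read_codes(seq1, k)
    codes2 = _read_codes(seq2, k)
    lid = assign_locus(codes1[0], codes2[0], rpgg, params)
    if lid is None:
        return ReadPairAlignment(locus=None)
    return thread_read_pair(
        seq1, seq2, rpgg.loci[lid], params, codes1=codes1, codes2=codes2
    )


def align_sample(
    pairs: Iterable[tuple[str, str, str]],
    rpgg: RPGG,
    params: AlignParams | None = None,
    per_kmer: bool = False,
) -> tuple[dict, dict, AlignStats]:
    """Phase 3 over a read set: returns (kms, per_kmer_counts, stats).

    ``kms`` maps locus id to the total count of feasible-pair canonical
    k-mers found in that locus' VNTR region (flank k-mers are never
    counted).  With ``per_kmer``, a per-locus Counter of individual VNTR
    k-mer counts is also filled (needed for alignment-quality regression
    and motif analyses).
    """
    if params is None:
        params = AlignParams()
    kms: dict[int, int] = {lid: 0 for lid in rpgg.loci}
    kvec: dict[int, Counter] = {lid: Counter() for lid in rpgg.loci} if per_kmer else {}
    stats = AlignStats()
    for _name, s1, s2 in pairs:
        stats.pairs += 1
        aln = align_pair(s1, s2, rpgg, params)
        if aln.locus is None:
            continue
        stats.assigned += 1
        if not aln.feasible:
            continue
        stats.feasible += 1
        if aln.identity >= 0.9:
            stats.identity_ge_90 += 1
        stats.per_locus_pairs[aln.locus] += 1
        vntr = rpgg.loci[aln.locus].vntr
        total = 0
        if per_kmer:
            counter = kvec[aln.locus]
            for codes in aln.codes:
                for c in codes.tolist():
                    if c in vntr:
                        total += 1
                        counter[c] += 1
        else:
            for codes in aln.codes:
                for c in codes.tolist():
                    if c in vntr:
                        total += 1
        kms[aln.locus] += total
    return kms, kvec, stats
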