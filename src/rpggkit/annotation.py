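"""VNTR interval filtering and boundary harmonization across haplotypes.

Raw tandem-repeat annotations (Tandem Repeats Finder output or a BED-like
table) are filtered to the VNTR definition used throughout this package:
motif longer than 6 bp and total length strictly between 150 bp and 10 kbp.
Reference loci are then lifted onto haplotype assemblies through a
correspondence table, and the multiple-boundary-expansion algorithm
harmonizes boundaries across haplotypes so that no haplotype's 700 bp
flank shares a k-mer with any haplotype's VNTR region.  A final QC/merging
pass removes haplotypes near contig breakpoints or with discordant
orthology, drops weakly supported loci, and merges loci that come within
one flank length of each other on any haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kmers import seq_to_canonical_codes

FLANK_LEN = 700
MIN_MOTIF = 6  # exclusive: motifs must be > 6 bp
MIN_LEN = 150  # exclusive
MAX_LEN = 10_000  # exclusive
MAX_EXPANSION = 10_000


@dataclass(frozen=True)
class RawRepeatInterval:
    """One raw tandem-repeat annotation (0-based half-open)."""

    contig: str
    start: int
    end: int
    motif: str

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def total_len(self) -> int:
        return self.end - self.start


def filter_vntr_intervals(
    raw: Sequence[RawRepeatInterval],
) -> list[RawRepeatInterval]:
    """Keep VNTR-sized intervals: motif > 6 bp and 150 < length < 10000.

    Order is preserved; a malformed interval (end <= start) raises."""
    out = []
    for r in raw:
        if r.end <= r.start:
            raise ValueError(f"malformed interval {r.contig}:{r.start}-{r.end}")
        if r.motif_len > MIN_MOTIF and MIN_LEN < r.total_len < MAX_LEN:
            out.append(r)
    return out


def read_trf_dat(path: str) -> list[RawRepeatInterval]:
    """Parse Tandem Repeats Finder ``.dat`` output (``-d`` flag).

    TRF reports 1-based closed coordinates; they are converted to 0-based
    half-open on read.  Field 14 of a record line is the consensus motif.
    """
    out: list[RawRepeatInterval] = []
    contig = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                contig = line.split(None, 1)[1].split()[0]
                continue
            parts = line.split()
            if len(parts) >= 14 and parts[0].isdigit() and parts[1].isdigit():
                start, end = int(parts[0]) - 1, int(parts[1])
                out.append(RawRepeatInterval(contig, start, end, parts[13]))
    return out


def read_repeat_bed(path: str) -> list[RawRepeatInterval]:
    """Read a 6-column BED-like table: contig, start, end, motif,
    motif_len, total_len (0-based half-open; the last two columns are
    redundant and only validated when present)."""
    out = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        out.append(RawRepeatInterval(str(row[0]), int(row[1]), int(row[2]), str(row[3])))
    return out


# ---------------------------------------------------------------------------
# catalog

#: haplotype status codes, in the order they can be assigned
STATUS_OK = "ok"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NEAR_BREAKPOINT = "near_breakpoint"
STATUS_FAILED_EXPANSION = "failed_expansion"
STATUS_ORTHOLOGY = "discordant_orthology"
STATUS_MERGE = "inconsistent_adjacency"


@dataclass
class LocusCatalog:
    """Harmonized VNTR intervals per haplotype.

    ``df`` has one row per (locus, hap) with columns contig, start, end,
    ref_start, ref_end, status; ``haplotypes`` is the full universe of
    haplotype names used for support fractions; ``dropped`` records loci
    removed by QC with the reason.
    """

    df: pd.DataFrame
    haplotypes: list[str]
    flank_len: int = FLANK_LEN
    dropped: dict = field(default_factory=dict)  # locus -> reason
    merged_from: dict = field(default_factory=dict)  # locus -> merged member loci

    @classmethod
    def from_truth(cls, truth: pd.DataFrame, flank_len: int = FLANK_LEN) -> "LocusCatalog":
        """Identity catalog from a simulation truth table (haplotype
        coordinates double as reference coordinates)."""
        df = truth[["locus", "genome", "hap", "contig", "start", "end"]].copy()
        df["hap"] = df["genome"] + "." + df["hap"].astype(str)
        df = df.drop(columns="genome")
        # all haplotypes of a locus share one reference anchor, as a real
        # liftover onto a single reference genome would give
        ref = df.groupby("locus")[["start", "end"]].first()
        df["ref_start"] = df["locus"].map(ref["start"])
        df["ref_end"] = df["locus"].map(ref["end"])
        df["status"] = STATUS_OK
        haps = sorted(df["hap"].unique())
        return cls(df=df.reset_index(drop=True), haplotypes=haps, flank_len=flank_len)

    def ok(self) -> pd.DataFrame:
        return self.df[self.df["status"] == STATUS_OK]

    def support(self, locus) -> int:
        sub = self.df[(self.df["locus"] == locus) & (self.df["status"] == STATUS_OK)]
        return len(sub)

    def loci(self) -> list:
        return sorted(self.df["locus"].unique())

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, flank_len: int = FLANK_LEN) -> "LocusCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls(df=df, haplotypes=sorted(df["hap"].unique()), flank_len=flank_len)

    def regions(
        self, sequences: Mapping[str, str]
    ) -> dict[object, list[tuple[str, int, int]]]:
        """Per-locus (sequence, vntr_start, vntr_end) triples over the
        flank-padded window, for graph construction."""
        out: dict[object, list[tuple[str, int, int]]] = {}
        for row in self.ok().itertuples():
            seq = sequences[row.contig]
            lo = max(0, row.start - self.flank_len)
            hi = min(len(seq), row.end + self.flank_len)
            out.setdefault(row.locus, []).append(
                (seq[lo:hi], row.start - lo, row.end - lo)
            )
        return out


def lift_loci(
    ref_loci: Sequence[tuple[object, int, int]],
    correspondence: pd.DataFrame,
    haplotypes: Sequence[str],
    flank_len: int = FLANK_LEN,
) -> LocusCatalog:
    """Assign reference loci to haplotype intervals via a correspondence
    table (columns: locus, hap, contig, start, end).

    Haplotypes with no correspondence for a locus contribute nothing; a
    locus mapping to two disjoint intervals on one haplotype is flagged
    ambiguous and that haplotype is excluded for that locus.
    """
    ref = {lid: (s, e) for lid, s, e in ref_loci}
    rows = []
    for (lid, hap), grp in correspondence.groupby(["locus", "hap"], sort=True):
        if lid not in ref:
            continue
        status = STATUS_OK if len(grp) == 1 else STATUS_AMBIGUOUS
        r = grp.iloc[0]
        rows.append(
            {
                "locus": lid,
                "hap": hap,
                "contig": r["contig"],
                "start": int(r["start"]),
                "end": int(r["end"]),
                "ref_start": ref[lid][0],
                "ref_end": ref[lid][1],
                "status": status,
            }
        )
    df = pd.DataFrame(rows)
    return LocusCatalog(df=df, haplotypes=list(haplotypes), flank_len=flank_len)


# ---------------------------------------------------------------------------
# boundary expansion


def _flank_offending(
    flank_codes: np.ndarray, union: set
) -> np.ndarray:
    """Indices of flank k-mers present in the VNTR k-mer union."""
    if len(flank_codes) == 0:
        return np.empty(0, dtype=int)
    hits = [i for i, c in enumerate(flank_codes.tolist()) if c in union]
    return np.asarray(hits, dtype=int)


def expand_boundaries(
    catalog: LocusCatalog,
    sequences: Mapping[str, str],
    k: int = 21,
    max_expansion: int = MAX_EXPANSION,
) -> LocusCatalog:
    """Multiple-boundary expansion to a locus-wise fixed point.

    Invariant sought: no haplotype's ``flank_len`` 5' or 3' flank shares a
    canonical k-mer with the union of all haplotypes' VNTR k-mers at that
    locus.  While violated, the offending haplotype's boundary is moved
    outward past the most distal offending k-mer and the union recomputed
    (haplotypes processed in row order — deterministic).  A haplotype
    whose cumulative expansion exceeds ``max_expansion`` in either
    direction is marked failed; one whose flank would run off the contig
    is marked near_breakpoint.  Intervals only ever grow.
    """
    df = catalog.df.copy()
    fl = catalog.flank_len
    for locus, idxs in df.groupby("locus").groups.items():
        idxs = list(idxs)
        orig = {i: (df.at[i, "start"], df.at[i, "end"]) for i in idxs}

        def union_kmers() -> set:
            u: set = set()
            for i in idxs:
                if df.at[i, "status"] != STATUS_OK:
                    continue
                seq = sequences[df.at[i, "contig"]]
                u.update(
                    seq_to_canonical_codes(
                        seq[df.at[i, "start"] : df.at[i, "end"]], k
                    ).tolist()
                )
            return u

        changed = True
        while changed:
            changed = False
            union = union_kmers()
            for i in idxs:
                if df.at[i, "status"] != STATUS_OK:
                    continue
                seq = sequences[df.at[i, "contig"]]
                start, end = df.at[i, "start"], df.at[i, "end"]
                if start - fl < 0 or end + fl > len(seq):
                    df.at[i, "status"] = STATUS_NEAR_BREAKPOINT
                    continue
                moved = False
                codes5 = seq_to_canonical_codes(seq[start - fl : start], k)
                off5 = _flank_offending(codes5, union)
                if len(off5):
                    df.at[i, "start"] = start - fl + int(off5.min())
                    moved = True
                codes3 = seq_to_canonical_codes(seq[end : end + fl], k)
                off3 = _flank_offending(codes3, union)
                if len(off3):
                    df.at[i, "end"] = end + int(off3.max()) + k
                    moved = True
                if moved:
                    if (
                        orig[i][0] - df.at[i, "start"] > max_expansion
                        or df.at[i, "end"] - orig[i][1] > max_expansion
                    ):
                        df.at[i, "status"] = STATUS_FAILED_EXPANSION
                        df.at[i, "start"], df.at[i, "end"] = orig[i]
                    changed = True
                    union = union_kmers()
    out = replace(catalog, df=df)
    return out


def check_flank_invariant(
    catalog: LocusCatalog, sequences: Mapping[str, str], k: int = 21
) -> bool:
    """Brute-force check of the post-expansion invariant: for every
    retained haplotype, flank k-mers are disjoint from the union of all
    haplotypes' VNTR k-mers at that locus."""
    fl = catalog.flank_len
    for locus, grp in catalog.ok().groupby("locus"):
        union: set = set()
        for row in grp.itertuples():
            seq = sequences[row.contig]
            union.update(seq_to_canonical_codes(seq[row.start : row.end], k).tolist())
        for row in grp.itertuples():
            seq = sequences[row.contig]
            for lo, hi in (
                (max(0, row.start - fl), row.start),
                (row.end, min(len(seq), row.end + fl)),
            ):
                codes = set(seq_to_canonical_codes(seq[lo:hi], k).tolist())
                if codes & union:
                    return False
    return True


# ---------------------------------------------------------------------------
# QC and merging


def merge_and_qc(
    catalog: LocusCatalog,
    orthology_tol: int = 1000,
    pre_merge_support: float = 0.90,
    post_merge_support: float = 0.80,
) -> LocusCatalog:
    """Post-expansion QC and merging, in order:

    1. drop haplotypes near breakpoints / failed expansion, and haplotypes
       whose reference (orthology) position deviates more than
       ``orthology_tol`` from the majority of supporting haplotypes;
    2. drop loci supported by fewer than 90% of all haplotypes;
    3. merge loci that lie within one flank length of each other on any
       haplotype, across all haplotypes, dropping haplotypes whose
       adjacency disagrees with the majority;
    4. drop merged/retained loci supported by fewer than 80%.

    All removals are recorded in ``catalog.dropped`` with a reason.
    """
    df = catalog.df.copy()
    n_haps = len(catalog.haplotypes)
    dropped: dict = {}

    # 1. haplotype-level QC
    for locus, grp in df[df["status"] == STATUS_OK].groupby("locus"):
        pos = grp["ref_start"].astype(float)
        med = pos.median()
        bad = grp.index[(pos - med).abs() > orthology_tol]
        # a strict majority must agree with the median cluster; a tie drops
        # the discordant haplotypes (conservative)
        df.loc[bad, "status"] = STATUS_ORTHOLOGY

    # 2. support >= 90% before merging
    for locus, grp in df.groupby("locus"):
        sup = (grp["status"] == STATUS_OK).sum()
        if sup < pre_merge_support * n_haps:
            dropped[locus] = f"support {sup}/{n_haps} < 90% before merging"
    df = df[~df["locus"].isin(dropped)]

    # 3. merging: union-find over loci that come within flank_len on any hap
    parent: dict = {l: l for l in df["locus"].unique()}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ok = df[df["status"] == STATUS_OK]
    adjacency_votes: dict[tuple, dict] = {}
    for (hap, _contig), grp in ok.groupby(["hap", "contig"]):
        grp = grp.sort_values("start")
        rows = list(grp.itertuples())
        for a, b in zip(rows, rows[1:]):
            pair = tuple(sorted((a.locus, b.locus)))
            gap = b.start - a.end
            adjacency_votes.setdefault(pair, {})[hap] = gap
    merged_pairs = []
    for pair, votes in adjacency_votes.items():
        close = [h for h, gap in votes.items() if gap < catalog.flank_len]
        if not close:
            continue
        merged_pairs.append((pair, votes, close))
        a, b = find(pair[0]), find(pair[1])
        if a != b:
            parent[max(a, b)] = min(a, b)

    groups: dict = {}
    for l in parent:
        groups.setdefault(find(l), []).append(l)

    merged_from: dict = {}
    out_rows = []
    for root, members in groups.items():
        members = sorted(members)
        sub = df[df["locus"].isin(members)]
        if len(members) == 1:
            out_rows.append(sub)
            continue
        merged_from[root] = members
        # majority rule per inducing pair: haplotypes whose adjacency calls
        # disagree with the (strict) majority are dropped from the merged locus
        bad_haps: set = set()
        for pair, votes, close in merged_pairs:
            if find(pair[0]) != root:
                continue
            far = [h for h in votes if h not in close]
            if len(close) > len(far):
                bad_haps.update(far)
            else:
                bad_haps.update(close)  # tie or minority-close: drop the movers
        rows = []
        for hap, grp in sub[sub["status"] == STATUS_OK].groupby("hap"):
            if hap in bad_haps or set(grp["locus"]) != set(members):
                continue
            rows.append(
                {
                    "locus": root,
                    "hap": hap,
                    "contig": grp["contig"].iloc[0],
                    "start": int(grp["start"].min()),
                    "end": int(grp["end"].max()),
                    "ref_start": int(grp["ref_start"].min()),
                    "ref_end": int(grp["ref_end"].max()),
                    "status": STATUS_OK,
                }
            )
        if rows:
            out_rows.append(pd.DataFrame(rows))
    df = pd.concat(out_rows, ignore_index=True) if out_rows else df.iloc[0:0]

    # 4. support >= 80% after merging
    for locus, grp in df.groupby("locus"):
        sup = (grp["status"] == STATUS_OK).sum()
        if sup < post_merge_support * n_haps:
            dropped[locus] = f"support {sup}/{n_haps} < 80% after merging"
    df = df[~df["locus"].isin([l for l in dropped if l in set(df["locus"])])]

    return LocusCatalog(
        df=df.reset_index(drop=True),
        haplotypes=list(catalog.haplotypes),
        flank_len=catalog.flank_len,
        dropped=dropped,
        merged_from=merged_from,
    )
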