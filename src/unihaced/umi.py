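"""Read scanning, UMI-pair clustering and UMI-chimera removal.

A valid read carries the full two-step-PCR construct on one strand: adapter
+ anchor + 13-base UMI + conserved primer site at both ends, with the
D-loop in between.  Scanning finds both flanks by semi-global alignment of
the degenerate construct models, extracts the UMI pair and the insert, and
rejects reads whose flanks fall below the identity threshold.  Raw UMI
pairs are then clustered greedily by abundance, and pairs that share one
tag but not the other are resolved as PCR chimeras.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from . import constructs
from .core_io import IUPAC_EQUALITIES, NucSeq, alignment_stats, cigar_ops, percent_identity, revcomp
from .errors import ContractError

#: Accepted UMI lengths after alignment through indels (13 +- 2).
UMI_LENGTH_SLOP = (11, 15)

#: Below this identity over the construct's non-UMI columns (adapter,
#: anchor, primer site) a flank is considered absent rather than merely
#: degraded (separates no_fwd/no_rev from low_identity rejections).  The
#: UMI block is excluded because N matches anything, which would let a
#: random sequence score ~0.7 overall.
DETECTION_FLOOR = 0.70


@dataclass(frozen=True)
class FlankHit:
    start: int
    end: int            # half-open on the oriented read
    identity: float
    umi: str


@dataclass(frozen=True)
class ReadScan:
    """A read that passed construct scanning."""

    read_id: str
    orientation: str           # strand on which the construct layout matched
    fwd_hit: FlankHit
    rev_hit: FlankHit          # coordinates on the reverse-complemented read
    fwd_umi: str
    rev_umi: str
    insert: str                # read bases between the two primer 3' ends


@dataclass(frozen=True)
class ScanRejection:
    read_id: str
    reason: str                # no_fwd | no_rev | low_identity | wrong_orientation


@dataclass
class UmiCluster:
    """Reads grouped under one canonical UMI pair."""

    fwd_umi: str
    rev_umi: str
    read_ids: list[str] = field(default_factory=list)
    variants: Counter = field(default_factory=Counter)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    @property
    def key(self) -> str:
        return self.fwd_umi + self.rev_umi


def _find_flank(target: str, construct: str, umi_offset: int, umi_len: int):
    """Best semi-global hit of a degenerate construct in an oriented read.

    Returns (start, end, identity, umi) with the UMI read off the read bases
    aligned to the construct's N-block; degenerate construct codes match any
    base they cover.
    """
    res = edlib.align(construct, target, mode="HW", task="path",
                      additionalEqualities=IUPAC_EQUALITIES)
    start, end_incl = res["locations"][0]
    matches, length = alignment_stats(res["cigar"])
    identity = matches / length
    # Walk the cigar to map construct (query) positions to read positions
    # and to score the non-UMI construct columns separately.
    qpos, tpos = 0, start
    umi_t_start = umi_t_end = None
    core_matches = core_cols = 0
    for n, op in cigar_ops(res["cigar"]):
        for _ in range(n):
            in_umi = umi_offset <= qpos < umi_offset + umi_len
            if op in "=X":
                if in_umi:
                    if umi_t_start is None:
                        umi_t_start = tpos
                    umi_t_end = tpos + 1
                else:
                    core_cols += 1
                    core_matches += op == "="
                qpos += 1
                tpos += 1
            elif op == "I":   # construct base absent from the read
                if not in_umi:
                    core_cols += 1
                qpos += 1
            elif op == "D":   # extra read base
                if in_umi and umi_t_start is not None:
                    umi_t_end = tpos + 1
                elif not in_umi:
                    core_cols += 1
                tpos += 1
    umi = target[umi_t_start:umi_t_end] if umi_t_start is not None else ""
    core_identity = core_matches / core_cols if core_cols else 0.0
    return start, end_incl + 1, identity, umi, core_identity


def scan_read(
    read: NucSeq,
    fwd_construct: str | None = None,
    rev_construct: str | None = None,
    min_identity: float = 0.80,
) -> ReadScan | ScanRejection:
    """Locate both construct flanks in a read and extract the UMI pair.

    Both strands are tried; the strand with the higher summed flank identity
    wins.  A read is accepted iff both flanks reach ``min_identity``, their
    orientation is convergent, and both UMIs are within
    ``UMI_LENGTH_SLOP`` bases of the nominal 13.
    """
    fwd_construct = fwd_construct or constructs.fwd_construct()
    rev_construct = rev_construct or constructs.rev_construct()
    umi_off_f = len(fwd_construct) - constructs.UMI_LENGTH - len(
        constructs.FWD_PRIMER_SITE
    )
    umi_off_r = len(rev_construct) - constructs.UMI_LENGTH - len(
        constructs.REV_PRIMER_SITE
    )

    best = None
    for orientation in "+-":
        seq = read.seq if orientation == "+" else revcomp(read.seq)
        rc_seq = revcomp(seq)
        f = _find_flank(seq, fwd_construct, umi_off_f, constructs.UMI_LENGTH)
        r = _find_flank(rc_seq, rev_construct, umi_off_r, constructs.UMI_LENGTH)
        score = f[2] + r[2]
        if best is None or score > best[0]:
            best = (score, orientation, seq, f, r)

    _, orientation, seq, f, r = best
    f_start, f_end, f_id, fwd_umi, f_core = f
    r_start, r_end, r_id, rev_umi, r_core = r
    if f_core < DETECTION_FLOOR:
        return ScanRejection(read.id, "no_fwd")
    if r_core < DETECTION_FLOOR:
        return ScanRejection(read.id, "no_rev")
    if f_id < min_identity or r_id < min_identity:
        return ScanRejection(read.id, "low_identity")
    lo, hi = UMI_LENGTH_SLOP
    if not (lo <= len(fwd_umi) <= hi and lo <= len(rev_umi) <= hi):
        return ScanRejection(read.id, "low_identity")
    # rev hit coordinates are on the reverse-complemented read
    rev_start_on_seq = len(seq) - r_end
    if f_end > rev_start_on_seq:
        return ScanRejection(read.id, "wrong_orientation")
    return ReadScan(
        read_id=read.id,
        orientation=orientation,
        fwd_hit=FlankHit(f_start, f_end, f_id, fwd_umi),
        rev_hit=FlankHit(r_start, r_end, r_id, rev_umi),
        fwd_umi=fwd_umi,
        rev_umi=rev_umi,
        insert=seq[f_end:rev_start_on_seq],
    )


def cluster_umis(
    scans: list[ReadScan],
    min_identity: float = 0.80,
    pair_mode: str = "concat",
) -> list[UmiCluster]:
    """Group raw UMI pairs by abundance-greedy identity clustering.

    Raw pairs are processed in descending read-count order (ties broken
    lexicographically); each joins the first already-founded cluster whose
    canonical tag exceeds ``min_identity`` with its own, else founds a new
    cluster whose canonical pair it becomes.  With ``pair_mode='concat'``
    identity is computed on the concatenated 26-mer; with ``'per-tag'`` both
    tags must individually exceed the threshold.
    """
    if not scans:
        raise ContractError("no scans to cluster")
    if pair_mode not in ("concat", "per-tag"):
        raise ContractError(f"unknown pair_mode {pair_mode!r}")

    def exceeds(a: str, b: str, t: float) -> bool:
        # identity > t forces editDistance <= (1-t)(|a|+|b|)/(1+t), so a
        # k-bounded distance computation is an exact prefilter
        k = int((1.0 - t) * (len(a) + len(b)) / (1.0 + t))
        if edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] < 0:
            return False
        return percent_identity(a, b) > t

    tallies: dict[tuple[str, str], list[str]] = {}
    for s in scans:
        tallies.setdefault((s.fwd_umi, s.rev_umi), []).append(s.read_id)
    order = sorted(tallies, key=lambda p: (-len(tallies[p]), p[0] + p[1]))

    clusters: list[UmiCluster] = []
    for pair in order:
        fwd, rev = pair
        home = None
        for cl in clusters:
            if pair_mode == "concat":
                ok = exceeds(fwd + rev, cl.key, min_identity)
            else:
                ok = exceeds(fwd, cl.fwd_umi, min_identity) and exceeds(
                    rev, cl.rev_umi, min_identity
                )
            if ok:
                home = cl
                break
        if home is None:
            home = UmiCluster(fwd_umi=fwd, rev_umi=rev)
            clusters.append(home)
        home.read_ids.extend(tallies[pair])
        home.variants[pair] += len(tallies[pair])
    return clusters


def remove_chimeras(
    clusters: list[UmiCluster],
) -> tuple[list[UmiCluster], list[UmiCluster]]:
    """Resolve UMI chimeras: pairs sharing exactly one tag with another pair.

    Clusters whose canonical pairs share a forward OR a reverse tag (but not
    both — canonical pairs are unique) form conflict components; in each
    component only the cluster with the most reads survives (ties broken by
    lexicographically smallest canonical pair).  Conflict-free clusters pass
    through.  Returns (kept, removed).
    """
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_side: dict[tuple[str, str], list[int]] = {}
    for i, cl in enumerate(clusters):
        by_side.setdefault(("F", cl.fwd_umi), []).append(i)
        by_side.setdefault(("R", cl.rev_umi), []).append(i)
    for members in by_side.values():
        for j in members[1:]:
            union(members[0], j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    kept, removed = [], []
    for members in components.values():
        winner = min(
            members,
            key=lambda i: (
                -clusters[i].read_count,
                (clusters[i].fwd_umi, clusters[i].rev_umi),
            ),
        )
        for i in members:
            (kept if i == winner else removed).append(clusters[i])
    # preserve input order for determinism of downstream processing
    index = {id(cl): i for i, cl in enumerate(clusters)}
    kept.sort(key=lambda cl: index[id(cl)])
    removed.sort(key=lambda cl: index[id(cl)])
    return kept, removed
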