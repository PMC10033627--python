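"""Universal degenerate primer design from a multiple alignment.

Given a multiple alignment of mitogenome regions flanking the control
region, this module profiles every column, extracts the consensus of
well-occupied columns, scores conservation with a gap-considered identity
score that penalizes poorly aligned interruptions, designs IUPAC degenerate
primers over conserved windows, and evaluates a primer pair by exhaustive
in-silico PCR against a reference database.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import (
    CODE_FOR_BASES,
    MitoRecord,
    expand_degenerate,
    revcomp,
)
from .errors import ContractError

GAP = "-"
_BASES = "ACGT"


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column summary of a multiple alignment.

    occupancy is the fraction of rows with a non-gap character;
    consensus_fraction is the count of the most frequent base over the
    non-gap count (0 when the column is all gaps).
    """

    occupancy: float
    base_counts: dict[str, int]
    consensus_base: str
    consensus_fraction: float
    n_nongap: int


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer with per-position conservation provenance."""

    name: str
    seq: str
    window: tuple[int, int]          # alignment columns, 0-based half-open
    conservation: tuple[float, ...]  # consensus_fraction per position


def profile_alignment(msa: list[str]) -> list[ColumnProfile]:
    """Profile every column of an aligned set of sequences (gap ``-``).

    Counts only plain A/C/G/T toward base_counts; any other non-gap
    character (e.g. N) contributes to occupancy but not to the consensus.
    """
    if len(msa) < 2:
        raise ContractError("alignment needs at least 2 rows")
    width = len(msa[0])
    rows = [r.upper() for r in msa]
    if any(len(r) != width for r in rows):
        raise ContractError("alignment rows have unequal lengths")
    nrows = len(rows)

    profiles = []
    for j in range(width):
        column = [r[j] for r in rows]
        nongap = [c for c in column if c != GAP]
        counts = {b: 0 for b in _BASES}
        for c in nongap:
            if c in counts:
                counts[c] += 1
        n_nongap = len(nongap)
        if n_nongap:
            # deterministic tie-break: alphabetic among equally frequent bases
            best = max(counts.values())
            consensus = min(b for b in _BASES if counts[b] == best)
            fraction = best / n_nongap
        else:
            consensus, fraction = "N", 0.0
        profiles.append(
            ColumnProfile(
                occupancy=n_nongap / nrows,
                base_counts=counts,
                consensus_base=consensus,
                consensus_fraction=fraction,
                n_nongap=n_nongap,
            )
        )
    return profiles


def consensus_sequence(
    profiles: list[ColumnProfile], occupancy_threshold: float = 0.90
) -> tuple[str, list[int]]:
    """Consensus over columns occupied in more than ``occupancy_threshold``.

    Returns the consensus string and the list of alignment columns kept
    (consensus position i came from alignment column ``index_map[i]``).
    """
    if not profiles:
        raise ContractError("no profiles given")
    seq = []
    index_map = []
    for j, p in enumerate(profiles):
        if p.occupancy > occupancy_threshold:
            seq.append(p.consensus_base)
            index_map.append(j)
    return "".join(seq), index_map


def gap_identity_score(
    profiles: list[ColumnProfile], occupancy_threshold: float = 0.90
) -> np.ndarray:
    """Gap-considered identity score along the alignment.

    A left-to-right running score accumulates the consensus fraction over
    well-occupied columns and loses one unit (floored at zero) at every
    poorly occupied column, so high values mark long conserved runs that are
    not interrupted by badly aligned regions.
    """
    if not profiles:
        raise ContractError("no profiles given")
    scores = np.empty(len(profiles))
    s = 0.0
    for j, p in enumerate(profiles):
        if p.occupancy > occupancy_threshold:
            s += p.consensus_fraction
        else:
            s = max(0.0, s - 1.0)
        scores[j] = s
    return scores


def _degenerate_code(counts: dict[str, int], cover_fraction: float) -> str:
    """Minimal IUPAC code for the smallest base set covering the column.

    Bases are added in decreasing frequency (alphabetic tie-break) until
    their summed count reaches ``cover_fraction`` of the non-gap total.
    """
    total = sum(counts.values())
    ranked = sorted(_BASES, key=lambda b: (-counts[b], b))
    chosen: list[str] = []
    cum = 0
    for b in ranked:
        if counts[b] == 0:
            break
        chosen.append(b)
        cum += counts[b]
        if cum >= cover_fraction * total:
            break
    return CODE_FOR_BASES[frozenset(chosen)]


def design_primer(
    profiles: list[ColumnProfile],
    window: tuple[int, int],
    conservation_threshold: float = 0.85,
    cover_fraction: float = 0.95,
    occupancy_threshold: float = 0.90,
    name: str = "primer",
) -> DegeneratePrimer:
    """Design a degenerate primer over a conserved alignment window.

    Positions conserved at or above ``conservation_threshold`` emit the
    consensus base; the rest become the minimal mixed-base code covering the
    common alleles.  The window must lie entirely in well-occupied columns.
    """
    start, end = window
    if not (0 <= start < end <= len(profiles)):
        raise ContractError(f"window [{start},{end}) outside alignment")
    cols = profiles[start:end]
    bad = [start + i for i, p in enumerate(cols) if p.occupancy <= occupancy_threshold]
    if bad:
        raise ContractError(
            f"window touches low-occupancy columns {bad}; primers must sit in "
            f"regions aligned in more than {occupancy_threshold:.0%} of species"
        )
    seq = []
    for p in cols:
        if p.consensus_fraction >= conservation_threshold:
            seq.append(p.consensus_base)
        else:
            seq.append(_degenerate_code(p.base_counts, cover_fraction))
    return DegeneratePrimer(
        name=name,
        seq="".join(seq),
        window=window,
        conservation=tuple(p.consensus_fraction for p in cols),
    )


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def _hamming_hits(target: np.ndarray, pattern: str, max_mismatch: int):
    """All start positions where ``pattern`` matches within max_mismatch subs."""
    L = len(pattern)
    if len(target) < L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = sliding_window_view(target, L)
    mism = (windows != _encode(pattern)).sum(axis=1)
    pos = np.nonzero(mism <= max_mismatch)[0]
    return pos, mism[pos]


def _site_hits(target: np.ndarray, expansions: list[str], max_mismatch: int):
    """Best mismatch count per start position over all primer expansions."""
    best: dict[int, int] = {}
    for exp in expansions:
        pos, mm = _hamming_hits(target, exp, max_mismatch)
        for p, m in zip(pos.tolist(), mm.tolist()):
            if p not in best or m < best[p]:
                best[p] = m
    return best


def in_silico_pcr(
    fwd: DegeneratePrimer | str,
    rev: DegeneratePrimer | str,
    db: list[MitoRecord],
    max_mismatch: int = 2,
    amplicon_range: tuple[int, int] = (500, 3000),
) -> pd.DataFrame:
    """Predict which references a degenerate primer pair amplifies.

    Every expansion of both primers is matched exhaustively (substitutions
    only) on both strands of each record; a hit needs convergent primer
    orientation with the distance between the primer 3' ends inside
    ``amplicon_range``.  Returns one row per record with columns
    ``accession, species, hit, fwd_pos, rev_pos, mismatches,
    amplicon_length``; the overall hit rate is ``df["hit"].mean()``.
    """
    fseq = fwd.seq if isinstance(fwd, DegeneratePrimer) else fwd
    rseq = rev.seq if isinstance(rev, DegeneratePrimer) else rev
    if not fseq or not rseq:
        raise ContractError("primers must be nonempty")
    if not db:
        raise ContractError("reference database is empty")
    lo, hi = amplicon_range
    if lo > hi:
        raise ContractError(f"inverted amplicon range ({lo} > {hi})")

    fwd_exp = expand_degenerate(fseq)
    rev_exp = expand_degenerate(rseq)
    fwd_rc_exp = [revcomp(e) for e in fwd_exp]
    rev_rc_exp = [revcomp(e) for e in rev_exp]
    Lf, Lr = len(fseq), len(rseq)

    rows = []
    for rec in db:
        target = _encode(rec.seq.seq)
        # orientation A: fwd binds + strand, rev binds - strand downstream
        # orientation B: the same arrangement on the opposite strand
        pairings = [
            (_site_hits(target, fwd_exp, max_mismatch), Lf,
             _site_hits(target, rev_rc_exp, max_mismatch), "+"),
            (_site_hits(target, rev_exp, max_mismatch), Lr,
             _site_hits(target, fwd_rc_exp, max_mismatch), "-"),
        ]
        best = None
        for left_hits, left_len, right_hits, strand in pairings:
            if not left_hits or not right_hits:
                continue
            right_pos = sorted(right_hits)
            for lp, lmm in sorted(left_hits.items()):
                three_prime = lp + left_len
                for rp in right_pos:
                    length = rp - three_prime  # bases between primer 3' ends
                    if lo <= length <= hi:
                        cand = (lmm + right_hits[rp], lp, rp, length, strand)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
        if best is not None:
            mm, lp, rp, length, strand = best
            rows.append(
                dict(accession=rec.accession, species=rec.species, hit=True,
                     strand=strand, fwd_pos=lp, rev_pos=rp,
                     mismatches=mm, amplicon_length=length)
            )
        else:
            rows.append(
                dict(accession=rec.accession, species=rec.species, hit=False,
                     strand="", fwd_pos=-1, rev_pos=-1,
                     mismatches=-1, amplicon_length=-1)
            )
    return pd.DataFrame(rows)


def amplicon_length_stats(lengths) -> dict[str, float]:
    """Mean and linearly interpolated quartiles of amplicon lengths."""
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise ContractError("no amplicon lengths given")
    q25, q75 = np.percentile(arr, [25, 75], method="linear")
    return {"mean": float(arr.mean()), "q25": float(q25), "q75": float(q75)}
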