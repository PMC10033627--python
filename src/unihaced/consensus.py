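"""Per-UMI-cluster consensus building and iterative pileup polishing.

Reads of one UMI cluster are copies of a single template molecule, so their
inserts are near-identical up to sequencing error.  A draft consensus is
built by center-star alignment of a capped, seeded subsample (the center is
the insert of median length; pairwise alignments to it are merged into
columns and voted per column).  The draft is then polished with *all*
cluster reads: each iteration realigns every insert to the current
consensus, builds a pileup that includes insertion alleles between columns,
and replaces every position by its majority allele, until a fixpoint.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .core_io import cigar_ops
from .errors import ContractError


@dataclass
class CandidateHaplotype:
    """A polished cluster consensus, candidate for a true D-loop haplotype."""

    consensus: str
    n_reads_used_draft: int
    n_reads_total: int
    support: list[float]       # per-position fraction of reads voting the call
    converged: bool
    n_iterations: int


_CODE_OF = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN-"):
    _CODE_OF[ord(_b)] = _i
_ALLELE = "ACGTN-"


def _pileup(ref: str, seqs: list[str]):
    """Align each sequence globally to ref and tally per-column alleles.

    Returns (column_votes, insertion_votes, total_edits): ``column_votes[i]``
    counts bases or '-' (deletion) aligned to ref position i;
    ``insertion_votes[i]`` counts inserted strings between ref positions
    i-1 and i (slot len(ref) is after the last base).  The vote matrix is
    accumulated with numpy; only the rare insertion alleles use counters.
    """
    ncols = len(ref)
    insertions: list[Counter] = [Counter() for _ in range(ncols + 1)]
    total_edits = 0
    flat_chunks: list[np.ndarray] = []
    for seq in seqs:
        res = edlib.align(seq, ref, mode="NW", task="path")
        total_edits += res["editDistance"]
        qcodes = _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        qpos = tpos = 0
        # spans of (target_start, query_start, length, is_deletion)
        t_starts: list[int] = []
        q_starts: list[int] = []
        lengths: list[int] = []
        del_flags: list[bool] = []
        for n, op in cigar_ops(res["cigar"]):
            if op == "=" or op == "X":
                t_starts.append(tpos)
                q_starts.append(qpos)
                lengths.append(n)
                del_flags.append(False)
                qpos += n
                tpos += n
            elif op == "I":    # read bases absent from ref
                insertions[tpos][seq[qpos:qpos + n]] += 1
                qpos += n
            elif op == "D":    # ref bases absent from read
                t_starts.append(tpos)
                q_starts.append(qpos)
                lengths.append(n)
                del_flags.append(True)
                tpos += n
        # expand all spans without per-span arange: cumsum of unit steps
        ls = np.asarray(lengths)
        ts = np.asarray(t_starts)
        qs = np.asarray(q_starts)
        dl = np.asarray(del_flags)
        total = int(ls.sum())
        step = np.ones(total, dtype=np.int64)
        first = np.zeros(len(ls), dtype=np.int64)
        first[1:] = ls.cumsum()[:-1]
        step[first] = ts - np.concatenate(([-1], ts[:-1] + ls[:-1] - 1))
        t_idx = step.cumsum() - 1
        step[first] = qs - np.concatenate(([-1], qs[:-1] + ls[:-1] - 1))
        q_idx = step.cumsum() - 1
        codes = qcodes[np.minimum(q_idx, len(qcodes) - 1)].astype(np.int64)
        codes[np.repeat(dl, ls)] = 5   # deletion allele
        flat_chunks.append(t_idx * 6 + codes)
    votes = np.bincount(
        np.concatenate(flat_chunks), minlength=ncols * 6
    ).reshape(ncols, 6)
    columns = [
        Counter({_ALLELE[a]: int(c) for a, c in enumerate(votes[i]) if c})
        for i in range(ncols)
    ]
    return columns, insertions, total_edits


def _majority(counter: Counter, prefer: str | None = None) -> str:
    """Majority allele with deterministic tie-breaks (prefer ref, then sort)."""
    best = max(counter.values())
    winners = sorted(a for a, c in counter.items() if c == best)
    if prefer is not None and prefer in winners:
        return prefer
    return winners[0]


def pileup_consensus(ref: str, seqs: list[str]) -> tuple[str, list[float]]:
    """One round of majority-vote consensus of ``seqs`` against ``ref``.

    Substitutions and deletions are decided per ref column; an insertion is
    emitted between columns when more than half of the reads carry one
    there (most common inserted string wins).  Returns the new consensus and
    the per-emitted-position support fractions.
    """
    n = len(seqs)
    columns, insertions, _ = _pileup(ref, seqs)
    out: list[str] = []
    support: list[float] = []
    for i in range(len(ref) + 1):
        ins_total = sum(insertions[i].values())
        if ins_total * 2 > n:
            allele = _majority(insertions[i])
            out.append(allele)
            support.extend([ins_total / n] * len(allele))
        if i < len(ref):
            allele = _majority(columns[i], prefer=ref[i])
            frac = columns[i][allele] / n
            if allele != "-":
                out.append(allele)
                support.append(frac)
    return "".join(out), support


def draft_consensus(
    inserts: list[str],
    cap: int = 100,
    seed: int = 0,
    stream_key: str = "",
    subsample: str = "random",
) -> str:
    """Center-star draft consensus from a capped subsample of inserts.

    At most ``cap`` inserts are used; the subsample is seeded with the run
    seed plus a per-cluster stream key (the canonical UMI pair), so results
    do not depend on cluster iteration order.  ``subsample='first'`` takes
    the first ``cap`` instead.
    """
    if not inserts:
        raise ContractError("cluster has no reads")
    if cap < 1:
        raise ContractError("cap must be >= 1")
    if len(inserts) <= cap:
        sample = list(inserts)
    elif subsample == "first":
        sample = inserts[:cap]
    else:
        rng = np.random.default_rng(
            [seed & 0x7FFFFFFF, zlib.crc32(stream_key.encode())]
        )
        idx = rng.choice(len(inserts), size=cap, replace=False)
        sample = [inserts[i] for i in sorted(idx)]
    center = sorted(sample, key=lambda s: (len(s), s))[len(sample) // 2]
    consensus, _ = pileup_consensus(center, sample)
    return consensus


def polish(
    draft: str, inserts: list[str], max_iters: int = 5
) -> tuple[str, list[float], bool, int]:
    """Iteratively realign all inserts and take per-position majorities.

    Stops at a fixpoint (consensus unchanged) or after ``max_iters``
    iterations; the flag in the return tuple records convergence.
    Returns (consensus, support, converged, n_iterations).
    """
    if not draft:
        raise ContractError("draft consensus is empty")
    current = draft
    support: list[float] = []
    for it in range(1, max_iters + 1):
        new, support = pileup_consensus(current, inserts)
        if new == current:
            return current, support, True, it
        current = new
    return current, support, False, max_iters


def consensus_for_cluster(
    inserts: list[str],
    cap: int = 100,
    seed: int = 0,
    stream_key: str = "",
    max_iters: int = 5,
) -> CandidateHaplotype:
    """Draft + polish for one UMI cluster."""
    draft = draft_consensus(inserts, cap=cap, seed=seed, stream_key=stream_key)
    consensus, support, converged, iters = polish(draft, inserts, max_iters)
    return CandidateHaplotype(
        consensus=consensus,
        n_reads_used_draft=min(cap, len(inserts)),
        n_reads_total=len(inserts),
        support=support,
        converged=converged,
        n_iterations=iters,
    )


def pileup_disagreement(ref: str, seqs: list[str]) -> int:
    """Total edit distance of all sequences against a consensus."""
    _, _, total = _pileup(ref, seqs)
    return total


def polish_with_external_tool(
    draft: str,
    inserts: list[str],
    command_template: str,
    workdir: str | None = None,
) -> str:
    """Optional hook: delegate polishing to an external consensus tool.

    ``command_template`` is a shell command with ``{draft}``, ``{reads}``
    and ``{out}`` placeholders (FASTA draft, FASTQ reads, output FASTA).
    The built-in pileup polisher is the default everywhere; this hook only
    exists for users who want to swap in a dedicated long-read polisher.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        draft_path = tmp / "draft.fasta"
        reads_path = tmp / "reads.fastq"
        out_path = tmp / "polished.fasta"
        draft_path.write_text(f">draft\n{draft}\n")
        with open(reads_path, "w") as fh:
            for i, seq in enumerate(inserts):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        cmd = command_template.format(
            draft=draft_path, reads=reads_path, out=out_path
        )
        subprocess.run(cmd, shell=True, check=True)
        lines = out_path.read_text().splitlines()
        return "".join(l.strip() for l in lines if not l.startswith(">"))
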