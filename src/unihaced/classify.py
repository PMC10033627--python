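"""Species assignment, read-supported variant calling, haplotype merging.

A polished candidate consensus is assigned to the reference species with
the best identity (semi-global alignment of the candidate against every
reference on both strands).  Within a species, candidates that carry no
read-supported mutation against the dominant haplotype are residual
consensus errors, not real haplotypes: their reads are piled up on the
dominant consensus and a variant is only called where a single non-reference
allele is backed by a clear majority of reads.  Candidates without such a
variant are merged into the dominant haplotype; the sweep repeats with the
next-largest unmerged candidate until all are processed.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .consensus import CandidateHaplotype, _pileup
from .core_io import MitoRecord, alignment_stats, revcomp
from .errors import ContractError


@dataclass(frozen=True)
class SpeciesAssignment:
    species: str               # "unassigned" when below the identity floor
    identity_pct: float        # 0..100
    accession: str
    strand: str


@dataclass(frozen=True)
class VariantCall:
    position: int              # on the reference haplotype, 0-based
    ref_allele: str            # "" for a pure insertion
    alt_allele: str            # "-" for a deletion
    count: int
    fraction: float


@dataclass
class ClassifiedCandidate:
    """A candidate consensus with its species call and member reads."""

    candidate: CandidateHaplotype
    species: str
    identity_pct: float
    reads: list[str]           # insert sequences of the cluster's reads
    umi_count: int = 1

    @property
    def read_count(self) -> int:
        return len(self.reads)


@dataclass
class HaplotypeCall:
    """A final haplotype with merged UMI and read counts."""

    haplotype_id: str
    species: str
    consensus: str
    umi_count: int
    read_count: int
    identity_pct: float

    @property
    def dloop_length(self) -> int:
        return len(self.consensus)


def assign_species(
    candidate: str | CandidateHaplotype,
    refdb: list[MitoRecord],
    min_identity: float = 0.90,
) -> SpeciesAssignment:
    """Best-hit species for a candidate consensus.

    The candidate is aligned semi-globally (as an infix) against both
    strands of every reference; the best hit by identity wins, with ties
    broken by longer alignment and then accession order.  Hits below
    ``min_identity`` are reported as unassigned.
    """
    if not refdb:
        raise ContractError("reference database is empty")
    seq = candidate.consensus if isinstance(candidate, CandidateHaplotype) else candidate
    # cheap distance pass first; identity of a semi-global hit with edit
    # distance d is at most |q|/(|q|+d), so hits whose bound cannot beat
    # the current best identity are skipped without a traceback
    hits = []
    for rec in refdb:
        for strand, target in (("+", rec.seq.seq), ("-", revcomp(rec.seq.seq))):
            d = edlib.align(seq, target, mode="HW", task="distance")["editDistance"]
            hits.append((d, rec, strand, target))
    hits.sort(key=lambda h: (h[0], h[1].accession, h[2]))
    lq = len(seq)
    best = None
    for d, rec, strand, target in hits:
        if best is not None and lq / (lq + d) < best[1]:
            continue
        res = edlib.align(seq, target, mode="HW", task="path")
        matches, length = alignment_stats(res["cigar"])
        identity = matches / length
        key = (-identity, -length, rec.accession, strand)
        if best is None or key < best[0]:
            best = (key, identity, rec.accession, rec.species, strand)
    _, identity, accession, species, strand = best
    if identity < min_identity:
        return SpeciesAssignment("unassigned", identity * 100, accession, strand)
    return SpeciesAssignment(species, identity * 100, accession, strand)


def call_variants(
    reference_hap: str,
    reads: list[str],
    min_fraction: float = 0.6,
    min_reads: int = 3,
) -> list[VariantCall]:
    """Read-supported mutations of a read set against a reference haplotype.

    Reads are piled up on the reference (global unit-cost alignments); a
    variant is called at every position where one non-reference allele
    (substitution, deletion, or insertion between columns) reaches a
    supporting fraction of at least ``min_fraction`` with at least
    ``min(min_reads, n_reads)`` reads.  With i.i.d. sequencing errors no
    allele approaches the fraction threshold, so reads drawn from the
    reference itself yield no calls.
    """
    if not reads:
        raise ContractError("no reads given")
    n = len(reads)
    need = min(min_reads, n)
    columns, insertions, _ = _pileup(reference_hap, reads)
    calls: list[VariantCall] = []
    for i in range(len(reference_hap) + 1):
        ins = insertions[i]
        if ins:
            allele, count = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            frac = count / n
            if frac >= min_fraction and count >= need:
                calls.append(VariantCall(i, "", allele, count, frac))
        if i < len(reference_hap):
            ref_base = reference_hap[i]
            for allele, count in sorted(columns[i].items()):
                if allele == ref_base:
                    continue
                frac = count / n
                if frac >= min_fraction and count >= need:
                    calls.append(VariantCall(i, ref_base, allele, count, frac))
    return calls


def merge_haplotypes(
    candidates: list[ClassifiedCandidate],
    min_fraction: float = 0.6,
    min_reads: int = 3,
) -> tuple[list[HaplotypeCall], list[ClassifiedCandidate]]:
    """Merge per-species candidates lacking read-supported mutations.

    Per species, the unprocessed candidate with the most reads anchors a
    round: every smaller unprocessed candidate whose reads produce no
    variant call against the anchor consensus is merged into it (UMI and
    read counts add); candidates with at least one call stay for later
    rounds.  Unassigned candidates are returned untouched, never merged.
    Returns (final haplotype calls, unassigned candidates).
    """
    unassigned = [c for c in candidates if c.species == "unassigned"]
    by_species: dict[str, list[ClassifiedCandidate]] = {}
    for c in candidates:
        if c.species != "unassigned":
            by_species.setdefault(c.species, []).append(c)

    calls: list[HaplotypeCall] = []
    n_out = 0
    for species in sorted(by_species):
        pending = sorted(
            by_species[species],
            key=lambda c: (-c.read_count, c.candidate.consensus),
        )
        while pending:
            anchor = pending.pop(0)
            umi_count = anchor.umi_count
            read_count = anchor.read_count
            remaining = []
            for cand in pending:
                if not call_variants(
                    anchor.candidate.consensus, cand.reads,
                    min_fraction=min_fraction, min_reads=min_reads,
                ):
                    umi_count += cand.umi_count
                    read_count += cand.read_count
                else:
                    remaining.append(cand)
            pending = remaining
            n_out += 1
            calls.append(
                HaplotypeCall(
                    haplotype_id=f"hap{n_out:03d}",
                    species=species,
                    consensus=anchor.candidate.consensus,
                    umi_count=umi_count,
                    read_count=read_count,
                    identity_pct=anchor.identity_pct,
                )
            )
    return calls, unassigned
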