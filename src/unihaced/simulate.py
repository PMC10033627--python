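"""Truth-tracked simulator for UMI-tagged D-loop amplicon sequencing.

Emulates the whole wet-lab path at desk scale: a reference database of
species-labelled control regions flanked by the universal primer sites,
per-species haplotype sets, first-PCR UMI tagging (including the extra-cycle
UMI inflation and UMI chimeras), and noisy long reads with an i.i.d.
substitution/insertion/deletion error model.  Every read is linked back to
its molecule, UMI pair, haplotype and species in a truth table so the
downstream pipeline can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constructs
from .core_io import MitoRecord, NucSeq, expand_degenerate, revcomp
from .errors import ContractError

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulated tank experiment.

    Defaults mirror the tank survey the method was validated on: 14 species,
    ~1 kb control regions, 13-base UMIs, a 5-cycle first PCR (so up to
    2**3 = 8 apparent molecules per template), and per-base error rates that
    put mean read accuracy near 94%.
    """

    seed: int = 0
    n_species: int = 14
    haplotypes_per_species: list[int] | int = 2
    individuals_per_haplotype: int = 1
    molecules_per_haplotype: int = 2
    dloop_length_range: tuple[int, int] = (1000, 1100)
    intra_species_divergence: tuple[int, int] = (2, 10)
    umi_length: int = 13
    first_pcr_cycles: int = 5
    sub_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.02
    umi_chimera_fraction: float = 0.0
    #: chimeric pairs arise in later PCR cycles than genuine pairs and so
    #: accumulate fewer copies; their read counts are scaled by this factor
    chimera_read_factor: float = 0.25
    reads_per_umi_range: tuple[int, int] = (5, 5000)  # log-uniform
    flank_length: int = 120

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "umi_chimera_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name}={v} outside [0,1]")
        if self.umi_length <= 0:
            raise ContractError("umi_length must be positive")
        if self.n_species < 1:
            raise ContractError("need at least one species")
        if self.first_pcr_cycles < 2:
            raise ContractError("first PCR needs >= 2 cycles")

    def haplotype_counts(self) -> list[int]:
        if isinstance(self.haplotypes_per_species, int):
            return [self.haplotypes_per_species] * self.n_species
        counts = list(self.haplotypes_per_species)
        if len(counts) != self.n_species:
            raise ContractError(
                "haplotypes_per_species length must equal n_species"
            )
        if any(c < 1 for c in counts):
            raise ContractError("each species needs >= 1 haplotype")
        return counts

    @property
    def mean_accuracy(self) -> float:
        return 1.0 - (self.sub_rate + self.ins_rate + self.del_rate)


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    species: str
    seq: str


@dataclass(frozen=True)
class Molecule:
    molecule_id: str
    haplotype_id: str
    species: str
    fwd_site: str   # concrete expansion carried by the tagging primer
    rev_site: str


@dataclass(frozen=True)
class TaggedMolecule:
    pair_id: str
    molecule_id: str
    haplotype_id: str
    species: str
    fwd_umi: str
    rev_umi: str
    fwd_site: str
    rev_site: str
    is_chimera: bool


@dataclass
class SimDataset:
    """Everything one simulated experiment produced, truth included."""

    config: SimConfig
    refdb: list[MitoRecord]
    haplotypes: dict[str, Haplotype]
    molecules: list[Molecule]
    tagged: list[TaggedMolecule]
    reads: list[NucSeq]
    truth: pd.DataFrame
    census: pd.DataFrame  # species, n_individuals, n_haplotypes

    def true_species_haplotype_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for hap in self.haplotypes.values():
            counts[hap.species] = counts.get(hap.species, 0) + 1
        return counts


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate_substitutions(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply exactly k substitutions at distinct positions."""
    arr = bytearray(seq, "ascii")
    positions = rng.choice(len(arr), size=k, replace=False)
    for p in positions:
        old = arr[p]
        choices = [b for b in b"ACGT" if b != old]
        arr[p] = choices[rng.integers(len(choices))]
    return arr.decode("ascii")


def simulate_reference_db(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[MitoRecord]:
    """One labelled control-region reference per species.

    Each record is flank + concrete forward primer site + D-loop + revcomp of
    a concrete reverse primer site + flank, with the D-loop annotated.
    Independently drawn random D-loops keep pairwise inter-species identity
    well below 90%.
    """
    rng = rng or np.random.default_rng(config.seed)
    fwd_exp = expand_degenerate(constructs.FWD_PRIMER_SITE)
    rev_exp = expand_degenerate(constructs.REV_PRIMER_SITE)
    lo, hi = config.dloop_length_range
    records = []
    for i in range(config.n_species):
        dloop = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        fwd_site = fwd_exp[rng.integers(len(fwd_exp))]
        rev_site = rev_exp[rng.integers(len(rev_exp))]
        left = _random_seq(rng, config.flank_length)
        right = _random_seq(rng, config.flank_length)
        seq = left + fwd_site + dloop + revcomp(rev_site) + right
        dstart = len(left) + len(fwd_site)
        records.append(
            MitoRecord(
                accession=f"SIM{i + 1:04d}",
                species=f"Species_{i + 1:02d}",
                seq=NucSeq(id=f"SIM{i + 1:04d}", seq=seq),
                features=(("D-loop", dstart, dstart + len(dloop)),),
            )
        )
    return records


def simulate_haplotypes(
    config: SimConfig,
    refdb: list[MitoRecord],
    rng: np.random.Generator | None = None,
) -> dict[str, Haplotype]:
    """Per-species haplotype sets derived from the reference D-loops.

    The first haplotype of each species is the reference D-loop itself;
    every further haplotype differs from it by a number of substitutions
    drawn from ``intra_species_divergence``, and all pairs are checked to
    differ by at least one substitution.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    counts = config.haplotype_counts()
    dlo, dhi = config.intra_species_divergence
    if dhi < 1 and any(c > 1 for c in counts):
        raise ContractError(
            "multiple haplotypes per species need divergence >= 1 substitution"
        )
    haplotypes: dict[str, Haplotype] = {}
    for rec, n_haps in zip(refdb, counts):
        start, end = rec.feature("D-loop")
        base = rec.seq.seq[start:end]
        seqs = [base]
        while len(seqs) < n_haps:
            k = int(rng.integers(max(1, dlo), dhi + 1))
            cand = _mutate_substitutions(rng, base, k)
            if cand not in seqs:
                seqs.append(cand)
        for h, seq in enumerate(seqs):
            hap_id = f"{rec.species}_hap{h + 1}"
            haplotypes[hap_id] = Haplotype(hap_id, rec.species, seq)
    return haplotypes


def make_molecules(
    config: SimConfig,
    haplotypes: dict[str, Haplotype],
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Template molecules entering the first PCR."""
    rng = rng or np.random.default_rng(config.seed + 2)
    fwd_exp = expand_degenerate(constructs.FWD_PRIMER_SITE)
    rev_exp = expand_degenerate(constructs.REV_PRIMER_SITE)
    molecules = []
    i = 0
    for hap in haplotypes.values():
        for _ in range(config.molecules_per_haplotype):
            i += 1
            molecules.append(
                Molecule(
                    molecule_id=f"mol{i:05d}",
                    haplotype_id=hap.haplotype_id,
                    species=hap.species,
                    fwd_site=fwd_exp[rng.integers(len(fwd_exp))],
                    rev_site=rev_exp[rng.integers(len(rev_exp))],
                )
            )
    return molecules


def attach_umis(
    molecules: list[Molecule],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TaggedMolecule]:
    """Tag each template with 1..2**(cycles-2) distinct UMI pairs.

    Extra first-PCR cycles re-tag copies of a template, inflating the number
    of apparent molecules; the count per template is drawn uniformly from
    that range.  With probability ``umi_chimera_fraction`` a pair is made
    chimeric: it reuses one side of a previously created pair and draws a
    fresh tag on the other side.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    max_pairs = constructs.max_umi_pairs_per_molecule(config.first_pcr_cycles)
    tagged: list[TaggedMolecule] = []
    n = 0
    for mol in molecules:
        n_pairs = int(rng.integers(1, max_pairs + 1))
        for _ in range(n_pairs):
            n += 1
            fwd_umi = _random_seq(rng, config.umi_length)
            rev_umi = _random_seq(rng, config.umi_length)
            is_chimera = False
            if tagged and rng.random() < config.umi_chimera_fraction:
                donor = tagged[rng.integers(len(tagged))]
                if rng.random() < 0.5:
                    fwd_umi = donor.fwd_umi
                else:
                    rev_umi = donor.rev_umi
                is_chimera = True
            tagged.append(
                TaggedMolecule(
                    pair_id=f"pair{n:05d}",
                    molecule_id=mol.molecule_id,
                    haplotype_id=mol.haplotype_id,
                    species=mol.species,
                    fwd_umi=fwd_umi,
                    rev_umi=rev_umi,
                    fwd_site=mol.fwd_site,
                    rev_site=mol.rev_site,
                    is_chimera=is_chimera,
                )
            )
    return tagged


def corrupt(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors.

    Per template base, independently: delete it with ``del_rate``, else
    substitute a random different base with ``sub_rate``; insert a random
    base after it with ``ins_rate``.
    """
    if sub_rate == ins_rate == del_rate == 0.0:
        return seq
    n = len(seq)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_code = np.zeros(n, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_code[codes == b] = i
    r = rng.random((n, 3))
    dels = r[:, 0] < del_rate
    subs = (~dels) & (r[:, 1] < sub_rate)
    # substitute: shift by 1..3 mod 4 guarantees a different base
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    base_code[subs] = (base_code[subs] + shift[subs]) % 4
    ins = r[:, 2] < ins_rate
    ins_code = rng.integers(0, 4, size=n).astype(np.uint8)

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.full((n, 2), 255, dtype=np.uint8)
    out[~dels, 0] = lut[base_code[~dels]]
    out[ins, 1] = lut[ins_code[ins]]
    flat = out.reshape(-1)
    return flat[flat != 255].tobytes().decode("ascii")


def simulate_reads(
    tagged: list[TaggedMolecule],
    haplotypes: dict[str, Haplotype],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[NucSeq], pd.DataFrame]:
    """Noisy reads plus a per-read truth table.

    Read counts per UMI pair are log-uniform over ``reads_per_umi_range``
    (matching the wide spread of real per-UMI coverage); each read is the
    full construct on a random strand with i.i.d. errors, and carries a flat
    phred quality consistent with the configured accuracy.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    lo, hi = config.reads_per_umi_range
    err = config.sub_rate + config.ins_rate + config.del_rate
    phred = 93 if err == 0 else min(93, int(round(-10 * math.log10(err))))
    reads: list[NucSeq] = []
    truth_rows = []
    k = 0
    for tm in tagged:
        template = constructs.assemble_molecule(
            tm.fwd_umi, tm.rev_umi, tm.fwd_site, tm.rev_site,
            haplotypes[tm.haplotype_id].seq,
        )
        n_reads = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        if tm.is_chimera:
            n_reads = int(round(n_reads * config.chimera_read_factor))
        n_reads = max(1, n_reads)
        for _ in range(n_reads):
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            seq = template if strand == "+" else revcomp(template)
            seq = corrupt(seq, rng, config.sub_rate, config.ins_rate,
                          config.del_rate)
            read_id = f"read{k:07d}"
            reads.append(NucSeq(id=read_id, seq=seq, qual=[phred] * len(seq)))
            truth_rows.append(
                dict(read_id=read_id, pair_id=tm.pair_id,
                     molecule_id=tm.molecule_id, fwd_umi=tm.fwd_umi,
                     rev_umi=tm.rev_umi, haplotype_id=tm.haplotype_id,
                     species=tm.species, strand=strand,
                     is_chimera=tm.is_chimera)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "pair_id", "molecule_id", "fwd_umi", "rev_umi",
                 "haplotype_id", "species", "strand", "is_chimera"],
    )
    return reads, truth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: references, haplotypes, UMIs, reads, truth."""
    rng = np.random.default_rng(config.seed)
    refdb = simulate_reference_db(config, rng)
    haplotypes = simulate_haplotypes(config, refdb, rng)
    molecules = make_molecules(config, haplotypes, rng)
    tagged = attach_umis(molecules, config, rng)
    reads, truth = simulate_reads(tagged, haplotypes, config, rng)

    hap_counts: dict[str, int] = {}
    for hap in haplotypes.values():
        hap_counts[hap.species] = hap_counts.get(hap.species, 0) + 1
    census = pd.DataFrame(
        {
            "species": list(hap_counts),
            "n_individuals": [
                hap_counts[s] * config.individuals_per_haplotype
                for s in hap_counts
            ],
            "n_haplotypes": [hap_counts[s] for s in hap_counts],
        }
    )
    return SimDataset(
        config=config, refdb=refdb, haplotypes=haplotypes,
        molecules=molecules, tagged=tagged, reads=reads, truth=truth,
        census=census,
    )
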