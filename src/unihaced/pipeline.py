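"""End-to-end pipeline: reads -> scans -> UMI clusters -> consensus ->
species assignment -> haplotype merging -> summary tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import report as report_mod
from .classify import ClassifiedCandidate, HaplotypeCall, assign_species, merge_haplotypes
from .consensus import consensus_for_cluster
from .core_io import MitoRecord, NucSeq
from .simulate import SimConfig, simulate_dataset
from .umi import ReadScan, ScanRejection, UmiCluster, cluster_umis, remove_chimeras, scan_read


@dataclass
class PipelineParams:
    """Tunable thresholds of the analysis pipeline."""

    scan_min_identity: float = 0.80
    umi_min_identity: float = 0.80
    consensus_cap: int = 100
    consensus_max_iters: int = 5
    #: UMI clusters with fewer reads cannot be error-corrected by consensus
    #: (a lone noisy read would pass all its errors through as "variants"),
    #: so they are dropped before consensus building.
    min_cluster_reads: int = 3
    assign_min_identity: float = 0.90
    variant_min_fraction: float = 0.6
    variant_min_reads: int = 3
    seed: int = 0


@dataclass
class PipelineResult:
    scans: list[ReadScan]
    rejections: list[ScanRejection]
    clusters: list[UmiCluster]
    chimeras: list[UmiCluster]
    candidates: list[ClassifiedCandidate]
    haplotypes: list[HaplotypeCall]
    unassigned: list[ClassifiedCandidate]
    funnel: pd.DataFrame = field(default_factory=pd.DataFrame)

    def haplotype_table(self) -> pd.DataFrame:
        return report_mod.haplotype_table(self.haplotypes)

    def species_haplotype_counts(self) -> dict[str, int]:
        return report_mod.species_haplotype_counts(self.haplotypes)


def run_pipeline(
    reads: list[NucSeq],
    refdb: list[MitoRecord],
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full analysis on a set of reads against a reference database."""
    params = params or PipelineParams()

    scans: list[ReadScan] = []
    rejections: list[ScanRejection] = []
    for read in reads:
        result = scan_read(read, min_identity=params.scan_min_identity)
        (scans if isinstance(result, ReadScan) else rejections).append(result)

    if scans:
        clusters = cluster_umis(scans, min_identity=params.umi_min_identity)
        kept, chimeras = remove_chimeras(clusters)
    else:
        clusters, kept, chimeras = [], [], []

    usable = [cl for cl in kept if cl.read_count >= params.min_cluster_reads]

    insert_of = {s.read_id: s.insert for s in scans}
    candidates: list[ClassifiedCandidate] = []
    for cl in usable:
        inserts = [insert_of[rid] for rid in cl.read_ids]
        cand = consensus_for_cluster(
            inserts,
            cap=params.consensus_cap,
            seed=params.seed,
            stream_key=cl.key,
            max_iters=params.consensus_max_iters,
        )
        assignment = assign_species(
            cand, refdb, min_identity=params.assign_min_identity
        )
        candidates.append(
            ClassifiedCandidate(
                candidate=cand,
                species=assignment.species,
                identity_pct=assignment.identity_pct,
                reads=inserts,
                umi_count=1,
            )
        )

    haplotypes, unassigned = merge_haplotypes(
        candidates,
        min_fraction=params.variant_min_fraction,
        min_reads=params.variant_min_reads,
    )

    funnel = report_mod.funnel_report(
        [
            ("total", len(reads)),
            ("construct_found", sum(len(c.read_ids) for c in clusters)),
            ("chimera_filtered", sum(len(c.read_ids) for c in kept)),
        ]
    )
    return PipelineResult(
        scans=scans, rejections=rejections, clusters=clusters,
        chimeras=chimeras, candidates=candidates, haplotypes=haplotypes,
        unassigned=unassigned, funnel=funnel,
    )


def recovery_trial(config: SimConfig, params: PipelineParams | None = None):
    """Simulate one experiment and score per-species haplotype recovery.

    Returns (dataset, result, exact) where ``exact`` is True iff the
    recovered per-species haplotype counts equal the simulated truth for
    every species.
    """
    dataset = simulate_dataset(config)
    params = params or PipelineParams(seed=config.seed)
    result = run_pipeline(dataset.reads, dataset.refdb, params)
    truth = dataset.true_species_haplotype_counts()
    recovered = result.species_haplotype_counts()
    exact = all(recovered.get(sp, 0) == n for sp, n in truth.items()) and set(
        recovered
    ) <= set(truth)
    return dataset, result, exact
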