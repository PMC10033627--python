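"""Summary artifacts: haplotype table, census comparison, stage funnel.

The haplotype table lists every final haplotype with its UMI and read
counts; the census comparison contrasts detected haplotypes with the known
tank population and yields two sensitivity statistics: the fraction of
censused species detected at all, and the fraction of censused individuals
represented by detected haplotypes among the detected species with known
headcounts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .classify import HaplotypeCall
from .errors import ContractError

TABLE_COLUMNS = [
    "haplotype_id", "n_umis", "reads", "dloop_length", "species",
    "identity_pct",
]


def _as_frame(haplotypes) -> pd.DataFrame:
    if isinstance(haplotypes, pd.DataFrame):
        return haplotypes.copy()
    rows = [
        dict(haplotype_id=h.haplotype_id, n_umis=h.umi_count,
             reads=h.read_count, dloop_length=h.dloop_length,
             species=h.species, identity_pct=h.identity_pct)
        for h in haplotypes
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def haplotype_table(haplotypes) -> pd.DataFrame:
    """Per-haplotype table with a totals row.

    Accepts a list of :class:`~unihaced.classify.HaplotypeCall` or an
    equivalent DataFrame.  Rows are sorted by species, then read count
    descending; a final ``Total`` row sums the UMI and read columns.
    """
    df = _as_frame(haplotypes)
    if df.empty:
        return pd.DataFrame(
            [dict(haplotype_id="Total", n_umis=0, reads=0, dloop_length=pd.NA,
                  species="", identity_pct=pd.NA)],
            columns=TABLE_COLUMNS,
        )
    df = df.sort_values(
        ["species", "reads"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    totals = pd.DataFrame(
        [dict(haplotype_id="Total", n_umis=int(df["n_umis"].sum()),
              reads=int(df["reads"].sum()), dloop_length=float("nan"),
              species="", identity_pct=float("nan"))]
    ).astype({"dloop_length": "float64", "identity_pct": "float64"})
    return pd.concat([df, totals], ignore_index=True)


def species_haplotype_counts(haplotypes) -> dict[str, int]:
    """Number of final haplotypes per species (totals row excluded)."""
    df = _as_frame(haplotypes)
    df = df[df["haplotype_id"] != "Total"]
    if df.empty:
        return {}
    return df.groupby("species").size().to_dict()


@dataclass(frozen=True)
class SensitivityStats:
    species_detected: int
    species_total: int
    species_sensitivity: float            # fraction
    species_sensitivity_pct: int          # rounded percentage
    haplotypes_detected: int              # over detected species w/ known census
    individuals_total: int
    population_sensitivity: float
    population_sensitivity_pct: int


def sensitivity_stats(census: pd.DataFrame, counts: dict[str, int]) -> SensitivityStats:
    """Species- and population-level detection sensitivity.

    ``census`` needs columns ``species`` and ``n_individuals`` (NA allowed
    for species of unknown headcount, e.g. feed fish).  Species sensitivity
    counts every censused species in the denominator; population
    sensitivity uses only detected species with known headcounts: detected
    haplotypes over censused individuals of those species.
    """
    if census.empty:
        raise ContractError("census is empty")
    species_total = len(census)
    detected = census["species"].map(lambda s: counts.get(s, 0) > 0)
    species_detected = int(detected.sum())
    if species_total == 0:
        raise ContractError("zero species in census")

    known = census["n_individuals"].notna()
    pop = census[detected & known]
    individuals_total = int(pop["n_individuals"].sum())
    haplotypes_detected = int(sum(counts.get(s, 0) for s in pop["species"]))
    if individuals_total == 0:
        raise ContractError("no detected species with known individual counts")

    species_sens = species_detected / species_total
    pop_sens = haplotypes_detected / individuals_total
    return SensitivityStats(
        species_detected=species_detected,
        species_total=species_total,
        species_sensitivity=species_sens,
        species_sensitivity_pct=int(round(species_sens * 100)),
        haplotypes_detected=haplotypes_detected,
        individuals_total=individuals_total,
        population_sensitivity=pop_sens,
        population_sensitivity_pct=int(round(pop_sens * 100)),
    )


def funnel_report(stages: list[tuple[str, int]]) -> pd.DataFrame:
    """Per-stage read counts as fractions of the first stage.

    Stages must be ordered and non-increasing (it is a funnel).
    """
    if not stages:
        raise ContractError("no stages given")
    counts = [c for _, c in stages]
    if counts[0] <= 0:
        raise ContractError("first stage must have positive reads")
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ContractError("funnel stage counts must be non-increasing")
    return pd.DataFrame(
        {
            "stage": [s for s, _ in stages],
            "reads": counts,
            "fraction": [c / counts[0] for c in counts],
        }
    )


# ---------------------------------------------------------------------------
# Bundled example data: a published 14-species aquarium-tank survey,
# re-entered from the printed tables (haplotype table and tank census).
# ---------------------------------------------------------------------------

def load_tank_haplotypes() -> pd.DataFrame:
    """Haplotype table of the bundled aquarium-tank example dataset."""
    with resources.files("unihaced.data").joinpath("tank_haplotypes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_tank_census() -> pd.DataFrame:
    """Tank census of the bundled example dataset (NA = unknown headcount)."""
    with resources.files("unihaced.data").joinpath("tank_census.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
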