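# unihaced

Counting fish by counting haplotypes: `unihaced` implements **universal
HaCeD-Seq** — estimating the number of individuals of each fish species in
an environment by counting distinct mitochondrial D-loop (control region)
haplotypes amplified from environmental DNA (eDNA) with universal primers
and sequenced as UMI-tagged long reads.

The D-loop is the most variable region of the fish mitogenome, so with high
haplotype diversity each detected haplotype marks at least one distinct
individual. The package covers the whole computational path:

* **Universal primer design** — profile a multiple alignment of the regions
  flanking the D-loop (tRNA-Thr and 12S rRNA), locate conserved runs with a
  *gap-considered identity score*, and emit IUPAC degenerate primers
  (positions conserved in ≥ 85% of species stay plain; the rest become
  minimal mixed-base codes). Primer pairs are evaluated by exhaustive
  in-silico PCR (all degenerate expansions, both strands, convergent
  orientation, plausible amplicon length).
* **UMI analysis of noisy long reads** — each sequenced molecule carries the
  construct `adapter+anchor | N13 UMI | fwd primer site | D-loop |
  rev primer site | N13 UMI | anchor+adapter`. Reads are scanned for both
  flanks by semi-global alignment (accepted at ≥ 80% identity), UMI pairs
  are clustered greedily by abundance (> 80% identity joins the more
  abundant tag), and UMI chimeras — pairs sharing exactly one tag with
  another pair — are resolved by keeping the pair with the most reads.
* **Consensus + polish** — per UMI cluster, a center-star draft consensus
  from at most 100 reads, then iterative pileup polishing with all cluster
  reads to a fixpoint.
* **Species assignment and haplotype merging** — best-hit identity against a
  D-loop reference database; within a species, a smaller cluster is merged
  into the dominant haplotype unless its reads support at least one mutation
  (allele fraction ≥ 0.6, ≥ 3 reads) against it.
* **A truth-tracked simulator** — reference databases, haplotype sets,
  first-PCR UMI tagging with extra-cycle UMI inflation (up to 2^(c−2)
  apparent molecules per template at *c* cycles) and chimera injection, and
  nanopore-like reads with i.i.d. substitution/insertion/deletion errors —
  so every stage is testable end to end against known ground truth.

## Worked example

Simulate a small tank, run the full pipeline, and compare against truth:

```python
import unihaced as uh
from unihaced.simulate import SimConfig

cfg = SimConfig(seed=1, n_species=3, haplotypes_per_species=2,
                molecules_per_haplotype=2, first_pcr_cycles=3,
                umi_chimera_fraction=0.05, reads_per_umi_range=(20, 60))
dataset, result, exact = uh.recovery_trial(cfg)
print(dataset.true_species_haplotype_counts())
print(result.species_haplotype_counts())
print(result.funnel)
```

prints

```
{'Species_01': 2, 'Species_02': 2, 'Species_03': 2}
{'Species_01': 2, 'Species_02': 2, 'Species_03': 2}
              stage  reads  fraction
0             total    612  1.000000
1   construct_found    612  1.000000
2  chimera_filtered    583  0.952614
```

i.e. from 612 noisy reads (≈ 94% accuracy) the pipeline found the construct
in every read, dropped 29 reads whose UMI pairs lost chimera conflicts, and
recovered exactly the two simulated haplotypes of each species.

The same stages are available from the shell:

```bash
unihaced simulate --seed 1 --out sim/
unihaced run --reads sim/reads.fastq --refdb sim/refs.fasta --out out/
unihaced report --haplotypes out/haplotypes.tsv --census sim/census.tsv --out report/
```

The package also bundles a re-entered haplotype table and tank census from
a published 14-species aquarium-tank survey
(`unihaced.load_tank_haplotypes()`, `unihaced.load_tank_census()`) as a
worked example for the reporting layer: 19 haplotypes over 5 detected
species, totals of 29 UMIs and 30,978 reads, species detection sensitivity
5/15 (33%) and population detection sensitivity 10/35 (29%).

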