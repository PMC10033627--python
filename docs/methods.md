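# Methods

This note records the models and procedures `unihaced` implements, the
parameters that matter, and the design decisions taken where the underlying
protocol leaves the computation open.

## Problem setting

HaCeD-Seq ("haplotype count from eDNA") estimates the number of individuals
of a species present in an environment by counting distinct mitochondrial
control-region (D-loop) haplotypes amplified from environmental DNA.
Because the D-loop is hypervariable, two individuals of the same species
usually carry different haplotypes; each distinct haplotype detected is
therefore a lower bound of one individual. The universal variant of the
protocol amplifies the D-loop of many fish species at once with degenerate
primers placed in the conserved tRNA-Thr and 12S rRNA regions flanking it,
tags every template molecule with a 13-base UMI on both ends during a short
first PCR, amplifies with adapter primers in a second PCR, and sequences
the ~1.2 kb products on a nanopore instrument.

## Sequence primitives

* Identity of two sequences is defined as matches / alignment columns of an
  optimal unit-cost alignment (match 0, mismatch 1, indel 1), computed with
  edlib. The protocol's "80% homology" thresholds never state a
  denominator; alignment columns is the standard choice and is what all
  thresholds here mean. In global mode the argument order is canonicalized
  (shorter, then lexicographic) because edlib's traceback among co-optimal
  alignments depends on which sequence is the query; this makes the
  statistic symmetric. Semi-global identity aligns the shorter sequence as
  an infix of the longer one.
* All coordinates are 0-based half-open. Sequences are uppercased on input;
  reads are restricted to `ACGTN`, primers to the 15 IUPAC codes.

## Primer design

Given a multiple alignment of D-loop-flanking regions (the aligner itself
is out of scope; any aligned FASTA works):

* **Column profiles**: occupancy (non-gap fraction), A/C/G/T counts,
  consensus base and consensus fraction (ties broken alphabetically).
* **Consensus sequence**: columns with occupancy strictly above 0.90 are
  kept (configurable; quoted thresholds of the protocol use "more than").
* **Gap-considered identity score**: a left-to-right running score that
  adds the consensus fraction at each well-occupied column and subtracts 1
  (floored at 0) at each poorly occupied column. A plain per-column
  identity cannot distinguish a long conserved run from conserved islands
  inside badly aligned sequence; the subtraction makes interruptions
  expensive, so score maxima mark primer-ready conserved runs. The exact
  arithmetic of the original description is ambiguous; this recurrence is
  our concrete operationalization and is documented as such.
* **Degenerate primer emission**: per window column, the consensus base if
  its fraction is ≥ 0.85, otherwise the minimal IUPAC code covering the
  smallest base set whose summed frequency reaches 0.95 of non-gap bases
  (bases added by decreasing frequency). The 0.95 cover rule is ours: it
  bounds degeneracy while covering common alleles; both thresholds are
  configurable. Windows must lie entirely in well-occupied columns.
* **In-silico PCR**: every expansion of both primers is matched exhaustively
  (substitutions only, default max 2 mismatches) on both strands of each
  reference; a hit needs convergent orientation and an inter-3'-end
  distance inside (500, 3000) bp. Substitution-only matching was chosen
  over a seeded blast-like search because it is deterministic and
  brute-force verifiable; the test suite checks equivalence against a
  literal all-expansions × all-positions scan.

## Simulator

The generator emulates the study conditions of a 14-species aquarium-tank
experiment and tracks ground truth per read (molecule, UMI pair, haplotype,
species).

* **References**: one labelled D-loop per species (length 1000–1100 bp,
  matching observed D-loop lengths), flanked by concrete expansions of the
  two primer sites plus 120 bp of random flank. Independent random D-loops
  keep inter-species identity far below the 90% assignment threshold.
* **Haplotypes**: per species, the reference D-loop plus variants carrying
  2–10 substitutions each (all pairs verified distinct). Haplotypes closer
  than 1 substitution are biologically identical and are rejected.
* **UMI tagging**: with *c* first-PCR cycles, each template acquires
  between 1 and 2^(c−2) distinct UMI pairs (uniform, seeded) — two cycles
  are needed to fix a pair, every extra cycle can double the apparent
  molecule count. UMIs are uniform over 4^13. With probability
  `umi_chimera_fraction` a pair is chimeric: it reuses one side of a
  previously created pair with a fresh opposite side. Chimeric pairs'
  read counts are scaled by `chimera_read_factor` (default 0.25): chimeras
  arise in later PCR cycles than genuine pairs, so they accumulate fewer
  copies — this is also the premise that makes the keep-the-most-reads
  chimera rule sound.
* **Reads**: the full two-PCR construct on a random strand, corrupted by
  i.i.d. per-base substitution/insertion/deletion errors (defaults
  0.02/0.02/0.02, giving mean read accuracy ≈ 94%, the accuracy scale of
  the nanopore flow cells the protocol used). Read counts per UMI pair are
  log-uniform over a configurable range (default 5–5000, matching the wide
  per-UMI spread seen in real runs). Base qualities are flat and encode the
  configured accuracy.
* Seeded runs are bit-reproducible.

What the generator does **not** model: homopolymer-biased indels, read
truncation and adapter dropout (the dominant loss mode in real runs —
hence real funnels lose ~88% of reads at scanning while simulated funnels
lose almost none), chimeric inserts (only chimeric UMI pairs), abundance
differences between species, and quality-score realism beyond the mean.
Passing tests therefore demonstrate the correctness of the pipeline's
logic under the stated error model, not performance on real flow-cell
data.

## UMI processing

* **Scanning**: both flank constructs (adapter+anchor+N13+primer site,
  degenerate codes matching the bases they cover) are located by
  semi-global alignment on both strands; the strand with the higher summed
  flank identity wins. A read is accepted iff both flanks reach 80%
  identity in convergent orientation. The UMI is read off the bases aligned
  to the N13 block; lengths 11–15 are accepted (indels inside the UMI are
  normalized by the alignment window), otherwise the read is rejected as
  low-identity. Presence/absence of a flank (the `no_fwd`/`no_rev`
  rejection reasons) is judged on the non-UMI columns only, because N13
  matches anything and would let random sequence score ~0.7.
* **Clustering**: raw UMI pairs are tallied and processed in descending
  read-count order (ties lexicographic); each pair joins the first
  already-accepted cluster whose canonical concatenated 26-mer exceeds 80%
  identity with its own, else founds a new cluster. Identity on the
  concatenated pair (rather than per tag) was chosen because chimera
  detection depends on pair semantics; a per-tag mode is available. The
  greedy first-match-in-abundance-order rule is order-deterministic.
* **Chimera removal**: clusters whose canonical pairs share exactly one
  side form conflict components (union-find over shared sides); each
  component keeps only its highest-read cluster (ties: lexicographically
  smallest pair). Conflict-free clusters pass through untouched.

## Consensus and polishing

* **Draft**: a seeded subsample of at most 100 inserts (the subsample
  stream is keyed by run seed + canonical UMI pair, so cluster iteration
  order cannot change results); the center is the insert of median length;
  all sampled inserts are aligned to the center and voted per column,
  including insertion slots; majority-gap columns are dropped. A
  center-star construction is adequate because cluster members are copies
  of one molecule (near-identical), and it is O(n·L²) and deterministic.
* **Polish**: iterate — align every insert to the current consensus, build
  a pileup with insertion alleles between columns, replace every position
  by its majority allele (ties prefer the current base, then alphabetic;
  insertions are emitted only when more than half the reads carry one) —
  until a fixpoint or 5 iterations. The original protocol used a neural
  polisher as a black box; a majority-pileup polisher is deterministic,
  auditable, and exact in the error-rate→0 limit. Convergence is almost
  always reached in ≤ 2 iterations.
* Clusters with fewer than 3 reads are dropped before consensus: a lone
  noisy read cannot be error-corrected, and under the variant-calling rule
  below each of its errors would count as a supported mutation, making such
  clusters unmergeable noise. A minimum-reads-per-UMI filter is standard
  practice in dual-UMI long-read consensus pipelines.

## Species assignment, variants, merging

* **Assignment**: the candidate consensus is aligned semi-globally against
  both strands of every reference; best identity wins (ties: longer
  alignment, then accession). Below 90% identity the candidate is reported
  unassigned and never merged. Semi-global was chosen over local alignment
  deliberately: a maximal-scoring local segment can be short and ~100%
  identical, which would defeat an identity threshold entirely.
* **Variant calling**: reads are piled up on a reference haplotype; a
  variant is called where one non-reference allele (substitution, deletion,
  or insertion) reaches fraction ≥ 0.6 with at least min(3, n_reads)
  reads. With i.i.d. errors at ~2% per type no allele approaches 60%, so
  reads drawn from the reference yield no calls; a single true substitution
  is called with near-certainty at any realistic cluster size. The 0.6/3
  thresholds are this package's own (the original delegates to an external
  caller); they are chosen to work down to ~7-read clusters while rejecting
  i.i.d. errors.
* **Merging**: per species, the unprocessed candidate with the most reads
  anchors a round; every smaller candidate whose reads produce no variant
  call against the anchor is merged into it (UMI and read counts add, the
  anchor's consensus is kept); candidates with calls wait for later rounds.
  Merging conserves per-species UMI and read totals and is idempotent.

## Reporting

The haplotype table (id, UMIs, reads, D-loop length, species, identity)
is sorted by species then reads, with a totals row. Species sensitivity is
detected species / censused species (species of unknown headcount stay in
the denominator). Population sensitivity is Σ detected haplotypes over
detected species *with known headcounts* / Σ censused individuals of those
species — species such as feed fish, with unknown counts, are excluded
from both sums. Percentages are reported rounded to the nearest integer
with exact fractions retained. Funnel reports give per-stage read counts
as fractions of stage 1 and must be non-increasing.

## Problem sizes and numerical choices

The bundled example tables (19 haplotypes, 15 censused species) reproduce
their aggregations exactly and instantly. Stochastic recovery experiments
use 14 species with 1–3 haplotypes each, 2 template molecules per
haplotype, 3 first-PCR cycles, 5% chimera injection, 50–200 reads per UMI
pair and the default 6% error rate (~8–11k reads per simulation); success
means exact per-species haplotype counts for all species. These sizes keep
a 20-trial experiment at desk scale while exercising every stage of the
pipeline. UMI clustering uses an exact k-bounded edit-distance prefilter
(identity > t forces d ≤ (1−t)(|a|+|b|)/(1+t)); species assignment uses a
distance-only first pass with the exact identity bound |q|/(|q|+d) to skip
hopeless references. Both shortcuts are provably lossless.

## Known limitations

* Haplotype sharing between individuals is not modelled: the method counts
  haplotypes, which is a lower bound on individuals.
* The simulator's i.i.d. error model understates structured nanopore error
  (homopolymers), so real-data consensus accuracy will be somewhat worse
  than simulated at equal coverage.
* Detection sensitivity on real eDNA is dominated by wet-lab factors (long
  fragments degrade quickly, low eDNA concentrations) that are outside the
  computational scope.
* Cross-species merging is never attempted; species partitions are hard
  boundaries, and unassigned candidates are reported but not merged.
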