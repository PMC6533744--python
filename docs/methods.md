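# Methods

## Model and assumptions

`radsub` treats sex-marker discovery as a set-subtraction problem over
exact, fixed-length sequence tags. Under female heterogamety (ZW), a
W-limited locus yields RAD-tags that appear in female libraries and in no
male library or male genome assembly; the pipeline operationalises this as

```
candidates = (∩ female tag sets) \ (∪ male tag sets)
markers    = candidates with no ≥90%-identity full-length alignment to the male genome
```

The two stages play different roles. The read-level screen is sensitive but
noisy in both directions: a shared locus can look female-limited simply
because no male read sampled it (sub-1× coverage makes this common), and
the genome-level filter removes exactly those cases, because a shared locus
is still present in male genomic data even when unsequenced in the RAD
library. Conversely a true W tag survives both stages. Tags are compared in
canonical orientation (lexicographic minimum of a sequence and its reverse
complement) so that library strand arbitrariness cannot break
presence/absence logic; a flag restores naive orientation.

Key assumptions: tags are exact (no allowance for polymorphism or
sequencing error at the screen stage — errors create singleton tags that
the per-individual presence requirement suppresses); candidates are fixed
at the 110-nt tag length; diploid heterozygosity, indels and PCR duplicates
are not modelled.

## Synthetic populations

The generator emulates the original experiment's design parameters: EcoRI
(`G^AATTC`) + NlaIII (`CATG^`) double digestion; retention of fragments
whose gel size (genomic insert + 75 bp adapter) lies in 400–600 bp
inclusive, i.e. 325–525 bp inserts; 150 bp paired-end reads whose read-1
carries a 4–6 nt inline MID followed by the `AATTC` residual; per-fragment,
per-individual read counts drawn Poisson(mean_depth), with mean_depth
defaulting to 5 so presence in every source individual is near-certain
(P(missing) = e⁻⁵ per individual per fragment); i.i.d. per-base
substitution errors at a configurable rate (default 0); Phred scores drawn
from a clipped normal(36, 3) — a crude HiSeq-like profile, independent of
the error process.

W-limited regions are random sequences (default 2 kb) inserted at random
points of the shared genome, each carrying one engineered cassette:
`GAATTC` + motif-free filler + `CATG`, with the filler length drawn so the
cassette's single A/B fragment passes size selection. Fillers are redrawn
until the cassette contains exactly one site of each enzyme, so the planted
fragment is guaranteed discoverable and serves as ground truth for recall
tests. Junction fragments spanning the insertion boundaries are a realistic
side effect: they are genuinely female-specific (they contain W sequence)
and are counted as true discoveries, not false positives.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: polymorphism between individuals of the same sex,
repetitive DNA (random sequence is repeat-free, so the genome filter is
easier than on a real 50 Gb genome), coverage heterogeneity beyond Poisson,
indel/quality-correlated errors, and fragment-length biases within the gel
window.

### Digestion model

The digestion is single-stranded and coordinate-based: cuts at motif+1
(EcoRI) and motif+4 (NlaIII), fragments between adjacent cuts, and only
fragments with one cut from each enzyme retained (standard ddRAD chemistry:
P1 ligates to EcoRI ends, P2 to NlaIII overhangs). Two consequences need
care. First, when the two enzymes cut the same phosphate (`CATGAATTC`),
cuts are ordered by how much of the motif lies downstream, so the upstream
fragment keeps its NlaIII end and the downstream one its EcoRI end, as the
chemistry dictates. Second, a fragment whose EcoRI end is on the right
cannot carry the 5′ `AATT` overhang in one cut coordinate; each fragment
therefore stores an `insert` — the library insert oriented EcoRI-end first
with both residues restored (`AATTC…CATG`) — from which reads are built,
while `sequence`/coordinates retain the plain genomic slice used for size
selection.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| tag_length | 110 | nt | trimmed tag length of the original study |
| max_n_fraction | 0.10 | fraction | reads with strictly more than 10% N removed |
| select_min/select_max | 400/600 | bp | gel window, adapter included |
| adapter_length | 75 | bp | adapter share of gel size; exposed because the original protocol is ambiguous about it |
| mean_depth | 5 | read pairs/fragment/individual | smallest depth at which per-individual presence is near-certain |
| min_source_individuals | all | individuals | a real sex-limited locus should be sequenced in every source animal; relaxable for sparse data |
| min_depth | 1 | reads | depth for counting a tag "present" in a source individual |
| max_mismatch_fraction | 0.10 | fraction | genome-filter identity threshold (~BLAST-like for 110-nt queries) |
| seed_length | 20 | nt | upper bound on the exact seed used by the genome filter |
| size_tolerance_bp | 5 | bp | gel-resolution analogue for band calling |
| primer_length | 20 | nt | naive primers from marker ends in the round-trip check |

## Numerical and design choices

* **Cleaning order.** The N-fraction is computed on the trimmed 110-nt tag,
  after the residual check; threshold is strict (>10%), so 11 N in 110 is
  kept and 12 removed. Cleaning is idempotent: with the residual kept
  (default) a read needs only `tag_length` bases, so cleaned output passes
  through unchanged.
* **MID matching** is exact with longest-match-wins, required because the
  study's barcodes vary from 4 to 6 nt and can nest.
* **Mean depth** is defined as raw reads / distinct tags, and **coverage**
  as raw bases / genome size (5.0×10¹⁰ by default). Values are held at full
  precision and rounded half-up only at report time (1 dp and 2 dp
  respectively). Recomputing the published eight-animal summary this way
  reproduces 6/8 printed depth cells and 5/8 printed coverage cells
  exactly; the five others (adX1, adX3 depth; adC2, adC3, adX3 coverage)
  disagree by one unit in the last printed digit and are consistent with no
  rounding convention, so the package reproduces per-row values from first
  principles and likewise recomputes the Subtotal/Subaverage/Total/Average
  rows (the published aggregate coverage rows are also internally
  inconsistent). The strict acceptance tests for those five cells fail by
  design and document the discrepancy.
* **Genome filter completeness.** With an 11-substitution budget on a
  110-nt query, fixed 20-nt seeds cannot guarantee sensitivity (pigeonhole
  needs 12 disjoint seeds of ≤9 nt). The filter therefore uses
  `min(seed_length, ⌊L/(m+1)⌋)`-nt seeds at m+1 disjoint offsets, which
  makes the seed-and-extend search provably equivalent to an exhaustive
  Hamming scan — the property the oracle tests assert. `seed_length` acts
  as an upper bound for speed on easier settings.
* **In-silico PCR** requires the 3′-terminal base of each primer to match
  exactly (extension chemistry), allows a configurable substitution budget
  elsewhere (default 0), tests both template strands, reports plus-strand
  coordinates, and requires non-overlapping primer footprints
  (product ≥ both primer lengths).
* **Sex calling** is a majority vote across panel markers; ties (including
  an empty panel) are `indeterminate`, and indeterminate calls are never
  listed as reversals. Reversal direction reads genetic → phenotypic.
* **Selection of candidates for validation** is a uniform
  without-replacement sample under a recorded seed, preserving input order.
* **Provenance.** Every TSV output carries the config hash and seed in
  `#` comment headers; FASTA/FASTQ formats have no comment syntax, so their
  provenance lives in the stage manifest (`sim/manifest.json`).
* **Reference tags.** The original workflow assembled one reference
  individual per sex and screened those sequences; here the source tag
  universe is the union of source-sex catalogs intersected with the
  presence-in-all requirement, which at the default settings equals using
  any single individual's tags as the universe, and avoids privileging an
  arbitrary reference. Passing a single reference catalog reproduces the
  literal design.

## Problem sizes

The shipped configuration (100 kb shared genome, 3 × 2 kb W regions, 4+4
individuals, mean depth 5) yields ~320 read pairs and runs the whole
pipeline in about a second; oracle-equivalence tests use 20–50 kb random
sequences and 10 instances per operation. These sizes were chosen so the
planted-truth guarantees hold with margin while the full suite stays
interactive; all scale linearly if larger studies are simulated.

## Known limitations

Exact-match stacking means a single sequencing error splits a tag, so
real-data use should keep `min_depth` low and rely on the genome filter;
the genome filter models substitutions only (no indels, no affine-gap local
alignment as BLAST would report); primer design is naive end-clipping, with
no thermodynamic screening; and the negative-control lane of a wet-lab gel
is modelled as template-free (always band-negative).
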