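# Methods

## Model and assumptions

The package treats a population of independently mutagenized lines as
replicates of the *error process*, not of the mutation process. Two
assumptions drive everything:

1. **True induced mutations are private.** EMS hits nearly random
   G/C sites; with m mutations per line over G mutable sites, the
   probability that two specific lines share a position is m²/G per
   pair, so shared positions are overwhelmingly artifacts.
2. **Systematic errors replicate.** The dominant error mechanism is a
   divergent paralog: reads from a duplicate segment mismap onto its
   twin and support the paralog's base at the divergent offset, in
   every line, always with the same allele. Such positions are
   recurrent across lines, allele-consistent, and their 51-nt context
   aligns elsewhere in the genome with a mismatch exactly at the
   variant site.

The filters preceding replication analysis are per-call predicates on
standard VCF annotations (QUAL, DP, GT, DP4), applied in a fixed
order: repeat filter (QUAL ≥ 10, 2 ≤ DP ≤ 100, strict removal below/
above), genotype-class filter (QUAL ≥ 20, inclusive), then the strand
predicate — DP4 = (0, 0, >0, >0) for homozygous-alternate calls,
alt-on-both-strands for heterozygous calls. Thresholds follow the
stated rules exactly: the boundary values 10, 2, 100 and 20 are kept.
A call parsed without DP4 receives (0,0,0,0) and therefore cannot
pass either strand predicate — deliberately conservative.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_keep_qual` | 10 | repeat-filter quality floor (phred) |
| `min_depth` / `max_depth` | 2 / 100 | read-depth band; above it, repetitive origin is presumed |
| `min_genotype_qual` | 20 | class-filter quality floor (phred) |
| `min_replicates` | 2 | lines sharing a position before it is cataloged as error-prone |
| `sibling_threshold` | 0.68 | pairwise overlap fraction above which a pair is flagged as contaminated |
| `recover_max_n` | 2 | largest replicate count eligible for false-negative recovery |
| scanner `word_size` | 11 | exact seed length for the ungapped scan |
| scanner `max_mismatches` | 3 | mismatch budget for 51-nt end-to-end alignments |

`min_replicates` = 2 and `recover_max_n` = 2 reflect the observed
signal-to-noise behavior: the G:C→A:T percentage among replicate
positions collapses for replicate counts above two, so only n = 2
positions retain an appreciable chance of being coincident true
mutations.

## Design choices at genuinely open points

* **Position matching ignores the allele.** Replicate positions are
  keyed by (chrom, pos) within a genotype class; nearly all real
  error-prone positions are allele-consistent anyway, and
  position-level matching is the more conservative mask. Allele-level
  matching is available via `mask_calls(..., match_allele=True)`.
* **Homozygous and heterozygous catalogs are separate**, matching the
  separate bookkeeping of the two call classes; the two masks do not
  cross-apply. Applying both sequentially gives the union-mask.
* **Overlap denominator.** The sibling overlap fraction uses
  |A∩B| / min(|A|,|B|): the choice most sensitive to one contaminated
  library dominating a smaller call set.
* **Both members of a flagged pair are dropped from the builder set**
  but their call sets are still masked, so pedigree-shared true
  mutations are not cataloged as errors yet their carriers still get
  artifact removal.
* **Recovery requires allele consistency** in addition to a canonical
  EMS consensus at n ≤ 2: two lines calling different alleles at one
  position contradict a single ancestral mutation event.
* **Indels are keyed by start position across genotype classes.** An
  insertion and a deletion starting at the same base in two lines
  both mark the position; event length and class are ignored for
  keying, because replicate indel artifacts shift alignment-dependent
  representations of the same locus.
* **Consensus alleles** are modal with lexicographic tie-breaking,
  for determinism.
* **Paralog search is a deterministic seed-and-verify scanner** built
  for exactly one job — end-to-end, gap-free alignment of short
  fixed-length windows with a hard mismatch budget — rather than a
  general-purpose local aligner with e-value statistics. The scan
  partitions a query of length 51 into `max_mismatches + 1`
  disjoint exact words of 11; by pigeonhole every alignment within
  the budget contains one exact word, so seeding is provably
  exhaustive whenever (max_mismatches+1)·word_size ≤ query length —
  hence the default budget of 3 for 51-nt queries, the largest value
  the guarantee covers. "Perfect" means 0 mismatches, "near-perfect"
  1..max mismatches. Both strands are scanned; the query's own
  source interval is excluded. The scanner is verified against an
  exhaustive slide-all-offsets oracle in the test suite.
* **Motif discovery is not reimplemented**; `export_windows_fasta`
  writes a seeded subsample of 21-nt windows for external motif
  tools.

## The synthetic population

The generator's defaults are the reference study conditions: a 2 Mb
i.i.d. genome in 2 chromosomes with 10 planted repeat families (one
master, 2 copies of 500 bp diverged at rate 0.02); 50 lines × 500
mutations at 98% G:C→A:T purity (the remainder drawn from the minor
classes with A:T→G:C most common), 27% heterozygous; 100 error-prone
positions planted at paralog-divergent offsets, each firing per line
with probability 0.5 and always with the copy's base as the artifact
allele; one contaminated pair sharing 80% of one line's mutations;
depths ~ Poisson(7).

What it emulates — and what it does not. Calls are generated at the
variant-call level, not the read level: DP4 is drawn consistently with
zygosity at *detectable* sites (homozygous: no reference reads,
alternate on both strands; heterozygous: both alleles present), and
QUAL is a deterministic monotone function of alternate-allele depth,
sufficient to exercise every threshold but not a genotype-likelihood
model. Real data additionally contain coverage dropouts (false
negatives), base-call noise, mapping-quality gradients, partial-
penetrance artifact alleles with variable DP4 balance, and reference-
line residual polymorphism — none of which are modeled. Passing tests
therefore demonstrate that the *replication logic* is correct under
the assumed causal structure, not that any particular real data set
is this clean. An optional `context_bias` multiplier enriches
mutations at CG-dinucleotide G/C sites for testing the context
profiler; a uniform-error mode is deliberately absent because
position-random errors would not replicate and are already handled by
the per-line filters.

## Numerical conventions

* Coordinates: 1-based inside the library (VCF convention); exported
  interval files are 0-based half-open BED.
* Multi-allelic records are split per alternate allele before
  filtering, each split inheriting QUAL, DP and DP4.
* Deviation profiles are 100·(mut − rand)/rand per position × base,
  defined only for equal sample sizes; cells with zero random count
  are NaN. Reported percentages round half away from zero; full
  precision is kept internally.
* Per-line means in summary tables are total/n_lines rounded half
  away from zero.
* Empty inputs yield NaN statistics (spectrum fraction, correlations
  with fewer than 3 lines or zero variance) rather than exceptions.
* All randomness flows from a single integer seed through
  `numpy.random.Generator`; identical configurations produce
  byte-identical simulation output.

## Problem sizes used in the checks

The bundled checks run the reference conditions (50 lines, 2 Mb, 500
mutations/line) for the end-to-end recovery, spectrum and
contamination assertions; 20 such simulations for the coincidence
expectation C(L,2)·m²·purity²·(h²+(1−h)²)/G_{G/C} (with G_{G/C} the
number of G/C sites, h the heterozygous fraction); and a 100 kb
genome with 50 planted paralogs for the exact scanner-oracle
equivalence. These sizes preserve the regime the method assumes —
coincidence rate far below the per-line mutation count, error
positions recurring in many lines — while the unit suite uses smaller
populations for speed.

## Known limitations

* The ungapped scanner's exhaustiveness guarantee requires
  (max_mismatches+1)·word_size ≤ query length; larger budgets fall
  back to raising an error rather than silently missing hits.
* Sibling detection is pairwise only; it flags contaminated pairs but
  does not reconstruct pedigrees or handle three-way contamination
  specially (all members of any flagged pair are excluded from
  building).
* Transcript assignment counts a SNP once per transcript containing
  it; overlapping transcripts each count it, as transcript-level
  target-size analyses require.
* The indel catalog stores the replicate start positions but no
  normalized event identity; left-alignment of indels is assumed to
  have happened upstream.
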