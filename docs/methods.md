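# Methods

## Problem and model

In a species with an XY sex-determination system, regions of the Y that have
stopped recombining with the X accumulate male-specific sequence. A k-mer of
fixed length drawn from such a hemizygous region appears in every male read
set (at roughly half the diploid coverage, since males carry one copy) and in
no female read set. `ystrata` exploits this signal in four steps:

1. **Male-specific k-mer derivation.** Canonical 16-mers are counted per
   sample; a k-mer is kept iff its count is at least `male_min` in every male
   and at most `female_max` in every female. Lower bounds exclude sequencing
   errors; the female tolerance absorbs recurrent errors without admitting
   genuinely shared sequence.
2. **Y-contig assignment.** In a phased diploid assembly of a male, each
   contig has two haplotype sequences. Male-specific matches concentrate on
   the Y-carrying haplotype, so a contig is called Y-linked when the match
   ratio between its haplotypes is at least 2.5, the Y haplotype carries at
   least 30 matches, and the match density is at least one per 2 kb of
   effective length.
3. **Density-block segmentation.** Under continuous Y degeneration the
   density of male-specific k-mers should fall off smoothly along contigs
   sorted densest-first; discrete recombination-suppression events instead
   produce runs of contigs sharing a density ("k-mer density blocks",
   candidate evolutionary strata). At each position the mean density of the
   previous `window` contigs is divided by that of the next `window`;
   sufficiently high local maxima of this ratio are called as block
   boundaries.
4. **Synteny anchoring.** Tabular alignment hits of Y contigs against an
   annotated reference are reduced to one best hit per contig (maximal
   bitscore); per block the dominant reference chromosome, the anchor
   position range and a Kendall-type concordance between density rank and
   anchor position summarise collinearity.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 16 | k-mer length; 4^16 ≈ 4.3e9 codes fit a 32-bit word, making random 16-mer collisions across a sub-gigabase genome rare |
| `male_min` / `female_max` | data-dependent | per-sample count bounds; the shipped "paper mode" profile is 25/21 for the deep reference pair and 3 / 9,8 for the additional pairs |
| `min_ratio` | 2.5 | minimal haplotype match-count ratio (inclusive) |
| `min_kmers` | 30 | minimal matches on the Y haplotype (inclusive) |
| `max_bp_per_kmer` | 2000 bp | maximal effective bp per match (inclusive); "at least one per 2 kb" |
| `window` | 5 | contigs per side in the ratio scan |
| `peak_min_ratio` | 1.5 | minimal scan ratio at a breakpoint |
| `min_separation` | = window | minimal spacing between called peaks |

The peak-calling threshold and separation have no published counterpart (the
original analysis read peaks by eye), so they are explicit configuration with
these defaults: 1.5 sits well above within-stratum sampling noise at window 5
yet below the ≥ 3-fold steps the block model predicts.

Boundary conventions: all three selection cutoffs are inclusive ("at least"
semantics). An exact tie in haplotype match counts yields no Y call — a tie
carries no phasing signal — and such contigs are never selected. Positions
are 0-based, intervals half-open.

## Numerical and convention choices

- **Canonical k-mers throughout.** Reads sample both strands uniformly, so
  every window is represented by the smaller of its forward and
  reverse-complement 2-bit encodings; a flag restores stranded counting.
- **Ambiguity.** Windows overlapping any non-ACGT character are skipped
  whole, matching standard k-mer counters; soft-masked lowercase reads as
  uppercase. Effective length excludes N bases always, and lowercase bases
  only for finished (BAC-like) contigs, whose resolved repeats would
  otherwise deflate their density relative to short-read contigs.
- **Density averages** in the scan use k-mers per effective bp. The
  reciprocal convention (bp per k-mer, the usual plotting axis) is exposed
  via a flag; means of reciprocals differ, so the convention is stated
  rather than silent.
- **Scan direction.** The leading (already-passed, denser) window is the
  numerator, so on a densest-first ordering ratios are ≥ 1 up to noise and a
  density drop is a peak. Plateau ties resolve to the leftmost position.
- **Trough detection** for threshold suggestion: the histogram mode is the
  argmax over counts ≥ 2 after 3-bin smoothing, with counts 0–1 zeroed first
  so the error peak cannot bleed into the mode; the trough is the observed
  count in [2, mode) with fewest distinct k-mers, ties toward the smaller
  count. Monotone histograms raise an error instead of guessing.
- **Best-hit reduction**: maximal bitscore, ties broken by file order then
  subject id, normalising the ambiguity between "first hit" and "best hit".

## The synthetic-data generator

The generator emulates the study design the pipeline assumes: one phased
male assembly individual plus male/female read pairs from the same
population.

- An ancestral X is drawn uniformly over ACGT; the Y is the X with
  substitutions planted per stratum at the configured density (default
  strata: 0.01, 0.0033, 0.0011 substitutions/bp, 200 kb each). Variants keep
  a minimum spacing of k, so each creates ≈ k novel Y-specific k-mers and
  planted k-mer density ≈ k × variant density — a closed-form check used by
  the tests.
- The sex region is tiled into 10 kb phased contigs (X window vs Y window,
  Y-carrying haplotype index Bernoulli(0.5) per contig); an autosome
  contributes contigs with identical haplotypes apart from private
  heterozygous variants (density 0.001). 5% of contigs receive an N run
  covering 10% of their length to exercise effective-length bookkeeping;
  reads always come from the gap-free genome.
- All males share the same X and Y; every individual carries private
  heterozygous variants on one autosomal (and, for females, one X)
  haplotype. Private variation is therefore correctly rejected by the
  all-males intersection, and shared X variation by the female filter.
- Reads: per haplotype, round(coverage × length / read_length) uniform
  100 bp reads, random strand, per-base substitution errors at `error_rate`.
  Read positions and strands are drawn before error bases, so two runs
  differing only in error rate sample identical fragments.
- Determinism: every stream is seeded as `[master_seed, stream_id]` with
  fixed per-purpose ids (one per sample), so outputs are byte-reproducible
  and adding a sample does not shift the others. Gzip timestamps are pinned.

Default synthetic thresholds are derived from coverage: `male_min` =
coverage/4 (5 at 20×) sits between the error-count regime and the hemizygous
peak at ~0.85 × coverage; `female_max` = 0.15 × coverage (3 at 20×) tolerates
recurrent errors while remaining far below the ≥ coverage counts of genuinely
shared k-mers.

**What the generator does not model:** indels, inversions or translocations
(substitution-only divergence — k-mer density is the observable under study
and substitutions control it directly), linked-read barcodes, assembly or
phasing errors, GC bias, and quality-score structure. Passing the recovery
tests therefore shows the inference chain is correct under its own model
assumptions, not that real assemblies are free of phasing switch errors or
collapsed repeats, which in real data are the dominant failure modes.

## Problem sizes

The default design (600 kb sex region + 200 kb autosome, six samples at 20×,
~2 million reads total) was chosen so a full simulate-plus-analyse cycle
completes in about a minute on one CPU while leaving per-stratum Poisson
noise (CV 6–30% in per-contig variant counts) small relative to the 3× steps
between strata — large enough to exercise the scan's separation behaviour,
small enough for routine regression runs.

## Known limitations

- Exact k-mer matching against the assembly may undercount relative to a
  mismatch-tolerant short-read aligner; divergence within k bases of a
  variant hides matches in both directions.
- The windowed-ratio scan is a heuristic, not model-based change-point
  inference; strata narrower than ~2 × window contigs, or with density
  ratios near 1, merge or vanish. Sorting by density also destroys genomic
  order within blocks, so block boundaries are defined on the density axis,
  not on coordinates.
- `find_error_trough` suggests thresholds but cannot replace judgement on
  histograms without a clear error peak (e.g. error-free simulations).
- The collinearity score treats anchor positions only; it does not detect
  balanced rearrangements that preserve rank order.
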