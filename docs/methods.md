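# Methods

## Model and normalization

A phasing result is one tool's output for one chromosome: ordered phase
blocks of biallelic heterozygous SNVs, each site carrying the allele code
(0 = reference, 1 = alternative) on each chromosome copy. Sites marked
`-` in tool output are *unphased*; homozygous or multi-allelic genotypes
are rejected at the model boundary (the comparison is defined over
haplotype-informative het sites only), and one result may not mix
chromosomes.

All analyses run on the *normalized* form:

* coordinates 1-based (SDhaP's 0-based output is shifted +1 on read);
* unphased sites removed;
* blocks left with fewer than two sites removed — a singleton block
  asserts no phase, which is why the minimum block size in any per-tool
  summary is always 2;
* sites sorted by position within blocks, blocks sorted by first
  position.

Normalization is idempotent and order-insensitive: parsing the same
result from a file sorted by block id or by position yields identical
normalized output, and therefore identical comparisons (a property the
test suite checks explicitly, since real tools disagree about sort
order). A position occurring in two blocks is a structural error, not a
warning.

Per-result summaries report total phased SNVs, block count and the
min/Q1/median/mean/Q3/max of SNVs per block. Quartiles use linear
interpolation between order statistics (numpy default, R type 7); the
mean is defined as `total_snvs / total_blocks` and rendered to two
decimals, half-up. Published summary tables of this kind occasionally
print a mean that differs from that quotient in the second decimal (e.g.
17.69 where 178,523/10,132 = 17.62); this package always reports the
quotient.

## Pairwise comparison

With HA1 as reference, each HA1 block is matched to the **unique** HA2
block sharing at least one position. Zero or multiple overlapping HA2
blocks both map to an NA disagreement — the multiple-overlap case cannot
be allele-compared without choosing a fragment arbitrarily, and the
uniqueness rule keeps the pairing deterministic. SNV match requires
identical ordered position lists, which is stricter than comparing counts
alone: equal counts over different positions cannot be compared
allele-by-allele. (When both tools phase subsets of one common variant
list, count equality and position-set equality coincide.)

The switch distance between same-position blocks is the number of
transitions in the agreement vector of the two h1 rows. This equals the
minimum number of suffix phase-switch operations needed to reconcile the
phasings, allowing a free global swap of either block's haplotypes; the
test suite verifies the equality against exhaustive search over all
switch placements on >= 1,000 random pairs.

The twelve metrics partition compared blocks by switch status — `blk.w.0sw`
(agreement), `blk.w.NAsw` (not comparable), `blk.w.sw` (switches needed) —
and analogously partition HA1's SNVs; `total.sw` sums switches over
comparable disagreement blocks, and `snv.by.sw` / `sw.per.blk` are ratios
over the `sw > 0` blocks only. Ratios with zero denominators are NA,
never 0: "no disagreement blocks" is not "zero switches per block". The
block/SNV disagreement matrices count every block with `hap_match !=
true` (NA included) over HA1's totals; the matrix is asymmetric because
HA1 supplies both the pairing direction and the denominators.

Rendered percentages use exact integer-ratio arithmetic and half-up
rounding to two decimals; thousands separators appear only in
human-readable cells, never in machine TSV.

## Reference analyses

*Gold-standard overlap* intersects a result's phased positions with an
externally known haplotype position set. By default the known set counts
**all** genotype classes including homozygous positions — published
known-haplotype position sets are built that way — with a `het_only`
option to restrict to 0|1 / 1|0 sites. Only position overlap is
reported: haplotype-level accuracy against a set that overlaps the
inferred positions partially would conflate calling and phasing
differences.

*Position restriction* filters one tool's output to the positions phased
by others (built with `intersect_result_positions`) and re-normalizes, so
blocks reduced to singletons vanish. Removing interior sites can alter
the surviving blocks' switch structure downstream — restricting a
long-block tool to a short-block tool's sites typically *increases* its
apparent switch disagreement, which is the intended, observable behavior,
not an artifact.

*Depth (DP) filtering* operates on extractHAIRS-style fragments, the
desk-scale stand-in for filtering BAM reads by coverage: a variant's
depth is the number of fragments covering it; positions below
`min_depth` are masked from every fragment (splitting allele runs where
needed) and fragments left covering fewer than two variants are dropped
as non-informative. The mask-then-drop rule is a declared convention; it
is monotone in `min_depth` by construction. Base qualities are read and
round-tripped but not used — filtering is by depth, not quality.

## Synthetic data generator

The generator emulates short-read phasing of one human chromosome so that
every stage of the pipeline has a recoverable ground truth:

| parameter | default | rationale |
|---|---|---|
| `n_sites` | 2000 | desk-scale; tests override per scenario |
| `mean_gap_bp` | 1160 | ~134 Mb chromosome / ~115k phased het SNVs |
| block sizes | 2–10, geometric decay 0.45 | matches the observed shape: median 2, Q3 ~4 |
| `long_block_fraction` / size | 0.002 / 400 | rare long blocks (hundreds–thousands of sites) |
| `switch_prob` | 0.02 | per-gap switch error, small as in real tool disagreement |
| `drop_site_prob` | 0.02 | tools phase slightly different SNV sets |
| `unphase_prob` | 0.01 | `-` entries in block files |
| `extra_block_break_prob` | 0.10 | two tools re-segment the same truth differently |

Truth haplotypes have strictly increasing positions (geometric gaps) and
i.i.d. uniform h1 alleles. Switch errors follow the classic model: at
each within-block gap the phase flips with probability `switch_prob` and
the flip persists to the block end — exactly the model under which the
transition-counting switch distance is the natural statistic, and under
which `total_sw / Σ(block sites − 1)` over matched blocks is the MLE of
the per-gap rate. Two tools share a base segmentation and differ by
independent extra breaks, mimicking the long-block vs short-block
contrast seen between real tools.

Every injected event is logged per site (kept/dropped/unphased, and the
cumulative phase orientation). `expected_metrics` re-derives the full
twelve-metric table from two logs alone — independent re-implementation
of the pairing and transition count over (orientation_a XOR orientation_b)
— and the central guarantee, tested on every seed tried, is that the
end-to-end pipeline (emit files → parse → normalize → compare) equals the
log prediction *exactly*, not approximately.

Randomness: numpy `default_rng` seeded explicitly everywhere; per-tool
seeds are spawned from the config seed via `SeedSequence`. No global
random state; identical configs give byte-identical outputs.

## Numerical and degenerate-input conventions

* Percent/mean rendering: two decimals, half-up, exact `Decimal`
  arithmetic on integer ratios.
* NA propagation: undefined switch counts and zero-denominator ratios
  are `None` in memory and `NA` in rendered tables.
* Empty inputs: summaries and overlap on empty results raise; an empty
  stream parses to an empty result; writing an empty result yields a
  header-only (VCF) or empty (block) file.
* Coordinate shifts below position 1 raise rather than clamp.
* Exclusion pairs in the all-vs-all matrix are unordered (both ordered
  cells suppressed and rendered `-`).

## What the simulator does and does not show

Passing tests demonstrate that the comparison machinery is exact under
the switch-error model: metrics agree with closed-form predictions, the
switch distance equals exhaustive search, rates are recovered within
binomial error. The simulator does **not** model read-level error
processes, reference bias, genotyping error, indels, or the spatial
clustering of real switch errors; agreement percentages on synthetic
pairs are therefore not forecasts of any particular tool pair's
agreement on real data — they validate the measuring instrument, not the
tools.

## Known limitations

* Block pairing is by unique position overlap; a fragmented counterpart
  (one HA1 block vs several HA2 blocks) is reported NA rather than
  scored piecewise.
* Depth filtering approximates BAM-level coverage filtering at the
  fragment level.
* Very large inputs are handled in memory; the target scale is a single
  chromosome's phased output (~10^5 sites), well within memory on a
  laptop.
* Some block-file emitters split their input into chunks for internal
  limits; parsing such chunked output is supported only as separate
  files.
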