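# hapcompare

Reference-free pairwise comparison of diploid haplotype-assembly outputs.

## The problem

Haplotype assembly (HA) reconstructs the two haplotypes of a diploid
individual from sequencing reads spanning heterozygous SNVs. Each tool
(HapCUT2, MixSIH, PEATH, WhatsHap, SDhaP, MAtCHap, ...) emits *phase
blocks* — sets of sites whose relative phase it asserts jointly — but
different tools phase different SNV sets into different blocks, and for
real samples there is rarely a trusted truth to score against. The natural
evaluation is then pairwise: take one tool's output as the reference
(HA1), match blocks by position, and measure how often the other tool
(HA2) disagrees.

`hapcompare` implements that evaluation for anyone benchmarking or
developing phasing tools:

* a canonical in-memory model of phased output with strict normalization
  (1-based coordinates, unphased `-` sites removed, blocks with fewer
  than 2 sites removed, everything position-sorted);
* readers/writers for the HapCUT2-family block text format (including the
  0-based SDhaP dialect), phased VCF with `PS` phase-set tags, and
  extractHAIRS fragment files;
* the block-by-block comparison with the switch distance and twelve
  switch metrics, plus block/SNV disagreement matrices;
* gold-standard position overlap, position-restriction filtering, and
  fragment-level DP (depth) filtering;
* a phasing simulator that injects switch errors, dropped and unphased
  sites and divergent block boundaries, with closed-form oracles that
  predict every downstream metric exactly from the injection logs.

## The statistic at the core

For an HA1 block and its position-matched HA2 block covering the same
ordered sites, write the agreement vector `a_i = [h1^{HA2}_i == h1^{HA1}_i]`.
The **switch distance** is

```
sw = #{ i : a_i != a_{i+1} }
```

— the number of positions where the assignment of alleles to the two
chromosomes must be exchanged for the phasings to match. It is invariant
under swapping either block's haplotypes (phase is only defined up to that
relabeling) and equals the minimum over all sequences of suffix switch
operations (verified against exhaustive search in the tests). Blocks whose
SNV sets differ get `sw = NA`; the twelve metrics partition blocks and
SNVs by `sw = 0 / NA / > 0` and report totals and ratios such as
`total.sw` and `sw.per.blk`.

## Worked example

```python
from hapcompare import (SimulationConfig, simulate_pair, normalize_result,
                        compare_results, summarize_pairwise)

config = SimulationConfig(n_sites=300, seed=42)
truth, [(raw_a, _), (raw_b, _)] = simulate_pair(config)
ha1, ha2 = normalize_result(raw_a), normalize_result(raw_b)
summary = summarize_pairwise(compare_results(ha1, ha2), ha1, ha2.tool_name)
print(f"block disagreement: {summary.disagree_blocks}/"
      f"{summary.ha1_total_blocks} ({summary.block_disagree_pct:.2f}%)")
print(f"SNV disagreement:   {summary.disagree_snvs}/"
      f"{summary.ha1_total_snvs} ({summary.snv_disagree_pct:.2f}%)")
```

prints

```
block disagreement: 43/90 (47.78%)
SNV disagreement:   136/275 (49.45%)
```

meaning: of toolA's 90 normalized blocks, 43 either had no unique
same-SNV counterpart in toolB's output (NA) or needed at least one switch;
those 43 blocks contain 136 of toolA's 275 phased SNVs. The two simulated
tools disagree this much because they re-segment the same truth with
independent extra block breaks — most disagreements are boundary (NA)
disagreements, not phase errors. See `examples/` for runnable scripts
covering each capability (summaries, comparison, depth filtering,
gold-standard overlap, parameter recovery).

## Command line

```bash
hapcompare summarize tool1.txt -d hapcut2
hapcompare compare tool1.txt tool2.txt -d hapcut2 --out-dir out/
hapcompare overlap tool1.txt --known-vcf known.vcf
hapcompare filter-depth fragments.txt --min-depth 15 -o filtered.txt
hapcompare simulate sim.yaml --out-dir simulated/
```

Data goes to files/stdout; progress goes to stderr; every output directory
gets a `manifest.json` recording inputs, dialects and seeds.

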