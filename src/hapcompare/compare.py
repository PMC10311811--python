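"""Reference-free pairwise comparison of two phasing results.

One result is taken as the reference (HA1) and the other (HA2) is compared
to it block by block.  For each HA1 block the unique HA2 block sharing at
least one position is found; if the two blocks cover exactly the same
ordered positions, the *switch distance* is computed — the number of
positions at which the assignment of alleles to the two chromosome copies
must be exchanged for HA2's phase to match HA1's.  Because phase is only
defined up to swapping the two haplotypes of a block, the distance equals
the number of transitions in the site-wise agreement vector and is
invariant under relabelling either block's haplotypes.

Per ordered pair the module reports block and SNV disagreement counts and
percentages, plus twelve switch-distance metrics partitioning the HA1
blocks into agreement (sw = 0), not-comparable (sw = NA: different SNV
sets) and switch (sw > 0) categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import EmptyInputError, UsageError
from .model import PhasedBlock, PhasingResult


@dataclass(frozen=True)
class BlockComparison:
    """One row of the block-by-block comparison table.

    ``switch_count`` is ``None`` (rendered NA) when the SNV sets differ and
    the switch distance therefore cannot be checked; ``hap_match`` is then
    ``None`` as well.
    """

    block_id: str
    ha1_snv_num: int
    ha2_snv_num: int
    snv_match: bool
    hap_match: Optional[bool]
    switch_count: Optional[int]
    pairing_note: str = ""

    def __post_init__(self) -> None:
        if not self.snv_match:
            assert self.hap_match is None and self.switch_count is None
        else:
            assert self.switch_count is not None
            assert self.hap_match == (self.switch_count == 0)
            assert 0 <= self.switch_count <= max(self.ha1_snv_num - 1, 0)


@dataclass(frozen=True)
class SwitchMetrics:
    """The twelve switch-distance metrics for one ordered (HA1, HA2) pair.

    Block counts partition the compared HA1 blocks by switch status
    (0 / NA / >0); SNV counts partition HA1's sites the same way.  Ratios
    are ``None`` when their denominator is zero (NA, never 0 — "no
    disagreement blocks" is not "zero switches per block").
    """

    blk_w_0sw: int
    blk_w_NAsw: int
    blk_w_sw: int
    snv_in_blk_w_0sw: int
    snv_in_blk_w_NAsw: int
    snv_in_blk_w_sw: int
    snv_per_blk_w_0sw: Optional[float]
    snv_per_blk_w_NAsw: Optional[float]
    snv_per_blk_w_sw: Optional[float]
    total_sw: int
    snv_by_sw: Optional[float]
    sw_per_blk: Optional[float]

    FIELD_ORDER = (
        "blk_w_0sw",
        "blk_w_NAsw",
        "blk_w_sw",
        "snv_in_blk_w_0sw",
        "snv_in_blk_w_NAsw",
        "snv_in_blk_w_sw",
        "snv_per_blk_w_0sw",
        "snv_per_blk_w_NAsw",
        "snv_per_blk_w_sw",
        "total_sw",
        "snv_by_sw",
        "sw_per_blk",
    )


@dataclass(frozen=True)
class PairwiseSummary:
    """Disagreement counts/percentages for one ordered pair (HA1 is the
    reference and the denominator)."""

    ha1_name: str
    ha2_name: str
    ha1_total_blocks: int
    ha1_total_snvs: int
    disagree_blocks: int
    disagree_snvs: int
    metrics: SwitchMetrics

    @property
    def block_disagree_pct(self) -> float:
        return 100.0 * self.disagree_blocks / self.ha1_total_blocks

    @property
    def snv_disagree_pct(self) -> float:
        return 100.0 * self.disagree_snvs / self.ha1_total_snvs


def pair_blocks(
    ha1: PhasingResult, ha2: PhasingResult
) -> list[tuple[PhasedBlock, Optional[PhasedBlock], str]]:
    """Match every HA1 block to its HA2 counterpart by position overlap.

    The counterpart is the unique HA2 block sharing at least one position;
    zero or multiple overlapping HA2 blocks map to ``None`` (the comparison
    is then an NA disagreement).  Returns one ``(ha1_block, ha2_block_or_
    None, note)`` triple per HA1 block.
    """
    if ha1.chromosome != ha2.chromosome:
        raise UsageError(
            f"cannot compare chromosomes {ha1.chromosome!r} and "
            f"{ha2.chromosome!r}"
        )
    pos_to_block: dict[int, int] = {}
    for j, block in enumerate(ha2.blocks):
        for pos in block.positions:
            pos_to_block[pos] = j

    paired: list[tuple[PhasedBlock, Optional[PhasedBlock], str]] = []
    for block in ha1.blocks:
        hits = {
            pos_to_block[p] for p in block.positions if p in pos_to_block
        }
        if len(hits) == 1:
            paired.append((block, ha2.blocks[hits.pop()], ""))
        elif not hits:
            paired.append((block, None, "no overlap"))
        else:
            paired.append((block, None, "multiple overlap"))
    return paired


def switch_count(b1: PhasedBlock, b2: PhasedBlock) -> Optional[int]:
    """Minimum number of phase switches turning b2's phasing into b1's.

    Returns ``None`` if the ordered position lists differ (the distance is
    then undefined).  Otherwise counts the transitions of the agreement
    vector ``a_i = [b2.h1_i == b1.h1_i]``: each transition is one position
    where the haplotype assignment must be exchanged; a constant vector
    (all agree, or all disagree = global phase relabelling) needs none.
    """
    if b1.positions != b2.positions:
        return None
    agree = []
    for s1, s2 in zip(b1.sites, b2.sites):
        if not (s1.phased and s2.phased):
            raise UsageError(
                f"unphased site at {s1.position} reached switch_count; "
                "normalize results first"
            )
        agree.append(s1.h1 == s2.h1)
    return sum(1 for a, b in zip(agree, agree[1:]) if a != b)


def compare_block_pair(
    b1: PhasedBlock, b2: Optional[PhasedBlock], note: str = ""
) -> BlockComparison:
    """One comparison-table row for an HA1 block and its pairing."""
    n1 = len(b1)
    if b2 is None:
        return BlockComparison(
            block_id=b1.block_id,
            ha1_snv_num=n1,
            ha2_snv_num=0,
            snv_match=False,
            hap_match=None,
            switch_count=None,
            pairing_note=note,
        )
    sw = switch_count(b1, b2)
    if sw is None:
        return BlockComparison(
            block_id=b1.block_id,
            ha1_snv_num=n1,
            ha2_snv_num=len(b2),
            snv_match=False,
            hap_match=None,
            switch_count=None,
            pairing_note=note or "positions differ",
        )
    return BlockComparison(
        block_id=b1.block_id,
        ha1_snv_num=n1,
        ha2_snv_num=len(b2),
        snv_match=True,
        hap_match=(sw == 0),
        switch_count=sw,
        pairing_note=note,
    )


def compare_results(
    ha1: PhasingResult, ha2: PhasingResult
) -> list[BlockComparison]:
    """Full block-by-block comparison with HA1 as the reference."""
    return [
        compare_block_pair(b1, b2, note)
        for b1, b2, note in pair_blocks(ha1, ha2)
    ]


def compute_switch_metrics(
    comparisons: Sequence[BlockComparison],
) -> SwitchMetrics:
    """Aggregate a comparison table into the twelve switch metrics."""
    blk0 = blkNA = blksw = 0
    snv0 = snvNA = snvsw = 0
    total_sw = 0
    for c in comparisons:
        if c.switch_count is None:
            blkNA += 1
            snvNA += c.ha1_snv_num
        elif c.switch_count == 0:
            blk0 += 1
            snv0 += c.ha1_snv_num
        else:
            blksw += 1
            snvsw += c.ha1_snv_num
            total_sw += c.switch_count
    return SwitchMetrics(
        blk_w_0sw=blk0,
        blk_w_NAsw=blkNA,
        blk_w_sw=blksw,
        snv_in_blk_w_0sw=snv0,
        snv_in_blk_w_NAsw=snvNA,
        snv_in_blk_w_sw=snvsw,
        snv_per_blk_w_0sw=snv0 / blk0 if blk0 else None,
        snv_per_blk_w_NAsw=snvNA / blkNA if blkNA else None,
        snv_per_blk_w_sw=snvsw / blksw if blksw else None,
        total_sw=total_sw,
        snv_by_sw=snvsw / total_sw if total_sw else None,
        sw_per_blk=total_sw / blksw if blksw else None,
    )


def summarize_pairwise(
    comparisons: Sequence[BlockComparison],
    ha1: PhasingResult,
    ha2_name: str,
) -> PairwiseSummary:
    """Reduce a comparison table to the disagreement counts reported in the
    block/SNV disagreement matrices.

    A block disagrees unless its haplotypes matched exactly (sw = 0); the
    SNV disagreement count is the number of HA1 sites inside disagreement
    blocks.  Denominators are HA1's totals.
    """
    if not comparisons:
        raise EmptyInputError("no block comparisons to summarize")
    disagree = [c for c in comparisons if c.hap_match is not True]
    return PairwiseSummary(
        ha1_name=ha1.tool_name,
        ha2_name=ha2_name,
        ha1_total_blocks=ha1.n_blocks,
        ha1_total_snvs=ha1.n_phased_sites,
        disagree_blocks=len(disagree),
        disagree_snvs=sum(c.ha1_snv_num for c in disagree),
        metrics=compute_switch_metrics(comparisons),
    )


def compare_pair(ha1: PhasingResult, ha2: PhasingResult) -> PairwiseSummary:
    """Convenience: compare_results + summarize_pairwise."""
    return summarize_pairwise(compare_results(ha1, ha2), ha1, ha2.tool_name)


def compare_all(
    results: Sequence[PhasingResult],
    exclusions: Sequence[tuple[str, str]] = (),
) -> dict[tuple[str, str], PairwiseSummary]:
    """All ordered (HA1, HA2) pairs except self-pairs and exclusions.

    The matrix is asymmetric by construction: HA1 supplies the block
    pairing direction and the denominators.  ``exclusions`` are unordered
    name pairs (both ordered cells are suppressed).
    """
    names = [r.tool_name for r in results]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate tool names in {names}")
    if len(results) < 2:
        raise UsageError("need at least two results to compare")
    excluded = {frozenset(pair) for pair in exclusions}
    out: dict[tuple[str, str], PairwiseSummary] = {}
    for ha1 in results:
        for ha2 in results:
            if ha1.tool_name == ha2.tool_name:
                continue
            if frozenset((ha1.tool_name, ha2.tool_name)) in excluded:
                continue
            out[(ha1.tool_name, ha2.tool_name)] = compare_pair(ha1, ha2)
    return out


def observed_gaps(comparisons: Sequence[BlockComparison]) -> int:
    """Number of within-block site gaps over which switches were countable
    (blocks with matching SNV sets only)."""
    return sum(
        c.ha1_snv_num - 1 for c in comparisons if c.switch_count is not None
    )


def switch_rate_estimate(
    comparisons: Sequence[BlockComparison],
) -> Optional[float]:
    """Estimated per-gap switch rate: total switches / countable gaps.

    Under the standard switch-error model (an independent phase flip
    persisting to the block end at each gap, probability p), each gap
    contributes one Bernoulli(p) transition, so this is the MLE of p.
    Returns ``None`` when no gaps were countable.
    """
    gaps = observed_gaps(comparisons)
    if gaps == 0:
        return None
    total = sum(
        c.switch_count for c in comparisons if c.switch_count is not None
    )
    return total / gaps
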