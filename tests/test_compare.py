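"""Pairwise comparison: block pairing, switch distance (with brute-force
oracle), metric aggregation and the disagreement matrices."""

import itertools

import numpy as np
import pytest

from hapcompare import (
    EmptyInputError,
    UsageError,
    compare_all,
    compare_block_pair,
    compare_pair,
    compare_results,
    compute_switch_metrics,
    normalize_result,
    pair_blocks,
    summarize_pairwise,
    switch_count,
    switch_rate_estimate,
)
from hapcompare.compare import BlockComparison

from .conftest import make_block, make_result, random_result


def brute_force_switch_count(h1_a, h1_b):
    """Independent oracle: the minimum number of suffix phase flips (one
    per gap) turning phasing b into phasing a, allowing a free global
    swap of b's two haplotypes."""
    n = len(h1_a)
    best = None
    for flips in itertools.product([0, 1], repeat=n - 1):
        orientation = 0
        transformed = []
        for i, allele in enumerate(h1_b):
            if i > 0 and flips[i - 1]:
                orientation ^= 1
            transformed.append(allele ^ orientation)
        if transformed == list(h1_a) or [
            1 - a for a in transformed
        ] == list(h1_a):
            cost = sum(flips)
            if best is None or cost < best:
                best = cost
    return best


class TestSwitchCount:
    def test_identical_blocks_zero(self):
        a = make_block("a", [10, 20], [0, 1])
        b = make_block("b", [10, 20], [0, 1])
        assert switch_count(a, b) == 0

    def test_global_complement_zero(self):
        a = make_block("a", [10, 20, 30], [0, 1, 0])
        b = make_block("b", [10, 20, 30], [1, 0, 1])
        assert switch_count(a, b) == 0

    def test_single_internal_flip(self):
        a = make_block("a", [1, 2, 3, 4], [0, 0, 0, 0])
        b = make_block("b", [1, 2, 3, 4], [0, 0, 1, 1])
        assert switch_count(a, b) == 1

    def test_alternating_disagreement(self):
        # agreement at sites 1,3,5 and disagreement at 2,4 -> 4 switches
        a = make_block("a", [1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        b = make_block("b", [1, 2, 3, 4, 5], [0, 1, 0, 1, 0])
        assert switch_count(a, b) == 4

    def test_different_positions_na(self):
        a = make_block("a", [10, 20], [0, 0])
        b = make_block("b", [10, 30], [0, 0])
        assert switch_count(a, b) is None

    def test_different_counts_na(self):
        a = make_block("a", [10, 20], [0, 0])
        b = make_block("b", [10, 20, 30], [0, 0, 0])
        assert switch_count(a, b) is None

    def test_unphased_site_is_internal_error(self):
        a = make_block("a", [10, 20], [0, None])
        b = make_block("b", [10, 20], [0, 0])
        with pytest.raises(UsageError):
            switch_count(a, b)

    def test_equals_brute_force_oracle(self, rng):
        """Transition counting equals exhaustive minimum-switch search
        on random same-position block pairs of <= 10 sites."""
        for _ in range(1000):
            n = int(rng.integers(2, 11))
            positions = np.cumsum(rng.integers(1, 30, size=n)).tolist()
            h1a = rng.integers(0, 2, size=n).tolist()
            h1b = rng.integers(0, 2, size=n).tolist()
            a = make_block("a", positions, h1a)
            b = make_block("b", positions, h1b)
            assert switch_count(a, b) == brute_force_switch_count(h1a, h1b)

    def test_symmetry_and_haplotype_swap_invariance(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            positions = np.cumsum(rng.integers(1, 30, size=n)).tolist()
            h1a = rng.integers(0, 2, size=n).tolist()
            h1b = rng.integers(0, 2, size=n).tolist()
            a = make_block("a", positions, h1a)
            b = make_block("b", positions, h1b)
            b_swapped = make_block("b", positions, [1 - x for x in h1b])
            assert switch_count(a, b) == switch_count(b, a)
            assert switch_count(a, b) == switch_count(a, b_swapped)


class TestPairBlocks:
    def test_self_pairing(self, rng):
        res = random_result(rng)
        for b1, b2, note in pair_blocks(res, res):
            assert b2 is b1 and note == ""

    def test_no_overlap_maps_to_none(self):
        ha1 = make_result("x", [make_block("a", [10, 20])])
        ha2 = make_result("y", [make_block("b", [30, 40])])
        (_, b2, note), = pair_blocks(ha1, ha2)
        assert b2 is None and note == "no overlap"

    def test_multiple_overlap_maps_to_none(self):
        ha1 = make_result("x", [make_block("a", [10, 20, 30, 40])])
        ha2 = make_result(
            "y", [make_block("b1", [10, 20]), make_block("b2", [30, 40])]
        )
        (_, b2, note), = pair_blocks(ha1, ha2)
        assert b2 is None and note == "multiple overlap"
        comparison = compare_block_pair(ha1.blocks[0], b2, note)
        assert comparison.switch_count is None

    def test_chromosome_mismatch_rejected(self):
        ha1 = make_result("x", [make_block("a", [10, 20])], "chr10")
        ha2 = make_result("y", [make_block("b", [10, 20])], "chr11")
        with pytest.raises(UsageError):
            pair_blocks(ha1, ha2)


def worked_example():
    """The six-block worked example: HA1/HA2 SNV counts
    (2,1),(7,4),(4,4),(2,3),(2,2),(2,2); pair 3 has one internal phase
    flip; pairs 5 and 6 are identical."""
    ha1_blocks = [
        make_block("1", [10, 20]),
        make_block("2", [30, 40, 50, 60, 70, 80, 90]),
        make_block("3", [100, 110, 120, 130], [0, 0, 0, 0]),
        make_block("4", [140, 150]),
        make_block("5", [160, 170], [0, 1]),
        make_block("6", [180, 190], [1, 0]),
    ]
    ha2_blocks = [
        make_block("1", [10]),
        make_block("2", [30, 40, 50, 60]),
        make_block("3", [100, 110, 120, 130], [0, 0, 1, 1]),
        make_block("4", [140, 150, 155]),
        make_block("5", [160, 170], [0, 1]),
        make_block("6", [180, 190], [1, 0]),
    ]
    ha1 = make_result("HA1", ha1_blocks)
    # raw ha2 kept raw on purpose: singleton block 1 must stay to supply
    # the (2,1) row, so we compare without re-normalizing ha2
    ha2 = make_result("HA2", ha2_blocks)
    return ha1, ha2


class TestWorkedExample:
    def test_row_pattern(self):
        ha1, ha2 = worked_example()
        comparisons = compare_results(ha1, ha2)
        got = [
            (c.ha1_snv_num, c.ha2_snv_num, c.switch_count)
            for c in comparisons
        ]
        assert got == [
            (2, 1, None),
            (7, 4, None),
            (4, 4, 1),
            (2, 3, None),
            (2, 2, 0),
            (2, 2, 0),
        ]

    def test_aggregated_metrics(self):
        ha1, ha2 = worked_example()
        m = compute_switch_metrics(compare_results(ha1, ha2))
        assert (m.blk_w_0sw, m.blk_w_NAsw, m.blk_w_sw) == (2, 3, 1)
        assert (
            m.snv_in_blk_w_0sw,
            m.snv_in_blk_w_NAsw,
            m.snv_in_blk_w_sw,
        ) == (4, 11, 4)
        assert m.total_sw == 1
        assert m.snv_by_sw == 4.0
        assert m.sw_per_blk == 1.0


def naive_metrics(comparisons):
    """Independent re-aggregation: one explicit pass per category."""
    na = [c for c in comparisons if c.switch_count is None]
    zero = [c for c in comparisons if c.switch_count == 0]
    pos = [
        c
        for c in comparisons
        if c.switch_count is not None and c.switch_count > 0
    ]
    total = sum(c.switch_count for c in pos)
    return {
        "blk": (len(zero), len(na), len(pos)),
        "snv": (
            sum(c.ha1_snv_num for c in zero),
            sum(c.ha1_snv_num for c in na),
            sum(c.ha1_snv_num for c in pos),
        ),
        "total_sw": total,
    }


class TestMetrics:
    def test_matches_naive_reaggregation(self, rng):
        for _ in range(50):
            ha1 = random_result(rng, "a", n_blocks=8)
            ha2 = random_result(rng, "b", n_blocks=8)
            comparisons = compare_results(ha1, ha2)
            m = compute_switch_metrics(comparisons)
            naive = naive_metrics(comparisons)
            assert (m.blk_w_0sw, m.blk_w_NAsw, m.blk_w_sw) == naive["blk"]
            assert (
                m.snv_in_blk_w_0sw,
                m.snv_in_blk_w_NAsw,
                m.snv_in_blk_w_sw,
            ) == naive["snv"]
            assert m.total_sw == naive["total_sw"]

    def test_all_identical_ratios_na(self, rng):
        res = random_result(rng)
        m = compute_switch_metrics(compare_results(res, res))
        assert m.blk_w_sw == 0 and m.total_sw == 0
        assert m.snv_by_sw is None and m.sw_per_blk is None
        assert m.snv_per_blk_w_NAsw is None

    def test_partition_identities(self, rng):
        for _ in range(20):
            ha1 = random_result(rng, "a", n_blocks=12)
            ha2 = random_result(rng, "b", n_blocks=12)
            comparisons = compare_results(ha1, ha2)
            m = compute_switch_metrics(comparisons)
            assert m.blk_w_0sw + m.blk_w_NAsw + m.blk_w_sw == len(
                comparisons
            )
            assert (
                m.snv_in_blk_w_0sw
                + m.snv_in_blk_w_NAsw
                + m.snv_in_blk_w_sw
                == sum(c.ha1_snv_num for c in comparisons)
            )
            for cat in ("0sw", "NAsw", "sw"):
                blk = getattr(m, f"blk_w_{cat}")
                snv = getattr(m, f"snv_in_blk_w_{cat}")
                per = getattr(m, f"snv_per_blk_w_{cat}")
                if blk:
                    assert per == pytest.approx(snv / blk)
                else:
                    assert per is None


class TestSummaries:
    def test_self_comparison_zero_disagreement(self, rng):
        res = random_result(rng)
        summary = compare_pair(res, res)
        assert summary.disagree_blocks == 0
        assert summary.disagree_snvs == 0
        assert summary.block_disagree_pct == 0.0

    def test_disagreement_accounting(self):
        ha1, ha2 = worked_example()
        summary = summarize_pairwise(
            compare_results(ha1, ha2), ha1, "HA2"
        )
        # 4 disagreement blocks (3 NA + 1 switch) of 6; 15 of 19 SNVs
        assert summary.disagree_blocks == 4
        assert summary.ha1_total_blocks == 6
        assert summary.disagree_snvs == 15
        assert summary.ha1_total_snvs == 19
        m = summary.metrics
        assert (
            summary.disagree_blocks == m.blk_w_NAsw + m.blk_w_sw
        )

    def test_empty_comparisons_rejected(self, rng):
        with pytest.raises(EmptyInputError):
            summarize_pairwise([], random_result(rng), "x")

    def test_compare_all_ordered_pairs(self, rng):
        results = [random_result(rng, name) for name in "abc"]
        out = compare_all(results)
        assert len(out) == 6
        assert ("a", "a") not in out

    def test_compare_all_exclusion_suppresses_both_cells(self, rng):
        results = [random_result(rng, name) for name in "abc"]
        out = compare_all(results, exclusions=[("a", "b")])
        assert ("a", "b") not in out and ("b", "a") not in out
        assert ("a", "c") in out

    def test_asymmetry(self, rng):
        a = random_result(rng, "a", n_blocks=10)
        b = random_result(rng, "b", n_blocks=10)
        ab = compare_pair(a, b)
        ba = compare_pair(b, a)
        assert ab.ha1_total_blocks == a.n_blocks
        assert ba.ha1_total_blocks == b.n_blocks

    def test_duplicate_names_rejected(self, rng):
        results = [random_result(rng, "same"), random_result(rng, "same")]
        with pytest.raises(UsageError):
            compare_all(results)


def test_switch_rate_estimate_no_gaps_is_na():
    comparisons = [
        BlockComparison("1", 2, 3, False, None, None),
    ]
    assert switch_rate_estimate(comparisons) is None
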