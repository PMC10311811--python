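"""Simulator: determinism, truth construction, corruption injection and
the closed-form metric oracle."""

import io

import numpy as np
import pytest

from hapcompare import (
    SimulationConfig,
    UsageError,
    compare_results,
    compute_switch_metrics,
    derive_result,
    expected_metrics,
    normalize_result,
    simulate_pair,
    simulate_truth,
    switch_rate_estimate,
)
from hapcompare.simulate import read_injection_log, write_injection_log


class TestTruth:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_sites=500, seed=42)
        assert simulate_truth(cfg) == simulate_truth(cfg)

    def test_sites_heterozygous_and_increasing(self):
        truth = simulate_truth(SimulationConfig(n_sites=1000, seed=1))
        assert truth.n_sites == 1000
        assert all(
            a < b for a, b in zip(truth.positions, truth.positions[1:])
        )
        assert set(truth.h1) <= {0, 1}

    def test_allele_frequency_binomial_bound(self):
        n = 10_000
        truth = simulate_truth(SimulationConfig(n_sites=n, seed=3))
        freq = sum(1 for a in truth.h1 if a == 0) / n
        se = (0.25 / n) ** 0.5
        assert abs(freq - 0.5) <= 3 * se

    def test_too_few_sites_rejected(self):
        with pytest.raises(UsageError):
            SimulationConfig(n_sites=1)

    def test_bad_probability_rejected(self):
        with pytest.raises(UsageError):
            SimulationConfig(switch_prob=1.5)


class TestDeriveResult:
    def test_no_corruption_matches_same_boundary_derivation(self):
        cfg = SimulationConfig(
            n_sites=400,
            seed=5,
            switch_prob=0,
            drop_site_prob=0,
            unphase_prob=0,
            extra_block_break_prob=0,
        )
        truth = simulate_truth(cfg)
        res_a, log_a = derive_result(truth, cfg, "a", seed=11, base_seed=5)
        res_b, log_b = derive_result(truth, cfg, "b", seed=22, base_seed=5)
        na, nb = normalize_result(res_a), normalize_result(res_b)
        metrics = compute_switch_metrics(compare_results(na, nb))
        assert metrics.blk_w_NAsw == 0
        assert metrics.blk_w_sw == 0
        assert metrics.total_sw == 0
        assert expected_metrics(log_a, log_b) == metrics

    def test_two_site_blocks_vanish_under_heavy_drop(self):
        cfg = SimulationConfig(
            n_sites=300,
            seed=9,
            min_block=2,
            max_block=2,
            drop_site_prob=0.3,
            switch_prob=0,
            unphase_prob=0,
            extra_block_break_prob=0,
            long_block_fraction=0,
        )
        truth = simulate_truth(cfg)
        res, log = derive_result(truth, cfg, "t", seed=1, base_seed=9)
        norm = normalize_result(res)
        # every 2-site block that lost a site became a singleton and was
        # removed; survivors are exactly the log-predicted blocks
        assert all(b.n_phased == 2 for b in norm.blocks)
        predicted = {
            tuple(p for p, _ in sites) for _, sites in log.kept_blocks()
        }
        assert {b.positions for b in norm.blocks} == predicted
        assert norm.n_phased_sites == 2 * len(predicted)
        n_dropped = sum(
            1 for rec in log.records if rec.status == "dropped"
        )
        assert n_dropped > 0  # the corruption actually fired

    def test_unphased_sites_emitted_then_normalized_away(self):
        cfg = SimulationConfig(
            n_sites=300,
            seed=2,
            unphase_prob=0.2,
            switch_prob=0,
            drop_site_prob=0,
            extra_block_break_prob=0,
        )
        truth = simulate_truth(cfg)
        res, log = derive_result(truth, cfg, "t", seed=7, base_seed=2)
        n_unphased = sum(
            1 for rec in log.records if rec.status == "unphased"
        )
        assert n_unphased > 0
        raw_unphased = sum(
            1
            for b in res.blocks
            for s in b.sites
            if not s.phased
        )
        assert raw_unphased == n_unphased
        assert all(
            s.phased
            for b in normalize_result(res).blocks
            for s in b.sites
        )


class TestOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pipeline_equals_log_prediction(self, seed):
        """The module's central guarantee: on every seed the end-to-end
        pipeline metrics equal the closed-form prediction from the logs."""
        cfg = SimulationConfig(n_sites=2000, seed=seed)
        truth, derived = simulate_pair(cfg)
        (res_a, log_a), (res_b, log_b) = derived
        na, nb = normalize_result(res_a), normalize_result(res_b)
        assert compute_switch_metrics(compare_results(na, nb)) == (
            expected_metrics(log_a, log_b)
        )
        assert compute_switch_metrics(compare_results(nb, na)) == (
            expected_metrics(log_b, log_a)
        )

    def test_single_injected_switch(self):
        cfg = SimulationConfig(
            n_sites=6,
            seed=0,
            min_block=6,
            max_block=6,
            switch_prob=0,
            drop_site_prob=0,
            unphase_prob=0,
            extra_block_break_prob=0,
            long_block_fraction=0,
        )
        truth = simulate_truth(cfg)
        clean, log_clean = derive_result(truth, cfg, "c", seed=1, base_seed=0)
        # inject exactly one switch by hand into a copy of the log/result
        from dataclasses import replace

        from hapcompare import PhasedBlock, PhasedSite

        block = clean.blocks[0]
        flipped_sites = tuple(
            s if i < 3 else PhasedSite(s.position, 1 - s.h1, s.h1)
            for i, s in enumerate(block.sites)
        )
        corrupted = replace(
            clean,
            tool_name="x",
            blocks=(PhasedBlock(block.block_id, flipped_sites),),
        )
        metrics = compute_switch_metrics(
            compare_results(
                normalize_result(clean), normalize_result(corrupted)
            )
        )
        assert metrics.blk_w_sw == 1 and metrics.total_sw == 1

    def test_logs_from_different_truths_rejected(self):
        cfg_a = SimulationConfig(n_sites=100, seed=1)
        cfg_b = SimulationConfig(n_sites=100, seed=2)
        _, [(_, log_a), _] = simulate_pair(cfg_a)
        _, [(_, log_b), _] = simulate_pair(cfg_b)
        with pytest.raises(UsageError):
            expected_metrics(log_a, log_b)


class TestParameterRecovery:
    @pytest.mark.parametrize("p", [0.01, 0.05, 0.1])
    def test_switch_rate_recovered_within_3se(self, p):
        """Comparing a corrupted derivation against a clean one with the
        same block boundaries recovers the injected per-gap switch
        probability to within 3 binomial standard errors."""
        base = dict(
            n_sites=15_000,
            drop_site_prob=0,
            unphase_prob=0,
            extra_block_break_prob=0,
            seed=123,
        )
        cfg_clean = SimulationConfig(switch_prob=0, **base)
        cfg_noisy = SimulationConfig(switch_prob=p, **base)
        truth = simulate_truth(cfg_clean)
        clean, _ = derive_result(
            truth, cfg_clean, "clean", seed=77, base_seed=123
        )
        noisy, _ = derive_result(
            truth, cfg_noisy, "noisy", seed=88, base_seed=123
        )
        comparisons = compare_results(
            normalize_result(clean), normalize_result(noisy)
        )
        from hapcompare.compare import observed_gaps

        gaps = observed_gaps(comparisons)
        assert gaps >= 10_000
        estimate = switch_rate_estimate(comparisons)
        se = (p * (1 - p) / gaps) ** 0.5
        assert abs(estimate - p) <= 3 * se


class TestLogSerialization:
    def test_roundtrip(self):
        cfg = SimulationConfig(n_sites=200, seed=6)
        _, [(_, log), _] = simulate_pair(cfg)
        buf = io.StringIO()
        write_injection_log(log, buf)
        back = read_injection_log(io.StringIO(buf.getvalue()))
        assert back == log
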