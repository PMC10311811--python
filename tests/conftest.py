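"""Shared fixtures: small hand-built results and randomized generators."""

from __future__ import annotations

import numpy as np
import pytest

from hapcompare import (
    PhasedBlock,
    PhasedSite,
    PhasingResult,
    normalize_result,
)


def make_block(
    block_id: str,
    positions,
    h1=None,
) -> PhasedBlock:
    """Build a block from positions and an optional h1 allele vector
    (default all 0; ``None`` entries mean unphased sites)."""
    if h1 is None:
        h1 = [0] * len(positions)
    sites = []
    for pos, allele in zip(positions, h1):
        if allele is None:
            sites.append(PhasedSite(pos, None, None))
        else:
            sites.append(PhasedSite(pos, allele, 1 - allele))
    return PhasedBlock(block_id, tuple(sites))


def make_result(tool, blocks, chromosome="chr10") -> PhasingResult:
    return PhasingResult(tool, chromosome, tuple(blocks))


def random_result(
    rng: np.random.Generator,
    tool: str = "rand",
    n_blocks: int = 5,
    max_sites: int = 10,
    start: int = 1,
) -> PhasingResult:
    """A random normalized-shaped result with disjoint position ranges."""
    blocks = []
    pos = start
    for b in range(n_blocks):
        n = int(rng.integers(2, max_sites + 1))
        positions = []
        for _ in range(n):
            pos += int(rng.integers(1, 50))
            positions.append(pos)
        h1 = rng.integers(0, 2, size=n).tolist()
        blocks.append(make_block(f"{tool}_b{b}", positions, h1))
        pos += 100
    return normalize_result(make_result(tool, blocks))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
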