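"""Synthetic diploid phasing data with a known injected error structure.

The generator produces a ground-truth pair of haplotypes over biallelic
heterozygous sites and then derives tool-style phased outputs from it by
injecting the corruption modes real haplotype-assembly outputs show:

* partition of the sites into phase blocks (mostly 2–10 sites, with a rare
  long-block tail, matching the block-size shape of short-read phasing);
* per-gap switch errors — at each within-block gap the phase flips, with a
  configurable probability, and the flip persists to the end of the block
  (the classic switch-error model);
* sites dropped entirely, or emitted unphased ("-");
* differing block boundaries between two derived tools (independent extra
  breaks on top of a shared base segmentation).

Every injection is recorded in an :class:`InjectionLog`; the log alone is
sufficient to predict every downstream comparison metric exactly, which
makes the whole pipeline verifiable end to end (see
:func:`expected_metrics`).

All randomness flows from explicit integer seeds through numpy
``default_rng``; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .compare import SwitchMetrics
from .errors import UsageError
from .model import ONE_BASED, PhasedBlock, PhasedSite, PhasingResult

KEPT = "kept"
DROPPED = "dropped"
UNPHASED_STATUS = "unphased"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate short-read phasing of one human chromosome: mean
    inter-SNV gap 1,160 bp (one het SNV per ~1.2 kb), block sizes mostly
    2–10 with a rare long-block tail, and small per-gap switch / site-loss
    rates.
    """

    n_sites: int = 2000
    chromosome: str = "chr10"
    mean_gap_bp: float = 1160.0
    min_block: int = 2
    max_block: int = 10
    #: geometric decay of block sizes inside [min_block, max_block];
    #: 0.45 puts the median at 2 and the upper quartile near 4
    block_size_decay: float = 0.45
    long_block_fraction: float = 0.002
    long_block_size: int = 400
    switch_prob: float = 0.02
    drop_site_prob: float = 0.02
    unphase_prob: float = 0.01
    extra_block_break_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise UsageError(f"n_sites must be >= 2, got {self.n_sites}")
        for name in (
            "block_size_decay",
            "long_block_fraction",
            "switch_prob",
            "drop_site_prob",
            "unphase_prob",
            "extra_block_break_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise UsageError(f"{name}={value} outside [0, 1]")
        if not 2 <= self.min_block <= self.max_block:
            raise UsageError(
                f"need 2 <= min_block <= max_block, got "
                f"{self.min_block}..{self.max_block}"
            )


@dataclass(frozen=True)
class TruthHaplotypes:
    """Ground truth: positions and the h1 allele at each (h2 = 1 - h1)."""

    chromosome: str
    positions: tuple[int, ...]
    h1: tuple[int, ...]
    truth_token: str  # identifies the generating (config, seed)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.h1):
            raise UsageError("positions and h1 must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SiteRecord:
    """One truth site's fate in a derived result."""

    position: int
    block_label: str
    status: str  # kept | dropped | unphased
    orientation: Optional[int]  # emitted h1 = truth h1 XOR orientation


@dataclass(frozen=True)
class InjectionLog:
    """Complete record of the corruptions injected into one derived result."""

    tool_name: str
    truth_token: str
    records: tuple[SiteRecord, ...]

    def kept_blocks(self) -> list[tuple[str, list[tuple[int, int]]]]:
        """Blocks after normalization, predicted from the log alone:
        kept phased sites grouped by block label, singletons removed,
        as ``(label, [(position, orientation), ...])`` sorted by position."""
        by_label: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for rec in self.records:
            if rec.status != KEPT:
                continue
            if rec.block_label not in by_label:
                by_label[rec.block_label] = []
                order.append(rec.block_label)
            by_label[rec.block_label].append(
                (rec.position, rec.orientation)
            )
        blocks = []
        for label in order:
            sites = sorted(by_label[label])
            if len(sites) >= 2:
                blocks.append((label, sites))
        blocks.sort(key=lambda b: b[1][0][0])
        return blocks


def simulate_truth(config: SimulationConfig) -> TruthHaplotypes:
    """Draw ground-truth haplotypes: strictly increasing positions with
    geometric gaps, h1 alleles i.i.d. uniform over {0, 1}."""
    rng = np.random.default_rng([config.seed, 1])
    p_gap = min(1.0, 1.0 / max(config.mean_gap_bp, 1.0))
    gaps = rng.geometric(p_gap, size=config.n_sites)
    positions = np.cumsum(gaps)
    h1 = rng.integers(0, 2, size=config.n_sites)
    return TruthHaplotypes(
        chromosome=config.chromosome,
        positions=tuple(int(p) for p in positions),
        h1=tuple(int(a) for a in h1),
        truth_token=f"seed={config.seed};n={config.n_sites}",
    )


def _sample_block_sizes(
    config: SimulationConfig, n_sites: int, rng: np.random.Generator
) -> list[int]:
    """Block sizes covering exactly ``n_sites`` sites: truncated-geometric
    on [min_block, max_block], with occasional long blocks."""
    sizes: list[int] = []
    remaining = n_sites
    support = np.arange(config.min_block, config.max_block + 1)
    decay = config.block_size_decay
    weights = (1.0 - decay) ** (support - config.min_block)
    weights /= weights.sum()
    while remaining > 0:
        if (
            config.long_block_fraction > 0
            and remaining >= config.long_block_size
            and rng.random() < config.long_block_fraction
        ):
            size = config.long_block_size
        else:
            size = int(rng.choice(support, p=weights))
        size = min(size, remaining)
        # a leftover single site is merged into the previous block
        if size == remaining - 1 and remaining - size < config.min_block:
            size = remaining
        sizes.append(size)
        remaining -= size
    return sizes


def derive_result(
    truth: TruthHaplotypes,
    config: SimulationConfig,
    tool_name: str,
    seed: int,
    base_seed: Optional[int] = None,
) -> tuple[PhasingResult, InjectionLog]:
    """Derive one tool-style raw output from the truth.

    ``base_seed`` controls the shared base segmentation: two tools derived
    with the same ``base_seed`` but different ``seed`` share base block
    boundaries and differ only by extra breaks and corruption — the way
    two real tools phase the same variant set into similar but not
    identical blocks.  The returned result is raw (unphased sites present,
    possibly singleton blocks); pass it through ``normalize_result`` before
    comparing.
    """
    part_rng = np.random.default_rng(
        [base_seed if base_seed is not None else seed, 2]
    )
    corrupt_rng = np.random.default_rng([seed, 3])

    sizes = _sample_block_sizes(config, truth.n_sites, part_rng)
    # base block index per site
    boundaries = np.zeros(truth.n_sites, dtype=bool)
    pos = 0
    for size in sizes:
        boundaries[pos] = True
        pos += size
    # independent extra breaks re-segment the shared base partition
    if config.extra_block_break_prob > 0:
        extra = (
            corrupt_rng.random(truth.n_sites)
            < config.extra_block_break_prob
        )
        extra[0] = False
        boundaries = boundaries | extra
    block_index = np.cumsum(boundaries) - 1

    switches = corrupt_rng.random(truth.n_sites) < config.switch_prob
    drops = corrupt_rng.random(truth.n_sites) < config.drop_site_prob
    unphase = corrupt_rng.random(truth.n_sites) < config.unphase_prob

    records: list[SiteRecord] = []
    blocks: list[PhasedBlock] = []
    cur_label: Optional[str] = None
    cur_sites: list[PhasedSite] = []
    orientation = 0

    def flush() -> None:
        nonlocal cur_sites
        if cur_label is not None and cur_sites:
            blocks.append(PhasedBlock(cur_label, tuple(cur_sites)))
        cur_sites = []

    prev_block = -1
    for i in range(truth.n_sites):
        bi = int(block_index[i])
        if bi != prev_block:
            flush()
            cur_label = f"{tool_name}_b{bi + 1}"
            orientation = 0  # orientation is only defined within a block
            prev_block = bi
        elif switches[i]:
            # a switch error at the gap before site i flips phase to the
            # end of the block
            orientation ^= 1
        if drops[i]:
            records.append(
                SiteRecord(truth.positions[i], cur_label, DROPPED, None)
            )
            continue
        if unphase[i]:
            records.append(
                SiteRecord(
                    truth.positions[i], cur_label, UNPHASED_STATUS, None
                )
            )
            cur_sites.append(
                PhasedSite(truth.positions[i], None, None)
            )
            continue
        h1 = truth.h1[i] ^ orientation
        records.append(
            SiteRecord(truth.positions[i], cur_label, KEPT, orientation)
        )
        cur_sites.append(
            PhasedSite(truth.positions[i], h1, 1 - h1)
        )
    flush()

    result = PhasingResult(
        tool_name=tool_name,
        chromosome=truth.chromosome,
        blocks=tuple(blocks),
        coordinate_basis=ONE_BASED,
    )
    log = InjectionLog(
        tool_name=tool_name,
        truth_token=truth.truth_token,
        records=tuple(records),
    )
    return result, log


def simulate_pair(
    config: SimulationConfig,
    tool_names: Sequence[str] = ("toolA", "toolB"),
) -> tuple[
    TruthHaplotypes,
    list[tuple[PhasingResult, InjectionLog]],
]:
    """Truth plus two (or more) derived tool outputs sharing a base
    segmentation; per-tool seeds are spawned from ``config.seed``."""
    truth = simulate_truth(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(tool_names))
    derived = []
    for tool, child in zip(tool_names, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        derived.append(
            derive_result(
                truth, config, tool, seed=seed, base_seed=config.seed
            )
        )
    return truth, derived


# ---------------------------------------------------------------------------
# closed-form oracle


def expected_metrics(
    log_a: InjectionLog, log_b: InjectionLog
) -> SwitchMetrics:
    """Predict the twelve switch metrics of comparing tool A (as HA1)
    against tool B from the injection logs alone.

    This never touches the comparison code: the normalized block structure
    is rebuilt from each log, A-blocks are matched to the unique B-block
    sharing a position, and for identical position lists the switch count
    is the number of transitions of ``orientation_a XOR orientation_b``.
    """
    if log_a.truth_token != log_b.truth_token:
        raise UsageError(
            f"logs from different truths: {log_a.truth_token!r} vs "
            f"{log_b.truth_token!r}"
        )
    a_blocks = log_a.kept_blocks()
    b_blocks = log_b.kept_blocks()
    pos_to_b: dict[int, int] = {}
    for j, (_, sites) in enumerate(b_blocks):
        for p, _ in sites:
            pos_to_b[p] = j

    blk0 = blkNA = blksw = 0
    snv0 = snvNA = snvsw = 0
    total_sw = 0
    for _, a_sites in a_blocks:
        n1 = len(a_sites)
        hits = {pos_to_b[p] for p, _ in a_sites if p in pos_to_b}
        sw: Optional[int] = None
        if len(hits) == 1:
            b_sites = b_blocks[next(iter(hits))][1]
            if [p for p, _ in a_sites] == [p for p, _ in b_sites]:
                xor = [
                    oa ^ ob
                    for (_, oa), (_, ob) in zip(a_sites, b_sites)
                ]
                sw = sum(
                    1 for x, y in zip(xor, xor[1:]) if x != y
                )
        if sw is None:
            blkNA += 1
            snvNA += n1
        elif sw == 0:
            blk0 += 1
            snv0 += n1
        else:
            blksw += 1
            snvsw += n1
            total_sw += sw
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


def write_injection_log(log: InjectionLog, sink) -> None:
    """Serialize a log as tab-separated text (one row per truth site)."""
    from .io import _open_text

    with _open_text(sink, "w") as fh:
        fh.write(f"# tool={log.tool_name}\ttruth={log.truth_token}\n")
        fh.write("position\tblock\tstatus\torientation\n")
        for rec in log.records:
            orient = "NA" if rec.orientation is None else str(rec.orientation)
            fh.write(
                f"{rec.position}\t{rec.block_label}\t{rec.status}\t{orient}\n"
            )


def read_injection_log(source) -> InjectionLog:
    from .io import _open_text

    tool = "unknown"
    token = ""
    records: list[SiteRecord] = []
    with _open_text(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    key, _, value = part.strip().partition("=")
                    if key == "tool":
                        tool = value
                    elif key == "truth":
                        token = value
                continue
            if not line or line.startswith("position\t"):
                continue
            pos_s, label, status, orient_s = line.split("\t")
            records.append(
                SiteRecord(
                    int(pos_s),
                    label,
                    status,
                    None if orient_s == "NA" else int(orient_s),
                )
            )
    return InjectionLog(tool, token, tuple(records))
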