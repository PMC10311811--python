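"""In-memory model of diploid phased output and per-result summaries.

A haplotype-assembly tool partitions the heterozygous SNVs of one chromosome
into *phase blocks*: within a block the relative phase of all sites is
asserted jointly, between blocks it is undefined.  Each site carries the
allele placed on each of the two chromosome copies, coded 0 (reference) and
1 (alternative); an unphased site carries the marker ``-`` in tool output
and is represented here by ``None``.

The canonical (normalized) form used by every downstream comparison is:
1-based coordinates, unphased sites removed, blocks with fewer than two
remaining sites removed (a single site carries no phase information),
sites sorted by position within blocks, blocks sorted by first position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import (
    CoordinateError,
    EmptyInputError,
    StructuralIntegrityError,
    UsageError,
)

#: allele code for the "-" (unphased) marker
UNPHASED = None

ZERO_BASED = "0-based"
ONE_BASED = "1-based"


@dataclass(frozen=True)
class PhasedSite:
    """One biallelic heterozygous site in a phase block.

    ``h1``/``h2`` are the allele codes assigned to the two chromosome
    copies; both are ``None`` for an unphased ("-") site.  ``variant_index``
    (the 1-based index of the record in the source VCF) and ``ref``/``alt``
    bases are carried for round-tripping only and do not take part in
    equality.
    """

    position: int
    h1: Optional[int]
    h2: Optional[int]
    variant_index: Optional[int] = field(default=None, compare=False)
    ref: str = field(default="A", compare=False)
    alt: str = field(default="C", compare=False)
    extra: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(
                f"position {self.position} is < 1; shift 0-based input first"
            )
        if (self.h1 is None) != (self.h2 is None):
            raise StructuralIntegrityError(
                f"site {self.position}: exactly one allele unphased"
            )
        if self.h1 is not None:
            if self.h1 not in (0, 1):
                raise StructuralIntegrityError(
                    f"site {self.position}: allele {self.h1!r} not in {{0, 1}}"
                )
            if self.h2 != 1 - self.h1:
                raise StructuralIntegrityError(
                    f"site {self.position}: h1 == h2 == {self.h1} "
                    "(not a biallelic heterozygous site)"
                )

    @property
    def phased(self) -> bool:
        return self.h1 is not None


@dataclass(frozen=True)
class PhasedBlock:
    """One phase block: an identifier and its ordered sites.

    Raw (just-parsed) blocks may hold sites in file order; normalization
    sorts them by position and checks for duplicates.
    """

    block_id: str
    sites: tuple[PhasedSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    @property
    def phased_sites(self) -> tuple[PhasedSite, ...]:
        return tuple(s for s in self.sites if s.phased)

    @property
    def n_phased(self) -> int:
        return sum(1 for s in self.sites if s.phased)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[PhasedSite]:
        return iter(self.sites)


@dataclass(frozen=True)
class PhasingResult:
    """One tool's phased output for one chromosome."""

    tool_name: str
    chromosome: str
    blocks: tuple[PhasedBlock, ...]
    coordinate_basis: str = ONE_BASED

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.coordinate_basis not in (ZERO_BASED, ONE_BASED):
            raise UsageError(
                f"unknown coordinate basis {self.coordinate_basis!r}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_phased_sites(self) -> int:
        return sum(b.n_phased for b in self.blocks)

    def positions(self) -> tuple[int, ...]:
        """All site positions, in block order (not necessarily sorted)."""
        return tuple(p for b in self.blocks for p in b.positions)

    def phased_positions(self) -> tuple[int, ...]:
        return tuple(
            s.position for b in self.blocks for s in b.sites if s.phased
        )


@dataclass(frozen=True)
class BlockSnvSummary:
    """Counts and five-number summary of phased SNVs per block."""

    tool_name: str
    total_snvs: int
    total_blocks: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float


def _check_no_duplicate_positions(blocks: Sequence[PhasedBlock]) -> None:
    seen: dict[int, str] = {}
    for block in blocks:
        for site in block.sites:
            prev = seen.get(site.position)
            if prev is not None:
                raise StructuralIntegrityError(
                    f"position {site.position} appears in blocks "
                    f"{prev!r} and {block.block_id!r}"
                )
            seen[site.position] = block.block_id


def shift_coordinates(result: PhasingResult, offset: int) -> PhasingResult:
    """Shift every position by ``offset`` base pairs.

    The +1 shift converts 0-based output (the SDhaP convention) to the
    1-based coordinates every other tool uses; any resulting position < 1
    raises :class:`CoordinateError`.
    """
    if offset == 0:
        return result
    new_blocks = []
    for block in result.blocks:
        new_sites = []
        for site in block.sites:
            pos = site.position + offset
            if pos < 1:
                raise CoordinateError(
                    f"shifting position {site.position} by {offset} "
                    f"gives {pos} (< 1)"
                )
            new_sites.append(replace(site, position=pos))
        new_blocks.append(PhasedBlock(block.block_id, tuple(new_sites)))
    basis = result.coordinate_basis
    if offset == 1 and basis == ZERO_BASED:
        basis = ONE_BASED
    elif offset == -1 and basis == ONE_BASED:
        basis = ZERO_BASED
    return replace(result, blocks=tuple(new_blocks), coordinate_basis=basis)


def normalize_result(
    result: PhasingResult, drop_unphased: bool = True
) -> PhasingResult:
    """Return the canonical form of a phasing result.

    Converts to 1-based coordinates, removes unphased ("-") sites when
    ``drop_unphased``, removes blocks left with fewer than two sites, sorts
    sites within blocks and blocks by first position.  Idempotent; the
    input is not modified.  A position occurring in two blocks raises
    :class:`StructuralIntegrityError`.
    """
    if result.coordinate_basis == ZERO_BASED:
        result = shift_coordinates(result, +1)
    _check_no_duplicate_positions(result.blocks)

    blocks = []
    for block in result.blocks:
        sites = block.sites
        if drop_unphased:
            sites = tuple(s for s in sites if s.phased)
        if len(sites) < 2:
            continue
        sites = tuple(sorted(sites, key=lambda s: s.position))
        blocks.append(PhasedBlock(block.block_id, sites))
    blocks.sort(key=lambda b: b.sites[0].position)
    return replace(result, blocks=tuple(blocks))


def result_summary(result: PhasingResult) -> BlockSnvSummary:
    """Five-number summary plus mean of phased SNVs per block.

    Quartiles use linear interpolation between order statistics (the
    default convention of numpy, R type 7 and spreadsheets); the mean is
    total phased SNVs divided by block count.
    """
    sizes = np.array([b.n_phased for b in result.blocks], dtype=float)
    if sizes.size == 0:
        raise EmptyInputError(
            f"result {result.tool_name!r} has no blocks to summarize"
        )
    q1, med, q3 = np.percentile(sizes, [25, 50, 75], method="linear")
    total = int(sizes.sum())
    return BlockSnvSummary(
        tool_name=result.tool_name,
        total_snvs=total,
        total_blocks=int(sizes.size),
        min=float(sizes.min()),
        q1=float(q1),
        median=float(med),
        mean=total / sizes.size,
        q3=float(q3),
        max=float(sizes.max()),
    )


def same_phasing(a: PhasingResult, b: PhasingResult) -> bool:
    """True when two results carry the same phasing: identical block
    membership, positions and alleles, ignoring block labels (formats
    relabel blocks — e.g. a VCF encodes them as PS values)."""
    if a.chromosome != b.chromosome or len(a.blocks) != len(b.blocks):
        return False
    def key(result: PhasingResult):
        return sorted(
            tuple((s.position, s.h1, s.h2) for s in block.sites)
            for block in result.blocks
        )
    return key(a) == key(b)


def render_2dp(value: float) -> str:
    """Render a number to exactly 2 decimals, rounding half up.

    This is the convention of every printed mean and percentage in the
    rendered tables (e.g. 115215/32150 -> "3.58").
    """
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))
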