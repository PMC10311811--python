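"""Gold-standard overlap, position-restriction and depth filtering.

Three auxiliary analyses around the pairwise comparison:

* overlap of the SNV positions a tool phased with the positions of an
  externally known ("gold standard") haplotype set;
* restricting one tool's output to the positions another tool phased, so
  that a tool calling many more SNVs can be compared on even footing
  (the filtered result is re-normalized: blocks left with a single site
  are dropped);
* depth (DP) filtering of haplotype-informative fragments: positions
  covered by fewer than ``min_depth`` fragments are masked everywhere,
  and fragments left covering fewer than two variants are removed, since
  a read linking a single SNV carries no phase information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Optional, Union

from .errors import EmptyInputError, FormatError, UsageError
from .io import Fragment, FragmentSet, PathOrStream, _open_text
from .model import PhasedBlock, PhasingResult, normalize_result

HET_CLASSES = frozenset({"0|1", "1|0"})
GENOTYPE_CLASSES = frozenset({"0|0", "1|1", "0|1", "1|0"})


@dataclass(frozen=True)
class KnownHaplotypeSet:
    """Positions (and genotype classes) of an external known-haplotype set."""

    positions: tuple[int, ...]  # sorted, unique
    genotype_class: Mapping[int, str]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(self.positions)))
        object.__setattr__(self, "positions", pos)
        bad = set(self.genotype_class.values()) - GENOTYPE_CLASSES
        if bad:
            raise UsageError(f"unknown genotype classes {sorted(bad)}")

    @property
    def het_positions(self) -> frozenset[int]:
        return frozenset(
            p
            for p, cls in self.genotype_class.items()
            if cls in HET_CLASSES
        )

    def __len__(self) -> int:
        return len(self.positions)


def read_known_vcf(source: PathOrStream) -> KnownHaplotypeSet:
    """Read a known-haplotype phased VCF, keeping all genotype classes
    (hom-ref 0|0 and hom-alt 1|1 positions included — the published
    position sets count them)."""
    import os
    import tempfile

    from cyvcf2 import VCF

    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return _read_known_path(path)
        finally:
            os.unlink(path)
    return _read_known_path(os.fspath(source))


def _read_known_path(path: str) -> KnownHaplotypeSet:
    from cyvcf2 import VCF

    classes: dict[int, str] = {}
    for rec in VCF(path):
        gt = rec.genotypes[0]
        if len(gt) != 3 or not gt[2]:
            continue
        a1, a2 = gt[0], gt[1]
        if a1 not in (0, 1) or a2 not in (0, 1):
            continue
        classes[rec.POS] = f"{a1}|{a2}"
    return KnownHaplotypeSet(
        positions=tuple(classes), genotype_class=classes
    )


@dataclass(frozen=True)
class OverlapReport:
    """How many of a tool's phased positions appear in the known set."""

    tool_name: str
    inferred_total: int
    overlap_count: int

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.overlap_count / self.inferred_total


def position_overlap(
    result: PhasingResult,
    known: Union[KnownHaplotypeSet, AbstractSet[int]],
    het_only: bool = False,
) -> OverlapReport:
    """Count the result's phased positions found in the known set.

    With ``het_only`` the known set is restricted to heterozygous
    positions (the only ones a phasing tool could in principle call).
    """
    inferred = set(result.phased_positions())
    if not inferred:
        raise EmptyInputError(
            f"result {result.tool_name!r} has no phased sites"
        )
    if isinstance(known, KnownHaplotypeSet):
        known_pos = known.het_positions if het_only else set(known.positions)
    else:
        known_pos = set(known)
    return OverlapReport(
        tool_name=result.tool_name,
        inferred_total=len(inferred),
        overlap_count=len(inferred & known_pos),
    )


def filter_to_positions(
    result: PhasingResult, keep: Iterable[int]
) -> PhasingResult:
    """Restrict a result to the given positions and re-normalize.

    Sites outside ``keep`` are removed; blocks left with fewer than two
    sites are dropped (singleton blocks carry no phase).  Block labels and
    internal order are preserved.  Note that removing interior sites can
    change the downstream switch structure of the surviving blocks.
    """
    keep_set = set(keep)
    blocks = []
    for block in result.blocks:
        sites = tuple(s for s in block.sites if s.position in keep_set)
        if sites:
            blocks.append(PhasedBlock(block.block_id, sites))
    filtered = PhasingResult(
        tool_name=result.tool_name,
        chromosome=result.chromosome,
        blocks=tuple(blocks),
        coordinate_basis=result.coordinate_basis,
    )
    return normalize_result(filtered)


def intersect_result_positions(
    a: PhasingResult, b: PhasingResult
) -> tuple[int, ...]:
    """Sorted positions phased by both results (a keep-set builder)."""
    return tuple(
        sorted(set(a.phased_positions()) & set(b.phased_positions()))
    )


@dataclass(frozen=True)
class DepthFilterConfig:
    """Minimum fragment coverage (DP level) a position must reach."""

    min_depth: int = 1

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise UsageError(f"min_depth must be >= 1, got {self.min_depth}")


def index_depths(fragments: FragmentSet) -> dict[int, int]:
    """Fragment coverage per 1-based variant index."""
    depths: dict[int, int] = {}
    for frag in fragments.fragments:
        for idx in frag.covered_indices:
            depths[idx] = depths.get(idx, 0) + 1
    return depths


def site_depths(fragments: FragmentSet) -> dict[int, int]:
    """Fragment coverage per chromosomal position.

    Requires ``index_to_position`` on the fragment set; an index without a
    mapped position raises :class:`FormatError`.
    """
    if fragments.index_to_position is None:
        raise FormatError(
            "fragment set has no index->position map; attach one with "
            "attach_positions()"
        )
    mapping = fragments.index_to_position
    out: dict[int, int] = {}
    for idx, depth in index_depths(fragments).items():
        if idx not in mapping:
            raise FormatError(f"variant index {idx} has no mapped position")
        out[mapping[idx]] = depth
    return out


def filter_by_depth(
    fragments: FragmentSet, config: DepthFilterConfig
) -> FragmentSet:
    """Apply a DP filter at the fragment level.

    Variant indices covered by fewer than ``min_depth`` fragments are
    masked out of every fragment (splitting allele runs where needed);
    fragments left covering fewer than two variants are dropped as
    non-informative.  Monotone in ``min_depth``: raising the threshold
    never adds back a site or a fragment.
    """
    depths = index_depths(fragments)
    keep_idx = {
        idx for idx, d in depths.items() if d >= config.min_depth
    }
    kept: list[Fragment] = []
    for frag in fragments.fragments:
        segments: list[tuple[int, str]] = []
        quals: list[str] = []
        run_start: Optional[int] = None
        run_alleles: list[str] = []
        q_iter = iter(frag.qualities)
        for start, alleles in frag.segments:
            for k, allele in enumerate(alleles):
                idx = start + k
                q = next(q_iter)
                if idx in keep_idx:
                    if run_start is None:
                        run_start = idx
                    elif run_start + len(run_alleles) != idx:
                        segments.append((run_start, "".join(run_alleles)))
                        run_start = idx
                        run_alleles = []
                    run_alleles.append(allele)
                    quals.append(q)
                else:
                    if run_start is not None:
                        segments.append((run_start, "".join(run_alleles)))
                        run_start = None
                        run_alleles = []
            if run_start is not None:
                segments.append((run_start, "".join(run_alleles)))
                run_start = None
                run_alleles = []
        new_frag = Fragment(frag.fragment_id, tuple(segments), "".join(quals))
        if new_frag.informative:
            kept.append(new_frag)
    return FragmentSet(
        fragments=tuple(kept),
        n_variants=fragments.n_variants,
        index_to_position=fragments.index_to_position,
    )


def read_position_set(source: PathOrStream) -> tuple[int, ...]:
    """Read a keep-set: single-column positions, or 3-column BED-like
    (chrom, start, end; 0-based half-open, expanded to 1-based points)."""
    positions: set[int] = set()
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            try:
                if len(fields) == 1:
                    positions.add(int(fields[0]))
                elif len(fields) >= 3:
                    start, end = int(fields[1]), int(fields[2])
                    positions.update(range(start + 1, end + 1))
                else:
                    raise ValueError
            except ValueError:
                raise FormatError(
                    f"cannot parse position line {line.strip()!r}", lineno
                ) from None
    return tuple(sorted(positions))


def write_position_set(
    positions: Iterable[int], sink: PathOrStream
) -> None:
    with _open_text(sink, "w") as fh:
        for pos in sorted(set(positions)):
            fh.write(f"{pos}\n")
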