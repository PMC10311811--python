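"""Readers and writers for the file dialects of haplotype-assembly tools.

Three families of files are supported:

* **Block text files** (HapCUT2 and the near-identical dialects of MixSIH,
  PEATH, SDhaP and MAtCHap): blocks delimited by a ``BLOCK:`` header line
  and a terminator line of asterisks; each site line holds the variant
  index in the input VCF, the allele on each chromosome copy (``0``, ``1``
  or ``-``), the chromosome and the 1-based position, plus trailing columns
  that are preserved verbatim but never interpreted.  The SDhaP dialect is
  0-based and is shifted to 1-based on read.
* **Phased VCF** (WhatsHap / MAtCHap style): ``|``-separated genotypes with
  a ``PS`` (phase set) tag grouping records into blocks.  Reading goes
  through cyvcf2/htslib.
* **extractHAIRS fragment files**: one haplotype-informative read per line
  with the variant indices it covers and the alleles observed.

All readers accept a path (plain or ``.gz``) or an open text stream.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

from .errors import EmptyInputError, FormatError, StructuralIntegrityError
from .model import (
    ONE_BASED,
    ZERO_BASED,
    PhasedBlock,
    PhasedSite,
    PhasingResult,
    shift_coordinates,
)

logger = logging.getLogger(__name__)

PathOrStream = Union[str, os.PathLike, IO[str]]


# ---------------------------------------------------------------------------
# dialects


@dataclass(frozen=True)
class BlockFileDialect:
    """A concrete block-file dialect.

    ``sort_order`` records how the tool orders its output: ``by_block_id``
    (HapCUT2, MixSIH, SDhaP — sites may be out of position order inside a
    block), ``by_position`` (WhatsHap-style), or ``clean`` (PEATH, MAtCHap —
    both block ids and positions well ordered).  Parsing is insensitive to
    the order; writing follows it.
    """

    name: str
    coordinate_basis: str = ONE_BASED
    sort_order: str = "clean"


DIALECTS: dict[str, BlockFileDialect] = {
    "hapcut2": BlockFileDialect("hapcut2", ONE_BASED, "by_block_id"),
    "mixsih": BlockFileDialect("mixsih", ONE_BASED, "by_block_id"),
    "peath": BlockFileDialect("peath", ONE_BASED, "clean"),
    "sdhap": BlockFileDialect("sdhap", ZERO_BASED, "by_block_id"),
    "matchap": BlockFileDialect("matchap", ONE_BASED, "clean"),
}


def get_dialect(name: str) -> BlockFileDialect:
    try:
        return DIALECTS[name.lower()]
    except KeyError:
        raise FormatError(
            f"unknown dialect {name!r}; known: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# stream plumbing


@contextmanager
def _open_text(source: PathOrStream, mode: str = "r") -> Iterator[IO[str]]:
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source  # caller-managed stream
        return
    path = os.fspath(source)
    if path.endswith(".gz"):
        with gzip.open(path, mode + "t") as fh:
            yield fh
    else:
        with open(path, mode) as fh:
            yield fh


# ---------------------------------------------------------------------------
# block text files

_TERMINATOR = "********"


def read_block_file(
    source: PathOrStream,
    dialect: Union[BlockFileDialect, str],
    tool_name: Optional[str] = None,
) -> PhasingResult:
    """Parse a HapCUT2-family block file into a raw :class:`PhasingResult`.

    Site lines are whitespace separated: variant index, h1 allele, h2
    allele, chromosome, position; any trailing fields are kept as opaque
    annotations.  The result is *not* normalized; SDhaP-dialect input is
    shifted to 1-based coordinates.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    blocks: list[PhasedBlock] = []
    sites: list[PhasedSite] = []
    block_id: Optional[str] = None
    n_anonymous = 0
    chromosome: Optional[str] = None
    # sdhap positions are 0-based; parse as-is, shift at the end
    min_pos = 1 if dialect.coordinate_basis == ONE_BASED else 0

    def flush() -> None:
        nonlocal sites, block_id
        if block_id is not None:
            blocks.append(PhasedBlock(block_id, tuple(sites)))
        sites = []
        block_id = None

    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("BLOCK:"):
                flush()
                n_anonymous += 1
                block_id = _block_id_from_header(line, n_anonymous)
                continue
            if line.startswith("****"):
                flush()
                continue
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(
                    f"site line needs >= 5 fields, got {len(fields)}", lineno
                )
            if block_id is None:
                raise FormatError("site line outside any BLOCK", lineno)
            idx_s, h1_s, h2_s, chrom, pos_s = fields[:5]
            h1 = _parse_allele(h1_s, lineno)
            h2 = _parse_allele(h2_s, lineno)
            if h1 is not None and h2 is not None and h1 == h2:
                raise FormatError(
                    f"h1 == h2 == {h1} on a phased line "
                    "(biallelic heterozygous sites expected)",
                    lineno,
                )
            if (h1 is None) != (h2 is None):
                raise FormatError(
                    "one allele phased, the other '-'", lineno
                )
            if chromosome is None:
                chromosome = chrom
            elif chrom != chromosome:
                raise FormatError(
                    f"chromosome {chrom!r} mixed with {chromosome!r}; one "
                    "result covers one chromosome",
                    lineno,
                )
            try:
                pos = int(pos_s)
                idx = int(idx_s)
            except ValueError:
                raise FormatError(
                    f"non-integer index/position {idx_s!r}/{pos_s!r}", lineno
                ) from None
            if pos < min_pos:
                raise FormatError(
                    f"position {pos} below minimum {min_pos} for "
                    f"{dialect.coordinate_basis} dialect {dialect.name!r}",
                    lineno,
                )
            sites.append(
                PhasedSite(
                    # 0-based dialects (sdhap) are shifted to 1-based here
                    position=pos + (0 if min_pos == 1 else 1),
                    h1=h1,
                    h2=h2,
                    variant_index=idx,
                    extra=tuple(fields[5:]),
                )
            )
        flush()

    result = PhasingResult(
        tool_name=tool_name or dialect.name,
        chromosome=chromosome or "unknown",
        blocks=tuple(blocks),
        coordinate_basis=ONE_BASED,
    )
    return result


def _parse_allele(text: str, lineno: int) -> Optional[int]:
    if text == "-":
        return None
    if text in ("0", "1"):
        return int(text)
    raise FormatError(f"allele {text!r} not in {{0, 1, -}}", lineno)


def _block_id_from_header(line: str, counter: int) -> str:
    # HapCUT2 headers look like "BLOCK: offset: 7 len: 3 phased: 3 ...";
    # use the offset as the id when present, else a running counter.
    tokens = line.split()
    for i, tok in enumerate(tokens):
        if tok.rstrip(":").lower() == "offset" and i + 1 < len(tokens):
            return tokens[i + 1]
    rest = line[len("BLOCK:"):].strip()
    if rest:
        return rest.split()[0]
    return str(counter)


def write_block_file(
    result: PhasingResult,
    sink: PathOrStream,
    dialect: Union[BlockFileDialect, str] = "hapcut2",
) -> None:
    """Write a result in the HapCUT2-family block layout.

    ``read_block_file(write_block_file(x))`` reproduces x's positions,
    alleles and block membership.  Variant indices from parsing are reused;
    otherwise they are regenerated as the position rank over the whole
    result.  The sdhap dialect writes 0-based positions.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    if dialect.coordinate_basis == ZERO_BASED:
        result = shift_coordinates(result, -1)

    rank = {
        pos: i + 1 for i, pos in enumerate(sorted(result.positions()))
    }
    blocks = list(result.blocks)
    if dialect.sort_order in ("by_position", "clean"):
        blocks = [
            PhasedBlock(
                b.block_id, tuple(sorted(b.sites, key=lambda s: s.position))
            )
            for b in blocks
        ]
        blocks.sort(key=lambda b: min(b.positions) if len(b) else 0)

    with _open_text(sink, "w") as fh:
        for block in blocks:
            n = len(block)
            first = block.sites[0] if n else None
            offset = (
                first.variant_index
                if first is not None and first.variant_index is not None
                else rank.get(first.position, 1) if first is not None else 1
            )
            fh.write(
                f"BLOCK: offset: {offset} len: {n} phased: {block.n_phased}\n"
            )
            for site in block.sites:
                idx = (
                    site.variant_index
                    if site.variant_index is not None
                    else rank[site.position]
                )
                h1 = "-" if site.h1 is None else str(site.h1)
                h2 = "-" if site.h2 is None else str(site.h2)
                fields = [
                    str(idx),
                    h1,
                    h2,
                    result.chromosome,
                    str(site.position),
                    *site.extra,
                ]
                fh.write("\t".join(fields) + "\n")
            fh.write(_TERMINATOR + "\n")


# ---------------------------------------------------------------------------
# phased VCF


def read_phased_vcf(
    source: PathOrStream, tool_name: Optional[str] = None
) -> PhasingResult:
    """Read a WhatsHap/MAtCHap-style phased VCF into a raw result.

    Only biallelic heterozygous ``|``-separated genotypes become sites
    (``0|1`` -> h1=0, ``1|0`` -> h1=1).  Records sharing a ``PS`` phase-set
    value form one block; phased records without a PS tag are grouped into
    one block per run of consecutive phased records.  ``/``-separated
    genotypes are skipped silently; homozygous or multi-allelic records are
    skipped and counted (``result`` carries no warning state — the count is
    logged).
    """
    # cyvcf2 needs a real path; spool stream input to a temp file
    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return _read_phased_vcf_path(path, tool_name)
        finally:
            os.unlink(path)
    return _read_phased_vcf_path(os.fspath(source), tool_name)


def _read_phased_vcf_path(
    path: str, tool_name: Optional[str]
) -> PhasingResult:
    from cyvcf2 import VCF

    vcf = VCF(path)
    if not vcf.samples:
        raise FormatError("VCF has no genotype (sample) column")
    if len(vcf.samples) > 1:
        logger.warning(
            "VCF has %d samples; using the first (%s)",
            len(vcf.samples),
            vcf.samples[0],
        )
    chromosome: Optional[str] = None
    n_skipped = 0
    # block label -> list of sites; None key handled via synthetic run labels
    block_sites: dict[str, list[PhasedSite]] = {}
    block_order: list[str] = []
    run_label: Optional[str] = None
    prev_phased = False
    n_records = 0

    for rec in vcf:
        n_records += 1
        if chromosome is None:
            chromosome = rec.CHROM
        elif rec.CHROM != chromosome:
            raise FormatError(
                f"chromosome {rec.CHROM!r} mixed with {chromosome!r}"
            )
        gt = rec.genotypes[0]
        if len(gt) != 3:  # haploid or missing
            n_skipped += 1
            prev_phased = False
            continue
        a1, a2, phased = gt
        if not phased:
            prev_phased = False
            continue
        if len(rec.ALT) != 1 or {a1, a2} != {0, 1}:
            # multi-allelic, homozygous (0|0, 1|1) or missing: not a
            # haplotype-informative het site ("no.HI" convention)
            n_skipped += 1
            prev_phased = False
            continue
        ps = _phase_set(rec)
        if ps is not None:
            label = str(ps)
        else:
            if not prev_phased or run_label is None:
                run_label = f"ps_run_{rec.POS}"
            label = run_label
        if label not in block_sites:
            block_sites[label] = []
            block_order.append(label)
        block_sites[label].append(
            PhasedSite(
                position=rec.POS,
                h1=a1,
                h2=a2,
                variant_index=n_records,
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        prev_phased = True

    if n_skipped:
        logger.warning(
            "skipped %d non-biallelic-het or unparseable records", n_skipped
        )
    blocks = tuple(
        PhasedBlock(label, tuple(block_sites[label])) for label in block_order
    )
    result = PhasingResult(
        tool_name=tool_name or "vcf",
        chromosome=chromosome or "unknown",
        blocks=blocks,
        coordinate_basis=ONE_BASED,
    )
    return result


def _phase_set(rec) -> Optional[int]:
    try:
        ps = rec.format("PS")
    except KeyError:
        return None
    if ps is None:
        return None
    value = ps[0]
    try:
        value = value.item() if hasattr(value, "item") else value[0]
    except (TypeError, IndexError):
        pass
    if value is None:
        return None
    try:
        iv = int(value)
    except (TypeError, ValueError):
        return None
    # htslib encodes missing integer FORMAT values as INT32_MIN
    if iv <= -(2**31) + 1:
        return None
    return iv


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hapcompare
##contig=<ID={chrom}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_phased_vcf(
    result: PhasingResult, sink: PathOrStream, sample: str = "SAMPLE"
) -> None:
    """Write a minimal phased VCF (GT:PS) that round-trips through
    :func:`read_phased_vcf`.

    Block ids are encoded as PS values; non-numeric ids are mapped to the
    block's first position (the WhatsHap convention).  Records are emitted
    in position order, as VCF requires.  Unphased sites are written with
    ``/``-separated genotypes.
    """
    rows = []
    for block in result.blocks:
        try:
            ps = int(block.block_id)
        except ValueError:
            ps = min(block.positions) if len(block) else 0
        for site in block.sites:
            if site.phased:
                gt = f"{site.h1}|{site.h2}:{ps}"
                fmt = "GT:PS"
            else:
                gt = "0/1"
                fmt = "GT"
            rows.append(
                (
                    site.position,
                    f"{result.chromosome}\t{site.position}\t.\t{site.ref}"
                    f"\t{site.alt}\t.\tPASS\t.\t{fmt}\t{gt}",
                )
            )
    rows.sort(key=lambda r: r[0])
    with _open_text(sink, "w") as fh:
        fh.write(
            _VCF_HEADER.format(chrom=result.chromosome, sample=sample)
        )
        for _, line in rows:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# extractHAIRS fragment files


@dataclass(frozen=True)
class Fragment:
    """One haplotype-informative read: the variant-index runs it covers and
    the alleles observed there."""

    fragment_id: str
    segments: tuple[tuple[int, str], ...]  # (1-based start index, alleles)
    qualities: str

    def __post_init__(self) -> None:
        n_alleles = sum(len(a) for _, a in self.segments)
        if n_alleles != len(self.qualities):
            raise FormatError(
                f"fragment {self.fragment_id!r}: {n_alleles} alleles but "
                f"{len(self.qualities)} quality characters"
            )
        last_end = 0
        for start, alleles in self.segments:
            if start <= last_end:
                raise FormatError(
                    f"fragment {self.fragment_id!r}: segment at index "
                    f"{start} overlaps or is out of order"
                )
            if not set(alleles) <= {"0", "1"}:
                raise FormatError(
                    f"fragment {self.fragment_id!r}: alleles {alleles!r} "
                    "not over {0, 1}"
                )
            last_end = start + len(alleles) - 1

    @property
    def covered_indices(self) -> tuple[int, ...]:
        return tuple(
            start + k
            for start, alleles in self.segments
            for k in range(len(alleles))
        )

    @property
    def informative(self) -> bool:
        """A read covering a single SNV cannot link alleles across sites."""
        return len(self.covered_indices) >= 2


@dataclass(frozen=True)
class FragmentSet:
    """A set of fragments over an indexed variant list.

    ``index_to_position`` maps the 1-based variant index of the source VCF
    to a chromosomal position; it is optional at parse time (the fragment
    file itself carries only indices) and required for position-keyed
    depth queries.
    """

    fragments: tuple[Fragment, ...]
    n_variants: int
    index_to_position: Optional[Mapping[int, int]] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragments", tuple(self.fragments))
        for frag in self.fragments:
            covered = frag.covered_indices
            if covered and max(covered) > self.n_variants:
                raise StructuralIntegrityError(
                    f"fragment {frag.fragment_id!r} covers index "
                    f"{max(covered)} > n_variants {self.n_variants}"
                )

    def __len__(self) -> int:
        return len(self.fragments)


def read_fragments(
    source: PathOrStream, n_variants: Optional[int] = None
) -> FragmentSet:
    """Parse an extractHAIRS-style fragment file.

    Line layout: segment count, fragment id, then (start index, allele
    string) pairs, then the quality string, e.g.
    ``2 frag1 3 01 9 1 ABC``.
    """
    fragments: list[Fragment] = []
    max_index = 0
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                n_seg = int(fields[0])
            except ValueError:
                raise FormatError(
                    f"segment count {fields[0]!r} not an integer", lineno
                ) from None
            expected = 2 + 2 * n_seg + 1
            if len(fields) != expected:
                raise FormatError(
                    f"fragment {fields[1] if len(fields) > 1 else '?'!r}: "
                    f"expected {expected} fields for {n_seg} segments, "
                    f"got {len(fields)}",
                    lineno,
                )
            frag_id = fields[1]
            segments = []
            for k in range(n_seg):
                start_s, alleles = fields[2 + 2 * k], fields[3 + 2 * k]
                try:
                    start = int(start_s)
                except ValueError:
                    raise FormatError(
                        f"fragment {frag_id!r}: start index {start_s!r} "
                        "not an integer",
                        lineno,
                    ) from None
                segments.append((start, alleles))
            qualities = fields[-1]
            try:
                frag = Fragment(frag_id, tuple(segments), qualities)
            except FormatError as exc:
                raise FormatError(str(exc), lineno) from None
            if frag.covered_indices:
                max_index = max(max_index, max(frag.covered_indices))
            fragments.append(frag)
    return FragmentSet(
        fragments=tuple(fragments),
        n_variants=n_variants if n_variants is not None else max_index,
    )


def write_fragments(fragset: FragmentSet, sink: PathOrStream) -> None:
    """Serialize a FragmentSet back to extractHAIRS layout."""
    with _open_text(sink, "w") as fh:
        for frag in fragset.fragments:
            fields = [str(len(frag.segments)), frag.fragment_id]
            for start, alleles in frag.segments:
                fields.extend([str(start), alleles])
            fields.append(frag.qualities)
            fh.write(" ".join(fields) + "\n")


def attach_positions(
    fragset: FragmentSet, index_to_position: Mapping[int, int]
) -> FragmentSet:
    """Return a copy of ``fragset`` with a variant-index -> position map
    (e.g. built from the VCF the fragments were extracted against)."""
    return FragmentSet(
        fragments=fragset.fragments,
        n_variants=fragset.n_variants,
        index_to_position=dict(index_to_position),
    )
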