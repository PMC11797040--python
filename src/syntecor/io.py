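"""Readers and writers for the on-disk formats the tool touches.

Formats
-------
* BED6 gene files (tab-separated, 0-based half-open intervals, gene ID in
  column 4, strand in column 6 when present).
* JCVI-style anchors files pairing query genes with reference genes plus a
  score; ``###`` block separators and ``#`` comments are skipped because the
  tool performs its own clustering.
* AGP v2.x assemblies (1-based inclusive coordinates; W rows place contigs,
  U/N rows record gaps).
* tours files: per-chromosome ordered contig lists with +/- orientation.
* A machine-readable blocks table (TSV) mirroring the labeled dot plot.

Internally all coordinates are 0-based half-open; conversion to and from
each format's native convention happens at the boundary.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ParseError, StructuralError, ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Default gap inserted between consecutive contigs when regenerating AGP.
DEFAULT_GAP_LENGTH = 100


def natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically (chr2 before chr10)."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A gene's location on a sequence, as read from a BED file."""

    gene_id: str
    seq_id: str
    start: int  # 0-based
    end: int    # half-open, end > start
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class AnchorPair:
    """One query<->reference ortholog pair with its synteny score."""

    query_gene: str
    ref_gene: str
    score: float = 1.0


@dataclass(frozen=True)
class AgpRow:
    """One raw AGP line (W contig row or U/N gap row), 1-based inclusive."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str
    # W rows
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # U/N rows
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None


@dataclass(frozen=True)
class ContigPlacement:
    """A contig placed on a chromosome, with its object interval.

    ``start``/``end`` are the 0-based half-open coordinates of the contig on
    its chromosome-scale object; ``end - start == length``.
    """

    contig_id: str
    length: int
    orientation: str  # '+' or '-'
    start: int = 0
    end: int = 0

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValidationError(
                f"contig {self.contig_id}: orientation must be + or -"
            )
        if self.length <= 0:
            raise ValidationError(f"contig {self.contig_id}: non-positive length")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig_id, self.length, self.orientation)


class AssemblyLayout:
    """Per-chromosome ordered contig placements derived from an AGP file.

    Equality (and the AGP round-trip guarantee) is defined on the core
    fields — chromosome order, and each chromosome's sequence of
    ``(contig_id, length, orientation)`` plus the unplaced set — not on the
    object intervals, which depend on the gap length used when the AGP was
    written.
    """

    def __init__(
        self,
        chromosomes: dict[str, list[ContigPlacement]] | None = None,
        unplaced: list[ContigPlacement] | None = None,
    ):
        self.chromosomes: dict[str, list[ContigPlacement]] = dict(chromosomes or {})
        self.unplaced: list[ContigPlacement] = list(unplaced or [])
        self._check_unique()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_lists(
        cls,
        chromosomes: dict[str, Sequence[tuple[str, int, str]]],
        gap_length: int = DEFAULT_GAP_LENGTH,
        unplaced: Sequence[tuple[str, int, str]] = (),
    ) -> "AssemblyLayout":
        """Build a layout from (contig_id, length, orientation) triples,
        computing object intervals with a uniform inter-contig gap."""
        chroms: dict[str, list[ContigPlacement]] = {}
        for chrom, triples in chromosomes.items():
            chroms[chrom] = _lay_out(triples, gap_length)
        unp = [
            ContigPlacement(cid, ln, ori, 0, ln) for cid, ln, ori in unplaced
        ]
        return cls(chroms, unp)

    def relayout(self, gap_length: int = DEFAULT_GAP_LENGTH) -> "AssemblyLayout":
        """Recompute all object intervals with a uniform gap length."""
        return AssemblyLayout.from_lists(
            {c: [p.key for p in ps] for c, ps in self.chromosomes.items()},
            gap_length,
            [p.key for p in self.unplaced],
        )

    # -- invariants ---------------------------------------------------------

    def _check_unique(self) -> None:
        seen: set[str] = set()
        for placements in self.chromosomes.values():
            for p in placements:
                if p.contig_id in seen:
                    raise ValidationError(
                        f"contig {p.contig_id} placed more than once"
                    )
                seen.add(p.contig_id)
        for p in self.unplaced:
            if p.contig_id in seen:
                raise ValidationError(f"contig {p.contig_id} placed more than once")
            seen.add(p.contig_id)

    # -- queries ------------------------------------------------------------

    def chrom_length(self, chrom: str) -> int:
        placements = self.chromosomes.get(chrom, [])
        return placements[-1].end if placements else 0

    def placement_at(self, chrom: str, pos: int) -> ContigPlacement | None:
        """The contig whose object interval contains ``pos`` (None for gaps)."""
        placements = self.chromosomes.get(chrom, [])
        starts = [p.start for p in placements]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and placements[i].start <= pos < placements[i].end:
            return placements[i]
        return None

    def find_contig(self, contig_id: str) -> tuple[str | None, int]:
        """Return (chromosome, index) of a placed contig; (None, i) if unplaced."""
        for chrom, placements in self.chromosomes.items():
            for i, p in enumerate(placements):
                if p.contig_id == contig_id:
                    return chrom, i
        for i, p in enumerate(self.unplaced):
            if p.contig_id == contig_id:
                return None, i
        raise KeyError(contig_id)

    def contig_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for placements in self.chromosomes.values():
            for p in placements:
                counts[p.contig_id] = counts.get(p.contig_id, 0) + 1
        for p in self.unplaced:
            counts[p.contig_id] = counts.get(p.contig_id, 0) + 1
        return counts

    def core(self):
        return (
            tuple(
                (chrom, tuple(p.key for p in placements))
                for chrom, placements in self.chromosomes.items()
            ),
            tuple(sorted(p.key for p in self.unplaced)),
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, AssemblyLayout) and self.core() == other.core()

    def __hash__(self):
        return hash(self.core())

    def __repr__(self) -> str:
        n = sum(len(v) for v in self.chromosomes.values())
        return (
            f"AssemblyLayout({len(self.chromosomes)} chromosomes, "
            f"{n} placed, {len(self.unplaced)} unplaced)"
        )


def _lay_out(
    triples: Iterable[tuple[str, int, str]], gap_length: int
) -> list[ContigPlacement]:
    if gap_length < 0:
        raise ValidationError("gap_length must be >= 0")
    placements = []
    pos = 0
    for i, (cid, length, ori) in enumerate(triples):
        if i > 0:
            pos += gap_length
        placements.append(ContigPlacement(cid, length, ori, pos, pos + length))
        pos += length
    return placements


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GeneFeature]:
    """Read a BED6 gene file; column 4 is the gene ID.

    Raises :class:`ParseError` on malformed lines (naming the line number)
    and on duplicate gene IDs (naming the ID).
    """
    path = Path(path)
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"expected >=4 tab-separated columns, got {len(cols)}",
                    path=str(path), line=lineno,
                )
            seq_id, s, e, gene_id = cols[0], cols[1], cols[2], cols[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {s!r}, {e!r}",
                    path=str(path), line=lineno,
                ) from None
            if end <= start or start < 0:
                raise ParseError(
                    f"invalid interval [{start}, {end})",
                    path=str(path), line=lineno,
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            if gene_id in seen:
                raise ParseError(
                    f"duplicate gene ID {gene_id!r}", path=str(path), line=lineno
                )
            seen.add(gene_id)
            genes.append(GeneFeature(gene_id, seq_id, start, end, strand))
    return genes


def write_bed(genes: Iterable[GeneFeature]) -> str:
    lines = [
        f"{g.seq_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
        for g in genes
    ]
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------

def read_anchors(path: str | Path) -> list[AnchorPair]:
    """Read a JCVI anchors file (query gene, reference gene, score).

    ``###`` block separators and ``#`` comments are skipped — block structure
    is discarded because clustering is redone downstream. A missing score
    column defaults to 1.
    """
    path = Path(path)
    pairs: list[AnchorPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(
                    f"expected >=2 tab-separated columns, got {len(cols)}",
                    path=str(path), line=lineno,
                )
            score = 1.0
            if len(cols) >= 3 and cols[2].strip():
                try:
                    score = float(cols[2])
                except ValueError:
                    raise ParseError(
                        f"non-numeric score {cols[2]!r}",
                        path=str(path), line=lineno,
                    ) from None
            if score < 0:
                raise ParseError(
                    f"negative score {score}", path=str(path), line=lineno
                )
            pairs.append(AnchorPair(cols[0], cols[1], score))
    return pairs


def write_anchors(pairs: Iterable[AnchorPair]) -> str:
    lines = ["###"]
    for p in pairs:
        score = int(p.score) if float(p.score).is_integer() else p.score
        lines.append(f"{p.query_gene}\t{p.ref_gene}\t{score}")
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

def read_agp(path: str | Path) -> tuple[list[AgpRow], AssemblyLayout]:
    """Read an AGP v2.x file into raw rows and an :class:`AssemblyLayout`.

    W rows become contig placements in object order; U/N gap rows are
    recorded but create no placement. Single-W-row objects whose object name
    equals the contig name are classified as unplaced singletons (the form
    this package writes for deleted contigs).
    """
    path = Path(path)
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(
                    f"expected >=8 tab-separated columns, got {len(cols)}",
                    path=str(path), line=lineno,
                )
            try:
                obj, beg, end, part = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            except ValueError:
                raise ParseError(
                    "non-integer object coordinates or part number",
                    path=str(path), line=lineno,
                ) from None
            ctype = cols[4]
            if end < beg or beg < 1:
                raise StructuralError(
                    f"invalid object interval [{beg}, {end}]",
                    path=str(path), line=lineno,
                )
            if ctype == "W":
                if len(cols) < 9:
                    raise ParseError(
                        "W row needs 9 columns", path=str(path), line=lineno
                    )
                try:
                    cbeg, cend = int(cols[6]), int(cols[7])
                except ValueError:
                    raise ParseError(
                        "non-integer component coordinates",
                        path=str(path), line=lineno,
                    ) from None
                ori = cols[8]
                if ori not in ("+", "-"):
                    raise ParseError(
                        f"invalid orientation {ori!r}", path=str(path), line=lineno
                    )
                if cend - cbeg != end - beg:
                    raise StructuralError(
                        f"component length {cend - cbeg + 1} != object span "
                        f"{end - beg + 1} for {cols[5]}",
                        path=str(path), line=lineno,
                    )
                rows.append(AgpRow(obj, beg, end, part, "W", cols[5], cbeg, cend, ori))
            elif ctype in ("U", "N"):
                try:
                    gap_len = int(cols[5])
                except ValueError:
                    raise ParseError(
                        "non-integer gap length", path=str(path), line=lineno
                    ) from None
                rows.append(AgpRow(
                    obj, beg, end, part, ctype,
                    gap_length=gap_len,
                    gap_type=cols[6] if len(cols) > 6 else "scaffold",
                    linkage=cols[7] if len(cols) > 7 else "yes",
                ))
            else:
                raise ParseError(
                    f"unsupported component type {ctype!r}",
                    path=str(path), line=lineno,
                )
    return rows, _layout_from_rows(rows, str(path))


def _layout_from_rows(rows: list[AgpRow], path: str) -> AssemblyLayout:
    by_object: dict[str, list[AgpRow]] = {}
    for row in rows:
        by_object.setdefault(row.object_id, []).append(row)
    chroms: dict[str, list[ContigPlacement]] = {}
    unplaced: list[ContigPlacement] = []
    for obj, obj_rows in by_object.items():
        expected_beg, expected_part = 1, 1
        placements = []
        for row in obj_rows:
            if row.part_number != expected_part:
                raise StructuralError(
                    f"object {obj}: part_number {row.part_number}, "
                    f"expected {expected_part}", path=path,
                )
            if row.object_beg != expected_beg:
                raise StructuralError(
                    f"object {obj} part {row.part_number}: begins at "
                    f"{row.object_beg}, expected {expected_beg}", path=path,
                )
            if row.component_type == "W":
                placements.append(ContigPlacement(
                    row.component_id,
                    row.object_end - row.object_beg + 1,
                    row.orientation,
                    row.object_beg - 1,  # to 0-based half-open
                    row.object_end,
                ))
            expected_beg = row.object_end + 1
            expected_part += 1
        is_singleton = (
            len(obj_rows) == 1
            and obj_rows[0].component_type == "W"
            and obj_rows[0].component_id == obj
        )
        if is_singleton:
            unplaced.append(placements[0])
        else:
            chroms[obj] = placements
    return AssemblyLayout(chroms, unplaced)


def write_agp(
    layout: AssemblyLayout,
    gap_length: int = DEFAULT_GAP_LENGTH,
    gap_type: str = "scaffold",
    linkage: str = "yes",
    evidence: str = "map",
) -> str:
    """Render a layout as AGP text with a uniform gap between contigs.

    Object coordinates are recomputed from contig lengths; unplaced contigs
    are emitted as singleton objects named by their contig ID. The output
    re-parses (:func:`read_agp`) to an equal layout for any gap length >= 0.
    """
    lines: list[str] = []
    for chrom, placements in layout.chromosomes.items():
        pos, part = 1, 1
        for i, p in enumerate(placements):
            if i > 0 and gap_length > 0:
                lines.append(
                    f"{chrom}\t{pos}\t{pos + gap_length - 1}\t{part}\tU\t"
                    f"{gap_length}\t{gap_type}\t{linkage}\t{evidence}"
                )
                pos += gap_length
                part += 1
            lines.append(
                f"{chrom}\t{pos}\t{pos + p.length - 1}\t{part}\tW\t"
                f"{p.contig_id}\t1\t{p.length}\t{p.orientation}"
            )
            pos += p.length
            part += 1
    for p in layout.unplaced:
        lines.append(
            f"{p.contig_id}\t1\t{p.length}\t1\tW\t"
            f"{p.contig_id}\t1\t{p.length}\t{p.orientation}"
        )
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# tours
# ---------------------------------------------------------------------------

def write_tours(layout: AssemblyLayout) -> str:
    """Render the per-chromosome contig order/orientation as a tours file.

    Each chromosome contributes a ``>name`` header and one line of
    space-separated ``contig+``/``contig-`` tokens. Unplaced contigs are
    omitted (they appear only in AGP output).
    """
    lines: list[str] = []
    for chrom, placements in layout.chromosomes.items():
        lines.append(f">{chrom}")
        lines.append(" ".join(f"{p.contig_id}{p.orientation}" for p in placements))
    return "".join(line + "\n" for line in lines)


def read_tours(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Parse a tours file into chromosome -> [(contig_id, orientation)]."""
    path = Path(path)
    tours: dict[str, list[tuple[str, str]]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].strip()
                tours[current] = []
            else:
                if current is None:
                    raise ParseError(
                        "contig line before any >header", path=str(path), line=lineno
                    )
                for token in line.split():
                    if token[-1] not in ("+", "-"):
                        raise ParseError(
                            f"token {token!r} lacks orientation sign",
                            path=str(path), line=lineno,
                        )
                    tours[current].append((token[:-1], token[-1]))
    return tours


# ---------------------------------------------------------------------------
# blocks table
# ---------------------------------------------------------------------------

BLOCKS_TABLE_COLUMNS = (
    "query_chrom", "block_label", "x_min", "x_max",
    "ref_chrom_majority", "orientation_sign", "n_genes", "contigs",
)


def write_blocks_table(blocks: Iterable) -> str:
    """Render labeled blocks as a TSV, sorted by (query_chrom, x_min).

    ``blocks`` is any iterable of objects exposing the Block attributes
    (query_chrom, label, x_min, x_max, best_ref_chrom, orientation_sign,
    points, contigs).
    """
    header = "\t".join(BLOCKS_TABLE_COLUMNS)
    rows = []
    for b in sorted(blocks, key=lambda b: (natural_key(b.query_chrom), b.x_min)):
        contigs = ",".join(f"{cid}{ori}" for cid, ori in b.contigs)
        rows.append(
            f"{b.query_chrom}\t{b.label}\t{b.x_min}\t{b.x_max}\t"
            f"{b.best_ref_chrom}\t{b.orientation_sign:+d}\t{len(b.points)}\t{contigs}"
        )
    return "".join(line + "\n" for line in [header, *rows])
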