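"""Contig-level edit operations on an assembly layout, with reclustering.

Corrections address blocks by their current labels — ``invert chr1:3``,
``insert chr2:5 after chr1:2``, ``swap chr1 chr2``, ``delete chr2:1`` — and
operate on whole contigs: a block never splits a contig, because the tours
format (and the downstream scaffolder) has no sub-contig resolution. Each
operation produces a new session state in which

1. the contig run addressed by the source block is spliced, reversed,
   exchanged, or moved to the unplaced set;
2. object intervals are recomputed with a uniform inter-contig gap;
3. every gene position is lifted from the old layout to the new one through
   contig-local coordinates (genes on deleted contigs drop out of the plot);
4. all chromosomes are reclustered and blocks relabeled 1..k, so prior
   labels are void;
5. the prior state is stored, giving exactly one step of undo.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field, replace

from .errors import (
    AddressError,
    GeneMappingError,
    ParseError,
    UndoError,
    ValidationError,
)
from .io import (
    DEFAULT_GAP_LENGTH,
    AnchorPair,
    AssemblyLayout,
    ContigPlacement,
    GeneFeature,
)
from .model import (
    Block,
    ClusterConfig,
    SyntenyPoint,
    build_synteny_points,
    cluster_chromosomes,
)

logger = logging.getLogger(__name__)

START = "START"
END = "END"
WHOLE = None  # block field of a whole-chromosome address


# ---------------------------------------------------------------------------
# Operations and their grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Address:
    """A chromosome, optionally narrowed to a block label or START/END."""

    chrom: str
    block: int | None = None       # None = whole chromosome
    position: str | None = None    # START or END (insert targets only)

    def __str__(self) -> str:
        if self.position is not None:
            return f"{self.chrom}:{self.position}"
        if self.block is not None:
            return f"{self.chrom}:{self.block}"
        return self.chrom


@dataclass(frozen=True)
class EditOperation:
    """One declarative correction action.

    ``kind`` is one of insert / invert / swap / delete / resolution.
    insert carries a placement (before / after / at); resolution carries
    the new resolution value instead of addresses.
    """

    kind: str
    source: Address | None = None
    target: Address | None = None
    placement: str | None = None
    resolution: int | None = None

    def __str__(self) -> str:
        if self.kind == "resolution":
            return f"resolution {self.resolution}"
        if self.kind == "insert":
            return f"insert {self.source} {self.placement} {self.target}"
        if self.kind == "swap":
            return f"swap {self.source} {self.target}"
        return f"{self.kind} {self.source}"


_ADDR_RE = re.compile(r"^(?P<chrom>[^\s:]+)(?::(?P<part>\S+))?$")


def _parse_address(token: str, line: int | None = None) -> Address:
    m = _ADDR_RE.match(token)
    if not m:
        raise ParseError(f"bad address {token!r}", line=line)
    chrom, part = m.group("chrom"), m.group("part")
    if part is None:
        return Address(chrom)
    if part.upper() in (START, END):
        return Address(chrom, position=part.upper())
    try:
        label = int(part)
    except ValueError:
        raise ParseError(
            f"block label in {token!r} must be an integer or START/END",
            line=line,
        ) from None
    if label < 1:
        raise ParseError(f"block label must be >= 1 in {token!r}", line=line)
    return Address(chrom, block=label)


def parse_operation(line: str, lineno: int | None = None) -> EditOperation:
    """Parse one operation-script line (case-insensitive keywords).

    Grammar::

        invert  <chrom>[:<block>]
        delete  <chrom>:<block>
        swap    <chrom>:<block> <chrom>:<block>
        swap    <chrom> <chrom>
        insert  <chrom>:<block> (before|after) <chrom>:<block>
        insert  <chrom>:<block> at <chrom>:(START|END)
        resolution <r>
    """
    tokens = line.split()
    if not tokens:
        raise ParseError("empty operation", line=lineno)
    kind = tokens[0].lower()
    if kind == "resolution":
        if len(tokens) != 2:
            raise ParseError("usage: resolution <r>", line=lineno)
        try:
            r = int(tokens[1])
        except ValueError:
            raise ParseError(
                f"resolution must be an integer, got {tokens[1]!r}", line=lineno
            ) from None
        return EditOperation("resolution", resolution=r)
    if kind == "invert":
        if len(tokens) != 2:
            raise ParseError("usage: invert <chrom>[:<block>]", line=lineno)
        src = _parse_address(tokens[1], lineno)
        if src.position is not None:
            raise ParseError("invert takes a chromosome or block", line=lineno)
        return EditOperation("invert", source=src)
    if kind == "delete":
        if len(tokens) != 2:
            raise ParseError("usage: delete <chrom>:<block>", line=lineno)
        src = _parse_address(tokens[1], lineno)
        if src.block is None:
            raise ParseError("delete takes a block address", line=lineno)
        return EditOperation("delete", source=src)
    if kind == "swap":
        if len(tokens) != 3:
            raise ParseError("usage: swap <addr> <addr>", line=lineno)
        a, b = _parse_address(tokens[1], lineno), _parse_address(tokens[2], lineno)
        if a.position is not None or b.position is not None:
            raise ParseError("swap addresses cannot be START/END", line=lineno)
        if (a.block is None) != (b.block is None):
            raise ValidationError(
                f"swap requires two addresses of the same granularity, "
                f"got {a} and {b}"
            )
        return EditOperation("swap", source=a, target=b)
    if kind == "insert":
        if len(tokens) != 4:
            raise ParseError(
                "usage: insert <chrom>:<block> (before|after|at) <target>",
                line=lineno,
            )
        src = _parse_address(tokens[1], lineno)
        if src.block is None:
            raise ParseError("insert source must be a block address", line=lineno)
        placement = tokens[2].lower()
        tgt = _parse_address(tokens[3], lineno)
        if placement in ("before", "after"):
            if tgt.block is None:
                raise ParseError(
                    f"insert {placement} needs a block target", line=lineno
                )
        elif placement == "at":
            if tgt.position not in (START, END):
                raise ParseError(
                    "insert at needs <chrom>:START or <chrom>:END", line=lineno
                )
        else:
            raise ParseError(
                f"placement must be before/after/at, got {placement!r}",
                line=lineno,
            )
        return EditOperation("insert", source=src, target=tgt, placement=placement)
    raise ParseError(f"unknown operation {tokens[0]!r}", line=lineno)


def parse_operation_script(text: str) -> list[EditOperation]:
    """Parse a whole operation script (one op per line, # comments)."""
    ops = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        ops.append(parse_operation(line, lineno))
    return ops


# ---------------------------------------------------------------------------
# Session state
# ---------------------------------------------------------------------------

@dataclass
class SessionState:
    """The in-memory curation session: layout, genes, points, blocks.

    Blocks are always consistent with the layout and points — they are
    recomputed after every mutation. ``previous`` holds at most one prior
    state (single-step undo).
    """

    layout: AssemblyLayout
    query_genes: list[GeneFeature]
    ref_genes: list[GeneFeature]
    anchors: list[AnchorPair]
    config: ClusterConfig
    gap_length: int = DEFAULT_GAP_LENGTH
    points: list[SyntenyPoint] = field(default_factory=list)
    blocks: dict[str, list[Block]] = field(default_factory=dict)
    n_dropped_anchors: int = 0
    previous: "SessionState | None" = None

    @classmethod
    def create(
        cls,
        query_genes: list[GeneFeature],
        ref_genes: list[GeneFeature],
        anchors: list[AnchorPair],
        layout: AssemblyLayout,
        config: ClusterConfig | None = None,
        gap_length: int = DEFAULT_GAP_LENGTH,
    ) -> "SessionState":
        """Build a session, dropping query genes that fall in gap intervals
        (they cannot be lifted through layout edits)."""
        config = config or ClusterConfig()
        kept, in_gaps = [], 0
        for g in query_genes:
            if g.seq_id not in layout.chromosomes:
                kept.append(g)  # genes off the layout never move
            elif layout.placement_at(g.seq_id, g.start) is not None:
                kept.append(g)
            else:
                in_gaps += 1
        if in_gaps:
            logger.warning(
                "%d query genes fall in AGP gap intervals and were excluded",
                in_gaps,
            )
        state = cls(
            layout=layout,
            query_genes=kept,
            ref_genes=ref_genes,
            anchors=anchors,
            config=config,
            gap_length=gap_length,
        )
        state._refresh()
        return state

    def _refresh(self) -> None:
        self.points, self.n_dropped_anchors = build_synteny_points(
            self.query_genes, self.ref_genes, self.anchors
        )
        self.blocks = cluster_chromosomes(self.points, self.layout, self.config)

    def find_block(self, chrom: str, label: int) -> Block:
        for b in self.blocks.get(chrom, []):
            if b.label == label:
                return b
        raise AddressError(f"no block {chrom}:{label}")

    def snapshot(self) -> "SessionState":
        """A value copy of this state with no further undo history."""
        return SessionState(
            layout=self.layout,
            query_genes=list(self.query_genes),
            ref_genes=self.ref_genes,
            anchors=self.anchors,
            config=self.config,
            gap_length=self.gap_length,
            points=list(self.points),
            blocks={c: list(bs) for c, bs in self.blocks.items()},
            n_dropped_anchors=self.n_dropped_anchors,
            previous=None,
        )

    def equivalent(self, other: "SessionState") -> bool:
        """Field-by-field equality ignoring undo history."""
        return (
            self.layout == other.layout
            and self.query_genes == other.query_genes
            and self.config == other.config
            and self.points == other.points
            and _blocks_signature(self.blocks) == _blocks_signature(other.blocks)
        )


def _blocks_signature(blocks: dict[str, list[Block]]):
    return {
        chrom: [
            (b.label, tuple(p.query_gene for p in b.points), tuple(b.contigs))
            for b in bs
        ]
        for chrom, bs in blocks.items()
    }


# ---------------------------------------------------------------------------
# Gene-position liftover
# ---------------------------------------------------------------------------

def recompute_gene_positions(
    old_layout: AssemblyLayout,
    new_layout: AssemblyLayout,
    genes: list[GeneFeature],
) -> list[GeneFeature]:
    """Lift gene positions from one layout of the same contigs to another.

    Each gene is expressed in contig-local coordinates through its old
    placement (local = x - start for '+', end - 1 - x for '-'), then
    re-projected through the contig's new placement. Genes whose contig is
    unplaced in the new layout are dropped. Relative gene order within a
    contig is preserved, reversed iff the contig's net orientation flipped.
    """
    new_pos: dict[str, tuple[str, ContigPlacement]] = {}
    for chrom, placements in new_layout.chromosomes.items():
        for p in placements:
            new_pos[p.contig_id] = (chrom, p)
    unplaced_new = {p.contig_id for p in new_layout.unplaced}

    out: list[GeneFeature] = []
    for g in genes:
        if g.seq_id not in old_layout.chromosomes:
            out.append(g)
            continue
        old = old_layout.placement_at(g.seq_id, g.start)
        if old is None:
            raise GeneMappingError(
                f"gene {g.gene_id} at {g.seq_id}:{g.start} lies in no contig "
                f"interval"
            )
        if old.contig_id in unplaced_new:
            continue  # deleted contig: gene leaves the plot
        if old.contig_id not in new_pos:
            raise GeneMappingError(
                f"contig {old.contig_id} (gene {g.gene_id}) missing from the "
                f"new layout"
            )
        new_chrom, new = new_pos[old.contig_id]
        # clamp the far end into the contig: BED features may overhang a cut
        lo, hi = g.start, min(g.end - 1, old.end - 1)
        flipped = old.orientation != new.orientation
        pts = []
        for x in (lo, hi):
            local = x - old.start if old.orientation == "+" else old.end - 1 - x
            y = (
                new.start + local
                if new.orientation == "+"
                else new.end - 1 - local
            )
            pts.append(y)
        start, end = min(pts), max(pts) + 1
        strand = g.strand
        if flipped and strand in ("+", "-"):
            strand = "-" if strand == "+" else "+"
        out.append(GeneFeature(g.gene_id, new_chrom, start, end, strand))
    return out


# ---------------------------------------------------------------------------
# Applying operations
# ---------------------------------------------------------------------------

def apply_operation(state: SessionState, op: EditOperation) -> SessionState:
    """Apply one operation and return a NEW state (the input is untouched).

    The edited layout gets fresh object intervals (uniform gap), gene
    positions are lifted old->new, points are rebuilt, every chromosome is
    reclustered and relabeled, and the prior state is stored for undo.
    """
    if op.kind == "resolution":
        if op.resolution is None or op.resolution < 1:
            raise ValidationError("resolution must be >= 1")
        return refresh_resolution(state, op.resolution)

    lists = {
        chrom: [p.key for p in placements]
        for chrom, placements in state.layout.chromosomes.items()
    }
    unplaced = [p.key for p in state.layout.unplaced]

    if op.kind == "invert":
        chrom, lo, hi = _resolve_span(state, op.source)
        lists[chrom][lo:hi] = _invert_run(lists[chrom][lo:hi])
    elif op.kind == "delete":
        chrom, lo, hi = _resolve_span(state, op.source)
        unplaced.extend(lists[chrom][lo:hi])
        del lists[chrom][lo:hi]
    elif op.kind == "swap":
        _apply_swap(state, op, lists)
    elif op.kind == "insert":
        _apply_insert(state, op, lists)
    else:
        raise ValidationError(f"unknown operation kind {op.kind!r}")

    new_layout = AssemblyLayout.from_lists(lists, state.gap_length, unplaced)
    new_genes = recompute_gene_positions(state.layout, new_layout, state.query_genes)
    new_state = SessionState(
        layout=new_layout,
        query_genes=new_genes,
        ref_genes=state.ref_genes,
        anchors=state.anchors,
        config=state.config,
        gap_length=state.gap_length,
        previous=state.snapshot(),
    )
    new_state._refresh()
    logger.info("applied %s", op)
    return new_state


def undo(state: SessionState) -> SessionState:
    """Revert to the stored prior state (exactly one step)."""
    if state.previous is None:
        raise UndoError("nothing to undo")
    return state.previous


def refresh_resolution(state: SessionState, resolution: int) -> SessionState:
    """Recluster at a new resolution; the layout and points are untouched."""
    if resolution < 1:
        raise ValidationError("resolution must be >= 1")
    new_state = SessionState(
        layout=state.layout,
        query_genes=list(state.query_genes),
        ref_genes=state.ref_genes,
        anchors=state.anchors,
        config=ClusterConfig(resolution=resolution),
        gap_length=state.gap_length,
        points=list(state.points),
        n_dropped_anchors=state.n_dropped_anchors,
        previous=state.snapshot(),
    )
    new_state.blocks = cluster_chromosomes(
        new_state.points, new_state.layout, new_state.config
    )
    return new_state


# -- address resolution ------------------------------------------------------

def _resolve_span(state: SessionState, addr: Address) -> tuple[str, int, int]:
    """Resolve an address to (chromosome, lo, hi) contig indices, half-open.

    A block address resolves to the contiguous span covering the block's
    contigs; a bare chromosome address covers the whole contig list.
    """
    if addr.chrom not in state.layout.chromosomes:
        raise AddressError(f"unknown chromosome {addr.chrom!r}")
    placements = state.layout.chromosomes[addr.chrom]
    if addr.block is None:
        return addr.chrom, 0, len(placements)
    block = state.find_block(addr.chrom, addr.block)
    if not block.contigs:
        raise AddressError(f"block {addr} has no contigs assigned")
    index = {p.contig_id: i for i, p in enumerate(placements)}
    try:
        idxs = [index[cid] for cid, _ in block.contigs]
    except KeyError as e:
        raise AddressError(f"block {addr} contig {e} not on {addr.chrom}") from None
    return addr.chrom, min(idxs), max(idxs) + 1


def _invert_run(run: list[tuple[str, int, str]]) -> list[tuple[str, int, str]]:
    return [
        (cid, ln, "-" if ori == "+" else "+") for cid, ln, ori in reversed(run)
    ]


def _apply_swap(state: SessionState, op: EditOperation, lists: dict) -> None:
    a, b = op.source, op.target
    if a.block is None:  # whole chromosomes
        for addr in (a, b):
            if addr.chrom not in lists:
                raise AddressError(f"unknown chromosome {addr.chrom!r}")
        if a.chrom == b.chrom:
            raise ValidationError("swap source and target must differ")
        lists[a.chrom], lists[b.chrom] = lists[b.chrom], lists[a.chrom]
        return
    ca, lo_a, hi_a = _resolve_span(state, a)
    cb, lo_b, hi_b = _resolve_span(state, b)
    if ca == cb:
        if (lo_a, hi_a) == (lo_b, hi_b):
            raise ValidationError("swap source and target must differ")
        # order the runs and check disjointness
        (lo1, hi1), (lo2, hi2) = sorted([(lo_a, hi_a), (lo_b, hi_b)])
        if hi1 > lo2:
            raise ValidationError(f"swap blocks {a} and {b} overlap")
        seq = lists[ca]
        run1, mid, run2 = seq[lo1:hi1], seq[hi1:lo2], seq[lo2:hi2]
        seq[lo1:hi2] = run2 + mid + run1
    else:
        run_a, run_b = lists[ca][lo_a:hi_a], lists[cb][lo_b:hi_b]
        lists[ca][lo_a:hi_a] = run_b
        lists[cb][lo_b:hi_b] = run_a


def _apply_insert(state: SessionState, op: EditOperation, lists: dict) -> None:
    src, tgt = op.source, op.target
    if src.chrom == tgt.chrom and src.block == tgt.block and tgt.block is not None:
        raise ValidationError("insert source and target must differ")
    chrom_s, lo, hi = _resolve_span(state, src)
    run = lists[chrom_s][lo:hi]
    run_ids = {cid for cid, _, _ in run}
    if tgt.chrom not in lists:
        raise AddressError(f"unknown chromosome {tgt.chrom!r}")

    if op.placement == "at":
        del lists[chrom_s][lo:hi]
        seq = lists[tgt.chrom]
        if tgt.position == START:
            seq[0:0] = run
        else:
            seq.extend(run)
        return

    # before/after a target block: locate the target run by contig identity
    # so indices survive the source removal (same-chromosome inserts).
    tchrom, tlo, thi = _resolve_span(state, tgt)
    target_ids = [
        cid for cid, _, _ in (
            (p.contig_id, p.length, p.orientation)
            for p in state.layout.chromosomes[tchrom][tlo:thi]
        )
    ]
    if run_ids & set(target_ids):
        raise ValidationError(
            f"insert source {src} overlaps target block {tgt}"
        )
    del lists[chrom_s][lo:hi]
    seq = lists[tchrom]
    positions = [i for i, (cid, _, _) in enumerate(seq) if cid in set(target_ids)]
    if not positions:
        raise AddressError(f"target block {tgt} vanished during insert")
    at = positions[0] if op.placement == "before" else positions[-1] + 1
    seq[at:at] = run
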