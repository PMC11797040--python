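"""Dot-plot coordinate construction and collinearity-block clustering.

The dot plot places each ortholog anchor at (x, y) where x is the query
gene's position on its query chromosome and y is the reference gene's
position on a concatenated reference axis (chromosomes in natural-sort
order, offset by cumulative chromosome extents). Approximately collinear
runs of anchors are grouped into labeled blocks by a two-pass procedure:

Pass 1 (threshold scan)
    Points on one query chromosome are sorted by x and scanned left to
    right; a new cluster starts whenever the Euclidean distance between the
    current point and the last point of the open cluster is at least
    ``chromosome_length / r``, where ``r`` is the resolution parameter
    (default 20). Larger ``r`` means a smaller merge threshold and hence
    more, finer blocks.

Pass 2 (inflection split)
    Within each cluster, any interior point whose y coordinate is a strict
    local extremum — both neighbors larger, or both smaller — marks an
    orientation inflection; the cluster is split immediately before and
    after it, isolating the extremum as a single-point block so that both
    flanks remain internally monotone.

Blocks are then labeled 1..k per query chromosome in order of their leftmost
point, and each contig of the assembly layout is assigned to the block
holding the most of its anchored genes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace

from .errors import ValidationError
from .io import AssemblyLayout, AnchorPair, GeneFeature, natural_key

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 20


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntenyPoint:
    """One query<->reference anchor projected to dot-plot coordinates."""

    query_gene: str
    ref_gene: str
    query_chrom: str
    ref_chrom: str
    xpos: int        # query gene position on its query chromosome (0-based)
    ypos_local: int  # reference gene position on its reference chromosome
    ypos: int        # global y = ypos_local + cumulative offset of ref_chrom
    score: float


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering granularity: pass-1 threshold is chromosome_length / resolution."""

    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.resolution < 1:
            raise ValidationError("resolution must be >= 1")

    def threshold(self, chrom_length: int) -> float:
        return chrom_length / self.resolution


@dataclass
class Block:
    """A labeled cluster of synteny points with its assigned contig run."""

    label: int
    query_chrom: str
    points: list[SyntenyPoint]             # sorted ascending by xpos
    contigs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def x_min(self) -> int:
        return self.points[0].xpos

    @property
    def x_max(self) -> int:
        return self.points[-1].xpos

    @property
    def orientation_sign(self) -> int:
        """Sign of the slope between the first and last point's y (0 if flat
        or single-point)."""
        dy = self.points[-1].ypos - self.points[0].ypos
        return (dy > 0) - (dy < 0)

    @property
    def best_ref_chrom(self) -> str:
        return suggest_block_assignment(self)[0]


# ---------------------------------------------------------------------------
# Coordinate construction
# ---------------------------------------------------------------------------

def reference_offsets(ref_genes: list[GeneFeature]) -> dict[str, int]:
    """Cumulative y-axis offset per reference chromosome.

    Chromosomes are concatenated in natural-sort order; each chromosome's
    extent is the maximum gene end it carries.
    """
    extents: dict[str, int] = {}
    for g in ref_genes:
        extents[g.seq_id] = max(extents.get(g.seq_id, 0), g.end)
    offsets: dict[str, int] = {}
    cum = 0
    for chrom in sorted(extents, key=natural_key):
        offsets[chrom] = cum
        cum += extents[chrom]
    return offsets


def build_synteny_points(
    query_genes: list[GeneFeature],
    ref_genes: list[GeneFeature],
    anchors: list[AnchorPair],
) -> tuple[list[SyntenyPoint], int]:
    """Project anchors to dot-plot points.

    Returns the points plus the count of anchors dropped because one of
    their genes was absent from its BED file. Raises
    :class:`ValidationError` when no anchor resolves at all.
    """
    qindex = {g.gene_id: g for g in query_genes}
    rindex = {g.gene_id: g for g in ref_genes}
    offsets = reference_offsets(ref_genes)
    points: list[SyntenyPoint] = []
    dropped = 0
    for a in anchors:
        qg = qindex.get(a.query_gene)
        rg = rindex.get(a.ref_gene)
        if qg is None or rg is None:
            dropped += 1
            continue
        points.append(SyntenyPoint(
            query_gene=qg.gene_id,
            ref_gene=rg.gene_id,
            query_chrom=qg.seq_id,
            ref_chrom=rg.seq_id,
            xpos=qg.start,
            ypos_local=rg.start,
            ypos=rg.start + offsets[rg.seq_id],
            score=a.score,
        ))
    if anchors and not points:
        raise ValidationError("no anchor pair resolves against the BED files")
    if dropped:
        logger.info("dropped %d unresolvable anchor pairs", dropped)
    return points, dropped


# ---------------------------------------------------------------------------
# Clustering (two-pass)
# ---------------------------------------------------------------------------

def cluster_points(
    points: list[SyntenyPoint],
    config: ClusterConfig,
    chrom_length: int,
) -> list[Block]:
    """Cluster the points of ONE query chromosome into labeled blocks.

    Pass 1 scans x-sorted points and opens a new cluster whenever the
    Euclidean (x, y) distance to the last point of the open cluster reaches
    ``chrom_length / resolution``. Pass 2 splits each cluster before and
    after every interior strict local extremum in y. Blocks are labeled
    1..k by ascending x_min.
    """
    if not points:
        return []
    if chrom_length <= 0:
        raise ValidationError("chrom_length must be positive")
    chroms = {p.query_chrom for p in points}
    if len(chroms) > 1:
        raise ValidationError(
            f"cluster_points expects one query chromosome, got {sorted(chroms)}"
        )
    threshold = config.threshold(chrom_length)

    ordered = sorted(points, key=lambda p: (p.xpos, p.ypos))

    # pass 1: threshold scan
    clusters: list[list[SyntenyPoint]] = [[ordered[0]]]
    for p in ordered[1:]:
        last = clusters[-1][-1]
        if math.hypot(p.xpos - last.xpos, p.ypos - last.ypos) < threshold:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    # pass 2: split at interior strict local extrema in y
    pieces: list[list[SyntenyPoint]] = []
    for cluster in clusters:
        pieces.extend(_split_at_extrema(cluster))

    chrom = ordered[0].query_chrom
    return [
        Block(label=i + 1, query_chrom=chrom, points=piece)
        for i, piece in enumerate(pieces)
    ]


def _split_at_extrema(cluster: list[SyntenyPoint]) -> list[list[SyntenyPoint]]:
    ys = [p.ypos for p in cluster]
    extremum = [
        0 < i < len(ys) - 1
        and ((ys[i - 1] > ys[i] and ys[i + 1] > ys[i])
             or (ys[i - 1] < ys[i] and ys[i + 1] < ys[i]))
        for i in range(len(ys))
    ]
    pieces: list[list[SyntenyPoint]] = []
    run: list[SyntenyPoint] = []
    for p, is_ext in zip(cluster, extremum):
        if is_ext:
            if run:
                pieces.append(run)
                run = []
            pieces.append([p])  # extremum isolated as its own block
        else:
            run.append(p)
    if run:
        pieces.append(run)
    return pieces


def cluster_chromosomes(
    points: list[SyntenyPoint],
    layout: AssemblyLayout,
    config: ClusterConfig,
    query_genes: list[GeneFeature] | None = None,
) -> dict[str, list[Block]]:
    """Cluster every query chromosome and assign contigs to blocks.

    Chromosomes follow layout order; chromosomes absent from the layout are
    clustered after them (natural-sort order) using their maximum point x
    as the length proxy, but receive no contig assignment.
    """
    by_chrom: dict[str, list[SyntenyPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.query_chrom, []).append(p)
    ordered = [c for c in layout.chromosomes if c in by_chrom]
    ordered += sorted(
        (c for c in by_chrom if c not in layout.chromosomes), key=natural_key
    )
    blocks: dict[str, list[Block]] = {}
    for chrom in ordered:
        length = layout.chrom_length(chrom)
        if length <= 0:
            length = max(p.xpos for p in by_chrom[chrom]) + 1
        chrom_blocks = cluster_points(by_chrom[chrom], config, length)
        if chrom in layout.chromosomes:
            chrom_blocks = assign_contigs_to_blocks(chrom_blocks, layout)
        blocks[chrom] = chrom_blocks
    return blocks


# ---------------------------------------------------------------------------
# Contig assignment
# ---------------------------------------------------------------------------

def assign_contigs_to_blocks(
    blocks: list[Block], layout: AssemblyLayout
) -> list[Block]:
    """Fill each block's contig run from the layout.

    Each anchored gene maps to the contig whose object interval contains its
    x position (genes landing in gaps are excluded with a warning). A contig
    goes to the single block holding the most of its anchored genes, ties
    resolved toward the block with smaller x_min. Contigs without anchored
    genes attach to the block of their nearest anchored neighbor on the
    chromosome (the preceding neighbor on ties). Within a block, contigs
    keep layout order.
    """
    if not blocks:
        return []
    chrom = blocks[0].query_chrom
    placements = layout.chromosomes.get(chrom, [])
    if not placements:
        return [replace_contigs(b, []) for b in blocks]

    votes: dict[str, Counter] = {p.contig_id: Counter() for p in placements}
    gap_hits = 0
    for b in blocks:
        for p in b.points:
            placement = layout.placement_at(chrom, p.xpos)
            if placement is None:
                gap_hits += 1
                continue
            votes[placement.contig_id][b.label] += 1
    if gap_hits:
        logger.warning(
            "%s: %d anchored genes fall in gap intervals and were excluded "
            "from contig assignment", chrom, gap_hits,
        )

    # blocks are labeled by ascending x_min, so the smaller label wins ties
    assigned: list[int | None] = []
    for p in placements:
        counter = votes[p.contig_id]
        if counter:
            best = max(counter.items(), key=lambda kv: (kv[1], -kv[0]))
            assigned.append(best[0])
        else:
            assigned.append(None)

    # anchorless contigs adopt the nearest assigned neighbor (preceding on ties)
    anchored_idx = [i for i, a in enumerate(assigned) if a is not None]
    for i, a in enumerate(assigned):
        if a is not None or not anchored_idx:
            continue
        nearest = min(anchored_idx, key=lambda j: (abs(j - i), 0 if j < i else 1))
        assigned[i] = assigned[nearest]

    by_label: dict[int, list[tuple[str, str]]] = {}
    for p, label in zip(placements, assigned):
        if label is not None:
            by_label.setdefault(label, []).append((p.contig_id, p.orientation))
    return [replace_contigs(b, by_label.get(b.label, [])) for b in blocks]


def replace_contigs(block: Block, contigs: list[tuple[str, str]]) -> Block:
    return Block(block.label, block.query_chrom, block.points, list(contigs))


# ---------------------------------------------------------------------------
# Linkage-group suggestion
# ---------------------------------------------------------------------------

def suggest_block_assignment(block: Block) -> tuple[str, dict[str, float]]:
    """Suggest the linkage group a block belongs to.

    Per reference chromosome, the synteny score is the sum of the block's
    anchor scores on that chromosome; the chromosome with the highest total
    wins (ties broken by gene count, then name order). Returns the winner
    and the full score table.
    """
    if not block.points:
        raise ValidationError("cannot score an empty block")
    scores: dict[str, float] = {}
    counts: Counter = Counter()
    for p in block.points:
        scores[p.ref_chrom] = scores.get(p.ref_chrom, 0.0) + p.score
        counts[p.ref_chrom] += 1
    best = min(
        scores,
        key=lambda c: (-scores[c], -counts[c], natural_key(c)),
    )
    return best, scores
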