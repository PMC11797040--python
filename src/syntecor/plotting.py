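"""Dot-plot rendering: scatter, per-block segments and labels, to PDF.

For each block a line is drawn from its leftmost point to its rightmost
point and annotated with the block label at the segment midpoint. The same
geometry is emitted as a deterministic TSV sidecar so tests (and users) can
assert on coordinates without touching PDF bytes.

The x axis concatenates query chromosomes in layout order; the y axis
concatenates reference chromosomes in natural-sort order (the same global y
used by the clustering itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import AssemblyLayout, GeneFeature
from .model import Block, SyntenyPoint, reference_offsets


@dataclass(frozen=True)
class BlockSegment:
    query_chrom: str
    label: int
    x0: float
    y0: float
    x1: float
    y1: float
    orientation_sign: int

    @property
    def label_x(self) -> float:
        return (self.x0 + self.x1) / 2

    @property
    def label_y(self) -> float:
        return (self.y0 + self.y1) / 2


@dataclass
class PlotGeometry:
    """Everything the dot plot draws, in global plot coordinates."""

    points: list[tuple[str, float, float]]        # (query_chrom, x, y)
    segments: list[BlockSegment]
    x_boundaries: list[tuple[str, float, float]]  # (chrom, start, end)
    y_boundaries: list[tuple[str, float, float]]


def query_offsets(layout: AssemblyLayout) -> dict[str, int]:
    """Cumulative x offset per query chromosome, in layout order."""
    offsets: dict[str, int] = {}
    cum = 0
    for chrom in layout.chromosomes:
        offsets[chrom] = cum
        cum += layout.chrom_length(chrom)
    return offsets


def build_geometry(
    blocks: dict[str, list[Block]],
    layout: AssemblyLayout,
    ref_genes: list[GeneFeature],
) -> PlotGeometry:
    """Project blocks into global plot coordinates.

    Each block contributes one segment from the point with the smallest x
    to the point with the largest x (zero-length for single-point blocks)
    and one label anchored at the segment midpoint.
    """
    qoff = query_offsets(layout)
    roff = reference_offsets(ref_genes)

    points: list[tuple[str, float, float]] = []
    segments: list[BlockSegment] = []
    for chrom, chrom_blocks in blocks.items():
        dx = qoff.get(chrom, 0)
        for b in chrom_blocks:
            for p in b.points:
                points.append((chrom, p.xpos + dx, p.ypos))
            first, last = b.points[0], b.points[-1]
            segments.append(BlockSegment(
                chrom, b.label,
                first.xpos + dx, first.ypos,
                last.xpos + dx, last.ypos,
                b.orientation_sign,
            ))

    x_bounds = [
        (chrom, float(off), float(off + layout.chrom_length(chrom)))
        for chrom, off in qoff.items()
    ]
    extents: dict[str, int] = {}
    for g in ref_genes:
        extents[g.seq_id] = max(extents.get(g.seq_id, 0), g.end)
    y_bounds = [
        (chrom, float(off), float(off + extents[chrom]))
        for chrom, off in roff.items()
    ]
    return PlotGeometry(points, segments, x_bounds, y_bounds)


def geometry_to_tsv(geom: PlotGeometry) -> str:
    """Serialize the geometry sidecar (deterministic for equal input)."""
    lines = ["kind\tname\tlabel\tx0\ty0\tx1\ty1\tsign"]
    for seg in geom.segments:
        lines.append(
            f"segment\t{seg.query_chrom}\t{seg.label}\t{seg.x0:g}\t{seg.y0:g}"
            f"\t{seg.x1:g}\t{seg.y1:g}\t{seg.orientation_sign:+d}"
        )
    for chrom, lo, hi in geom.x_boundaries:
        lines.append(f"xchrom\t{chrom}\t.\t{lo:g}\t.\t{hi:g}\t.\t.")
    for chrom, lo, hi in geom.y_boundaries:
        lines.append(f"ychrom\t{chrom}\t.\t.\t{lo:g}\t.\t{hi:g}\t.")
    return "".join(line + "\n" for line in lines)


_CYCLE = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def render_pdf(
    geom: PlotGeometry,
    out_path: str | Path,
    color_by: str = "block",
    title: str | None = None,
) -> Path:
    """Draw the dot plot (scatter + segments + labels + chromosome grid).

    ``color_by`` is 'block' (cycle per block label) or 'ref' (cycle per
    reference chromosome band). Returns the written path.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(8, 8))

    ybands = sorted(geom.y_boundaries, key=lambda b: b[1])

    def ref_band(y: float) -> int:
        for i, (_, lo, hi) in enumerate(ybands):
            if lo <= y < hi:
                return i
        return len(ybands) - 1

    if geom.points:
        xs = [x for _, x, _ in geom.points]
        ys = [y for _, _, y in geom.points]
        colors = [_CYCLE[ref_band(y) % len(_CYCLE)] for y in ys] \
            if color_by == "ref" else "0.55"
        ax.scatter(xs, ys, s=4, c=colors, linewidths=0, zorder=2)

    for seg in geom.segments:
        color = _CYCLE[(seg.label - 1) % len(_CYCLE)] if color_by == "block" \
            else _CYCLE[ref_band(seg.y0) % len(_CYCLE)]
        ax.plot(
            [seg.x0, seg.x1], [seg.y0, seg.y1],
            color=color, linewidth=1.8, zorder=3,
        )
        ax.annotate(
            str(seg.label), (seg.label_x, seg.label_y),
            fontsize=7, ha="center", va="bottom", zorder=4,
        )

    for _, lo, hi in geom.x_boundaries:
        ax.axvline(hi, color="0.85", linewidth=0.6, zorder=1)
    for _, lo, hi in geom.y_boundaries:
        ax.axhline(hi, color="0.85", linewidth=0.6, zorder=1)

    ax.set_xticks([(lo + hi) / 2 for _, lo, hi in geom.x_boundaries])
    ax.set_xticklabels([n for n, _, _ in geom.x_boundaries], fontsize=8)
    ax.set_yticks([(lo + hi) / 2 for _, lo, hi in geom.y_boundaries])
    ax.set_yticklabels([n for n, _, _ in geom.y_boundaries], fontsize=8)
    ax.set_xlabel("query assembly")
    ax.set_ylabel("reference genome")
    if title:
        ax.set_title(title)
    if geom.x_boundaries:
        ax.set_xlim(0, max(hi for _, _, hi in geom.x_boundaries))
    if geom.y_boundaries:
        ax.set_ylim(0, max(hi for _, _, hi in geom.y_boundaries))

    fig.tight_layout()
    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    return out_path
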