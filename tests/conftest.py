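import numpy as np
import pytest

from syntecor import (
    AnchorPair,
    AssemblyLayout,
    ClusterConfig,
    GeneFeature,
    SessionState,
    SyntenyPoint,
)


def mk_points(xy, chrom="chr1", ref_chrom="ref1", score=1.0):
    """Build SyntenyPoints from bare (x, y) pairs (global y == local y)."""
    return [
        SyntenyPoint(f"q{i}", f"r{i}", chrom, ref_chrom,
                     int(x), int(y), int(y), score)
        for i, (x, y) in enumerate(xy)
    ]


def random_layout(rng: np.random.Generator) -> AssemblyLayout:
    """A random multi-chromosome layout with mixed orientations."""
    n_chrom = int(rng.integers(1, 4))
    chroms = {}
    c = 0
    for i in range(n_chrom):
        n_ctg = int(rng.integers(1, 7))
        triples = []
        for _ in range(n_ctg):
            c += 1
            triples.append((
                f"tig{c:04d}",
                int(rng.integers(1, 500_000)),
                "+" if rng.random() < 0.5 else "-",
            ))
        chroms[f"chr{i + 1}"] = triples
    unplaced = []
    for _ in range(int(rng.integers(0, 3))):
        c += 1
        unplaced.append((f"tig{c:04d}", int(rng.integers(1, 100_000)), "+"))
    return AssemblyLayout.from_lists(chroms, gap_length=100, unplaced=unplaced)


@pytest.fixture
def toy_session() -> SessionState:
    """A hand-built two-chromosome session with known blocks.

    chr1 carries contig X (one gene anchored to refChr1); chr2 carries
    contigs Y and Z whose genes hit refChr2 regions far enough apart that
    Y and Z land in separate blocks at the default resolution.
    """
    layout = AssemblyLayout.from_lists(
        {"chr1": [("X", 1000, "+")], "chr2": [("Y", 1000, "+"), ("Z", 1000, "+")]},
        gap_length=100,
    )
    query = [
        GeneFeature("gx1", "chr1", 100, 200, "+"),
        GeneFeature("gy1", "chr2", 100, 200, "+"),
        GeneFeature("gz1", "chr2", 1200, 1300, "+"),
    ]
    ref = [
        GeneFeature("rx1", "refChr1", 100, 200, "+"),
        GeneFeature("ry1", "refChr2", 100, 200, "+"),
        GeneFeature("rz1", "refChr2", 50_000, 50_100, "+"),
    ]
    anchors = [
        AnchorPair("gx1", "rx1", 500),
        AnchorPair("gy1", "ry1", 500),
        AnchorPair("gz1", "rz1", 500),
    ]
    return SessionState.create(query, ref, anchors, layout, ClusterConfig(20))
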