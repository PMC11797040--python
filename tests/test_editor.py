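"""Edit operations: grammar, splice semantics, liftover, undo, invariants."""

import numpy as np
import pytest

from syntecor import (
    AssemblyLayout,
    ClusterConfig,
    GeneFeature,
    GeneMappingError,
    ParseError,
    PlantedError,
    SimParams,
    UndoError,
    ValidationError,
    apply_operation,
    generate_dataset,
    parse_operation,
    parse_operation_script,
    recompute_gene_positions,
    refresh_resolution,
    undo,
)


def keys(state, chrom):
    return [p.key for p in state.layout.chromosomes[chrom]]


def _find_label(state, contig_id):
    for chrom, blocks in state.blocks.items():
        for b in blocks:
            if any(c == contig_id for c, _ in b.contigs):
                return chrom, b.label
    raise AssertionError(f"{contig_id} not in any block")


@pytest.fixture
def session():
    """A 2-chromosome, 4-contig-per-chromosome synthetic session."""
    params = SimParams(n_chromosomes=2, genes_per_chromosome=16,
                       contigs_per_chromosome=4, mean_gene_spacing=5000,
                       seed=5)
    return generate_dataset(params).session()


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("line,expected", [
    ("invert chr1:3", "invert chr1:3"),
    ("INVERT CHR1", "invert CHR1"),
    ("insert chr2:5 after chr1:2", "insert chr2:5 after chr1:2"),
    ("insert chr2:5 AT chr1:start", "insert chr2:5 at chr1:START"),
    ("swap chr1:2 chr3:4", "swap chr1:2 chr3:4"),
    ("swap chr1 chr2", "swap chr1 chr2"),
    ("delete chr2:1", "delete chr2:1"),
    ("resolution 40", "resolution 40"),
])
def test_grammar_round_trips(line, expected):
    assert str(parse_operation(line)) == expected


@pytest.mark.parametrize("line", [
    "", "frobnicate chr1:1", "invert", "invert chr1:0", "invert chr1:END",
    "insert chr1:1 sideways chr2:2", "insert chr1:1 at chr2:3",
    "delete chr1", "resolution x", "swap chr1:1",
])
def test_bad_grammar_is_a_parse_error(line):
    with pytest.raises(ParseError):
        parse_operation(line)


def test_mixed_granularity_swap_rejected():
    with pytest.raises(ValidationError):
        parse_operation("swap chr1:2 chr3")


def test_script_parsing_skips_comments_and_blanks():
    ops = parse_operation_script("# fix inversions\n\ninvert chr1:1\n")
    assert len(ops) == 1 and ops[0].kind == "invert"


# ---------------------------------------------------------------------------
# operation semantics on the contig list
# ---------------------------------------------------------------------------

def test_invert_block_reverses_and_flips(session):
    chrom, label = _find_label(session, "ctg1_2")
    block = session.find_block(chrom, label)
    before = keys(session, chrom)
    span = [c for c, _ in block.contigs]
    lo = [k[0] for k in before].index(span[0])
    out = apply_operation(session, parse_operation(f"invert {chrom}:{label}"))
    after = keys(out, chrom)
    expected = [(cid, ln, "-" if o == "+" else "+")
                for cid, ln, o in reversed(before[lo:lo + len(span)])]
    assert after[lo:lo + len(span)] == expected
    assert after[:lo] == before[:lo]
    assert after[lo + len(span):] == before[lo + len(span):]


def test_invert_whole_chromosome_is_involution(session):
    once = apply_operation(session, parse_operation("invert chr1"))
    assert keys(once, "chr1") == [
        (cid, ln, "-" if o == "+" else "+")
        for cid, ln, o in reversed(keys(session, "chr1"))
    ]
    twice = apply_operation(once, parse_operation("invert chr1"))
    assert twice.layout == session.layout


def test_insert_block_at_chromosome_end(session):
    chrom, label = _find_label(session, "ctg2_4")
    block = session.find_block(chrom, label)
    moved = [c for c, _ in block.contigs]
    out = apply_operation(
        session, parse_operation(f"insert {chrom}:{label} at chr1:END")
    )
    assert [k[0] for k in keys(out, "chr1")] == \
        [k[0] for k in keys(session, "chr1")] + moved
    assert all(k[0] not in moved for k in keys(out, "chr2"))


def test_insert_before_and_after_target_block(session):
    src_chrom, src_label = _find_label(session, "ctg1_1")
    tgt_chrom, tgt_label = _find_label(session, "ctg2_3")
    src = [c for c, _ in session.find_block(src_chrom, src_label).contigs]
    tgt_first = session.find_block(tgt_chrom, tgt_label).contigs[0][0]
    out = apply_operation(session, parse_operation(
        f"insert {src_chrom}:{src_label} before {tgt_chrom}:{tgt_label}"))
    ids = [k[0] for k in keys(out, tgt_chrom)]
    at = ids.index(src[0])
    assert ids[at:at + len(src)] == src
    assert ids[at + len(src)] == tgt_first


def test_delete_moves_contigs_to_unplaced(session):
    chrom, label = _find_label(session, "ctg2_1")
    block = session.find_block(chrom, label)
    doomed = {c for c, _ in block.contigs}
    out = apply_operation(session, parse_operation(f"delete {chrom}:{label}"))
    assert {p.contig_id for p in out.layout.unplaced} >= doomed
    assert all(k[0] not in doomed for k in keys(out, chrom))
    # the deleted contigs' genes leave the point set
    gone = {p.query_gene for p in session.points} - \
        {p.query_gene for p in out.points}
    assert gone


def test_swap_chromosomes_exchanges_contig_lists(session):
    out = apply_operation(session, parse_operation("swap chr1 chr2"))
    assert keys(out, "chr1") == keys(session, "chr2")
    assert keys(out, "chr2") == keys(session, "chr1")
    again = apply_operation(out, parse_operation("swap chr1 chr2"))
    assert again.layout == session.layout


def test_swap_blocks_across_chromosomes_is_involution(session):
    c1, l1 = _find_label(session, "ctg1_2")
    c2, l2 = _find_label(session, "ctg2_2")
    once = apply_operation(session, parse_operation(f"swap {c1}:{l1} {c2}:{l2}"))
    # relocate both runs in the relabeled state and swap back
    b1 = _find_label(once, "ctg1_2")
    b2 = _find_label(once, "ctg2_2")
    back = apply_operation(
        once, parse_operation(f"swap {b1[0]}:{b1[1]} {b2[0]}:{b2[1]}"))
    assert back.layout == session.layout


def test_unknown_addresses_raise(session):
    from syntecor import AddressError
    with pytest.raises(AddressError):
        apply_operation(session, parse_operation("invert chrX:1"))
    with pytest.raises(AddressError):
        apply_operation(session, parse_operation("invert chr1:99"))


# ---------------------------------------------------------------------------
# gene-position liftover
# ---------------------------------------------------------------------------

def _two_layouts(ori_new):
    old = AssemblyLayout.from_lists({"chr1": [("c", 1000, "+")]})
    new = AssemblyLayout.from_lists(
        {"chr1": [("pad", 5000 - 100, "+"), ("c", 1000, ori_new)]},
        gap_length=100,
    )
    return old, new


def test_liftover_translation():
    old, new = _two_layouts("+")  # c moves to [5000, 6000) forward
    genes = [GeneFeature("g", "chr1", 10, 20, "+")]
    (moved,) = recompute_gene_positions(old, new, genes)
    assert (moved.start, moved.end) == (5010, 5020)


def test_liftover_flip_formula_and_double_flip():
    old, new = _two_layouts("-")  # c moves to [5000, 6000) reversed
    genes = [GeneFeature("g", "chr1", 10, 20, "+")]
    (moved,) = recompute_gene_positions(old, new, genes)
    # start maps to 5000 + (1000 - 1 - 19) = 5980, span preserved
    assert moved.start == 5000 + (1000 - 1 - 19)
    assert moved.end - moved.start == 10
    assert moved.strand == "-"
    (back,) = recompute_gene_positions(new, old, [moved])
    assert (back.start, back.end, back.strand) == (10, 20, "+")


def test_liftover_identity_on_unchanged_layout():
    old = AssemblyLayout.from_lists(
        {"chr1": [("a", 300, "+"), ("b", 200, "-")]})
    genes = [GeneFeature("g1", "chr1", 10, 30, "+"),
             GeneFeature("g2", "chr1", 410, 450, "-")]
    assert recompute_gene_positions(old, old, genes) == genes


def test_liftover_rejects_gene_in_gap():
    old = AssemblyLayout.from_lists(
        {"chr1": [("a", 100, "+"), ("b", 100, "+")]}, gap_length=50)
    with pytest.raises(GeneMappingError) as e:
        recompute_gene_positions(old, old, [GeneFeature("g", "chr1", 120, 130)])
    assert "g" in str(e.value)


# ---------------------------------------------------------------------------
# undo / resolution
# ---------------------------------------------------------------------------

def test_undo_restores_previous_state(session):
    out = apply_operation(session, parse_operation("invert chr1"))
    back = undo(out)
    assert back.equivalent(session)
    assert back.previous is None
    with pytest.raises(UndoError):
        undo(back)


def test_undo_depth_is_exactly_one(session):
    s1 = apply_operation(session, parse_operation("invert chr1"))
    s2 = apply_operation(s1, parse_operation("invert chr2"))
    back = undo(s2)
    assert back.equivalent(s1)
    with pytest.raises(UndoError):
        undo(undo(s2))


def test_refresh_same_resolution_is_identity(session):
    out = refresh_resolution(session, session.config.resolution)
    assert out.equivalent(session)


def test_refresh_r1_merges_each_chromosome(session):
    out = refresh_resolution(session, 1)
    assert all(len(bs) == 1 for bs in out.blocks.values())


def test_refresh_rejects_bad_resolution(session):
    with pytest.raises(ValidationError):
        refresh_resolution(session, 0)


# ---------------------------------------------------------------------------
# randomized invariants
# ---------------------------------------------------------------------------

OPS_POOL = ("invert", "delete", "swap", "insert_end")


def _random_op(rng, state):
    blocks = [(c, b.label) for c, bs in state.blocks.items() for b in bs
              if b.contigs]
    kind = OPS_POOL[int(rng.integers(0, len(OPS_POOL)))]
    c, l = blocks[int(rng.integers(0, len(blocks)))]
    if kind == "invert":
        return f"invert {c}:{l}"
    if kind == "delete":
        return f"delete {c}:{l}"
    if kind == "insert_end":
        other = [ch for ch in state.layout.chromosomes if ch != c]
        tgt = other[int(rng.integers(0, len(other)))] if other else c
        return f"insert {c}:{l} at {tgt}:END"
    others = [x for x in blocks if x != (c, l)]
    c2, l2 = others[int(rng.integers(0, len(others)))]
    return f"swap {c}:{l} {c2}:{l2}"


@pytest.mark.parametrize("seed", range(6))
def test_contig_conservation_and_undo_on_random_ops(seed):
    """multiset(placed) + unplaced is invariant; undo inverts any op."""
    rng = np.random.default_rng(seed)
    params = SimParams(
        n_chromosomes=2, genes_per_chromosome=12, contigs_per_chromosome=4,
        mean_gene_spacing=4000, seed=seed,
        errors=(PlantedError("inversion", 2),),
    )
    state = generate_dataset(params).session()
    baseline = state.layout.contig_multiset()
    for _ in range(5):
        op = parse_operation(_random_op(rng, state))
        try:
            new_state = apply_operation(state, op)
        except ValidationError:
            continue  # e.g. same-chromosome swap of overlapping spans
        assert new_state.layout.contig_multiset() == baseline
        assert undo(new_state).equivalent(state)
        state = new_state


@pytest.mark.parametrize("seed", range(4))
def test_points_lie_inside_their_contigs_after_edits(seed):
    """Post-edit, every synteny point sits in its contig's new interval."""
    rng = np.random.default_rng(100 + seed)
    state = generate_dataset(SimParams(
        n_chromosomes=2, genes_per_chromosome=12, contigs_per_chromosome=4,
        mean_gene_spacing=4000, seed=seed)).session()
    for _ in range(3):
        op = parse_operation(_random_op(rng, state))
        try:
            state = apply_operation(state, op)
        except ValidationError:
            continue
        for p in state.points:
            assert state.layout.placement_at(p.query_chrom, p.xpos) is not None
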