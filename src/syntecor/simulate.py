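"""Ground-truth fixture generation: a reference genome, a query assembly
with planted misassemblies, their anchors, and the operation log that
repairs them.

The simulator lays out reference chromosomes with jittered gene spacing,
builds a query assembly whose "true" form is perfectly collinear with the
reference (anchors 1:1, scores uniform on [100, 1000]), cuts each query
chromosome into contigs between genes, and then perturbs the contig layout:

inversion
    a run of contigs is reversed and orientation-flipped in place;
translocation
    a run is moved from the end of one chromosome to the end of another
    (an end run, so one ``insert ... at <src>:END`` restores it exactly);
order_shuffle
    two equal-length disjoint runs on one chromosome exchange positions;
deletion
    junk contigs carrying duplicated anchors (hits to another chromosome's
    reference genes, at reduced score) are appended — an error whose fix is
    deleting the spurious block, emulating the duplicated-syntenic-block
    grouping errors that arise in polyploid phasing.

The truth log is computed by replay: the erroneous dataset is clustered,
each planted error's contig run is located in the current block labeling,
the repairing operation is emitted and applied, and the next error is
addressed against the relabeled state — so the log uses labels valid at
the moment each operation would be issued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .editor import (
    SessionState,
    apply_operation,
    parse_operation,
    recompute_gene_positions,
)
from .errors import ValidationError
from .io import (
    DEFAULT_GAP_LENGTH,
    AnchorPair,
    AssemblyLayout,
    GeneFeature,
    write_agp,
    write_anchors,
    write_bed,
)
from .model import ClusterConfig, DEFAULT_RESOLUTION

ERROR_TYPES = ("inversion", "translocation", "order_shuffle", "deletion")


@dataclass(frozen=True)
class PlantedError:
    """One misassembly to plant: an error type and its span in contigs."""

    type: str
    span: int = 2

    def __post_init__(self):
        if self.type not in ERROR_TYPES:
            raise ValidationError(
                f"error type must be one of {ERROR_TYPES}, got {self.type!r}"
            )
        if self.span < 1:
            raise ValidationError("error span must be >= 1")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic dataset.

    Defaults model a small but realistic curation scenario: three
    chromosomes of 40 genes spaced ~20 kb apart (10% jitter), eight contigs
    per chromosome — comfortably inside the default clustering threshold of
    chromosome_length / 20 for an error-free genome.
    """

    n_chromosomes: int = 3
    genes_per_chromosome: int = 40
    mean_gene_spacing: int = 20_000
    contigs_per_chromosome: int = 8
    errors: tuple[PlantedError, ...] = ()
    seed: int = 0
    resolution: int = DEFAULT_RESOLUTION
    gap_length: int = DEFAULT_GAP_LENGTH
    spacing_jitter: float = 0.1
    wgd: bool = False

    def __post_init__(self):
        for name in ("n_chromosomes", "genes_per_chromosome",
                     "mean_gene_spacing", "contigs_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.genes_per_chromosome < self.contigs_per_chromosome:
            raise ValidationError(
                "need at least one gene per contig: genes_per_chromosome "
                ">= contigs_per_chromosome"
            )
        for e in self.errors:
            if e.span > self.contigs_per_chromosome:
                raise ValidationError(
                    f"{e.type} span {e.span} exceeds contigs_per_chromosome"
                )
            if e.type == "order_shuffle" and 2 * e.span > self.contigs_per_chromosome:
                raise ValidationError(
                    "order_shuffle needs two disjoint runs: 2*span must not "
                    "exceed contigs_per_chromosome"
                )
            if e.type == "translocation" and self.n_chromosomes < 2:
                raise ValidationError("translocation needs >= 2 chromosomes")


@dataclass
class SyntheticDataset:
    """Everything :func:`generate_dataset` produces."""

    params: SimParams
    ref_genes: list[GeneFeature]
    query_genes: list[GeneFeature]       # erroneous assembly coordinates
    anchors: list[AnchorPair]
    layout: AssemblyLayout               # erroneous layout (the input AGP)
    true_layout: AssemblyLayout          # layout before errors were planted
    truth_ops: list[str]                 # operation-script lines that repair

    def session(self) -> SessionState:
        return SessionState.create(
            self.query_genes, self.ref_genes, self.anchors, self.layout,
            ClusterConfig(self.params.resolution), self.params.gap_length,
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write ref.bed, query.bed, anchors.txt, query.agp, truth_ops.txt."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref_bed": outdir / "ref.bed",
            "query_bed": outdir / "query.bed",
            "anchors": outdir / "anchors.txt",
            "agp": outdir / "query.agp",
            "truth_ops": outdir / "truth_ops.txt",
        }
        paths["ref_bed"].write_text(write_bed(self.ref_genes))
        paths["query_bed"].write_text(write_bed(self.query_genes))
        paths["anchors"].write_text(write_anchors(self.anchors))
        paths["agp"].write_text(write_agp(self.layout, self.params.gap_length))
        paths["truth_ops"].write_text(
            "".join(op + "\n" for op in self.truth_ops)
        )
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _gene_track(
    rng: np.random.Generator, n: int, spacing: int, jitter: float
) -> tuple[list[tuple[int, int]], int]:
    """Jittered gene intervals along one sequence; returns intervals and
    the position reached."""
    glen = max(1, int(0.3 * spacing))
    pos = 0
    intervals = []
    for _ in range(n):
        gap = int(spacing * (1 + jitter * rng.uniform(-1, 1)))
        start = pos + max(1, gap)
        intervals.append((start, start + glen))
        pos = start + glen
    return intervals, pos


def _chunk_sizes(n_genes: int, n_contigs: int) -> list[int]:
    base, extra = divmod(n_genes, n_contigs)
    return [base + (1 if k < extra else 0) for k in range(n_contigs)]


def generate_dataset(params: SimParams) -> SyntheticDataset:
    """Generate the four input artifacts plus the repairing operation log.

    Fully reproducible from ``params.seed``: identical parameters yield
    byte-identical files.
    """
    rng = np.random.default_rng(params.seed)
    P = params

    # --- reference genome ---------------------------------------------------
    ref_genes: list[GeneFeature] = []
    ref_ids: dict[int, list[str]] = {}
    for c in range(1, P.n_chromosomes + 1):
        intervals, _ = _gene_track(
            rng, P.genes_per_chromosome, P.mean_gene_spacing, P.spacing_jitter
        )
        ids = []
        for j, (s, e) in enumerate(intervals, 1):
            gid = f"R{c:02d}G{j:03d}"
            ids.append(gid)
            ref_genes.append(GeneFeature(gid, f"refChr{c}", s, e, "+"))
        ref_ids[c] = ids

    # --- true (error-free) query assembly ----------------------------------
    true_lists: dict[str, list[tuple[str, int, str]]] = {}
    # gene -> (contig, local offset within contig) for later projection
    gene_contig: list[tuple[str, str, int, int]] = []  # (gid, ctg, local, glen)
    query_ids: dict[int, list[str]] = {}
    for c in range(1, P.n_chromosomes + 1):
        intervals, track_end = _gene_track(
            rng, P.genes_per_chromosome, P.mean_gene_spacing, P.spacing_jitter
        )
        sizes = _chunk_sizes(P.genes_per_chromosome, P.contigs_per_chromosome)
        margin = P.mean_gene_spacing // 2
        boundaries = [0]
        idx = 0
        for size in sizes[:-1]:
            idx += size
            prev_end = intervals[idx - 1][1]
            next_start = intervals[idx][0]
            boundaries.append((prev_end + next_start) // 2)
        boundaries.append(track_end + margin)

        triples = []
        ids = []
        idx = 0
        for k, size in enumerate(sizes):
            ctg = f"ctg{c}_{k + 1}"
            lo, hi = boundaries[k], boundaries[k + 1]
            triples.append((ctg, hi - lo, "+"))
            for j in range(idx, idx + size):
                s, e = intervals[j]
                gid = f"Q{c:02d}G{j + 1:03d}"
                ids.append(gid)
                gene_contig.append((gid, ctg, s - lo, e - s))
            idx += size
        true_lists[f"chr{c}"] = triples
        query_ids[c] = ids

    true_layout = AssemblyLayout.from_lists(true_lists, P.gap_length)
    true_query: list[GeneFeature] = []
    placement_by_ctg = {
        p.contig_id: (chrom, p)
        for chrom, ps in true_layout.chromosomes.items()
        for p in ps
    }
    for gid, ctg, local, glen in gene_contig:
        chrom, p = placement_by_ctg[ctg]
        true_query.append(GeneFeature(gid, chrom, p.start + local,
                                      p.start + local + glen, "+"))

    # --- anchors ------------------------------------------------------------
    anchors: list[AnchorPair] = []
    for c in range(1, P.n_chromosomes + 1):
        for qg, rg in zip(query_ids[c], ref_ids[c]):
            anchors.append(AnchorPair(qg, rg, float(rng.integers(100, 1001))))
    if P.wgd and P.n_chromosomes >= 2:
        # duplicated hits to the partner chromosome at half score, modelling
        # whole-genome duplication: the true hit keeps the best synteny score
        true_score = {a.query_gene: a.score for a in anchors}
        extra = []
        for c in range(1, P.n_chromosomes + 1):
            partner = c % P.n_chromosomes + 1
            for qg, rg in zip(query_ids[c], ref_ids[partner]):
                extra.append(AnchorPair(qg, rg, true_score[qg] / 2))
        anchors.extend(extra)

    # --- plant errors -------------------------------------------------------
    lists = {c: list(t) for c, t in true_lists.items()}
    chrom_names = list(lists)
    perm = [chrom_names[i] for i in rng.permutation(len(chrom_names))]
    planted: list[tuple] = []
    junk_genes: list[tuple[str, str, int, int]] = []  # (gid, ctg, local, glen)
    junk_anchors: list[AnchorPair] = []

    # Each error gets its own chromosome. Translocations are planted LAST so
    # in-place errors only ever touch their chromosome's original contigs,
    # and the truth log (derived in reverse planting order, i.e. LIFO) can
    # undo each error as a single block at the state where it was planted.
    error_order = sorted(
        range(len(P.errors)),
        key=lambda i: P.errors[i].type == "translocation",
    )
    error_chroms = {perm[i % len(perm)] for i in range(len(P.errors))}
    transloc_sources = {
        perm[i % len(perm)] for i in error_order
        if P.errors[i].type == "translocation"
    }

    for e_idx in error_order:
        err = P.errors[e_idx]
        chrom = perm[e_idx % len(perm)]
        seq = lists[chrom]
        n = len(seq)
        if err.type == "inversion":
            a = int(rng.integers(0, n - err.span + 1))
            run = seq[a:a + err.span]
            seq[a:a + err.span] = [
                (cid, ln, "-" if ori == "+" else "+")
                for cid, ln, ori in reversed(run)
            ]
            planted.append(("inversion", [cid for cid, _, _ in run]))
        elif err.type == "translocation":
            # prefer error-free targets; never another translocation's
            # source, whose end must stay intact for the LIFO restore
            candidates = [c for c in chrom_names
                          if c != chrom and c not in error_chroms]
            if not candidates:
                candidates = [c for c in chrom_names
                              if c != chrom and c not in transloc_sources]
            if not candidates:
                candidates = [c for c in chrom_names if c != chrom]
            target = candidates[int(rng.integers(0, len(candidates)))]
            run = seq[n - err.span:]
            del seq[n - err.span:]
            lists[target].extend(run)
            planted.append(
                ("translocation", [cid for cid, _, _ in run], chrom)
            )
        elif err.type == "order_shuffle":
            s = err.span
            a = int(rng.integers(0, n - 2 * s + 1))
            b = int(rng.integers(a + s, n - s + 1))
            run1, run2 = seq[a:a + s], seq[b:b + s]
            seq[a:a + s], seq[b:b + s] = run2, run1
            planted.append((
                "order_shuffle",
                [cid for cid, _, _ in run1],
                [cid for cid, _, _ in run2],
            ))
        elif err.type == "deletion":
            # junk contigs with duplicated anchors to a donor chromosome
            c_num = int(chrom.removeprefix("chr"))
            donors = [c for c in range(1, P.n_chromosomes + 1) if c != c_num]
            donor = donors[int(rng.integers(0, len(donors)))] if donors else c_num
            gpc = max(1, P.genes_per_chromosome // P.contigs_per_chromosome)
            glen = max(1, int(0.3 * P.mean_gene_spacing))
            junk_ids = []
            # anchor junk to the donor's mid-chromosome genes: a run starting
            # at a chromosome edge could continue the global-y diagonal of an
            # adjacent reference chromosome and hide the discontinuity
            taken = len(ref_ids[donor]) // 3
            for k in range(err.span):
                ctg = f"junk{e_idx + 1}_{k + 1}"
                junk_ids.append(ctg)
                length = gpc * P.mean_gene_spacing + P.mean_gene_spacing
                seq.append((ctg, length, "+"))
                for j in range(gpc):
                    rg = ref_ids[donor][taken % len(ref_ids[donor])]
                    gid = f"J{e_idx + 1}X{k + 1}G{j + 1:02d}"
                    local = P.mean_gene_spacing // 2 + j * P.mean_gene_spacing
                    junk_genes.append((gid, ctg, local, glen))
                    junk_anchors.append(
                        AnchorPair(gid, rg, float(rng.integers(50, 501)))
                    )
                    taken += 1
            planted.append(("deletion", junk_ids))

    err_layout = AssemblyLayout.from_lists(lists, P.gap_length)
    query_genes = recompute_gene_positions(true_layout, err_layout, true_query)
    err_placements = {
        p.contig_id: (chrom, p)
        for chrom, ps in err_layout.chromosomes.items()
        for p in ps
    }
    for gid, ctg, local, glen in junk_genes:
        chrom, p = err_placements[ctg]
        query_genes.append(
            GeneFeature(gid, chrom, p.start + local, p.start + local + glen, "+")
        )
    anchors = anchors + junk_anchors

    # --- truth log by replay (LIFO: undo the last-planted error first) -----
    truth_ops = _derive_truth_ops(
        list(reversed(planted)), query_genes, ref_genes, anchors, err_layout, P
    )

    return SyntheticDataset(
        params=P,
        ref_genes=ref_genes,
        query_genes=query_genes,
        anchors=anchors,
        layout=err_layout,
        true_layout=true_layout,
        truth_ops=truth_ops,
    )


def _locate_block(state: SessionState, contig_id: str) -> tuple[str, int]:
    for chrom, blocks in state.blocks.items():
        for b in blocks:
            if any(cid == contig_id for cid, _ in b.contigs):
                return chrom, b.label
    raise ValidationError(f"contig {contig_id} is in no block")


def _derive_truth_ops(
    planted: list[tuple],
    query_genes: list[GeneFeature],
    ref_genes: list[GeneFeature],
    anchors: list[AnchorPair],
    layout: AssemblyLayout,
    params: SimParams,
) -> list[str]:
    if not planted:
        return []
    state = SessionState.create(
        query_genes, ref_genes, anchors, layout,
        ClusterConfig(params.resolution), params.gap_length,
    )
    ops: list[str] = []
    for record in planted:
        kind = record[0]
        if kind == "inversion":
            chrom, label = _locate_block(state, record[1][0])
            op = f"invert {chrom}:{label}"
        elif kind == "translocation":
            _, run_ids, source = record
            tchrom, tlabel = _locate_block(state, run_ids[0])
            op = f"insert {tchrom}:{tlabel} at {source}:END"
        elif kind == "order_shuffle":
            _, run1, run2 = record
            c1, l1 = _locate_block(state, run1[0])
            c2, l2 = _locate_block(state, run2[0])
            op = f"swap {c1}:{l1} {c2}:{l2}"
        else:  # deletion of junk contigs
            chrom, label = _locate_block(state, record[1][0])
            op = f"delete {chrom}:{label}"
        ops.append(op)
        state = apply_operation(state, parse_operation(op))
    return ops


# ---------------------------------------------------------------------------
# Collinearity verdict
# ---------------------------------------------------------------------------

def monotone_chromosomes(state: SessionState) -> dict[str, bool]:
    """Per query chromosome: do the x-sorted points rise monotonically in y,
    against a single reference chromosome, with no negative block?

    This is the verdict for 1:1 datasets (each query chromosome drawn from
    exactly one reference chromosome): the single-reference requirement
    catches translocated or duplicated runs whose global y happens to
    continue the diagonal of an adjacent reference chromosome. It is not
    meaningful for datasets with duplicated (WGD) anchors.
    """
    verdict: dict[str, bool] = {}
    by_chrom: dict[str, list] = {}
    for p in state.points:
        by_chrom.setdefault(p.query_chrom, []).append(p)
    for chrom, pts in by_chrom.items():
        pts = sorted(pts, key=lambda p: (p.xpos, p.ypos))
        ys = [p.ypos for p in pts]
        monotone = all(a <= b for a, b in zip(ys, ys[1:]))
        one_ref = len({p.ref_chrom for p in pts}) == 1
        signs_ok = all(
            b.orientation_sign >= 0 for b in state.blocks.get(chrom, [])
        )
        verdict[chrom] = monotone and one_ref and signs_ok
    return verdict


def is_fully_collinear(state: SessionState) -> bool:
    verdict = monotone_chromosomes(state)
    return bool(verdict) and all(verdict.values())
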