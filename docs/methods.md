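# Methods

## Dot-plot model

The unit of evidence is an ortholog anchor: a query gene paired with a
reference gene plus a synteny score (as produced by MCscan-style ortholog
calling; any `query_gene <tab> ref_gene [<tab> score]` file works, `###`
block separators are ignored because clustering is redone here). Anchors
whose genes are missing from either BED file are dropped and counted; an
input in which no anchor resolves is rejected.

Coordinates are 0-based half-open internally; BED is consumed natively
and AGP (1-based inclusive) is converted at the boundary. A gene is
represented by its interval start — deterministic and standard dot-plot
practice; the whole interval is carried along so liftover preserves gene
spans. The global *y* axis concatenates reference chromosomes in
natural-sort order of their names, each offset by the cumulative extent
(maximum gene end) of its predecessors. The *x* axis is per query
chromosome; plots concatenate query chromosomes in layout order.

## Two-pass clustering

Pass 1 sorts a chromosome's points by (*x*, *y*) and scans once; a new
cluster opens when the Euclidean distance between the current point and
the last point of the open cluster is at least *L/r* (*L* = query
chromosome length from the AGP, *r* = resolution, default 20). Because
every appended point immediately becomes the last point of the open
cluster, the test is always against the immediate predecessor, so the
pass-1 partition is exactly "cut where consecutive distance ≥ *L/r*" —
which is why smaller thresholds strictly refine larger ones. Euclidean
distance (not *x*-only) is used so that points far apart on the reference
axis never merge into one "collinear" block.

Pass 2 removes orientation breaks: every interior point that is a strict
local *y* extremum (both neighbours above, or both below) is split out as
a single-point block. Isolating the extremum — rather than cutting the
cluster once at it — leaves both flanks internally monotone, which the
downstream orientation sign (sign of last-minus-first *y*) relies on.
Equal neighbouring *y* values are not extrema. Blocks are relabelled
1..k per chromosome by ascending leftmost *x* after every operation.

### Resolution monotonicity is a property of collinear data

"Higher resolution ⇒ at least as many blocks" holds whenever pass 2 never
fires, i.e. on monotone (collinear) chromosomes, by the refinement
argument above. It is **not** a theorem in general: around a misassembly
junction, one coarse cluster isolates the two junction extrema as
singletons (ascending / max / descending / min / ascending = 5 blocks),
while a finer threshold cuts between the flanks first, demoting those
extrema to run boundaries (3 blocks) — the count dips as *r* grows. The
sequence *y* = 0, 10, 5, 15 exhibits the same effect for any split rule.
The package therefore verifies monotonicity on error-free synthetic dot
plots, where it is exact, and documents that on real, broken assemblies
the count is only *typically* increasing.

## Contig assignment and linkage-group suggestion

Each anchored gene maps to the contig whose AGP interval contains its
*x*; genes landing in gap intervals are excluded with a warning. A contig
joins the single block holding the plurality of its anchored genes (ties
go to the leftmost block); contigs without anchors adopt the block of
their nearest anchored neighbour on the chromosome, preferring the
preceding one. Per block, the suggested linkage group is the reference
chromosome with the highest sum of anchor scores, ties broken by gene
count and then name — so a duplicated (e.g. WGD-derived) hit at lower
score never outvotes the true placement.

## Edit operations

Operations address blocks by their current labels and act on whole
contigs (the tours format has no sub-contig resolution). A block address
resolves to the contiguous contig span covering the block's assigned
contigs. Semantics on the per-chromosome contig list:

* `invert` — reverse the span and flip every orientation sign (block or
  whole chromosome);
* `swap` — exchange two spans (same or different chromosomes; two whole
  chromosomes exchange entire lists); overlapping same-chromosome spans
  are rejected;
* `insert` — splice the source span before/after a target block's span or
  at a chromosome's START/END; inter-chromosome moves are the main use;
* `delete` — move the span to the unplaced set. Deleted contigs are kept
  as singleton AGP objects named by their contig ID (reversible, no
  sequence loss); their genes leave the point set and return on undo.

After any operation the object intervals are recomputed with a uniform
inter-contig gap (default 100 b, the AGP convention for gaps of unknown
size), every gene is lifted through contig-local coordinates
(local = x − start on forward contigs, end − 1 − x on reverse ones;
strand flips when the contig's net orientation flips), points are
rebuilt, and every chromosome is reclustered — so prior labels are void
after each edit, and the CLI echoes the new labelling. Exactly one prior
state is retained for undo.

## Synthetic datasets

The generator's defaults model a small curation scenario: 3 chromosomes
× 40 genes, mean spacing 20 kb with ±10% uniform jitter, gene length 30%
of spacing, 8 contigs per chromosome cut midway between genes, anchors
1:1 with scores uniform on [100, 1000], contigs separated by 100 b gaps.
These sizes keep consecutive-point steps (≈1.55× spacing worst case)
below the default threshold *L*/20 (≈2× spacing), so an error-free
chromosome is exactly one block, while a single displaced contig
(≥ ~100 kb) always exceeds the threshold and forms its own block.

Planted error types: **inversion** (reverse+flip a contig run),
**translocation** (move a run from the end of one chromosome to the end
of another — an end run, so a single `insert … at src:END` restores it
exactly), **order_shuffle** (exchange two disjoint equal-length runs),
and **deletion** (append junk contigs whose genes duplicate anchors of
another chromosome's mid-section at reduced score — the
duplicated-syntenic-block signature of polyploid grouping errors, fixed
by deleting the spurious block). Junk anchors deliberately avoid donor
chromosome edges: a run continuing an adjacent reference chromosome's
global-*y* diagonal would be invisible to a monotonicity check.

Each error gets its own chromosome; translocations are planted last and
prefer error-free target chromosomes, so in-place errors never touch
relocated contigs. The ground-truth log is derived by replay in reverse
planting order (LIFO): the erroneous dataset is clustered, the
last-planted error's contig run is located in the current labelling, the
repairing operation is emitted and applied, and the next error is
addressed against the relabelled state — guaranteeing each log line uses
labels valid at the moment it would be issued.

The correction verdict for these 1:1 datasets requires, per query
chromosome: *x*-sorted points non-decreasing in global *y*, a single
reference chromosome, and no negative block. The single-reference clause
matters: a translocated tail can be *y*-monotone if its donor sits higher
on the concatenated axis. The verdict is not meaningful for WGD-flagged
datasets, whose duplicate anchors intentionally span two reference
chromosomes.

What the generator does not emulate: paralogy beyond the optional 1-to-2
WGD flag, missing annotations/unanchored genes, sub-contig misassemblies,
tandem duplications, and anchor noise (scattered false orthologs).
Passing tests therefore demonstrate the correctness of clustering, edit
algebra and coordinate bookkeeping — not robustness to noisy ortholog
calling, which upstream c-score filtering is assumed to handle.

## Numerical and interface choices

* Threshold comparison: a new cluster opens at distance ≥ *L/r* (strict
  "less than" keeps a point in the cluster, matching the rule as stated).
* Ties in *x* are ordered by *y*; equal consecutive *y* never splits.
* Single-point blocks have orientation sign 0; the repair verdict treats
  0 as non-negative.
* AGP layout equality (and the round-trip guarantee) is over contig
  order, length and orientation plus the unplaced set — object intervals
  are derived quantities that change with the configured gap length.
* Session persistence stores only the contig layout (plus one undo
  layout) and re-derives genes, points and blocks from the original
  inputs on load; an untouched layout keeps the input AGP's own gap
  structure so coordinates match the BED exactly until the first edit.
* Exit codes: 0 success, 2 parse error, 3 validation/address error,
  4 I/O error.

## Known limitations

* Block addresses on non-contiguous assignments resolve to the covering
  span; with pathological anchor patterns an edit may drag along an
  interleaved contig (not observed on generator data, where every contig
  is anchored).
* Undo depth is exactly one, by design.
* Block count vs resolution can dip around misassembly junctions (see
  above).
* The clusterer processes each query chromosome independently; blocks
  never span query chromosomes.
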