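# syntecor

Collinearity-based curation of chromosome-level genome assemblies.

Chromosome-scale assemblies built by Hi-C scaffolding of polyploid genomes
frequently carry large-scale errors — contig runs that are inverted,
placed on the wrong homoeologous group, shuffled within a chromosome, or
spuriously duplicated between haplotypes. `syntecor` detects and repairs
these errors using collinearity against a reference genome instead of
Hi-C signal: it needs only two gene BED files, an ortholog anchors file
and the assembly's AGP, making it light enough to iterate interactively
from a shell.

## Method

Each query↔reference ortholog pair becomes a dot-plot point: *x* is the
query gene's position on its query chromosome, *y* the reference gene's
position on a concatenated reference axis (chromosomes in natural-sort
order, offset by cumulative extents). Points of one query chromosome are
grouped into **collinearity blocks** in two passes:

1. **Threshold scan** — points are sorted by *x* and scanned left to
   right; a new cluster opens whenever the Euclidean distance to the
   previous point reaches *L/r*, where *L* is the query chromosome length
   and *r* the resolution parameter (default 20; larger *r* → finer
   blocks).
2. **Inflection split** — within each cluster, any interior point whose
   *y* is a strict local extremum (both neighbours larger, or both
   smaller) marks an orientation break and is cut out, keeping every
   block internally monotone.

Blocks are labelled 1..k per chromosome by leftmost point; each contig of
the AGP layout is assigned to the block holding the most of its anchored
genes, and each block reports the reference chromosome with the highest
summed anchor score (its suggested linkage group). Corrections are
scripted block operations — `insert`, `invert`, `swap`, `delete` — applied
at contig granularity; after every operation gene positions are lifted
through contig-local coordinates into the new layout, points are rebuilt,
blocks are reclustered and relabelled, and one step of undo is kept. The
corrected assembly is exported as a `tours` file (per-chromosome contig
order/orientation) and a regenerated AGP.

A synthetic-data module generates complete ground-truth fixtures:
reference/query BEDs, anchors and AGP for an assembly with planted
inversions, translocations, order shuffles and duplicated junk contigs,
plus the operation log that repairs them.

## Worked example

Generate a three-chromosome fixture with one planted three-contig
inversion, cluster it, fix it, and export:

```
$ syntecor synth --out fixture --seed 11 --error inversion:3
truth log: fixture/truth_ops.txt

$ syntecor cluster --query-bed fixture/query.bed --ref-bed fixture/ref.bed \
    --anchors fixture/anchors.txt --agp fixture/query.agp --out session
3 chromosomes, 5 blocks at resolution 20
```

`session/blocks.tsv` shows the inversion as a negative-orientation block
on chr3 (columns: chromosome, label, x range, suggested reference
chromosome, orientation, gene count, contigs):

```
chr3  1  19485   507291   refChr3  +1  20  ctg3_1+,ctg3_2+,ctg3_3+,ctg3_4+
chr3  2  533531  898780   refChr3  -1  15  ctg3_7-,ctg3_6-,ctg3_5-
chr3  3  925021  1025421  refChr3  +1  5   ctg3_8+
```

Block 2 runs downhill (`-1`): contigs 5–7 are reversed. Invert it and
save:

```
$ syntecor modify --out session --op "invert chr3:2"
applied: invert chr3:2
$ syntecor save --out session
wrote session/corrected.tours and session/corrected.agp
```

chr3 now reclusters to a single ascending block of all eight contigs in
the correct order, and `corrected.tours` reads
`ctg3_1+ ctg3_2+ ... ctg3_8+`. `syntecor modify --out session --undo`
reverts exactly one operation; `session/dotplot.pdf` holds the labelled
dot plot before/after each step.

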