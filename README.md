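# annolift

Transfer structural gene annotations from a well-annotated genome to a
similar, un-annotated one. Given per-exon alignments of the source
transcripts onto the target genome (standard 12-column tabular format),
annolift selects the optimal exon combination for each transcript with a
stage-wise shortest-path model, enforces canonical GT-AG splice sites
with a bounded (±10 bp) rescue search, filters by a normalized path
score, and writes genePred-style annotations plus transcript FASTA for
the target genome.

## How it works

1. **Stages** — every source exon becomes a decision stage holding its
   alignment hits on the target (capped, best E-value first) plus an
   implicit *skip* state.
2. **Shortest path** — one state is chosen per stage so the summed
   one-step costs are minimal. A hit→hit step costs
   `chr_dist + strand + (1 − Align·Rela)` where
   `Align = (align_length/exon_length)·e^(−evalue)` and `Rela` is the
   min/max ratio of the source intron length and the target gap;
   chromosome or strand changes are infeasible (∞). Skipping a stage
   costs a flat `K = 0.95`. The last retained hit pays `1 − Align`
   toward the End point.
3. **Score** — `(1 − f*/N) · 100`, where `f*` is the optimal total cost
   and `N` the exon count; 100 is a perfect transfer. Annotations
   scoring `> 80` are kept.
4. **Quality control** — every intron must read GT..AG on the
   annotation strand; non-canonical junctions get a rescue search over
   donor/acceptor shifts up to ±10 bp (smallest total displacement
   first, exon+intron length conserved); unrescuable annotations are
   retained but flagged `N` in the last output column.

## CLI

Generate a fully synthetic, seeded world (source genome + genePred,
mutated target genome, simulated alignment table, truth map):

```bash
annolift fixtures --seed 1 --preset default --out world/
```

Presets: `identity` (target = source), `default` (substitutions, small
indels, segmental-duplication decoys, occasional exon deletions),
`misassembly` (a 2 bp acceptor defect recoverable only by splice
rescue), `repeats` (more duplication decoys).

Run the pipeline:

```bash
annolift annotate \
    --annotations world/source.genepred \
    --source-genome world/source.fa \
    --alignments world/alignments.tsv \
    --target-genome world/target.fa \
    --out out/ \
    [--min-score 80] [--max-splice-shift 10] [--max-hits-per-exon 500] \
    [--skip-penalty 0.95] [--chrom-map map.tsv] [--workers N] [--config run.cfg]
```

Outputs in `out/`: `annotations.genepred` (genePred columns plus
`score` and `flag`), `transcripts.fa`, and `summary.json` with
per-transcript accounting. Results are byte-identical regardless of
worker count. `annolift validate` performs the same input checks as a
dry run (exit code 2 on diagnostics; 1 on fatal errors).

Annotations may be genePred (default) or GTF (`--annotation-format
gtf`). The alignment table's query ids must encode exon identity as
`transcriptID|exonIndex|exonLength`; an optional `--chrom-map` TSV
(source chrom → target chrom) restricts each transcript's search to one
target chromosome.

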