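# Methods

## The retention statistic

The unit of analysis is the gene locus. From a GTF annotation every exon
of every transcript of a gene is collected; exons that overlap **or
abut** (distance-0, matching bedtools-merge's default) are merged into
disjoint super-exons, and the locus span runs from the first to the last
exonic base. The complement of the super-exons inside the span is the
intron set; by construction super-exons and introns tile the span
exactly, which the code asserts as an integer length-conservation
invariant. Gene-level GTF lines are ignored: the locus is defined purely
by its exons, because the denominator of the statistic is reads in
exon-derived sequence. All internal coordinates are 0-based half-open
(BED convention); GTF 1-based inclusive coordinates are converted at the
parsing boundary so interval arithmetic carries no ±1 bookkeeping.

Each aligned record is reduced to its 5′-end position: the leftmost
aligned base for `+` or unstranded records, the rightmost covered base
for `−`. Per gene and sample, `#locus` is the number of 5′ ends with
`span.start ≤ pos < span.end` and `#exonic` the number inside any
super-exon; the proportion of intronic reads is `1 − #exonic/#locus`.
Numerically this is computed as `(#locus − #exonic)/#locus`, which is
algebraically identical but exact in binary floating point (e.g.
`(100−80)/100` is exactly `0.2`, while `1 − 80/100` is not).

A locus with zero reads has an *undefined* proportion (NaN), not zero:
absence of evidence is not zero retention. In practice the count filter
removes such genes before they matter.

## Filtering and normalization

Genes are retained only if their intronic 5′-end counts, summed over
**all samples**, reach a threshold (default 100). Summing over samples
is our reading of "over all conditions", since the conditions comprise
the samples; a `collapse_replicates` flag sums the per-condition
replicate means instead, for users who want the replicate-number-
invariant variant. The filter is strict (`sum ≥ 100` passes, 99 fails)
and applied **before** normalization, so normalized values exist only
for retained genes.

Because exon-to-intron size ratios differ between genes, raw proportions
are not comparable across genes. Each retained gene's proportions are
therefore divided by the gene's maximum across the samples, so its
highest-retention sample scores exactly 1. Ties at the maximum all map
to 1; a gene whose maximum is 0 keeps all-zero values; undefined entries
stay undefined. Both raw and normalized proportions are emitted.

Per-sample distributions of normalized proportions are summarized by the
median and the 5th/95th percentiles, computed with linear interpolation
between closest ranks (numpy's default); undefined values are excluded
and `n_genes` counts only defined ones. The condition contrast reports
the per-condition mean of replicate medians and its difference from the
control condition.

## Counting conventions

- Every aligned record (each mate of a pair) contributes one 5′ end by
  default; `first_mate_only` restricts SAM/BAM counting to first mates
  for fragment-level counting. Which the original protocol used is not
  recoverable, so both are provided and the default documented.
- Counting is strand-agnostic by default; `strand_mode="match"` counts
  only ends whose orientation equals the gene strand.
- Secondary, supplementary and unmapped SAM/BAM records are skipped; BED
  input is taken at face value.
- A 5′ end inside several overlapping loci is counted in each: genes are
  counted independently, mirroring per-gene interval-intersection runs.
- Ends on chromosomes absent from the annotation are tallied per sample
  as "unassigned" and logged, never silently dropped.

The engine indexes each sample's 5′ ends as per-chromosome sorted
position arrays and counts interval membership with binary search
(`searchsorted`), so counting is `O((reads + genes·exons)·log reads)`
and exact — it is verified against a per-base brute-force oracle in the
tests.

## Biotype abundance-change matrix

From a per-isoform abundance table (FPKM-like, non-negative) and the
design, per-condition abundance is the mean over that condition's
replicates. Per isoform and knockdown, the log2 fold change is
`log2((kd + c)/(control + c))` with pseudocount `c = 0.1`, and per
biotype the isoform values are aggregated by the mean (median available
by flag). Pseudocount, replicate averaging and mean aggregation are our
reconstruction choices — the upstream description fixes none of them —
and are exposed as parameters; abundance estimation itself (e.g.
Cuffdiff) is out of scope. The matrix is antisymmetric under swapping
knockdown and control labels, which the tests assert.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: six
samples, two biological replicates each of `cwc22_kd`, `eif4a3_kd` and
`control`, with per-condition ground-truth retention `r = 0.30` under
CWC22 knockdown and `0.05` elsewhere — only the CWC22 condition has
elevated retention, so the knockdown contrast has a known sign.

- **Annotation**: single-transcript genes laid out left-to-right on one
  synthetic chromosome, 2–8 exons of 80–300 bp separated by introns of
  200–1500 bp, 500–2000 bp intergenic gaps (introns scaled down from
  human medians to keep simulated loci compact; the statistic only sees
  base-set membership, so absolute lengths are immaterial). Genes are
  non-overlapping by default; an option injects overlapping pairs to
  exercise multi-locus counting.
- **Reads**: per gene and sample, `N ~ Poisson(depth · w · f)` 5′ ends,
  with `w` a per-gene log-normal expression weight (σ = 0.5) and `f` a
  per-sample mean-one log-normal library factor (σ = 0.1). Each end is
  intronic with probability `r`, placed uniformly on the intron base
  set, else uniformly on the super-exon base set; intronless genes get
  only exonic ends (a positive `r` is demoted to 0 with a warning).
  Ends are emitted as 75 bp BED6 mates on random strands, arranged so
  the record's 5′ end is exactly the placed position. The simulator's
  own intronic/exonic bookkeeping is returned alongside and serves as
  the strongest end-to-end oracle: re-counting the emitted BED files
  must reproduce it exactly.
- **Abundances**: one isoform per gene; sample values are log-normal
  (mean-one noise, σ = 0.2) around `w` times a condition × biotype fold
  change, by default 2.0 for `retained_intron` and 0.7 for
  `protein_coding` under CWC22 knockdown — encoding the finding that
  retained-intron isoforms rise while gene-expression machinery falls —
  and 1.0 elsewhere.
- **Randomness**: everything flows from one integer seed; per-sample
  streams are derived by hashing the sample id into a `SeedSequence`,
  so runs are byte-identical per seed and any sample regenerates
  independently.

What the generator does **not** model: fragment lengths, positional or
GC bias, junction-spanning reads, mapping error, overlapping-gene
ambiguity in expression, or NMD-target dynamics. Passing tests
therefore demonstrate correctness of the *quantification* given ideal
placements, not robustness to alignment artefacts in real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the interval and counting
oracles on ~1000 and 100 random instances, the pipeline closure on 500
genes × 6 samples, parameter recovery on 40 genes at ~10,000 reads per
gene (binomial SE ≈ 0.005, so the ±0.02 check is a 4-SE bound), and the
contrast-shape check over 10 seeds at 500 genes — sizes at which every
stochastic bound holds with large margin while the whole suite stays
fast. Degenerate inputs are defined explicitly: empty interval lists
merge to empty, empty alignment sets yield explicit zero counts, an
unreachable filter threshold produces an empty (but well-formed)
summary, and an all-undefined gene is passed through with a warning.

## Known limitations

- Retention is per gene, not per intron: one strongly retained intron
  and many spliced ones average out.
- Max-normalization makes values relative within a gene across these
  samples; normalized values are not comparable between experiments.
- Multi-counting of overlapping loci slightly inflates counts in dense
  annotations; genes are treated independently by design.
- No significance testing on the contrast — the summaries are
  descriptive, as in the source analysis.
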