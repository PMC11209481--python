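# Methods

This note records the models, parameter choices and numerical details
behind `erv_charter`, and what the synthetic validation does and does
not establish about real genome data.

## Coordinates and formats

All internal coordinates are 0-based half-open on the plus strand;
external TSV tables print 1-based inclusive positions, BED stays
0-based, GFF3 and the reference region layout are read as 1-based
inclusive. Minus-strand loci are reverse-complemented before any
sequence-level analysis; interval coordinates always refer to the plus
strand. `N` bases never count as matches anywhere.

PSL input keeps its native half-open coordinates; 12-column tabular
BLAST is converted, with a reversed subject range encoding a
minus-strand hit. The PSL `qBaseInsert` field feeds the query-gap
ratio that the locus tables report; its printed form
(`Qgap/(Match+Mismatch+Qgap)`) is exposed exactly as computed from the
PSL fields, without further interpretation.

## Reference provirus

The canonical HML-9 layout on the 8,608-nt LTR14C–HERVK14C–LTR14C
consensus is: 5′LTR 1–587, gag 758–2548, pro 2548–3435, pol 3411–6060,
env 5975–8020, 3′LTR 8022–8608. Adjacent coding regions overlap
(gag/pro, pro/pol, pol/env); positions in overlaps belong to every
region containing them, and per-region statistics count overlap bases
toward each region independently. The consensus sequence itself is
user-supplied (Dfam content is not redistributed); the synthetic
module fabricates a stand-in with the same layout proportions for
tests.

## Locus mining

The built-in search is a deliberately simple seed-and-extend scheme
for toy genomes, not a BLAT replacement: exact k-mer seeds (k = 12) on
both strands, grouped by diagonal, merged into runs, and extended
without gaps until the identity of the last 16 compared bases drops
below 0.75. Two details matter for correctness on diverged elements:

- the reported end of an extension is rolled back to the best-scoring
  endpoint (match +1, mismatch −2), so hits do not overrun into
  unrelated flanking sequence — without this the window rule overruns
  by up to a window length, which is enough to misclassify a solo LTR;
- same-diagonal spans separated by ≤ 48 bases are re-merged after
  extension, because a local mismatch cluster (≥ 5 mismatches inside
  one window, which a 4%-diverged element produces somewhere along
  8.6 kb more often than not) stops extension mid-element.

Because the reference's two LTRs are identical, every genomic LTR is
hit twice (once per query LTR copy); hits whose target interval is
mostly (> 50%) inside a stronger hit are dropped before chaining.

Chaining merges same-chromosome, same-strand hits whose target gap is
≤ 5,000 bp and whose query spans advance colinearly (30 bp slop);
unaligned query bases between chained hits accumulate as query gaps —
that is where an element's internal deletions appear. The 5 kb default
keeps multi-kb internally deleted proviruses as single loci. A
consequence worth knowing: two independent solo LTRs closer than the
chaining gap with consistent query-LTR assignments are evidence-wise
indistinguishable from a heavily deleted provirus; the synthetic
generator therefore refuses layouts that would place elements that
close together.

Classification: a candidate whose matched consensus span stays inside
an LTR region (10 bp slop) is a solo LTR if it covers ≥ 90% of the LTR
model, otherwise it is rejected as sub-threshold noise; any candidate
reaching internal coding bases is a provirus. Completeness is
(matches + mismatches) / reference length, capped at 1, binned by
decile. Completeness bands read "longer than 70%" strictly: (0.70, 1],
[0.40, 0.70], [0, 0.40) — a ratio of exactly 0.70 falls in the middle
band. Flags: deletion when the query-gap ratio exceeds 0.10, insertion
when the target span exceeds the aligned query span by more than
100 bp; both thresholds are tunables with no published rule behind
them. Homolog pairing between two genomes is consumed as input, never
computed.

## Structural annotation

Elements are aligned to the full consensus with Biopython's
`PairwiseAligner` (match +2, mismatch −3, gap open −5, gap extend −2,
end gaps free on both sequences); the first optimal trace is used,
which is deterministic. The exact aligner is used at every size — at
the ≤ ~10 kb scale of a provirus the quadratic DP takes seconds, so no
banding heuristic is applied. Region completeness is the percentage of
a region's consensus positions aligned to an element base (values in
[0, 100], reported to 2 decimals); indels are maximal gap runs in
consensus coordinates, with deletions giving their first deleted base
and insertions the base they follow. Terminal truncations appear as
end-gap deletion runs; callers that only want internal events filter
by `min_len`.

## Chromosomal distribution

Expected insertions per chromosome are `e = Cl · n / Tl` over a
chromosome-length table; the shipped panTro6/hg38 tables are
approximate assembly lengths standing in for gap-excluded lengths,
which are not published — the chrY excess this feeds (observed 15 of
26 proviruses against an expectation of ~0.23) is significant at any
plausible length table. Two χ² variants are reported, since "the
chi-square test" underdetermines the design: a genome-wide
goodness-of-fit over all chromosomes (df = k − 1) and a per-chromosome
two-cell test (on-chromosome vs elsewhere, df = 1). For small
expectations (e < 5) the two-cell χ² is unreliable, so an exact
binomial p-value is reported alongside; measurement shows the χ² p
only approaches the exact central binomial p to ~0.02 once the
expectation reaches the tens-to-hundreds, so the exact value is the
one to trust for sparse chromosomes.

Genomic context uses exon > intron precedence inside gene bodies and
labels any partial gene-body overlap `genic&intergenic`; the five
labels (intergenic, intron, exon, exonic&intronic, genic&intergenic)
are exhaustive and mutually exclusive by construction.

## Insertion dating

Divergence is the uncorrected p-distance (fraction of differing
columns; gap and N columns excluded from numerator and denominator).
D is stored as a fraction; the clock formulas take percent, and the
×100 conversion happens in exactly one place. With a substitution rate
of 0.2%/nt/My: `T_2LTR = 100·D/0.2/2` (two independently diverging
LTRs) and `T_int = 100·D/0.2` (one lineage against a consensus). The
internal-region consensus is the per-column majority of the aligned
elements, ties broken by the reference base; it can be swapped for the
reference itself. Printed summaries round half away from zero
(22.75 → 23, 25.39 → 25).

Group aggregation consumes the per-element age column of the shipped
divergence table rather than recomputing ages from the printed
3-decimal divergences, because the printed divergences are rounded
past the point of reproducing their own age column (e.g. 0.106 beside
26.00, where 0.106 → 26.5). Species comparison is the pooled-variance
unpaired Student's t (df = nA + nB − 2, two-sided); on the six
homologous 2-LTR pairs it gives p = 0.889 — no species difference,
which is the only claim asserted at that granularity. Dating against
an element-derived consensus is biased upward relative to 2-LTR ages
(replication-cycle mutations inflate internal divergence), which is
why 2-LTR ages are the primary estimate wherever both LTRs survive.

## PBS typing and logos

The PBS window is the 18 nt starting 3 residues after the 5′LTR end of
a plus-strand-oriented element; absence of the LTR, or a window
running off the element, is recorded rather than erroring. Typing
compares the PBS to the reverse complement of each tRNA's 3′-terminal
18 nt (CCA tails included when present in the input; this is the
biological priming duplex), best match wins with ties broken by name,
and an assignment requires ≥ 14/18 positions — a tunable default, as
no published cutoff exists. Logo matrices renormalize each column over
observed A/C/G/T (gaps and Ns dropped) and report information as
2 − H(column) bits; the conserved TGG start surfaces as the
first-three-column consensus.

## Regulatory association and ORA

Regulatory domains follow the basal-plus-extension rule: basal = 5 kb
upstream / 1 kb downstream of the TSS (strand-aware, inclusive of the
TSS base), extension outward to the nearest of 1 Mb past the basal
edge, the closest neighboring basal domain boundary, and the
chromosome end. Only base+extension is implemented (no curated
domains). Extensions from facing genes may both cover the gap between
their basal domains — that overlap is how the rule works, not an
error. A locus associates with every gene whose extended domain it
overlaps; distance is locus midpoint minus TSS, signed by gene strand,
binned at 5 kb / 50 kb / 500 kb.

ORA intersects every category with the universe (default: all genes
with a domain), keeps sizes in [5, 2000], computes the hypergeometric
upper tail P[X ≥ k], adjusts with Benjamini–Hochberg across all tested
categories, and returns the top 10 by (FDR, p). The null calibration
test uses a universe of 5,000 genes, 20 categories of 500 and lists of
400, where attainable p-values are dense; sparser configurations make
the discrete hypergeometric test conservative (measured null fraction
at p < 0.05 drops to ~0.03 for lists of 100), which is a property of
the statistic, not a miscalibration.

## Synthetic data: what it does and does not show

The generator inserts a copy of the reference with a target-site
duplication and substitutes every site independently with probability
min(r·τ, 0.75), uniform over the three alternative bases — a linear
clock with no multiple-hit correction, matching the linear dating
formulas. Expected LTR–LTR p-distance is 2p(1−p) + (2/3)p² with
p = r·τ, so the 2-LTR estimator carries a small O(p²) downward bias
(~4% at τ = 30 My, r = 0.002); recovery tolerances (mean within 10%
over 50 replicates) hold for τ ≤ 30 and would not for much older
insertions. Solo LTRs are made by excising the internal span plus one
LTR between the duplications; truncations delete explicit consensus
intervals, so per-region completeness has an exact interval-arithmetic
answer the aligner must reproduce. Background sequence is i.i.d.
uniform and indels arise only from the explicit operations — passing
tests therefore demonstrate correctness of the machinery under the
stated model, not robustness to repeat-rich backgrounds, segmental
duplications, gene conversion between LTRs, or stochastic indel
processes, none of which are simulated. Everything is bit-reproducible
from a single seed.

Default simulation sizes (60 kb chromosome, 2 kb scaled reference in
unit tests; 120 kb with the full 8,608-nt reference in the worked
example and recovery tests) keep the whole suite in the
tens-of-seconds range while leaving every planted element long enough
for its classification and dating to be non-trivial.

## Shipped catalogs

The TSVs under `erv_charter/data/` record the published HML-9 survey
tables for panTro6/hg38 (locus coordinates, completeness, contexts,
homolog pairings, per-region integrity, divergences and ages) plus the
approximate chromosome lengths. One transcription fix: the chimp chrY
provirus ending printed as "61,571,65" in the homolog table is stored
as 6,157,165, the value the locus table itself prints. The age columns
are treated as authoritative over re-deriving ages from the rounded
divergence columns, as explained above.

## Known limitations

- The search is exact-seed and ungapped; it will miss elements whose
  divergence leaves no clean 12-mer in a region, and it reports
  substitution-level identity only. Real surveys should ingest
  BLAT/BLAST hits instead.
- Homolog pairing, cytoband naming tables and the gene universe are
  inputs, not inferences.
- Dating assumes a uniform clock and no gene conversion between LTRs;
  conversion rejuvenates 2-LTR ages undetectably.
- The per-chromosome χ² is approximate at small expectations; use the
  reported exact binomial there.
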