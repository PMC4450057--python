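# Methods

## The problem and the model

A chimeric RNA joining two genes can arise three ways: a genomic
rearrangement (including an interstitial deletion that fuses the loci), a
trans-splicing reaction between two separate transcripts, or *cis*-splicing
of a single read-through precursor that spans two same-strand neighboring
genes (cis-SAGe). Only the last leaves the genome intact and requires an
intergenic primary transcript. The pipeline operationalizes that
distinction: the taxonomy isolates calls whose parents are same-strand
immediate neighbors in transcriptional order, and the cascade then demands
positive evidence for the read-through mechanism while excluding the
alternatives.

### Taxonomy

`INTRACHR_SS_0GAP` requires: one chromosome, one strand, zero annotated
genes (either strand) overlapping the inter-gene interval, and the call's
5′ gene transcriptionally upstream. A same-strand adjacent pair reported in
the reverse order is demoted to `INTRACHR_OTHER` with a `reversed-order`
note — a read-through precursor can only be spliced downstream. Overlapping
same-strand neighbors remain eligible at distance 0 (the class is named for
a zero *gene* gap, not a positive base-pair gap).

### The cascade

Six tri-state criteria (Y/N/NA) in fixed order: Sanger → immediate neighbor
→ interstitial deletion → CTCF binding → siCTCF induction → intergenic
transcript. The deletion flag has inverted polarity (N = no deletion =
pass). A pair's `eliminated_at` is its first failing stage; membership in
the final set is a pure conjunction, so stage order affects only the
elimination labels (property-tested). NA at a stage a pair has reached is
treated as a failure with a logged warning: the cascade demands positive
evidence, and an unevaluable criterion cannot supply it. (In the published
matrix, blanks occur only after a pair is already eliminated, so this
convention does not alter its counts.)

Tunable thresholds (`FilterConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `fc_threshold` | 1.5 | induction ≥ 1.5-fold (and "down" ≤ 1/1.5) on CTCF knockdown |
| `deletion_log2_cutoff` | −0.3 | CNV log2 ratio at or below this is a loss (single-copy-loss heuristic; the evidence source is an array segmentation, so the cutoff is configurable) |
| `min_peak_overlap_bp` | 1 | minimal peak/segment overlap with the target interval |
| `min_intergenic_mean_coverage` | 1.0 | mean read coverage over the gap that counts as an intergenic transcript when no RT-PCR flag is supplied; an experimental flag always takes precedence |
| `pseudocount` | 0.01 | added to both conditions in the fold change so zero expression is defined; note it pulls ratios of small values toward 1, so an exact 1.5-fold pair scores "unchanged" |
| `read_length`, `min_anchor` | 101, 8 | define the junction effective length 2·(read_length − min_anchor)/1000 kb used to put junction-read counts on the FPKM scale |
| `breakpoint_slack` | 5 bp | breakpoints this close to an exon boundary still match it; farther ones are flagged non-canonical and excluded from rank statistics |

### Exon ranking and the exon-2 test

Exon ranks are 1-based in transcription order; backward rank counts from
the 3′ end, so forward + backward = exon count + 1 for every exon (the
"second-to-last" donor is backward rank 2). The null model for acceptor
usage lets each of the *n* 3′ genes contribute a junction at one exon
chosen uniformly from 1..E_i — exon 1 must be reachable because observed
sets include first-exon acceptors; an "acceptor-bearing exons only"
(2..E_i) null is available by flag. The count of rank-2 hits is then
Poisson-binomial with p_i = 1/E_i (0 if E_i < 2); the tail Pr(K ≥ k) is
computed exactly by convolving the per-gene Bernoulli PMFs, and also
estimated by Monte-Carlo resampling (default 10,000 replicates) for
fidelity to how such tests are usually reported. The exact tail is the
reference; the simulation is validated against it (within 3 standard
errors in ≥ 99/100 seeded runs).

### KS comparisons

Two-sample Kolmogorov–Smirnov via `scipy.stats.ks_2samp(method="asymp")`:
D is the maximal CDF gap, p the asymptotic Smirnov approximation. Sample
sizes here are 16–32 pairs, so p-values are approximate by construction;
tests pin D against a brute-force CDF-gap maximization to 1e-12.

### Reading-frame arithmetic

Junctions must sit at annotated exon boundaries of the canonical
transcripts (most exons; ties: longest span, then smallest id). Both
boundaries are mapped to transcript coordinates; a junction point in UTR on
either side (including a 3′ junction upstream of the 3′ CDS, which leaves
the downstream coding sequence intact) is NR. Otherwise the coding length
from the 5′ CDS start to the donor point and the coding length skipped in
the 3′ gene up to the acceptor point are compared modulo 3: equal →
in-frame. The computation is done entirely in transcript space, making it
strand-symmetric by construction (tested with a minus-strand mirror).

### Candidate rules

Rule 2 ("< 30 kb") is strict, rule 3 ("FPKM > 1") is strict and applies to
the 5′ gene only (a flag adds the 3′ gene). A default-on multi-exon
requirement (both parents ≥ 2 exons) reflects that validated cis-SAGe
parents are multi-exonic and that the predicted "2-2" junction needs a
second-to-last and a second exon to exist; disable it to reproduce the
bare 4-rule count. Genes missing from the expression table count as
FPKM 0 (logged).

## Coordinates and formats

Internally 0-based half-open everywhere; GTF I/O is 1-based inclusive, BED
and bedGraph 0-based half-open. GTF/GFF3 parsing is delegated to `gffutils`
(in-memory database), interval queries to `intervaltree`, tables to
`pandas`. Writers and readers are paired and round-trip losslessly; the
GTF writer is deterministic, so one seed yields byte-identical files.

## The synthetic cohort

The generator emulates the shapes that make the discovery problem
non-trivial, with defaults chosen once as the study conditions:

* 2 chromosomes × 1,000 genes; strand iid ± with probability 0.5.
* Exon count: 12% single-exon point mass, else 2 + Poisson(3) (mode ≈ 5) —
  the two-peak shape of genome-wide exon-count distributions.
* Exon length 30 + Exp(150) bp (mean ≈ 180); intron length lognormal
  (median 1.5 kb); same-strand intergenic distance lognormal (median
  54 kb, σ = 1.1), matching the genome-scale median that makes the < 30 kb
  rule discriminative (~30% of pairs fall under it).
* CDS on multi-exon genes from the midpoint of the first to the midpoint
  of the last exon, so internal junctions are frame-classifiable.
* Planted events: 16 cis-SAGe (same-strand adjacent, gap 1–30 kb, 5′ gene
  ≥ 2 exons, 3′ gene ≥ 4 exons), 5 deletion-driven (junction last → first
  exon with a log2 = −1.0 CNV loss spanning the fused interval), 13
  interchromosomal, 5 trans-splicing-like (CTCF peak present but 0.5-fold
  under knockdown). Parental genes are disjoint across events. Exactly
  round(11/16 · n) cis junctions take the "2-2" configuration — a fixed
  count rather than a per-event coin flip, so the configured bias is the
  realized bias.
* Tracks are noise-free by default (copy-neutral background, peaks only in
  cis and trans-like gaps, coverage 5× only over cis gaps, fold changes
  2.0 / 1.0 / 0.5), which is what makes exact sensitivity = specificity =
  1.0 recovery a meaningful contract rather than a statistical accident.

What the generator does **not** emulate: mapping artifacts and false calls,
expression measurement noise, CNV segmentation error, shared parental genes
between events, multiple junction isoforms per pair, and annotation
incompleteness. Passing recovery tests therefore demonstrate the logic of
the pipeline, not its robustness to noisy real data; the noise knobs exist
but default to 0.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 2,000-gene cohort
(sub-second), 10,000-replicate exon-usage simulations, enumeration oracles
up to 10 genes with ≤ 4 exons each, and 200-instance KS oracle sweeps —
sizes at which every expected value is exactly computable or tightly
bounded. Sub-seeds are derived additively from the master seed. Degenerate
inputs are explicit errors (empty KS samples, zero parental FPKM in
expression ratios, single-exon genes in junction prediction) or flagged
states (zero cytoplasmic level in fractionation ratios; pairs missing from
evidence tables become NA and are conservatively eliminated).

## Known limitations

* The genome-wide counts tied to a specific human annotation (the number
  of same-strand pairs within 30 kb, the ~54 kb median, the published KS
  statistics and the exon-2 simulation p-value) are annotation-version
  dependent; the package reports them for whatever annotation is supplied
  rather than asserting fixed values.
* The published induction counts among the 36 CTCF-bound candidates are
  internally inconsistent in the source material (16 + 5 + 16 = 37 ≠ 36);
  the shipped criteria matrix follows the tabulated Y/N column, which
  yields 16 induced of 36.
* The asymptotic KS p-value is inaccurate at n = 16; D is exact.
* Whether multiple junction isoforms of one pair should count once or
  separately in category fractions is exposed as a flag
  (`unique_pairs`), not decided.
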