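# cissage

Discovery and characterization of **cis-SAGe** fusion RNAs — chimeric
transcripts produced by *cis*-splicing between adjacent genes, where RNA
polymerase II reads through a gene's terminator into its same-strand
downstream neighbor and the intergenic precursor is spliced into a chimeric
mRNA without any DNA rearrangement.

The package is for transcriptomics analysts who have chimeric-RNA calls
(e.g. SOAPfuse-style tables) and want to know which of them are genuine
read-through events rather than products of interstitial deletion or
trans-splicing. It provides:

1. **Taxonomy** — each call is classified by the genomic relation of its
   parental genes: `INTERCHR` (different chromosomes), `INTRACHR_SS_0GAP`
   (same chromosome, same strand, immediate neighbors, transcriptional
   order preserved — the cis-SAGe candidate class), or `INTRACHR_OTHER`.
2. **Six-criteria cascade** — candidates survive, in order: Sanger
   confirmation; no intervening gene; no copy-number loss between the fused
   exons (log2 ratio ≤ −0.3 fails); ≥ 1 CTCF peak in the intergenic gap;
   induction ≥ 1.5-fold on CTCF knockdown (CTCF is an insulator-binding
   protein whose loss de-represses read-through, so a fusion that *drops*
   under siCTCF behaves like a trans-splicing product); detectable
   intergenic transcript.
3. **Characterization** — two-sample Kolmogorov–Smirnov comparisons of the
   surviving pairs against the genome background (intergenic distance, exon
   counts, flanking intron lengths); exon-position histograms around the
   junction; a significance test for preferential use of the 3′ gene's
   second exon (the number of rank-2 acceptors among *n* genes is
   Poisson-binomial with success probabilities 1/E_i under the uniform-exon
   null — computed exactly by convolution and by Monte-Carlo resampling);
   and reading-frame classification of each junction (NR / in-frame /
   out-of-frame).
4. **Prediction** — genome-wide enumeration of novel candidates by four
   rules: same-strand immediate neighbors, intergenic distance < 30 kb,
   5′ gene expressed (FPKM > 1), and the favored junction geometry
   (second-to-last exon of the 5′ gene → second exon of the 3′ gene),
   emitting the donor/acceptor exon coordinates an RT-PCR assay would
   target.
5. **Synthetic cohorts** — a generator that plants cis-SAGe events and all
   three decoy classes in a simulated genome with matching evidence tracks,
   so the whole pipeline is testable with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (2,000 genes, 16 planted cis-SAGe events, 23 decoys):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_fusions.py
python analysis/03_filter_criteria.py
python analysis/04_characterize.py
python analysis/05_predict_candidates.py
```

Output of step 03 (abridged):

```
published matrix cascade:
  46 -> 38 -> 38 -> 36 -> 16 -> 16
  final set equals the 16 starred pairs: True

synthetic cohort cascade:
input pairs: 26
after sanger: 26
after immediate_neighbor: 26
after interstitial_deletion: 21
after ctcf_binding: 21
after sictcf_induced: 16
after intergenic_transcript: 16
elimination breakdown: {'sictcf_induced': 5, 'survived': 16, 'interstitial_deletion': 5}
```

The 48-pair criteria matrix loses 2 pairs to failed Sanger validation, 8 to
intervening genes, none to interstitial deletions, 2 to absent CTCF
binding, and 20 to a missing knockdown response, leaving exactly the 16
validated cis-SAGe pairs. On the synthetic cohort the five deletion-driven
decoys die at the deletion check, the five trans-splicing-like decoys at
the induction check, and all 16 planted events survive.

Step 04 then reports (same run):

```
intergenic distance vs genome: KS D = 0.6829, p = 6.185e-08
3' second-exon usage: 11/16 pairs; p_sim = 1.00e-04, p_exact = 1.46e-05
top junction configurations: [('2-2', 11), ('3-3', 1), ('3-4', 1)]
```

i.e. the recovered pairs are dramatically closer together than the genome
background (whose median same-strand intergenic distance is ~54 kb), and
the second-exon acceptor bias (11 of 16) is far beyond the uniform-usage
null.

A `cissage` console command exposes the same stages
(`simulate | classify | filter | characterize | predict | matrix | run`);
`cissage matrix` prints the published-matrix cascade above.

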