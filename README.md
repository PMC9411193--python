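# episcreen

**Rescuing sub-threshold GWAS variants through a tissue's regulatory
epigenome.**

Genome-wide association studies only call a variant significant below
P < 5×10⁻⁸, which misses real risk variants of modest effect. `episcreen`
implements a screen for such *sub-threshold* variants (10⁻⁶ ≤ P < 10⁻³) in
a tissue of interest — motivated by non-syndromic cleft palate and the oral
epithelium — by requiring convergent functional evidence instead of
association strength alone:

1. **Active enhancers.** ATAC-seq nucleosome-free regions (fragments
   < 100 bp) are classified by H3K27ac: *overlapped* (≥1 bp peak overlap),
   *flanked* (1–20 kb edge-to-edge from a peak) or *negative*; the first two
   classes are active enhancers/promoters (AEs).
2. **Chromatin contacts.** Cis Hi-C bin pairs (10 kb) are tested against an
   equal-occupancy, isotonic distance-decay expected model with an exact
   binomial upper tail, p = P(X ≥ k), X ~ Binomial(N, p_d); pairs with
   p < 0.05 are significant.
3. **Linking.** A candidate SNP inside an AE whose bin forms a significant
   contact with a bin overlapped by the promoter of an expressed gene
   (TPM > 0.5) yields a (SNP, AE, gene) link triple.
4. **Allele scoring.** A gapped k-mer SVM (l = 10, k = 6; l-mer pairs with
   m mismatches contribute C(l−m, k) to the kernel) is trained on linked
   AEs (400 bp, >70%-repeat sequences removed) vs 10× random genomic
   windows; deltaSVM scores each allele swap as Σ w(alt l-mer) − w(ref
   l-mer) over the l l-mers covering the variant, with Tukey-fence outlier
   calls against 1 000 random background SNPs. PWM gain/loss at an 80%
   relative profile score completes the mechanistic picture.

A first-class synthetic-data module generates every input (genome, genes,
expression, NFRs, peaks, coverage, GWAS table, contact pairs) with planted
causal structure and a ground-truth manifest, so the whole screen runs and
is tested with no downloads.

## Worked example

The numbered scripts under `analysis/` run the screen end to end on the
default synthetic conditions (run from the repository root):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_annotate_variants.py
python analysis/03_classify_enhancers.py
python analysis/04_contact_significance.py
python analysis/05_link_variants.py
python analysis/06_gkm_deltasvm.py
python analysis/07_motif_gain_loss.py
```

Selected output (seed 1):

```
100 candidate SNPs of 2000 (P < 0.001)
1500 NFRs: {'flanked': 750, 'overlapped': 600, 'negative': 150}  (AEs: 1350, 90% of NFRs)
709979 read pairs: trans 15.0%, cis <=5 kb 0.0%, cis >5 kb 85.0%
4785 / 128439 tested bin pairs significant at p < 0.05
99 SNPs in AEs interact with the promoters of 102 expressed genes (318 interactions at 10 kb bins)
  hub variant rs000159 targets 30 genes
  planted-variant recovery: 99.0%; non-planted linked share: 0.0%
training set: 92 positives / 920 negatives (400 bp)
5-fold CV AUROC 1.000, average precision 1.000
linked variants: 99; Tukey outliers: 99
planted functional alleles: median delta -5.75 (rank test vs background, one-sided p = 5.69e-61)
99 linked variants scanned against 1 PWMs at threshold 80%
  planted functional variants losing their motif: 99/99
```

Reading this: of 2 000 simulated GWAS SNPs, 100 pass the sub-threshold
cut; all of them sit in active enhancers (the generator plants exactly this
structure). The binomial contact test recovers the planted 8-fold enhancer–
promoter loops, linking 99/100 planted functional variants to expressed
genes — including a deliberately planted 30-target hub variant — with no
spurious variants linked. The gapped k-mer SVM trained on the linked
enhancers separates them perfectly from random genomic windows, deltaSVM
scores every linked risk allele as a negative Tukey outlier against 1 000
random background SNPs (median delta −5.75 vs a background IQR of 0.34),
and every linked risk allele destroys its planted transcription-factor
motif.

The same pipeline runs on real data by pointing `PipelineConfig` (or the
`episcreen` CLI: `simulate`, `annotate`, `call-enhancers`,
`hic-significance`, `link`, `train-gkm`, `score-variants`, `motif-delta`,
`run-all`, `report`) at standard-format files: GWAS TSV, BED fragments and
peaks, bedGraph coverage, GENCODE GTF, TPM table, pairs/BEDPE contacts,
FASTA genome and JASPAR PFMs.

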