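# Methods

`episcreen` implements a screen for *sub-threshold* GWAS variants — those
with association P values below a relaxed cutoff (P < 10⁻³) but short of
genome-wide significance (P < 5·10⁻⁸) — that are nonetheless plausibly
functional in a tissue of interest. The screen combines four evidence
layers: open chromatin (ATAC-seq nucleosome-free regions), active-chromatin
marking (H3K27ac ChIP-seq peaks), chromatin contacts (Hi-C-type read
pairs), and gene expression (TPM), then scores candidate alleles with a
sequence model (gapped k-mer SVM / deltaSVM) and PWM gain/loss analysis.

## Variant selection and annotation

Candidates are SNPs with P strictly below `p_max` (default 10⁻³).
Strata: genome-wide (P < 5·10⁻⁸), suggestive (P < 10⁻⁶), sub-threshold
(10⁻⁶ ≤ P < 10⁻³); a point exactly at 10⁻⁶ is sub-threshold.
Genomic context uses precedence promoter > exon > intron > intergenic over
all gene models. The promoter window is 2 000 bp upstream / 500 bp
downstream of the TSS, strand-oriented; this is a common convention (no
single standard exists) and both ends are configurable. One TSS per gene:
the 5′-most transcript start on the gene strand. All internal coordinates
are 0-based half-open; GTF, GWAS tables (1-based by convention, with a
flag) and pair files are converted on read.

## Active-enhancer classification

NFRs are ATAC fragments strictly shorter than 100 bp. An NFR is
*overlapped* when it intersects an H3K27ac peak by ≥ 1 bp, *flanked* when
it does not overlap any peak but its edge-to-edge gap to the nearest peak
falls in [1 000, 20 000] bp, and *negative* otherwise; an NFR closer than
1 kb to a peak without overlapping it is negative. The flank condition is
evaluated on at least one side by default (`flank_sides: any`); the
two-sided reading is available as a switch since the published definition
does not say which was used. Precedence is overlapped > flanked, because
direct overlap is the stronger evidence. Active enhancers/promoters (AEs)
are the union of overlapped and flanked NFRs. The NFR *summit* is the
position of maximal ATAC coverage within the NFR (leftmost on ties),
falling back to the midpoint without coverage.

## Contact significance

Cis bin-pair counts at resolution `bin_size` (default 10 kb) are tested
against a distance-decay expected model in the mid-range window
[2·resolution, 2 Mb]. The model groups distance offsets into ~100
equal-occupancy strata (equal contact counts per stratum), estimates a raw
per-locus-pair probability per stratum, enforces non-increasing decay with
isotonic regression, and renormalises so probabilities sum to one over all
locus pairs. Isotonic regression replaces the spline fit of the classical
two-pass approach: it imposes exactly the assumption the model makes
(monotone decay), has no smoothing parameter, and is testable; a single
estimation pass is used. No coverage-bias (ICE/KR) correction is applied in
v1, matching a raw-bin workflow; a config hook is reserved.

Each observed bin pair with count k gets the exact binomial upper tail
p = P(X ≥ k), X ~ Binomial(N, p_d), with N the informative cis contact
count; pairs with p < 0.05 are significant (Benjamini–Hochberg optional,
off by default to match the published raw-p convention). Because the test
statistic is discrete, the realised type-I error of an exact tail test is
structurally *below* the nominal level by up to the probability mass of the
critical count; the gap shrinks as ~φ(z₀.₀₅)/√μ with the expected bin-pair
count μ. The calibration experiment therefore uses a deep library
(μ in the hundreds) so the discreteness gap is small against its
acceptance band; at shallow depths the test is simply conservative.

A/B compartments come from the leading eigenvector of the Pearson
correlation of the distance-normalised (observed/expected) matrix at
100 kb; the sign is oriented so the positive (A) class has the higher
gene density, and bins without coverage are unlabelled. An eigenvalue share
below 0.2 is flagged as weak compartment signal.

## Variant–gene linking

Promoters of *expressed* genes (TPM strictly > 0.5) are intersected with
significant contacts: a link triple (SNP, AE, gene promoter) is emitted
when the SNP (point-in-bin) falls in one anchor of a significant pair, lies
inside an AE, and an expressed promoter overlaps the other anchor; both
orientations are tested and triples are deduplicated on (SNP, gene, binA,
binB). Point-in-bin for the SNP avoids double counting; the AE's own
coordinates are recorded but not required to overlap the anchor, since the
published definition pins only the SNP to the 10 kb bin.

## Gapped k-mer SVM and deltaSVM

The gkm kernel counts shared gapped k-mers between l-mers: an l-mer pair
with m mismatches contributes C(l−m, k), zero for m > l−k (defaults
l = 10, k = 6). The kernel is exact — no truncated or approximate variants
— computed pairwise by mismatch combinatorics and, for Gram matrices,
through an integer-identical sparse feature expansion over all C(l, k)
position subsets. Kernels are normalised (K/√(K_AA·K_BB)) by default.
Positives are the AEs appearing in link triples, recentred on their summit
and resized to 400 bp; sequences more than 70% soft-masked (repeat) are
removed. Negatives are 10× as many random genomic windows avoiding the
positive intervals and N bases. A soft-margin SVM (C = 1) is trained on the
precomputed kernel with stratified 5-fold cross-validated ROC/PR reporting;
the final model is refit on all data.

deltaSVM of a variant is the sum over the l l-mers covering the variant of
w(alt l-mer) − w(ref l-mer), where w is the model's unbiased decision score
of a single l-mer. No reverse-complement collapsing is applied in v1 (the
strand convention of the training windows is preserved). Outlier calls use
Tukey fences (1.5·IQR) against the deltaSVM scores of 1 000 uniformly drawn
genomic SNPs with random alternative alleles, matching a box-and-whisker
presentation; a z-score rule would be an easy alternative. Background
construction is seeded and recorded.

## PWM gain/loss

The relative profile score of a PWM placement is (s − s_min)/(s_max −
s_min) with s the log-odds sum and s_min/s_max the per-column extrema; a
motif is present for an allele when any placement on either strand reaches
0.80. Pseudocounts are background-proportional totalling 0.8 per column.
Only placements covering the SNP base count toward presence by default, so
every gain or loss is attributable to the allele (`require_snp_overlap`
switch provided). Lost = present for ref, absent for alt; gained the
reverse. PWMs are user-supplied JASPAR PFM text; no database is vendored,
so absolute gain/loss counts depend on the database version.

## Synthetic data

The generator emulates every input with the statistical structure the
analysis assumes, under one seeded `numpy` generator (byte-identical
outputs per seed, seed echoed in the manifest):

- **Genome**: i.i.d. uniform bases, 2 × 5 Mb chromosomes, with ~10%
  lowercased in 0.5–2 kb blocks to emulate soft-masked repeats (exercises
  the 70% repeat filter).
- **NFR layout**: 1 500 NFRs of 50–99 bp in class mix 40% overlapped /
  50% flanked / 10% negative, laid out as sequential cassettes whose peak
  placement guarantees the truth label: overlapped cassettes carry an
  overlapping 300–800 bp peak; flanked cassettes a peak at a 1–6 kb gap
  (inside the 1–20 kb window; the narrower draw keeps the layout feasible
  on a 5 Mb chromosome); negative NFRs are grouped into peak-free deserts
  with 21 kb margins. Inter-cassette spacing ≥ 1.5 kb keeps foreign peaks
  from flipping labels.
- **Expression**: zero-inflated (30%) log-normal TPM (μ = 1, σ = 1.5).
- **GWAS**: 2 000 SNPs, 5% functional. Functional SNPs get log-uniform
  P ∈ [10⁻⁶, 10⁻⁴] — sub-threshold but never genome-wide significant —
  background SNPs uniform P. Each functional SNP lies inside an AE where a
  planted PWM instance (12 columns: 4 near-deterministic, 8 weakly
  informative) is written into the genome; the ref allele completes the
  instance (relative score 1.0 ≥ 0.9) and the alt allele hits a strong
  column chosen by scanning so the score drops below 0.8. The planting
  routine verifies both bounds and errors if the PWM admits no such pair.
- **Contacts**: per chromosome 300 000 cis background pairs with distance
  density ∝ (d + d₀)^(−α) on [10 kb, 2 Mb] (α = 1, d₀ = 1 kb avoids the
  singularity at d = 0); each functional SNP's AE–promoter pair receives
  extra reads Poisson((fold−1)·μ_d) around the anchors, fold = 8, with
  anchor jitter ±300 bp; trans pairs are added uniformly across
  chromosome pairs to a 15% share. Two hub SNPs with 16 and 30 promoter
  targets mirror the many-target variants the screen is meant to surface.
  Loop anchor distances are restricted to [30 kb, 1.5 Mb] so planted loops
  stay inside the significance model's range.
- **Coverage**: a triangular ATAC peak (height 5–15, half-width 300 bp) at
  each NFR summit, written as bedGraph.

What the generator does **not** emulate: TAD/CTCF grammar, coverage bias,
GC structure, linkage disequilibrium between SNPs, replicate noise, and
realistic motif co-occurrence. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the generative
assumptions, not performance on real sequencing data.

## Problem sizes and numerical choices

The default synthetic conditions (2 × 5 Mb genome, 2 000 SNPs / 100
functional, 1 500 NFRs, 3·10⁵ cis pairs per chromosome, fold-8 loops) are
the package's study conditions; the full pipeline on them runs in a few
minutes on one CPU, with the gkm stage (~100 positives / ~1 000 negatives
at 400 bp) dominating. The binomial calibration experiment uses a single
5 Mb chromosome at 3·10⁷ loop-free pairs and 5 kb bins, generating
distances over 10–200 kb but testing only the 20–100 kb window — strictly
inside the sampling bounds, because bin offsets straddling a sampling bound
receive phase-truncated counts that are genuinely non-monotone in distance
— giving ≥ 10⁴ tested bin pairs with expected counts in the hundreds (see
the discreteness argument above). The null-uniformity check
of the KS test uses 2 000 simulations at n = 1 000 per sample; the exact
finite-sample null of the two-sample KS statistic is discrete, so
uniformity is asserted to within five percentage points of CDF deviation.
Ties in summit selection break leftmost; zero-coverage windows fall back to
interval midpoints; SVM kernels that fail to factorise are retried with a
1e-8 diagonal jitter (logged).

## Known limitations

- The gkm Gram computation is exact and dense in sequence count; training
  beyond a few thousand 400 bp sequences becomes memory- and time-bound
  (the published tree-based implementations scale further).
- One estimation pass for the contact model; no ICE/KR bias correction.
- deltaSVM has no reverse-complement weight symmetrisation in v1.
- The capture-per-interaction comparison is implemented for any two
  contact datasets but the shipped analysis only exercises it against a
  down-sampled library of the same protocol.
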