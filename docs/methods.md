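# Methods

This note documents the statistical procedures, the synthetic-data
model behind all benchmarks, the numerical choices, and what the tests
do and do not establish about real data.

## Differential expression and FDR

Groups are compared with the Welch (unequal-variance) two-sample t
statistic; the source study does not name its test, and Welch is the
robust default for small, possibly heteroscedastic groups (4–6
replicates per cell). Genes with zero within-group variance fall back
to a variance floor (1e-12) and are flagged; two identical degenerate
groups report statistic 0, p 1 rather than 0/0.

FDR control is Benjamini–Hochberg by default. The mouse contrasts use a
deliberately permissive threshold of 0.30 so that an adequately large
fraction of true responders is carried into the network stages; the
knockdown screens use 0.1 (0.05 for the largest network, both
config-exposed). An empirical-null local FDR is provided as an
alternative: z = Φ⁻¹(one-sided p) signed by the statistic, null
N(δ̂, σ̂²) fitted by central matching on the middle 50% of z (median;
half-IQR scaled to the normal), π̂₀ from the central mass capped at 1,
marginal density by Gaussian KDE, and membership at local fdr below the
threshold. Note that tail FDR (BH) and local fdr are different
quantities: at q = 0.30, BH admits ≈ q·k boundary genes that any
local-fdr rule excludes, so the two methods can only agree closely when
the discovery boundary falls in a sparse region of the z scale (the
calibration test therefore compares them at 0.05).

A consequence worth stating explicitly: under BH at threshold q with
true-null fraction π₀, the expected Jaccard overlap between the
discovery set and the planted truth is capped near 1/(1 + q·π₀) even at
recall 1. At q = 0.30 with planted sizes 238/1306/2231 over the 6000
gene universe used here, the attainable Jaccard is ≈ 0.72/0.80/0.87 by
this bound; recovery assertions of Jaccard ≥ 0.8 are made where the
planted fraction permits them (the advanced stage), and all three are
reported.

Transcript-level inputs are collapsed to genes by keeping each gene's
maximum-variance transcript. Outlier samples are never excluded
automatically; a configured exclusion list is honored and logged.

## Risk enrichment

cis-eSNPs: additive regression of expression on dosage for every
(gene, SNP) pair with |pos − TSS| ≤ 1 Mb on the same chromosome
(1-based inclusive; strand ignored), significance by BH FDR < 0.05
across all tested cis pairs. Monomorphic SNPs and genes without a TSS
are skipped. LD expansion adds SNPs with squared Pearson dosage
correlation (composite LD — phased haplotypes are not assumed) above
0.9 within 200 kb of a seed; expansion is idempotent at a fixed
threshold/window. Reactive SNP sets have causal-set overlap removed.

The matched null draws each random set without replacement from
MAF > 5% universe SNPs, excluding the observed set's members (so the
null cannot contain the signal), reproducing the observed
per-chromosome counts exactly; no finer positional or MAF binning is
applied. The empirical P uses the (r+1)/(n+1) estimator and so is never
0 and never exceeds 1; since 5000 resamples cannot resolve P below
2×10⁻⁴, a clearly labeled normal approximation to the null fraction
distribution is also reported for small-P reporting.

## CLR networks

Similarity is |Pearson r| — negative regulation is still evidence of
interaction, and CLR scores undirected evidence. Background statistics
use each row of M with the diagonal excluded (population SD); rows with
zero SD get z = 0 and are flagged. The joint score is the canonical
Euclidean combination of the two clipped z's. The analytic edge
probability exp(−z²/2) is the Rayleigh tail of a pair of standard
scores: parameter-free, monotone in z, and under inversion it
reproduces the order of magnitude of the printed network cutoffs
(z ≈ 3.25 ↔ P ≈ 0.0051). It is approximate on real data; the
permutation mode — every gene's sample vector permuted independently,
CLR recomputed, null z pooled across pairs and iterations — is the
calibrated reference and is what the null-rate tests assert on, with
the analytic mode asserted to be monotone-consistent with it.

Candidate interactions are restricted to TF × gene-set pairs (TF–TF
pairs counted once), matching the TF-regulatory framing; the TF list is
an external one-column annotation file. Retention keeps the
`retain_fraction` (default 0.5) of candidates with smallest edge P,
keeping ties at the quantile, with one qualification: pairs with zero
evidence (z = 0, P = 1 exactly) are never retained. The clipping step
puts a large point mass of candidates at exactly P = 1 (every pair
below both of its row backgrounds), and a keep-all-ties rule applied to
that mass would return the complete graph whenever the quantile lands
in it. The actually retained fraction and the realized P threshold are
reported in the run log. Hubs are TFs ranked by degree in the retained
network, ties broken lexicographically.

## Perturbation screens

The hypergeometric specificity test treats the 673-gene panel as the
population M, the stage network membership within the panel as K, the
affected genes as X draws, and reports the upper tail P(overlap ≥ x).
Percentages are rounded half away from zero to integers, matching the
reporting style of the assay tables (+12, −17). Knockdown efficiency is
the linear-scale relative target expression, 2^(mean log2 difference).
Relative expression from qPCR uses the comparative Ct method,
2^(−ΔΔCt). CE accumulation is (total − free cholesterol)/protein per
replicate, both arms scaled so the control mean is 100 (hence invariant
to common protein rescaling), percent change as an integer with a
two-sided Welch p; negative CE after subtraction is flagged but kept.

## Phenotype metrics

The plaque stability score is (SM22α + collagen)/(CD68 + Oil-Red-O)
stained-area percentages, divided by per-mouse lesion burden. A zero
unstable-area denominator makes the score undefined; such mice are
flagged and excluded from group means. Missing histology cells (the
fixtures plant 16% missing completely at random) are imputed by group
means of observed values — which leaves group means unchanged — with an
optional seeded draw from the group's Normal fit standing in for a full
multiple-imputation procedure, whose original settings are not
recoverable; every imputed cell is logged. Fold changes are computed
from unrounded internal values, since ratios of rounded endpoints need
not reproduce a published fold.

## Synthetic data model

All generators are seeded `numpy` Generators and bit-reproducible given
(parameters, seed); truth objects round-trip through JSON. Expression
noise is Gaussian on the log2 scale, the scale on which normalized
array data are analyzed.

* **Macrophage panel** (default 38 samples, 20 TFs, 200 targets, noise
  SD 0.5): TFs and unregulated genes are independent standard normals;
  each planted target is Σ β·TF + N(0, σ). For a single edge the
  expected correlation is β/√(β² + σ²) ≈ 0.89 at the defaults. Planted
  module sizes descend 17, 13, 12, 9, 9, 5... so hub degrees are
  distinguishable.
* **Mouse timecourse** (3 stages × {control, immediately-after-PCL,
  10-weeks-after} × 5 replicates, 6000 genes, planted PCL sets of
  238/1306/2231 genes and reactive sets of 42/300/600, |log2 effect|
  1.5): the PCL shift is applied to both post-PCL groups — the response
  persists while cholesterol stays low — so only reactive genes move
  between immediately-after and 10-weeks-after. The reactive set sizes
  beyond week 30 are scaled below the published counts to fit the
  6000-gene desk-scale universe while preserving the increasing-
  with-stage ordering.
* **Genotypes/GWAS** (156 individuals; 5 chromosomes × 400 SNPs at
  50 kb spacing; 40 genes, 25 with a planted cis effect of 1.0 anchoring
  a 5-SNP LD block at r² 0.95): LD blocks are generated on haplotypes by
  copy-or-redraw — each non-seed site copies the seed haplotype allele
  with probability √r², else redraws Bernoulli(MAF) — which preserves
  MAF and targets the pairwise r² in expectation (a plain allele flip
  would distort the frequency). GWAS P values are Uniform(0,1) except
  planted enriched SNPs, which fall below 0.05 with probability
  p_hit = 0.10; the downstream fold statistic only sees this hit
  indicator, so no case/control genotype model is needed.
* **Perturbation screens** (673-gene panel, 6 replicates per arm, 80%
  target knockdown, planted downstream shifts of |1.5| log2, CE shift
  +12% with SD 10): knockdown shifts the target by log2(1 − kd) on the
  log2 scale.
* **Histology** (8 mice per group, 16% MCAR missingness): per-group
  Normal area percentages clipped to [0, 100], group means patterned on
  the published staining ranges; burden is kept positive and never
  deleted.

What the generators deliberately do **not** emulate: probe-level array
structure and normalization artifacts, realistic genome-wide haplotype
structure, case/control GWAS sampling, siRNA off-target effects, and
correlated (non-MCAR) missingness. Passing tests therefore demonstrate
that the statistics are implemented correctly and calibrated under
their stated models, not that the pipeline is robust to those
real-data complications.

## Problem sizes and randomness

Simulation sizes used by the test suite and the acceptance script —
5000 matched random sets, 100-run null calibrations, 25 replicates for
the fold-recovery benchmark, 20 seeds for the AUROC benchmark, the
6000-gene timecourse — are the package's chosen desk-scale study
conditions; all complete in well under a minute each on one CPU. Every
stochastic stage receives a seed derived from the global seed and the
stage name via SHA-256 (kept below 2³¹), so any full run with a fixed
config reproduces its outputs byte-identically, which the manifest
(config hash, seeds, versions, input/output checksums) makes checkable.

## Known limitations

* The analytic CLR edge P is a convenient monotone score, not a
  calibrated tail probability; use the permutation mode when calibrated
  edge significance matters.
* The empirical enrichment P cannot go below 1/(n_sets + 1); the normal
  approximation extrapolates and should be labeled as such wherever
  reported.
* The eSNP significance rule (BH FDR < 0.05 over cis pairs) is a
  config-exposed choice; reference eQTL catalogs use a variety of
  thresholds.
* Group-mean imputation understates between-imputation variance
  relative to full multiple imputation; the stochastic mode restores
  spread but is a single draw.
* With 38 samples, |r|-based similarities have a substantial null
  floor; hub degrees in the retained network are informative about
  planted module sizes only when module effects are strong relative to
  that floor.
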