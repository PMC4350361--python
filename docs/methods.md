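# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic data does and does not emulate, and the places
where the design was genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention; GTF's 1-based inclusive coordinates are converted at the I/O
boundary in both directions, so conversion errors can only occur in one
place. The TSS is `start` on the + strand and `end − 1` on the − strand.
Gencode biotypes collapse onto a binary coding/lncRNA scheme through a
user-overridable table; biotypes missing from the table fall into the
non-coding bucket. Genes on unplaced contigs are kept — filtering is the
caller's decision. narrowPeak summit offsets are used when present and
non-negative, otherwise the summit falls back to the interval midpoint;
out-of-interval offsets are clamped with a warning.

## Expression and differential calling

CPM is plain within-sample normalization: no TMM, quantile or batch
adjustment. The pseudocount for log₂CPM defaults to 0.5 and is
configurable. The detection filter removes genes with fewer than 5 counts
in their lowest sample; "expressed in a condition" means ≥5 reads in every
replicate of that condition (both thresholds configurable).

The DE caller is a self-contained negative-binomial exact test:

1. Counts are equalized to the geometric-mean library size (rounded).
   User-supplied library sizes act as relative size factors — only their
   ratios matter — so globally rescaling the vector changes nothing.
2. One common dispersion is estimated across genes by a ratio-of-sums
   method of moments on within-condition residuals (Var = μ + φμ², clipped
   at zero). There is no gene-wise or trended dispersion and no
   empirical-Bayes shrinkage; with ≥3 replicates and thousands of genes the
   pooled estimate is accurate (on Poisson data it lands below 10⁻⁴).
3. Per gene, the split of the equalized counts between conditions is
   tested conditional on their total, using the fact that a sum of n iid
   NB(μ, φ) variables is NB(nμ, φ/n); the two-sided p-value sums all
   splits at most as probable as the observed one. In the φ→0 limit the
   conditional distribution is binomial.

Significance follows the raw-scale rule — condition-mean CPM ratio above
2-fold and raw P < 10⁻³ — with BH FDR reported for context but not
thresholded. The fold change is computed on mean CPM with the pseudocount,
not on a fitted coefficient.

Known limitation: with CPM-only normalization, a strongly asymmetric mass
of regulation (e.g. 40% of genes regulated with more induced than repressed
RNA) shifts the library totals and makes unregulated genes appear
oppositely regulated (composition bias). The default synthetic bundle
deliberately shows this; the operating-characteristics tests use planted
fractions of 10% or pure nulls, where the bias is negligible.

Validation candidates are genes that are significantly upregulated more
than 8-fold, detected with more than 5 reads in every sample (strict
inequality), and MYC-bound within 500 bp of the TSS; the occupancy input
must have been computed at that window or the call errors out, because a
mismatched window silently changes the criterion.

## Promoter occupancy and bidirectional classification

Distances are summit-to-TSS (the summit being the sharpest point estimate
of a binding event), signed positive downstream in the gene's direction of
transcription, and the binding window (default 1 kb) is inclusive at the
edge. Nearest-summit ties break toward the smaller coordinate. Genes on
chromosomes without peaks are unbound with an undefined distance.

A bidirectional promoter is a − strand gene and a + strand gene whose TSS
face away from each other at most 1 kb apart (inclusive), with neither TSS
inside the other gene's body. The 1 kb default is the conventional
divergent-promoter scale; it is configurable. Each gene joins at most one
pair — candidates are accepted greedily by smallest gap, ties broken by
leftmost coordinate — so dense loci cannot double-count promoters. The
promoter is MYC-bound when either TSS is bound (one shared binding event
serves both genes).

Classification: 0 expressed transcripts → no transcription; 1 →
unidirectional, regulated or not by that gene's DE call; 2 → bidirectional:
concordant when both genes are significant in the same direction,
unregulated when neither is significant, discordant otherwise (opposite
directions, or exactly one responder). The six categories partition the
pair total by construction. "Discordant" could also be read as expression
asymmetry between the two directions rather than DE disagreement; the
module exposes `expression_asymmetry` (|Δ mean log₂CPM| of the pair) for
that alternative reading, but the categorical definition is primary.

TSS profiles are binned mean coverage in [TSS − flank, TSS + flank)
(defaults 2 kb / 50 bp), reversed on the − strand so transcription always
runs rightward, rows ordered by an expression key.

## Polyadenylation discrimination

Features are per condition: x = mean log₂CPM over ribo-depleted samples,
y = the same over poly-A samples. The detection filter for this module is
applied on the ribo-depleted samples only: the ribo library sees every
transcript, whereas filtering on poly-A counts would remove exactly the
non-polyadenylated genes the classifier exists to find.

The discriminant is the classical two-class Fisher rule — pooled
within-class covariance, w = Σ⁻¹(μ_polyA − μ_non), threshold at the
midpoint of the projected class means shifted by the log prior ratio.
Priors default to equal because the genomic class balance is extreme
(sub-percent for coding, ~20% for lncRNA) and rarely matches the training
set; they are configurable. Training is on coding transcripts with known
status, and the trained rule is applied to all genes, so lncRNA calls are
out-of-class generalization. Per-condition calls are merged conservatively:
non-polyA only when called non-polyA in every condition the gene was
detected in. Degenerate training inputs (coincident class means, singular
or near-singular pooled covariance, fewer than two examples in a class)
raise instead of returning an unusable rule.

`fit_linear` is ordinary least squares (scipy) with R² = 1 − SS_res/SS_tot
and the slope's two-sided t-test; it quantifies the overall agreement of
the two library preps.

## Kinetics and qPCR

Half-life per time point is t·ln2/(ln N₀ − ln N); the summary is the
arithmetic mean over valid points. N₀ is the abundance at t = 0
(pre-shutoff); when no t = 0 measurement exists the earliest point can be
designated baseline. Points with N ≥ N₀ would give non-positive
denominators; they are excluded from the mean and counted in the output
rather than producing negative half-lives. A log-linear regression
estimator (slope of ln N on t through ln N₀) is reported alongside as an
alternative, but the per-point mean is the primary summary. Estimates for
slow transcripts are intrinsically noise-sensitive: by the early time
points little decay has occurred, so the per-point denominator is a small
difference of logs.

qPCR assumes amplification efficiency 2 (an efficiency-correction hook
exists but is off by default). ΔCq = Cq_target − mean(Cq_refs); averaging
reference Cqs is algebraically identical to normalizing to the geometric
mean of reference quantities at efficiency 2. ΔΔCq subtracts the
calibrator sample, whose fold is therefore exactly 1. Nuclear run-on data
use the identical arithmetic with a per-reaction spike-in as the sole
reference; because the spike is not transcribed by the cells, global
transcriptional amplification shifts every cellular target relative to it
and survives into the folds, where cellular reference genes would cancel
it.

## Synthetic data

The generator emulates a tet-off MYC induction experiment: two MYC states
in triplicate, a global amplification factor (default 2, a free parameter —
the real effect is reported only qualitatively) multiplying every gene's
expected molecules in the high state, planted up/down regulation
(default 40% of genes, |log₂FC| uniform on [1.5, 4], the >2-fold scale of
the system under study), MYC peaks with summits N(TSS, 150 bp) truncated at
±500 bp plus intergenic decoys ≥5 kb from any TSS, divergent lncRNA pairs
with TSS gaps uniform on [50, 900] bp, a non-polyadenylated subset (18% of
lncRNAs, 0.6% of coding — the coding fraction exists so that a
coding-trained discriminant has both classes to learn from) whose poly-A
library signal is a 2% residual rather than zero (the classifier should
face a non-separable problem), and exponential decay series with
log-uniform half-lives on [20, 240] min sampled at 30/60/120/240 min under
mean-preserving lognormal noise.

Counts are negative binomial with a single common dispersion (default
0.05); gene means are lognormal (median 150, σ_ln = 1). Per-sample size
factors are drawn first (lognormal, σ = 0.1), then counts sampled. By
default expected totals are equalized across samples (equal sequencing
depth), which is why CPM masks the amplification factor; switching
`equalize_depth` off emits per-cell-proportional counts for spike-in-style
designs. Everything runs off one integer seed through numpy's PCG64;
fixed seed means byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: gene-wise or trended dispersions, GC/length
biases, multimapping and counting ambiguity, isoform structure, correlated
genes, batch effects, and real ChIP background. Recovery rates on this
synthetic data are upper bounds for real experiments.

## Pipeline

The `run` orchestration executes filter → CPM/heatmap → DE → occupancy →
validation candidates → bidirectional classification → overlap (when ≥2
cell lines are present) → poly-A (when dual-library data and training
labels are present) → kinetics (when a decay table is present). Stages
write plain TSVs; the JSON summary is re-derivable from them, and the
manifest records package version, seed, thresholds and SHA-256 input
checksums. Default problem size (~2,500 genes, 12 samples) runs in a few
seconds on one CPU. Missing required inputs fail before any computation;
a stage failure aborts with the stage name.
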