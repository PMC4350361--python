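# lncmyc

Analysis toolkit for studying how the MYC transcription factor regulates the
long non-coding transcriptome. It is aimed at computational biologists who
have gene-level read counts from high/low-MYC RNA-seq experiments (plus,
optionally, MYC ChIP-seq peaks, paired poly-A/ribo-depleted libraries,
transcription-shutoff time courses and qPCR Cq tables) and want the whole
downstream analysis — normalization, differential calling, promoter
occupancy, divergent-promoter classification, polyadenylation status,
transcript kinetics — as tested, reusable, deterministic code. A bundled
synthetic-data generator with planted ground truth makes every stage
testable without any sequencing data.

## What it computes

**Expression.** Counts are normalized to counts per million
(CPM<sub>s,g</sub> = 10⁶ · n<sub>s,g</sub> / Σ<sub>g'</sub> n<sub>s,g'</sub>),
log₂-transformed with a pseudocount, and row-centered for display:
log2FC<sub>s,g</sub> = log2CPM<sub>s,g</sub> − (1/N)Σ<sub>s'</sub>log2CPM<sub>s',g</sub>.
Genes with fewer than 5 counts in their lowest sample are filtered.
Differential expression between MYC states uses a negative-binomial exact
test: counts are equalized to a common library size, a single common
dispersion φ is estimated across genes by method of moments
(Var = μ + φμ²), and each gene's high/low split is tested conditional on
its total (the sum of n iid NB(μ, φ) variables is NB(nμ, φ/n)). A gene is
called regulated when its condition-mean CPM ratio exceeds 2-fold in either
direction and the raw P < 10⁻³ (BH-adjusted FDR is reported alongside).

**Promoters.** Each gene's strand-aware TSS is assigned its nearest ChIP
peak summit; it is MYC-bound when |summit − TSS| ≤ 1 kb. Divergent
(head-to-head) gene pairs with TSS ≤ 1 kb apart define bidirectional
promoters, classified into six categories by how many of the two
transcripts are expressed (≥5 reads in every replicate of a condition) and
whether the expressed ones respond to MYC concordantly or discordantly.
Binned TSS coverage profiles and cross-cell-line expressed-set overlaps
round out the module.

**Polyadenylation.** Per gene, the features (mean log₂CPM in ribo-depleted
samples, mean log₂CPM in poly-A samples) separate polyadenylated
transcripts (on the diagonal) from non-polyadenylated ones (depleted in the
poly-A library). A two-class Fisher linear discriminant
w = Σ<sub>pooled</sub>⁻¹(μ_polyA − μ_non) is trained on coding transcripts
of known status and applied to all genes; the consensus non-polyA call
requires the non-polyA class in every condition tested.

**Kinetics and qPCR.** After transcription shutoff, abundance decays as
N(t) = N₀·2^(−t/t½), so each time point gives t½ = t·ln2/(ln N₀ − ln N);
the reported half-life is the mean over valid points (apparent increases
are excluded and counted). Relative qPCR expression uses 2^(−ΔΔCq) with
the arithmetic mean of reference Cqs (the geometric mean of reference
quantities at efficiency 2); nuclear run-on data use the same arithmetic
with a spike-in reference, which preserves global transcriptional
amplification that cellular references would cancel.

## Worked example

`examples/04_polyadenylation.py` simulates 1,200 coding and 1,400 lncRNA
genes with 18% of the lncRNAs planted non-polyadenylated (0.6% of coding),
dual-library triplicates, trains the discriminant on the coding genes and
classifies everything:

```
ribo vs poly-A linear fit: slope=0.97, R^2=0.41, n=2600
lncRNA called non-polyA:   18.0%  (planted 18.0%)
coding called non-polyA:   0.58%
```

The linear fit shows the overall agreement between the two library preps;
the recovered lncRNA fraction matches the planted 18% even though the
classifier never saw a lncRNA during training, and the coding call rate
stays at the planted 0.6% scale. The other scripts in `examples/` walk
through differential expression (`01`), TSS occupancy (`02`),
bidirectional-promoter classification (`03`), kinetics/qPCR (`05`) and the
end-to-end pipeline (`06`) in the same style.

## Command line

Every stage is also a subcommand of the `lncmyc` CLI (`simulate`, `de`,
`promoters`, `polya`, `halflife`, `qpcr`, `overlap`, `run`), reading and
writing plain TSV/GTF/narrowPeak/bedGraph files. `lncmyc run` executes all
applicable stages from one YAML config and writes per-stage TSVs, a JSON
summary and a run manifest (seed, thresholds, input checksums); identical
config and seed give byte-identical outputs.

```sh
lncmyc simulate --seed 1 --outdir bundle
lncmyc run --annotation bundle/annotation.gtf --peaks bundle/peaks.narrowPeak \
    --counts bundle/counts.tsv --metadata bundle/samples.tsv --outdir results
```

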