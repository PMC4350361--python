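"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of a MYC shutoff experiment in a
tet-off B-cell system: triplicate RNA-seq libraries under high and low MYC,
a global transcriptional-amplification factor acting on all genes in the
high-MYC state, a planted set of up/down-regulated genes, MYC peaks enriched
near TSS, divergent (head-to-head) gene pairs sharing a promoter, a subset
of lncRNAs lacking polyadenylation (visible in ribo-depleted but not poly-A
libraries), and exponential decay series with known half-lives.

Everything is driven by one integer seed through numpy's PCG64 generator;
a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .models import CODING, HIGH_MYC, LNCRNA, LOW_MYC, POLYA, RIBO, CountMatrix, GeneModel, Peak, SampleMeta

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment.

    Fractions refer to the gene class they are named for; ``frac_non_polya``
    applies to lncRNAs (the paper-scale 18%), ``frac_non_polya_coding`` to
    coding genes (the 0.6% scale) so that a coding-only training set still
    contains both polyadenylation classes.
    """

    n_coding: int = 1500
    n_lncrna: int = 1000
    frac_regulated: float = 0.4
    frac_bidirectional_pairs: float = 0.2
    frac_non_polya: float = 0.18
    frac_non_polya_coding: float = 0.006
    frac_bound_coding: float = 0.67
    frac_bound_lncrna: float = 0.48
    bound_boost_regulated: float = 0.2
    effect_log2fc: tuple[float, float] = (1.5, 4.0)  # |log2FC| range for regulated genes
    replicates: int = 3
    amplification: float = 2.0   # global high-MYC RNA-per-cell multiplier
    dispersion: float = 0.05     # common NB dispersion
    mu_median: float = 150.0     # median expected count per gene
    mu_sigma: float = 1.0        # sd of ln(mu); 0 gives a constant mu
    polya_residual: float = 0.02  # poly-A library signal of non-polyA genes
    libsize_sigma: float = 0.1   # lognormal spread of per-sample size factors
    equalize_depth: bool = True  # emulate equal sequencing depth (True) or per-cell counts (False)
    summit_sigma: float = 150.0  # sd of peak summit around the TSS, bp
    summit_max_offset: int = 500
    peak_halfwidth: int = 250
    n_decoy_peaks: int = 50
    gene_length: tuple[int, int] = (500, 5000)
    intergenic_gap: tuple[int, int] = (2000, 8000)
    pair_tss_gap: tuple[int, int] = (50, 900)
    half_life_range: tuple[float, float] = (20.0, 240.0)  # minutes, log-uniform
    chrom: str = "chrS"
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_regulated", "frac_bidirectional_pairs", "frac_non_polya",
                     "frac_non_polya_coding", "frac_bound_coding", "frac_bound_lncrna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_coding < 0 or self.n_lncrna < 0:
            raise ValueError("gene counts must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.amplification < 1:
            raise ValueError("amplification_factor must be >= 1")


@dataclass
class SimTruth:
    """Planted per-gene ground truth plus the per-simulation parameters."""

    genes: pd.DataFrame  # indexed by gene_id
    amplification: float
    dispersion: float
    seed: int
    polya_residual: float = SimConfig.polya_residual
    libsize_sigma: float = SimConfig.libsize_sigma
    equalize_depth: bool = SimConfig.equalize_depth

    def to_tsv(self, path: str | Path) -> None:
        df = self.genes.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, amplification: float = np.nan,
                 dispersion: float = np.nan, seed: int = -1) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", index_col=0)
        for col in ("myc_bound", "polyadenylated"):
            df[col] = df[col].astype(bool)
        return cls(df, amplification, dispersion, seed)


def simulate_annotation(cfg: SimConfig) -> tuple[list[GeneModel], SimTruth]:
    """Lay genes on a synthetic chromosome and draw all per-gene truth.

    Divergent pairs (lncRNA-lncRNA, minus-then-plus strand, TSS gap drawn
    from ``pair_tss_gap``) are planted first; all other genes are placed
    singly with intergenic gaps large enough that no unplanned divergent
    pair falls within the conventional 1 kb window.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pairs = int(cfg.frac_bidirectional_pairs * cfg.n_lncrna) // 2

    ids = [f"LNC{i:05d}" for i in range(cfg.n_lncrna)] + [f"PC{i:05d}" for i in range(cfg.n_coding)]
    biotypes = [LNCRNA] * cfg.n_lncrna + [CODING] * cfg.n_coding
    order = rng.permutation(len(ids))

    # first 2*n_pairs lncRNAs (by original index) form the divergent pairs
    pair_members = set(range(2 * n_pairs))
    units: list[tuple[int, ...]] = [(2 * i, 2 * i + 1) for i in range(n_pairs)]
    units += [(int(j),) for j in order if int(j) not in pair_members]
    rng.shuffle(units)

    genes: list[GeneModel] = []
    pair_ids = {}
    pos = int(rng.integers(*cfg.intergenic_gap))
    for unit in units:
        if len(unit) == 2:
            ia, ib = unit
            la = int(rng.integers(*cfg.gene_length))
            lb = int(rng.integers(*cfg.gene_length))
            gap = int(rng.integers(cfg.pair_tss_gap[0], cfg.pair_tss_gap[1] + 1))
            # gene_a transcribes leftward (tss at its right end), gene_b rightward
            a = GeneModel(ids[ia], biotypes[ia], cfg.chrom, "-", pos, pos + la)
            start_b = a.tss + gap
            b = GeneModel(ids[ib], biotypes[ib], cfg.chrom, "+", start_b, start_b + lb)
            genes += [a, b]
            pid = f"pair_{len(pair_ids) // 2:04d}"
            pair_ids[ids[ia]] = pid
            pair_ids[ids[ib]] = pid
            pos = b.end + int(rng.integers(*cfg.intergenic_gap))
        else:
            (i,) = unit
            length = int(rng.integers(*cfg.gene_length))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(ids[i], biotypes[i], cfg.chrom, strand, pos, pos + length))
            pos = pos + length + int(rng.integers(*cfg.intergenic_gap))

    if cfg.chrom_length is not None and genes and pos > cfg.chrom_length:
        raise ValueError(
            f"cannot pack {len(genes)} genes into chrom_length={cfg.chrom_length}; "
            f"needs about {pos} bp — increase chrom_length or reduce gene count"
        )

    n = len(genes)
    gid = [g.gene_id for g in genes]
    bt = pd.Series([g.biotype for g in genes], index=gid)

    regulation = np.array([NONE] * n, dtype=object)
    effect = np.zeros(n)
    reg_idx = rng.choice(n, size=int(round(cfg.frac_regulated * n)), replace=False) if n else np.array([], int)
    half = len(reg_idx) // 2
    lo, hi = cfg.effect_log2fc
    for k, i in enumerate(reg_idx):
        mag = float(rng.uniform(lo, hi))
        if k < half:
            regulation[i], effect[i] = UP, mag
        else:
            regulation[i], effect[i] = DOWN, -mag

    p_bound = np.where(bt.values == CODING, cfg.frac_bound_coding, cfg.frac_bound_lncrna)
    p_bound = np.minimum(1.0, p_bound + np.where(regulation != NONE, cfg.bound_boost_regulated, 0.0))
    myc_bound = rng.random(n) < p_bound

    polyadenylated = np.ones(n, dtype=bool)
    for biotype, frac in ((LNCRNA, cfg.frac_non_polya), (CODING, cfg.frac_non_polya_coding)):
        idx = np.flatnonzero(bt.values == biotype)
        k = int(round(frac * len(idx)))
        if k:
            polyadenylated[rng.choice(idx, size=k, replace=False)] = False

    log_mu = np.log(cfg.mu_median) + cfg.mu_sigma * rng.standard_normal(n)
    mu = np.exp(log_mu)
    t_lo, t_hi = cfg.half_life_range
    half_life = np.exp(rng.uniform(np.log(t_lo), np.log(t_hi), size=n))

    truth = pd.DataFrame(
        dict(
            biotype=bt.values,
            strand=[g.strand for g in genes],
            tss=[g.tss for g in genes],
            regulation=regulation,
            effect=effect,
            myc_bound=myc_bound,
            polyadenylated=polyadenylated,
            mu=mu,
            half_life_min=half_life,
            pair_id=[pair_ids.get(g, "") for g in gid],
        ),
        index=pd.Index(gid, name="gene_id"),
    )
    return genes, SimTruth(truth, cfg.amplification, cfg.dispersion, cfg.seed,
                           cfg.polya_residual, cfg.libsize_sigma, cfg.equalize_depth)


def make_design(replicates: int = 3, cell_line: str = "sim1",
                libraries: Sequence[str] = (RIBO, POLYA)) -> list[SampleMeta]:
    """Fully crossed condition x library x replicate design."""
    design = []
    for lib in libraries:
        tag = "ribo" if lib == RIBO else "polyA"
        for cond, ctag in ((HIGH_MYC, "high"), (LOW_MYC, "low")):
            for r in range(1, replicates + 1):
                design.append(SampleMeta(f"{cell_line}_{tag}_{ctag}_{r}", cond, lib, cell_line, r))
    return design


def simulate_counts(annotation: Sequence[GeneModel], truth: SimTruth,
                    design: Sequence[SampleMeta], seed: int | None = None) -> CountMatrix:
    """Sample NB counts for the design from the planted truth.

    Expected counts: mu_g, times 2^effect in the high-MYC condition for
    regulated genes, times the amplification factor for every gene in
    high-MYC, and reduced to ``polya_residual`` of the ribo signal in poly-A
    libraries for non-polyadenylated genes.  Per-sample size factors are
    drawn first, then counts sampled.
    """
    conditions = {s.condition for s in design}
    if len(conditions) < 2:
        raise ValueError("design must include both MYC conditions")
    for cond in conditions:
        for lib in {s.library for s in design}:
            n = sum(1 for s in design if s.condition == cond and s.library == lib)
            if 0 < n < 2:
                raise ValueError(f"need >=2 replicates per condition per library, got {n} for {cond}/{lib}")

    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    df = truth.genes
    mu = df["mu"].to_numpy()
    effect = df["effect"].to_numpy()
    non_polya = ~df["polyadenylated"].to_numpy()
    disp = truth.dispersion
    residual = truth.polya_residual

    size_factors = np.exp(rng.normal(0.0, truth.libsize_sigma, size=len(design)))
    expected = np.empty((len(mu), len(design)))
    for j, s in enumerate(design):
        e = mu.copy()
        if s.condition == HIGH_MYC:
            e = e * np.exp2(effect) * truth.amplification
        if s.library == POLYA:
            e = np.where(non_polya, e * residual, e)
        expected[:, j] = e
    if truth.equalize_depth and expected.size:
        totals = expected.sum(axis=0)
        expected *= totals.mean() / totals
    expected *= size_factors

    if disp < 1e-8:
        counts = rng.poisson(expected)
    else:
        r = 1.0 / disp
        p = r / (r + expected)
        counts = rng.negative_binomial(r, p)
    cdf = pd.DataFrame(counts, index=df.index.copy(), columns=[s.name for s in design])
    return CountMatrix(cdf, list(design))


def simulate_peaks(annotation: Sequence[GeneModel], truth: SimTruth,
                   cfg: SimConfig | None = None, seed: int | None = None) -> list[Peak]:
    """One peak per MYC-bound gene plus intergenic decoys.

    Summits are drawn N(tss, summit_sigma) truncated to +/- summit_max_offset;
    peaks at regulated bound genes carry higher scores.  Decoys are placed
    beyond the last gene, at least 5 kb from any TSS.
    """
    cfg = cfg or SimConfig(seed=truth.seed)
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    df = truth.genes
    peaks: list[Peak] = []
    k = 0
    for g in annotation:
        row = df.loc[g.gene_id]
        if not bool(row["myc_bound"]):
            continue
        off = float(rng.normal(0.0, cfg.summit_sigma))
        while abs(off) > cfg.summit_max_offset:
            off = float(rng.normal(0.0, cfg.summit_sigma))
        summit = int(round(g.tss + off))
        score = float(rng.uniform(5, 10))
        if row["regulation"] != NONE:
            score *= 2.0
        start = max(0, summit - cfg.peak_halfwidth)
        peaks.append(Peak(g.chrom, start, summit + cfg.peak_halfwidth + 1, summit,
                          round(score, 3), f"peak_{k:05d}"))
        k += 1
    tail = (max(g.end for g in annotation) if annotation else 0) + 6000
    for d in range(cfg.n_decoy_peaks):
        summit = tail + d * 2000
        peaks.append(Peak(cfg.chrom, summit - cfg.peak_halfwidth, summit + cfg.peak_halfwidth + 1,
                          summit, round(float(rng.uniform(1, 3)), 3), f"peak_{k:05d}"))
        k += 1
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


DEFAULT_DECAY_TIMES = (30.0, 60.0, 120.0, 240.0)


def simulate_decay(truth: SimTruth, times: Sequence[float] = DEFAULT_DECAY_TIMES,
                   cv: float = 0.1, gene_ids: Sequence[str] | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Exponential decay series N(t) = 2^(-t/t_half) with lognormal noise.

    Emulates an Actinomycin D transcription-shutoff time course; baseline
    abundance at t=0 is 1.  ``cv`` is the coefficient of variation of the
    multiplicative noise (0 gives noiseless series).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    times = np.asarray(list(times), dtype=float)
    if (times <= 0).any():
        raise ValueError("times must be strictly positive")
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    gene_ids = list(gene_ids) if gene_ids is not None else list(truth.genes.index)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    rows = []
    for g in gene_ids:
        t_half = float(truth.genes.loc[g, "half_life_min"])
        clean = np.exp2(-times / t_half)
        noise = np.exp(sigma * rng.standard_normal(len(times))) if cv > 0 else 1.0
        for t, n in zip(times, clean * noise):
            rows.append((g, float(t), float(n)))
    return pd.DataFrame(rows, columns=["gene_id", "time_min", "abundance"])


def coverage_from_peaks(peaks: Sequence[Peak]) -> dict[str, np.ndarray]:
    """Flat per-peak coverage track (value = score) as a bedGraph surrogate."""
    cov: dict[str, list] = {}
    for p in peaks:
        cov.setdefault(p.chrom, []).append((p.start, p.end, p.score))
    return {c: np.array(sorted(v), dtype=float) for c, v in cov.items()}


def write_bundle(cfg: SimConfig, outdir: str | Path,
                 decay_genes: int = 10, decay_cv: float = 0.1) -> dict[str, Path]:
    """Generate the full synthetic bundle and write it beside its truth.

    Files: annotation.gtf, peaks.narrowPeak, coverage.bedgraph, counts.tsv,
    samples.tsv, decay.tsv, truth.tsv, config.yaml.  Deterministic for a
    fixed cfg.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_annotation(cfg)
    design = make_design(cfg.replicates)
    counts = simulate_counts(genes, truth, design)
    peaks = simulate_peaks(genes, truth, cfg)
    decay_ids = list(truth.genes.index[: min(decay_genes, len(truth.genes))])
    decay = simulate_decay(truth, cv=decay_cv, gene_ids=decay_ids)

    paths = {
        "annotation": outdir / "annotation.gtf",
        "peaks": outdir / "peaks.narrowPeak",
        "coverage": outdir / "coverage.bedgraph",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "decay": outdir / "decay.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    lio.write_gene_models(genes, paths["annotation"])
    lio.write_peaks(peaks, paths["peaks"])
    lio.write_bedgraph(coverage_from_peaks(peaks), paths["coverage"])
    lio.write_counts(counts, paths["counts"], paths["samples"])
    decay.to_csv(paths["decay"], sep="\t", index=False, lineterminator="\n", float_format="%.8g")
    truth.to_tsv(paths["truth"])
    with open(paths["config"], "w", newline="\n") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    return paths
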