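"""End-to-end orchestration: filter -> CPM -> DE -> occupancy ->
bidirectional classification -> cross-line overlap -> poly-A -> kinetics,
driven by one config, writing every stage's TSV plus a summary and a
machine-readable run manifest.

Stages whose inputs are absent (no dual-library samples, no decay table,
single cell line) are skipped and recorded as such in the summary; a stage
failure aborts with the stage name.  All outputs are deterministic for
fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, expression, io as lio, kinetics, polya, promoters
from .models import CODING, HIGH_MYC, LNCRNA, LOW_MYC, POLYA, RIBO


@dataclass
class PipelineConfig:
    annotation: str = ""
    peaks: str = ""
    counts: str = ""
    metadata: str = ""
    coverage: str | None = None
    decay: str | None = None
    cq: str | None = None
    polya_labels: str | None = None  # gene_id<TAB>label training table; synthetic truth works
    outdir: str = "lncmyc_out"
    fc_threshold: float = 2.0
    p_threshold: float = 1e-3
    min_count: int = 5
    tss_window: int = 1000
    validation_window: int = 500
    validation_fc: float = 8.0
    bidirectional_gap: int = 1000
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "min_count", "tss_window",
                     "validation_window", "bidirectional_gap"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p_threshold < 0 or self.p_threshold > 1:
            raise ValueError("p_threshold must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index_label: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_label
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.8g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all applicable stages; returns the summary dict (also written)."""
    for name in ("annotation", "peaks", "counts", "metadata"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")
    for name in ("coverage", "decay", "cq", "polya_labels"):
        p = getattr(cfg, name)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} missing: {p}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    def stage(name):
        def deco(fn):
            try:
                fn()
                summary["stages"][name] = "ok"
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    genes = lio.read_gene_models(cfg.annotation)
    peaks = lio.read_peaks(cfg.peaks)
    counts = lio.read_counts(cfg.counts, cfg.metadata)
    biotypes = pd.Series({g.gene_id: g.biotype for g in genes})

    # DE runs on the ribo-depleted libraries of the first cell line present
    cell_lines = sorted({s.cell_line for s in counts.samples})
    ribo = counts.select(library=RIBO, cell_line=cell_lines[0])
    filtered = expression.filter_low(ribo, cfg.min_count)

    state: dict = {}

    @stage("expression")
    def _expr():
        state["heatmap"] = expression.heatmap_matrix(filtered, cfg.pseudocount)
        _write(state["heatmap"], outdir / "heatmap_matrix.tsv")
        de = expression.call_de(filtered, cfg.fc_threshold, cfg.p_threshold, cfg.pseudocount)
        state["de"] = de
        _write(de, outdir / "de_results.tsv")

    @stage("occupancy")
    def _occ():
        occ = promoters.assign_peak_occupancy(genes, peaks, cfg.tss_window)
        state["occupancy"] = occ
        rows = pd.DataFrame(
            [dict(gene_id=o.gene_id, tss=o.tss, nearest_peak=o.nearest_peak or "",
                  distance="" if o.distance is None else o.distance, bound=o.bound)
             for o in occ]).set_index("gene_id")
        _write(rows, outdir / "tss_occupancy.tsv")
        summary["bound_fraction"] = {}
        for bt in (CODING, LNCRNA):
            b, t, f = promoters.bound_fraction(occ, genes, bt)
            summary["bound_fraction"][bt] = dict(bound=b, total=t, fraction=round(f, 6) if t else None)

    @stage("validation_candidates")
    def _val():
        occ500 = promoters.assign_peak_occupancy(genes, peaks, cfg.validation_window)
        cand = expression.select_validation_candidates(
            state["de"], filtered, occ500, cfg.validation_fc, cfg.min_count, cfg.validation_window)
        (outdir / "validation_candidates.txt").write_text("".join(f"{g}\n" for g in cand))
        summary["n_validation_candidates"] = len(cand)

    @stage("bidirectional")
    def _bidir():
        pairs = promoters.detect_bidirectional(genes, cfg.bidirectional_gap)
        expressed = (expression.expressed_genes(ribo, HIGH_MYC, cfg.min_count)
                     | expression.expressed_genes(ribo, LOW_MYC, cfg.min_count))
        occ_map = {o.gene_id: o for o in state["occupancy"]}
        de_full = state["de"].reindex(
            state["de"].index.union(pd.Index(sorted(expressed))))
        de_full["significant"] = de_full["significant"].astype(object).where(
            de_full["significant"].notna(), False).astype(bool)
        de_full["direction"] = de_full["direction"].astype(object).where(
            de_full["direction"].notna(), "none")
        classified = [promoters.classify_bidirectional(p, expressed, de_full, occ_map)
                      for p in pairs]
        rows = pd.DataFrame(
            [dict(gene_a=p.gene_a, gene_b=p.gene_b, gap=p.gap, myc_bound=p.myc_bound,
                  n_expressed=p.n_expressed, category=p.category) for p in classified])
        rows.to_csv(outdir / "bidirectional_pairs.tsv", sep="\t", index=False, lineterminator="\n")
        summary["bidirectional"] = dict(
            n_pairs=len(classified),
            n_myc_bound=int(sum(p.myc_bound for p in classified)),
            categories=promoters.category_counts(classified),
        )

    if len(cell_lines) >= 2:
        @stage("overlap")
        def _overlap():
            sets = {}
            for cl in cell_lines:
                sub = counts.select(library=RIBO, cell_line=cl)
                sets[cl] = expression.expressed_genes(sub, min_count=cfg.min_count)
            table = promoters.expression_overlap(sets)
            table.to_csv(outdir / "expression_overlap.tsv", sep="\t", index=False, lineterminator="\n")
            summary["overlap"] = dict(
                n_union=table.attrs["n_union"],
                frac_all_lines=round(table.attrs["frac_all_lines"], 6),
                frac_exactly_one=round(table.attrs["frac_exactly_one"], 6),
            )
    else:
        summary["stages"]["overlap"] = "skipped (single cell line)"

    if cfg.coverage:
        @stage("profile")
        def _profile():
            cov = lio.read_bedgraph(cfg.coverage)
            mean_expr = expression.log2cpm(filtered.counts, cfg.pseudocount).mean(axis=1)
            prof = promoters.occupancy_profile(
                [g for g in genes if g.gene_id in mean_expr.index], cov,
                order_by=mean_expr.to_dict())
            _write(prof, outdir / "tss_profile.tsv")
    else:
        summary["stages"]["profile"] = "skipped (no coverage)"

    has_dual = {POLYA, RIBO} <= {s.library for s in counts.samples}
    if has_dual and cfg.polya_labels:
        @stage("polya")
        def _polya():
            labels = pd.read_csv(cfg.polya_labels, sep="\t", index_col=0).iloc[:, 0]
            line_counts = counts.select(cell_line=cell_lines[0])
            X, y = polya.training_features(line_counts, labels, LOW_MYC, cfg.min_count)
            disc = polya.train_lda(X, y)
            fits = {}
            for cond in (LOW_MYC, HIGH_MYC):
                feats = polya.extract_features(line_counts, cond, cfg.min_count)
                fit = polya.fit_linear(feats["ribo"], feats["polya"])
                fits[cond] = dict(slope=round(fit.slope, 6), r_squared=round(fit.r_squared, 6),
                                  p_value=fit.p_value, n=fit.n)
            calls = polya.classify_polya(disc, line_counts, (LOW_MYC, HIGH_MYC), cfg.min_count)
            _write(calls, outdir / "polya_calls.tsv")
            frac = polya.non_polya_fraction(calls, biotypes)
            summary["polya"] = dict(
                linear_fits=fits,
                non_polya_fraction={k: round(float(v), 6) for k, v in frac.items()},
            )
    else:
        summary["stages"]["polya"] = "skipped (no dual-library data or labels)"

    if cfg.decay:
        @stage("kinetics")
        def _kin():
            decay = lio.read_decay_table(cfg.decay)
            hl = kinetics.estimate_half_lives(decay)
            _write(hl, outdir / "half_lives.tsv")
            summary["half_life_minutes"] = {
                g: round(float(v), 3) for g, v in hl["half_life_min"].items()}
    else:
        summary["stages"]["kinetics"] = "skipped (no decay table)"

    de = state["de"]
    lnc = de.index.intersection(biotypes[biotypes == LNCRNA].index)
    summary["n_genes_annotated"] = len(genes)
    summary["n_genes_tested"] = int(len(de))
    summary["lncRNA"] = dict(
        detected=int(len(lnc)),
        up=int((de.loc[lnc, "direction"] == "up").sum()),
        down=int((de.loc[lnc, "direction"] == "down").sum()),
    )

    with open(outdir / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = dict(
        package="lncmyc", version=__version__, seed=cfg.seed,
        thresholds=dict(fc=cfg.fc_threshold, p=cfg.p_threshold, min_count=cfg.min_count,
                        tss_window=cfg.tss_window, validation_window=cfg.validation_window,
                        bidirectional_gap=cfg.bidirectional_gap),
        inputs={name: dict(path=str(getattr(cfg, name)), sha256=_sha256(getattr(cfg, name)))
                for name in ("annotation", "peaks", "counts", "metadata")
                if getattr(cfg, name)},
    )
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
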