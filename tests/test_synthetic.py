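"""The generator's construction rules, closed forms, and determinism."""

import numpy as np
import pandas as pd
import pytest

from lncmyc import io as lio
from lncmyc.models import HIGH_MYC, LOW_MYC, POLYA, RIBO
from lncmyc.promoters import detect_bidirectional
from lncmyc.synthetic import (
    SimConfig,
    make_design,
    simulate_annotation,
    simulate_counts,
    simulate_decay,
    simulate_peaks,
    write_bundle,
)


def cfg_with(**kw):
    base = dict(seed=5, n_coding=40, n_lncrna=40)
    base.update(kw)
    return SimConfig(**base)


class TestAnnotation:
    def test_empty_config_gives_empty_annotation(self):
        genes, truth = simulate_annotation(cfg_with(n_coding=0, n_lncrna=0))
        assert genes == [] and truth.genes.empty

    def test_all_lncrnas_paired(self):
        genes, truth = simulate_annotation(
            cfg_with(n_coding=0, n_lncrna=10, frac_bidirectional_pairs=1.0))
        pairs = detect_bidirectional(genes, max_gap=1000)
        assert len(pairs) == 5
        assert all(50 <= p.gap <= 900 for p in pairs)
        assert truth.genes["pair_id"].ne("").sum() == 10

    def test_planted_pairs_recorded_in_truth(self):
        genes, truth = simulate_annotation(cfg_with(frac_bidirectional_pairs=0.5))
        planted = truth.genes[truth.genes["pair_id"] != ""]
        found = detect_bidirectional(genes)
        found_genes = {g for p in found for g in (p.gene_a, p.gene_b)}
        assert set(planted.index) <= found_genes

    def test_fixed_seed_gives_byte_identical_gtf(self, tmp_path):
        for d in ("a", "b"):
            genes, _ = simulate_annotation(cfg_with())
            lio.write_gene_models(genes, tmp_path / f"{d}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="chrom_length"):
            simulate_annotation(cfg_with(n_coding=500, n_lncrna=500, chrom_length=10_000))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="frac_regulated"):
            cfg_with(frac_regulated=1.5)


class TestCounts:
    def test_poisson_limit_variance_over_mean_near_one(self):
        # dispersion -> 0, no regulation, amplification 1: counts are Poisson
        cfg = cfg_with(n_coding=0, n_lncrna=400, frac_regulated=0.0, amplification=1.0,
                       dispersion=1e-10, mu_sigma=0.0, mu_median=200.0,
                       libsize_sigma=0.0, frac_non_polya=0.0)
        genes, truth = simulate_annotation(cfg)
        design = make_design(6, libraries=(RIBO,))
        cm = simulate_counts(genes, truth, design)
        vals = cm.counts.to_numpy(float)
        ratio = vals.var(axis=1, ddof=1) / vals.mean(axis=1)
        assert 0.9 < ratio.mean() < 1.1

    def test_planted_effect_ratio_matches_monte_carlo_interval(self):
        # recomputed oracle interval for effect +3, mu=500, 3 reps, disp 0.05:
        # median 8.0, 1st-99th pct about [5.1, 12.6] over 1,000 regulated genes
        design = make_design(3, libraries=(RIBO,))
        ratios = []
        for seed in range(250):
            cfg = SimConfig(seed=seed, n_coding=0, n_lncrna=4, frac_regulated=1.0,
                            effect_log2fc=(3.0, 3.0), amplification=1.0, dispersion=0.05,
                            mu_median=500.0, mu_sigma=0.0, libsize_sigma=0.0,
                            equalize_depth=False, frac_bidirectional_pairs=0.0,
                            frac_non_polya=0.0, frac_non_polya_coding=0.0)
            genes, truth = simulate_annotation(cfg)
            up = truth.genes.index[truth.genes["regulation"] == "up"]
            cm = simulate_counts(genes, truth, design)
            hi = cm.counts.loc[up, [s.name for s in design if s.condition == HIGH_MYC]].mean(axis=1)
            lo = cm.counts.loc[up, [s.name for s in design if s.condition == LOW_MYC]].mean(axis=1)
            ratios.extend((hi / lo).tolist())
        ratios = np.array(ratios)
        assert 7.0 < np.median(ratios) < 9.0
        assert 4.0 < np.percentile(ratios, 1) < 6.5
        assert 10.5 < np.percentile(ratios, 99) < 14.5

    def test_non_polya_genes_depleted_in_polya_library(self):
        cfg = cfg_with(n_coding=0, n_lncrna=200, frac_non_polya=0.5, mu_median=1000.0,
                       mu_sigma=0.0, frac_regulated=0.0, amplification=1.0,
                       libsize_sigma=0.0, equalize_depth=False)
        genes, truth = simulate_annotation(cfg)
        cm = simulate_counts(genes, truth, make_design(3))
        non = truth.genes.index[~truth.genes["polyadenylated"]]
        ribo_cols = [s.name for s in cm.samples if s.library == RIBO]
        pa_cols = [s.name for s in cm.samples if s.library == POLYA]
        ratio = cm.counts.loc[non, pa_cols].mean(axis=1) / cm.counts.loc[non, ribo_cols].mean(axis=1)
        assert ratio.mean() <= 0.05

    def test_cpm_masks_global_amplification(self):
        # with amplification > 1 the per-gene CPM ratio of unregulated genes
        # is still centered at 1 (within-sample normalization hides it)
        from lncmyc.expression import cpm

        cfg = cfg_with(n_coding=0, n_lncrna=400, frac_regulated=0.0, amplification=2.0,
                       mu_sigma=0.5, dispersion=0.01, frac_non_polya=0.0)
        genes, truth = simulate_annotation(cfg)
        cm = simulate_counts(genes, truth, make_design(3, libraries=(RIBO,)))
        tab = cpm(cm)
        hi = tab[[s.name for s in cm.samples if s.condition == HIGH_MYC]].mean(axis=1)
        lo = tab[[s.name for s in cm.samples if s.condition == LOW_MYC]].mean(axis=1)
        assert abs(np.log2(hi / lo).mean()) < 0.05

    def test_single_condition_design_rejected(self):
        genes, truth = simulate_annotation(cfg_with())
        design = [s for s in make_design(3) if s.condition == HIGH_MYC]
        with pytest.raises(ValueError, match="condition"):
            simulate_counts(genes, truth, design)


class TestPeaks:
    def test_no_bound_genes_no_decoys_gives_empty_list(self):
        cfg = cfg_with(frac_bound_coding=0.0, frac_bound_lncrna=0.0,
                       bound_boost_regulated=0.0, n_decoy_peaks=0)
        genes, truth = simulate_annotation(cfg)
        assert simulate_peaks(genes, truth, cfg) == []

    def test_bound_gene_summits_within_500bp_of_tss(self):
        cfg = cfg_with(n_decoy_peaks=0)
        genes, truth = simulate_annotation(cfg)
        peaks = simulate_peaks(genes, truth, cfg)
        tss = {g.gene_id: g.tss for g in genes}
        bound_tss = sorted(tss[g] for g in truth.genes.index[truth.genes["myc_bound"]])
        for p in peaks:
            assert min(abs(p.summit - t) for t in bound_tss) <= 500

    def test_fixed_seed_gives_identical_narrowpeak(self, tmp_path):
        cfg = cfg_with()
        for d in ("a", "b"):
            genes, truth = simulate_annotation(cfg)
            lio.write_peaks(simulate_peaks(genes, truth, cfg), tmp_path / f"{d}.np")
        assert (tmp_path / "a.np").read_bytes() == (tmp_path / "b.np").read_bytes()


class TestDecay:
    @pytest.mark.parametrize("t_half,t,expected", [(60.0, 60.0, 0.5),
                                                   (215.0, 215.0, 0.5),
                                                   (30.0, 240.0, 2.0 ** -8)])
    def test_noiseless_closed_form(self, t_half, t, expected):
        genes, truth = simulate_annotation(cfg_with(n_coding=1, n_lncrna=0))
        truth.genes["half_life_min"] = t_half
        d = simulate_decay(truth, times=[t], cv=0.0)
        assert d["abundance"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_negative_cv_rejected(self):
        _, truth = simulate_annotation(cfg_with(n_coding=1, n_lncrna=0))
        with pytest.raises(ValueError, match="cv"):
            simulate_decay(truth, cv=-0.1)

    def test_nonpositive_times_rejected(self):
        _, truth = simulate_annotation(cfg_with(n_coding=1, n_lncrna=0))
        with pytest.raises(ValueError, match="times"):
            simulate_decay(truth, times=[0.0, 30.0])


def test_bundle_is_deterministic(tmp_path):
    cfg = SimConfig(seed=42, n_coding=60, n_lncrna=40)
    p1 = write_bundle(cfg, tmp_path / "one")
    p2 = write_bundle(cfg, tmp_path / "two")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
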