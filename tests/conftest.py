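"""Shared fixtures and brute-force oracles.

The oracles deliberately use O(n*m) all-pairs scans or plain enumeration so
they stay independent of the sorted/searchsorted implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncmyc.models import (
    HIGH_MYC,
    LOW_MYC,
    RIBO,
    CountMatrix,
    GeneModel,
    Peak,
    SampleMeta,
)
from lncmyc.synthetic import SimConfig, make_design, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact synthetic bundle on disk, shared across tests."""
    from lncmyc.synthetic import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    # frac_non_polya_coding raised so the minority class still has a handful
    # of training examples at this reduced gene count
    cfg = SimConfig(seed=11, n_coding=150, n_lncrna=100, frac_non_polya_coding=0.04)
    paths = write_bundle(cfg, outdir)
    return cfg, paths


@pytest.fixture(scope="session")
def ribo_design():
    return make_design(3, libraries=(RIBO,))


def nb_count_matrix(rng, mu, design, dispersion=0.05, effects=None):
    """Direct NB sampler used as independent input for DE tests."""
    mu = np.asarray(mu, dtype=float)
    n = mu.size
    effects = np.zeros(n) if effects is None else np.asarray(effects, dtype=float)
    cols = {}
    for s in design:
        m = mu * np.exp2(effects) if s.condition == HIGH_MYC else mu
        if dispersion < 1e-12:
            cols[s.name] = rng.poisson(m)
        else:
            r = 1.0 / dispersion
            cols[s.name] = rng.negative_binomial(r, r / (r + m))
    df = pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n)])
    return CountMatrix(df, list(design))


def random_genes(rng, n, chroms=("chrA", "chrB"), span=200_000):
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 3000))
        genes.append(
            GeneModel(
                f"g{i:04d}",
                "lncRNA" if rng.random() < 0.5 else "coding",
                str(rng.choice(list(chroms))),
                "+" if rng.random() < 0.5 else "-",
                start,
                start + length,
            )
        )
    return genes


def random_peaks(rng, n, chroms=("chrA", "chrB"), span=200_000):
    peaks = []
    for i in range(n):
        summit = int(rng.integers(50, span))
        peaks.append(Peak(str(rng.choice(list(chroms))), summit - 50, summit + 51,
                          summit, float(rng.uniform(1, 10)), f"p{i:04d}"))
    return peaks


def oracle_nearest_peak(genes, peaks, window):
    """All-pairs nearest-summit scan; returns gene -> (summit, signed, bound)."""
    out = {}
    for g in genes:
        best = None
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            key = (abs(p.summit - g.tss), p.summit)
            if best is None or key < best:
                best = key
        if best is None:
            out[g.gene_id] = (None, None, False)
        else:
            signed = best[1] - g.tss
            if g.strand == "-":
                signed = -signed
            out[g.gene_id] = (best[1], signed, abs(signed) <= window)
    return out


def oracle_bidirectional(genes, max_gap):
    """All-pairs divergent-pair enumeration with the same greedy matching."""
    cands = []
    for a in genes:
        if a.strand != "-":
            continue
        for b in genes:
            if b.strand != "+" or b.chrom != a.chrom:
                continue
            gap = b.tss - a.tss
            if gap < 0 or gap > max_gap:
                continue
            if a.start <= b.tss < a.end or b.start <= a.tss < b.end:
                continue
            cands.append((gap, min(a.tss, b.tss), a.gene_id, b.gene_id))
    cands.sort()
    used, pairs = set(), set()
    for gap, _left, ga, gb in cands:
        if ga in used or gb in used:
            continue
        used.update((ga, gb))
        pairs.add((ga, gb, gap))
    return pairs


def oracle_venn(sets):
    """Plain enumeration of Venn-partition counts: pattern -> count."""
    lines = sorted(sets)
    counts = {}
    for g in set().union(*sets.values()):
        pat = tuple(g in sets[l] for l in lines)
        counts[pat] = counts.get(pat, 0) + 1
    return counts
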