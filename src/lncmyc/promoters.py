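"""Strand-aware TSS occupancy, divergent-promoter detection and
classification, TSS coverage profiles, and cross-cell-line expression
overlap.

Distances are summit-to-TSS and signed in the gene's direction of
transcription: positive values lie downstream of the TSS.  A gene is
"bound" when the nearest summit on its chromosome falls within the window
(inclusive at the edge).
"""

from __future__ import annotations

import warnings
from collections import Counter
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    BIDIR_CONCORDANT,
    BIDIR_DISCORDANT,
    BIDIR_UNREG,
    CATEGORIES,
    NO_TRANSCRIPTION,
    UNIDIR_REG,
    UNIDIR_UNREG,
    BidirectionalPromoter,
    GeneModel,
    Peak,
    TSSOccupancy,
)


def assign_peak_occupancy(genes: Sequence[GeneModel], peaks: Sequence[Peak],
                          window: int = 1000) -> list[TSSOccupancy]:
    """Nearest peak summit per TSS, per chromosome.

    Ties in |summit - tss| are broken toward the smaller summit coordinate.
    Genes on chromosomes without peaks are unbound with distance None.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    index: dict[str, tuple[np.ndarray, list[Peak]]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.summit)
        index[chrom] = (np.array([p.summit for p in plist]), plist)

    out: list[TSSOccupancy] = []
    for g in genes:
        if g.chrom not in index:
            out.append(TSSOccupancy(g.gene_id, g.tss, None, None, False, window))
            continue
        summits, plist = index[g.chrom]
        i = int(np.searchsorted(summits, g.tss))
        # candidates around the insertion point; scan left to prefer the
        # smaller summit on exact distance ties
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(plist):
                d = abs(int(summits[j]) - g.tss)
                if best is None or d < best[0] or (d == best[0] and summits[j] < summits[best[1]]):
                    best = (d, j)
        assert best is not None
        peak = plist[best[1]]
        signed = peak.summit - g.tss
        if g.strand == "-":
            signed = -signed
        out.append(TSSOccupancy(g.gene_id, g.tss, peak.name, int(signed),
                                abs(signed) <= window, window))
    return out


def bound_fraction(occupancy: Sequence[TSSOccupancy], genes: Sequence[GeneModel],
                   biotype: str) -> tuple[int, int, float]:
    """(bound, total, fraction) among genes of one biotype."""
    wanted = {g.gene_id for g in genes if g.biotype == biotype}
    occ = [o for o in occupancy if o.gene_id in wanted]
    if len(occ) < len(wanted):
        missing = wanted - {o.gene_id for o in occ}
        raise ValueError(f"occupancy missing for {len(missing)} {biotype} gene(s)")
    bound = sum(o.bound for o in occ)
    total = len(occ)
    return bound, total, (bound / total if total else float("nan"))


def detect_bidirectional(genes: Sequence[GeneModel], max_gap: int = 1000) -> list[BidirectionalPromoter]:
    """Divergent (head-to-head) gene pairs sharing a promoter region.

    A candidate pair is a - strand gene (a) and a + strand gene (b) whose
    TSS face away from each other with tss_b >= tss_a, separated by at most
    ``max_gap`` bp, with neither TSS inside the other gene's body.  Each
    gene joins at most one pair; candidates are accepted greedily by
    smallest gap, ties broken by leftmost coordinate.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    candidates: list[tuple[int, int, str, str]] = []
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.tss)
        minus = [g for g in glist if g.strand == "-"]
        plus = [g for g in glist if g.strand == "+"]
        plus_tss = np.array([g.tss for g in plus])
        for a in minus:
            lo = int(np.searchsorted(plus_tss, a.tss, side="left"))
            hi = int(np.searchsorted(plus_tss, a.tss + max_gap, side="right"))
            for b in plus[lo:hi]:
                gap = b.tss - a.tss
                if not (a.start <= b.tss < a.end) and not (b.start <= a.tss < b.end):
                    candidates.append((gap, min(a.tss, b.tss), a.gene_id, b.gene_id))

    candidates.sort()
    used: set[str] = set()
    pairs: list[BidirectionalPromoter] = []
    for gap, _left, ga, gb in candidates:
        if ga in used or gb in used:
            continue
        used.update((ga, gb))
        pairs.append(BidirectionalPromoter(ga, gb, gap))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def classify_bidirectional(pair: BidirectionalPromoter,
                           expressed: Mapping[str, bool] | set,
                           de: pd.DataFrame,
                           occupancy: Mapping[str, TSSOccupancy] | Sequence[TSSOccupancy]) -> BidirectionalPromoter:
    """Assign the promoter's functional category from expression and DE calls.

    0 expressed genes -> no transcription; 1 -> unidirectional, regulated or
    not by that gene's DE significance; 2 -> bidirectional: concordant when
    both genes are significant in the same direction, unregulated when
    neither is significant, discordant otherwise (directions differ, or
    exactly one gene responds).  The promoter is MYC-bound if either TSS is.
    """
    if not isinstance(occupancy, Mapping):
        occupancy = {o.gene_id: o for o in occupancy}
    is_expr = (lambda g: g in expressed) if isinstance(expressed, (set, frozenset)) else (lambda g: bool(expressed.get(g, False)))

    flags = [is_expr(pair.gene_a), is_expr(pair.gene_b)]
    n_expressed = sum(flags)
    bound = any(
        occupancy[g].bound for g in (pair.gene_a, pair.gene_b) if g in occupancy
    )

    def de_row(g: str):
        if g not in de.index:
            raise ValueError(f"expressed gene {g} missing from DE table")
        return de.loc[g]

    if n_expressed == 0:
        cat = NO_TRANSCRIPTION
    elif n_expressed == 1:
        g = pair.gene_a if flags[0] else pair.gene_b
        cat = UNIDIR_REG if bool(de_row(g)["significant"]) else UNIDIR_UNREG
    else:
        ra, rb = de_row(pair.gene_a), de_row(pair.gene_b)
        sa, sb = bool(ra["significant"]), bool(rb["significant"])
        if sa and sb:
            cat = BIDIR_CONCORDANT if ra["direction"] == rb["direction"] else BIDIR_DISCORDANT
        elif sa or sb:
            cat = BIDIR_DISCORDANT
        else:
            cat = BIDIR_UNREG
    return BidirectionalPromoter(pair.gene_a, pair.gene_b, pair.gap,
                                 myc_bound=bound, n_expressed=n_expressed, category=cat)


def category_counts(pairs: Sequence[BidirectionalPromoter]) -> dict[str, int]:
    """Counts per category over all classified pairs (they partition the total)."""
    c = Counter(p.category for p in pairs)
    return {cat: int(c.get(cat, 0)) for cat in CATEGORIES}


def expression_asymmetry(pair: BidirectionalPromoter, log2cpm_means: Mapping[str, float]) -> float:
    """|log2 expression ratio| of the two genes — the alternative reading of
    "discordant" as a preference for one direction over the other."""
    return abs(float(log2cpm_means[pair.gene_a]) - float(log2cpm_means[pair.gene_b]))


def occupancy_profile(genes: Sequence[GeneModel], coverage: Mapping[str, np.ndarray],
                      flank: int = 2000, bin_width: int = 50,
                      order_by: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Binned mean coverage in [tss - flank, tss + flank) per gene.

    Minus-strand profiles are reversed so transcription always runs
    rightward.  Rows are sorted by ``order_by`` (e.g. expression) descending
    when given.  ``coverage`` is chrom -> (start, end, value) rows, as from
    :func:`lncmyc.io.read_bedgraph`.
    """
    if (2 * flank) % bin_width != 0:
        raise ValueError("bin width must divide 2*flank")
    n_bins = 2 * flank // bin_width
    rows = {}
    warned: set[str] = set()
    for g in genes:
        win = np.zeros(2 * flank)
        cov = coverage.get(g.chrom)
        if cov is None:
            if g.chrom not in warned:
                warnings.warn(f"no coverage for chromosome {g.chrom}; zeros used")
                warned.add(g.chrom)
        else:
            w0 = g.tss - flank
            for s, e, v in cov:
                lo = max(int(s), w0)
                hi = min(int(e), w0 + 2 * flank)
                if lo < hi:
                    win[lo - w0:hi - w0] = v
        if g.strand == "-":
            win = win[::-1]
        rows[g.gene_id] = win.reshape(n_bins, bin_width).mean(axis=1)
    prof = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"bin_{i}" for i in range(n_bins)])
    if order_by is not None:
        key = pd.Series({g: order_by.get(g, -np.inf) for g in prof.index})
        prof = prof.loc[key.sort_values(ascending=False, kind="stable").index]
    return prof


def expression_overlap(expressed_sets: Mapping[str, set]) -> pd.DataFrame:
    """Venn partition of per-cell-line expressed gene sets.

    Returns one row per non-empty membership pattern (columns: one boolean
    per cell line, ``count``), plus the summary fractions of the union
    expressed in all lines and in exactly one line as DataFrame attrs
    (``frac_all_lines``, ``frac_exactly_one``).
    """
    lines = sorted(expressed_sets)
    if len(lines) < 2:
        raise ValueError("need >=2 cell lines")
    universe = set().union(*expressed_sets.values())
    patterns: Counter = Counter()
    for g in universe:
        patterns[tuple(g in expressed_sets[l] for l in lines)] += 1
    rows = []
    for r in range(len(lines), 0, -1):
        for combo in combinations(range(len(lines)), r):
            pat = tuple(i in combo for i in range(len(lines)))
            rows.append({**{lines[i]: pat[i] for i in range(len(lines))},
                         "count": int(patterns.get(pat, 0))})
    table = pd.DataFrame(rows)
    n = len(universe)
    in_all = patterns.get(tuple([True] * len(lines)), 0)
    in_one = sum(v for k, v in patterns.items() if sum(k) == 1)
    table.attrs["n_union"] = n
    table.attrs["frac_all_lines"] = in_all / n if n else float("nan")
    table.attrs["frac_exactly_one"] = in_one / n if n else float("nan")
    return table
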