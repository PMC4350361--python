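"""Polyadenylation status from paired poly-A-selected and ribo-depleted
libraries.

Ribo-depleted libraries capture transcripts regardless of their 3' tail;
poly-A selection captures only polyadenylated ones.  Per gene and condition
the features are (x, y) = (mean log2CPM in ribo-depleted samples, mean
log2CPM in poly-A samples): polyadenylated genes fall on the diagonal,
non-polyadenylated ones far below it.  A two-class Fisher linear
discriminant is trained on labelled genes (coding transcripts with known
polyadenylation status) and applied to everything; the final non-polyA call
is conservative, requiring the non-polyA class in every condition tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import HIGH_MYC, LOW_MYC, POLYA, RIBO, CountMatrix
from .expression import log2cpm

LABEL_POLYA = "polyA"
LABEL_NON_POLYA = "non_polyA"


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares y ~ x with R^2 and the slope's two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), float(res.pvalue), int(x.size))


@dataclass
class Discriminant:
    """Two-class Fisher discriminant in the (ribo, polyA) feature plane.

    score(x) = w . x - offset; positive scores are the polyA class.
    """

    weights: np.ndarray        # shape (2,)
    offset: float
    mean_polya: np.ndarray
    mean_non: np.ndarray
    pooled_cov: np.ndarray
    n_polya: int
    n_non: int

    def score(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights - self.offset

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.where(self.score(features) > 0, LABEL_POLYA, LABEL_NON_POLYA)


def train_lda(features: np.ndarray, labels: np.ndarray,
              priors: tuple[float, float] | None = None) -> Discriminant:
    """Fit the discriminant: w = pooled_cov^-1 (mu_polyA - mu_non).

    The decision offset sits at the midpoint of the projected class means,
    shifted by the log prior ratio (equal priors by default, because the
    genomic class balance is extreme and the training set rarely reflects
    the application set).
    """
    X = np.asarray(features, dtype=float)
    lab = np.asarray(labels)
    mask_p = lab == LABEL_POLYA
    mask_n = lab == LABEL_NON_POLYA
    if not (mask_p | mask_n).all():
        bad = sorted(set(lab) - {LABEL_POLYA, LABEL_NON_POLYA})
        raise ValueError(f"unknown label(s): {bad}")
    if mask_p.sum() < 2 or mask_n.sum() < 2:
        raise ValueError("need >=2 training examples per class")
    mu_p = X[mask_p].mean(axis=0)
    mu_n = X[mask_n].mean(axis=0)
    if np.allclose(mu_p, mu_n):
        raise ValueError("class means coincide: no separation to learn")
    dp = X[mask_p] - mu_p
    dn = X[mask_n] - mu_n
    cov = (dp.T @ dp + dn.T @ dn) / (mask_p.sum() + mask_n.sum() - 2)
    try:
        w = np.linalg.solve(cov, mu_p - mu_n)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance; jitter the features or add data") from exc
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("pooled covariance is numerically singular; jitter the features or add data")
    pi_p, pi_n = priors if priors is not None else (0.5, 0.5)
    offset = float(w @ (mu_p + mu_n) / 2 - np.log(pi_p / pi_n))
    return Discriminant(w, offset, mu_p, mu_n, cov, int(mask_p.sum()), int(mask_n.sum()))


def extract_features(counts: CountMatrix, condition: str,
                     min_count: int = 5, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene (ribo, polyA) mean log2CPM features for one condition.

    Detection is assessed on the ribo-depleted samples (the library that
    sees every transcript): genes with fewer than ``min_count`` reads in
    their lowest ribo sample are dropped.  Filtering on the poly-A library
    would remove exactly the non-polyadenylated genes under study.
    """
    sub = counts.select(condition=condition)
    ribo = sub.select(library=RIBO)
    pa = sub.select(library=POLYA)
    if not ribo.samples or not pa.samples:
        raise ValueError(f"condition {condition}: need both ribo-depleted and poly-A samples")
    keep = ribo.counts.min(axis=1) >= min_count
    lc = log2cpm(sub.counts, pseudocount)
    feats = pd.DataFrame(
        dict(
            ribo=lc[[s.name for s in ribo.samples]].mean(axis=1),
            polya=lc[[s.name for s in pa.samples]].mean(axis=1),
        )
    ).loc[keep]
    feats.attrs["condition"] = condition
    return feats


def classify_polya(d: Discriminant, counts: CountMatrix,
                   conditions: tuple[str, ...] = (LOW_MYC, HIGH_MYC),
                   min_count: int = 5) -> pd.DataFrame:
    """Per-condition calls plus the conservative consensus.

    A gene's consensus is non_polyA only when it is classified non_polyA in
    every condition in which it passed the detection filter.  Returns a
    DataFrame with one score/call column pair per condition and a
    ``consensus`` column; genes detected in no condition are absent.
    """
    per_cond = {}
    for cond in conditions:
        feats = extract_features(counts, cond, min_count=min_count)
        scores = d.score(feats.to_numpy())
        per_cond[cond] = pd.DataFrame(
            dict(score=scores, call=np.where(scores > 0, LABEL_POLYA, LABEL_NON_POLYA)),
            index=feats.index,
        )
    all_genes = sorted(set().union(*(v.index for v in per_cond.values())))
    out = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"))
    for cond, tab in per_cond.items():
        out[f"score_{cond}"] = tab["score"]
        out[f"call_{cond}"] = tab["call"]
    call_cols = [f"call_{c}" for c in conditions]
    consensus = []
    for g in out.index:
        calls = [out.loc[g, c] for c in call_cols if isinstance(out.loc[g, c], str)]
        consensus.append(LABEL_NON_POLYA if calls and all(c == LABEL_NON_POLYA for c in calls)
                         else LABEL_POLYA)
    out["consensus"] = consensus
    return out


def non_polya_fraction(calls: pd.DataFrame, biotypes: pd.Series) -> pd.Series:
    """Fraction of consensus non-polyA calls per biotype."""
    bt = biotypes.reindex(calls.index)
    return (calls["consensus"] == LABEL_NON_POLYA).groupby(bt).mean()


def training_features(counts: CountMatrix, labels: pd.Series, condition: str,
                      min_count: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Align a gene -> {polyA, non_polyA} label series with one condition's
    feature table, returning (features, labels) arrays for train_lda."""
    feats = extract_features(counts, condition, min_count=min_count)
    common = feats.index.intersection(labels.index)
    return feats.loc[common].to_numpy(), labels.loc[common].to_numpy()
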