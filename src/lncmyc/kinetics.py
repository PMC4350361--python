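"""Transcript half-lives from transcription-shutoff time courses and
relative quantification of qPCR / nuclear run-on data.

Half-life: after Actinomycin D blocks transcription, abundance decays as
N(t) = N0 * 2^(-t / t_half), so each time point yields
t_half = t * ln2 / (ln N0 - ln N); the reported value is the mean over
valid points (0 < N < N0).  Points showing an apparent increase are
excluded (and counted) rather than producing negative half-lives.

qPCR: fold change by the 2^(-ddCq) method with efficiency 2; the reference
aggregate is the arithmetic mean of the reference Cqs, which under
efficiency 2 equals normalizing to the geometric mean of the reference
quantities.  Nuclear run-on data use the same arithmetic with a single
spike-in reference, which — unlike cellular reference genes — preserves
global (transcriptional-amplification) differences between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def half_life_single(t: float, n0: float, n: float) -> float:
    """t_half = t * ln2 / (ln n0 - ln n); NaN when n >= n0 (invalid point)."""
    if t <= 0:
        raise ValueError("t must be > 0")
    if n0 <= 0 or n <= 0:
        raise ValueError("abundances must be > 0")
    if n >= n0:
        return float("nan")
    return t * np.log(2) / (np.log(n0) - np.log(n))


@dataclass
class DecaySeries:
    gene_id: str
    times: np.ndarray            # minutes
    abundances: np.ndarray       # same length; baseline n0 at t=0
    n0: float = 1.0

    def per_point(self) -> np.ndarray:
        return np.array([half_life_single(t, self.n0, n)
                         for t, n in zip(self.times, self.abundances)])


@dataclass
class HalfLifeEstimate:
    gene_id: str
    half_life: float             # mean of valid per-point estimates, minutes
    half_life_regression: float  # log-linear fit alternative
    n_points: int
    n_excluded: int
    per_point: np.ndarray = field(repr=False, default=None)


def estimate_half_life(series: DecaySeries) -> HalfLifeEstimate:
    """Mean per-point half-life, with a log-linear regression alternative.

    The regression estimator fits ln N on t through ln N0 and converts the
    slope (-ln2 / t_half); it is reported alongside, not used for the
    summary.  With zero valid points both estimates are NaN (warned).
    """
    per = series.per_point()
    valid = ~np.isnan(per)
    n_excl = int((~valid).sum())
    if n_excl:
        warnings.warn(f"{series.gene_id}: {n_excl} point(s) with N >= N0 excluded")
    if valid.sum() == 0:
        warnings.warn(f"{series.gene_id}: no valid decay points; half-life is NA")
        mean_est = float("nan")
    else:
        mean_est = float(per[valid].mean())
    t = np.asarray(series.times, dtype=float)
    y = np.log(np.asarray(series.abundances, dtype=float) / series.n0)
    denom = float(t @ t)
    slope = float(t @ y) / denom if denom > 0 else float("nan")
    reg = -np.log(2) / slope if slope < 0 else float("nan")
    return HalfLifeEstimate(series.gene_id, mean_est, float(reg),
                            int(valid.sum()), n_excl, per)


def estimate_half_lives(decay: pd.DataFrame, n0: float = 1.0) -> pd.DataFrame:
    """Half-life table from a long decay DataFrame (gene_id, time_min, abundance)."""
    rows = []
    for gene, sub in decay.groupby("gene_id", sort=True):
        series = DecaySeries(gene, sub["time_min"].to_numpy(float),
                             sub["abundance"].to_numpy(float), n0)
        est = estimate_half_life(series)
        rows.append(dict(gene_id=gene, half_life_min=est.half_life,
                         half_life_regression_min=est.half_life_regression,
                         n_points=est.n_points, n_excluded=est.n_excluded))
    return pd.DataFrame(rows).set_index("gene_id")


def qpcr_relative(target_cq: Mapping[str, float],
                  reference_cqs: Mapping[str, Sequence[float]],
                  calibrator_sample: str) -> pd.Series:
    """2^(-ddCq) fold changes relative to a calibrator sample.

    dCq = Cq_target - mean(Cq_references); ddCq subtracts the calibrator's
    dCq, so the calibrator's fold is exactly 1.  Averaging reference Cqs is
    the geometric-mean normalization of reference quantities at efficiency 2.
    """
    if calibrator_sample not in target_cq:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    dcq = {}
    for sample, cq in target_cq.items():
        refs = reference_cqs.get(sample)
        if refs is None or len(list(refs)) == 0:
            raise ValueError(f"sample {sample!r}: missing reference Cq(s)")
        refs = np.asarray(list(refs), dtype=float)
        if not np.isfinite(refs).all() or not np.isfinite(cq):
            raise ValueError(f"sample {sample!r}: non-finite Cq")
        dcq[sample] = float(cq) - float(refs.mean())
    ddcq = {s: v - dcq[calibrator_sample] for s, v in dcq.items()}
    return pd.Series({s: float(2.0 ** (-v)) for s, v in ddcq.items()}, name="fold")


def nro_normalize(target_cq: Mapping[str, float], spike_cq: Mapping[str, float],
                  calibrator_sample: str) -> pd.Series:
    """Nuclear run-on fold changes normalized to a spike-in transcript.

    Identical ddCq arithmetic with the spike as sole reference.  Because the
    spike is added per reaction rather than transcribed by the cells, global
    transcriptional amplification shifts every target relative to it and is
    therefore retained in the folds, where a cellular reference would cancel
    it.
    """
    missing = [s for s in target_cq if s not in spike_cq]
    if missing:
        raise ValueError(f"sample(s) missing spike-in Cq: {missing}")
    return qpcr_relative(target_cq, {s: [spike_cq[s]] for s in target_cq}, calibrator_sample)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
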