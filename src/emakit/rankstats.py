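"""Shared ranking statistics for EMA evaluation.

Implements the CASP-style two-pass Z-score (low outliers removed before the
final mean/sd; negative Z clamped to zero; missing predictions scored 0),
plus the per-target statistics the rankings consume: Pearson/Spearman
correlations, ROC AUC as a rank statistic, top-1 loss and min–max
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ZConfig:
    """Configuration of the CASP Z-score.

    ``exclusion_sd`` — pass-1 cutoff: values below ``mean − exclusion_sd·sd``
    are dropped before the final mean/sd (2 for most rankings, 3 for the
    model-selection cross-check). ``two_pass=False`` reproduces the plain
    single-pass Z used by the QMODE1/2 ranking-score formula. Missing
    predictors always contribute a Z of exactly 0.
    """

    exclusion_sd: float = 2.0
    missing_policy: str = "zero"
    clamp_negative: bool = True
    two_pass: bool = True
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.exclusion_sd <= 0:
            raise ValueError("exclusion_sd must be positive")
        if self.missing_policy != "zero":
            raise ValueError("only the 'zero' missing policy is supported")


def two_pass_z(values: Mapping[str, float], cfg: ZConfig = ZConfig()) -> Dict[str, float]:
    """CASP Z-scores over a predictor → value mapping (higher is better).

    Degenerate spreads (sd = 0, or a single value) yield all-zero Z.
    """
    names = list(values)
    vals = np.array([float(values[n]) for n in names])
    if vals.size == 0:
        return {}
    finite = np.isfinite(vals)
    if not np.all(finite):
        raise ValueError("values must be finite; encode missing predictors by omission")

    def _stats(v: np.ndarray) -> Tuple[float, float]:
        if v.size <= cfg.ddof:
            return float(v.mean()) if v.size else 0.0, 0.0
        return float(v.mean()), float(v.std(ddof=cfg.ddof))

    mean, sd = _stats(vals)
    if cfg.two_pass and sd > 0:
        keep = vals >= mean - cfg.exclusion_sd * sd
        if keep.any():
            mean, sd = _stats(vals[keep])
    if sd == 0:
        return {n: 0.0 for n in names}
    z = (vals - mean) / sd
    if cfg.clamp_negative:
        z = np.maximum(z, 0.0)
    return {n: float(zv) for n, zv in zip(names, z)}


def correlations(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """(Pearson, Spearman) of paired observations; NaN when undefined.

    Spearman uses average ranks for ties. Either vector having zero variance
    makes both undefined (NaN) — upstream rankings treat that as a missing
    statistic contributing 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("correlations need ≥ 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlations need finite inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def roc_auc(scores: Mapping[str, float], labels: Mapping[str, int]) -> float:
    """ROC AUC = P(score⁺ > score⁻) + ½·P(tie), via the rank statistic.

    Returns NaN when either class is absent.
    """
    keys = list(scores)
    if set(keys) != set(labels):
        raise ValueError("scores and labels must cover the same items")
    y = np.array([int(labels[k]) for k in keys])
    s = np.array([float(scores[k]) for k in keys])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = stats.rankdata(s)  # average ranks on ties → the ½-credit rule
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def top1_loss(predicted: Mapping[str, float], reference: Mapping[str, float]) -> float:
    """Reference-value gap between the pool's best model and the predictor's pick.

    ``loss = max(reference) − reference[argmax(predicted)]`` over the shared
    model ids (reference oriented higher-better). Ties in the predicted score
    break by lexicographically smallest model id.
    """
    shared = sorted(set(predicted) & set(reference))
    if not shared:
        raise ValueError("no shared model ids between prediction and reference")
    best_pred = max(float(predicted[m]) for m in shared)
    top = min(m for m in shared if float(predicted[m]) == best_pred)
    best = max(float(reference[m]) for m in shared)
    return best - float(reference[top])


def minmax_normalize(values: Mapping[str, float]) -> Dict[str, float]:
    """Rescale to [0, 1]: best → 0 handled by callers; here plain (v−min)/(max−min).

    All-equal inputs map to all-zero.
    """
    if not values:
        return {}
    vals = np.array([float(v) for v in values.values()])
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: (float(v) - lo) / (hi - lo) for k, v in values.items()}
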