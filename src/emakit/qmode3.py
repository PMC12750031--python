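"""Top-5 model-selection evaluation with a covariance-weighted ranking penalty.

Predictors select the five best models from a large pool per target. For each
structural criterion the ranking error (RE) compares the selected models'
scores, sorted best-first, against the pool's true top five:

    RE = Σ_{k=1..5} |S_true(k) − S_pred(k)|

RE is zero whenever the selected multiset of scores matches the pool's best
five — in particular, any selection among tied top models is perfect, which
makes the penalty robust to the heavy redundancy of large sampled pools.

Because the criteria are strongly correlated, per-criterion REs are combined
through the Mahalanobis form P_w = RE Σ⁻¹ REᵀ, with Σ the per-category
covariance of criteria estimated in two passes (severe outliers screened by
Mahalanobis distance before the final pass). Penalties are min–max normalized
per target (best predictor 0, worst 1) and averaged over submitted targets;
an equal-weight two-pass Z-score ranking on the same REs serves as a
cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .rankstats import ZConfig, minmax_normalize, two_pass_z

MONOMER_METRICS: Tuple[str, ...] = (
    "lddt", "tm_score", "qs_global", "qs_best", "rmsd", "oligo_gdtha", "oligo_gdtts",
)
OLIGOMER_EXTRA: Tuple[str, ...] = ("ilddt", "ips", "ics", "dockq_ave", "dockq_wave")
EXCLUDED_FROM_PENALTY: Tuple[str, ...] = ("rmsd", "ips", "ics")
LOWER_BETTER: Tuple[str, ...] = ("rmsd",)

CATEGORIES = ("monomer", "homomer", "heteromer")


def category_metrics(category: str) -> Tuple[str, ...]:
    if category == "monomer":
        return MONOMER_METRICS
    if category in ("homomer", "heteromer"):
        return MONOMER_METRICS + OLIGOMER_EXTRA
    raise ValueError(f"unknown category {category!r}")


def penalty_metrics(category: str) -> Tuple[str, ...]:
    return tuple(m for m in category_metrics(category) if m not in EXCLUDED_FROM_PENALTY)


class ResolutionError(KeyError):
    """A submitted model id does not exist in the pool."""


class ConfigurationError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Long-form (target, model, metric) → value table with orientations."""

    values: pd.DataFrame  # columns: target, model, metric, value
    category: str = "monomer"
    orientation: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"target", "model", "metric", "value"}
        if not required.issubset(self.values.columns):
            raise ValueError(f"score table needs columns {sorted(required)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for m in self.values["metric"].unique():
            self.orientation.setdefault(
                m, "lower_better" if m in LOWER_BETTER else "higher_better"
            )

    @property
    def targets(self) -> List[str]:
        return sorted(self.values["target"].unique())

    @property
    def metrics(self) -> List[str]:
        return sorted(self.values["metric"].unique())

    def higher_better(self, metric: str) -> bool:
        return self.orientation[metric] != "lower_better"

    def pool_scores(self, target: str, metric: str) -> Dict[str, float]:
        sub = self.values[(self.values["target"] == target) & (self.values["metric"] == metric)]
        return dict(zip(sub["model"], sub["value"].astype(float)))

    def pivot(self, metrics: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """(target, model) rows × metric columns, complete cases only."""
        wide = self.values.pivot_table(
            index=["target", "model"], columns="metric", values="value", aggfunc="first"
        )
        if metrics is not None:
            missing = [m for m in metrics if m not in wide.columns]
            if missing:
                raise ConfigurationError(f"score table lacks metrics {missing}")
            wide = wide[list(metrics)]
        return wide.dropna()


def ranking_error(
    pool_scores: Mapping[str, float],
    selection: Sequence[str],
    higher_better: bool = True,
    allow_short: bool = False,
    n_slots: int = 5,
) -> float:
    """Ranking error of a top-``n_slots`` selection against the full pool.

    Both the pool and the selection are sorted best-first by the metric's
    orientation; the error sums absolute slot-wise score gaps. Short
    selections are rejected unless ``allow_short``, in which case each empty
    slot is charged the gap between the slot's true score and the pool's
    worst score.
    """
    unknown = [m for m in selection if m not in pool_scores]
    if unknown:
        raise ResolutionError(f"selected models not in pool: {unknown}")
    if len(set(selection)) != len(selection):
        raise ResolutionError("selection contains duplicate model ids")
    if len(selection) != n_slots and not allow_short:
        raise ValueError(f"selection must contain exactly {n_slots} models")
    if len(pool_scores) < n_slots:
        raise ValueError(f"pool smaller than {n_slots} models")

    sign = 1.0 if higher_better else -1.0
    pool_sorted = sorted((sign * float(v) for v in pool_scores.values()), reverse=True)
    s_true = pool_sorted[:n_slots]
    s_pred = sorted((sign * float(pool_scores[m]) for m in selection), reverse=True)
    worst = pool_sorted[-1]
    err = 0.0
    for k in range(n_slots):
        got = s_pred[k] if k < len(s_pred) else worst
        err += abs(s_true[k] - got)
    return err


@dataclass
class CovarianceModel:
    sigma: np.ndarray
    inverse: np.ndarray
    metrics: Tuple[str, ...]
    category: str
    outlier_quantile: float
    n_models_used: Tuple[int, int]  # (pass 1, pass 2)
    mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    ridge: float = 0.0


def _inverse(sigma: np.ndarray, ridge: float) -> np.ndarray:
    if ridge > 0:
        d = sigma.shape[0]
        eps = ridge * np.trace(sigma) / d
        return np.linalg.pinv(sigma + eps * np.eye(d))
    return np.linalg.pinv(sigma)


def robust_covariance(
    table: ScoreTable,
    metrics: Optional[Sequence[str]] = None,
    outlier_quantile: float = 0.975,
    ridge: float = 0.0,
) -> CovarianceModel:
    """Two-pass covariance of criteria over all models of a category's targets.

    Pass 1 estimates mean/covariance from every (target, model) row; rows
    whose squared Mahalanobis distance from the mean exceeds the chi-square
    quantile at d degrees of freedom are screened out; pass 2 recomputes the
    covariance on the survivors. Near-singular pass-2 covariances fall back
    to the pseudo-inverse with a warning (optionally ridge-stabilized).
    """
    if metrics is None:
        metrics = [m for m in table.metrics if m not in EXCLUDED_FROM_PENALTY]
    metrics = tuple(metrics)
    X = table.pivot(metrics).to_numpy(dtype=float)
    d = len(metrics)
    if X.shape[0] < d + 2:
        raise ValueError(f"need ≥ {d + 2} complete model rows, got {X.shape[0]}")

    mean1 = X.mean(axis=0)
    cov1 = np.cov(X, rowvar=False, ddof=1)
    inv1 = np.linalg.pinv(cov1)
    centered = X - mean1
    d2 = np.einsum("ij,jk,ik->i", centered, inv1, centered)
    cut = stats.chi2.ppf(outlier_quantile, df=d)
    keep = d2 <= cut
    if keep.sum() < d + 2:  # degenerate screen; fall back to everything
        keep = np.ones(X.shape[0], dtype=bool)
    Xk = X[keep]
    mean2 = Xk.mean(axis=0)
    cov2 = np.cov(Xk, rowvar=False, ddof=1)
    cond = np.linalg.cond(cov2)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "near-singular criterion covariance; using pseudo-inverse"
            + (" with ridge" if ridge > 0 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    return CovarianceModel(
        sigma=cov2,
        inverse=_inverse(cov2, ridge),
        metrics=metrics,
        category=table.category,
        outlier_quantile=outlier_quantile,
        n_models_used=(int(X.shape[0]), int(keep.sum())),
        mean=mean2,
        ridge=ridge,
    )


def weighted_penalty(re: Mapping[str, float], cov: CovarianceModel) -> float:
    """Mahalanobis penalty P_w = RE Σ⁻¹ REᵀ of an RE vector from all-zero."""
    if set(re) != set(cov.metrics):
        raise ConfigurationError(
            f"RE metrics {sorted(re)} do not match covariance metrics {sorted(cov.metrics)}"
        )
    v = np.array([float(re[m]) for m in cov.metrics])
    return float(v @ cov.inverse @ v)


def ranking_error_matrix(
    submissions: pd.DataFrame,
    table: ScoreTable,
    metrics: Optional[Sequence[str]] = None,
    allow_short: bool = False,
) -> pd.DataFrame:
    """Long-form RE per (predictor, target, metric) from top-5 submissions.

    ``submissions`` columns: predictor, target, rank (1–5), model.
    """
    required = {"predictor", "target", "rank", "model"}
    if not required.issubset(submissions.columns):
        raise ValueError(f"submissions need columns {sorted(required)}")
    if metrics is None:
        metrics = penalty_metrics(table.category)
    known_targets = set(table.targets)
    rows = []
    for (p, t), grp in submissions.groupby(["predictor", "target"]):
        if t not in known_targets:
            raise ResolutionError(f"submission references unknown target {t!r}")
        selection = list(grp.sort_values("rank")["model"])
        for metric in metrics:
            pool = table.pool_scores(t, metric)
            re = ranking_error(
                pool, selection, table.higher_better(metric), allow_short=allow_short
            )
            rows.append((p, t, metric, re))
    return pd.DataFrame(rows, columns=["predictor", "target", "metric", "re"])


@dataclass
class CategoryEvaluation:
    penalties: pd.DataFrame            # predictor × target raw P_w
    normalized: pd.DataFrame           # predictor × target min–max normalized P_w
    ranking: pd.DataFrame              # predictor, mean_penalty, rank
    eligible_predictors: List[str]
    excluded_predictors: List[str]


def evaluate_category(
    submissions: pd.DataFrame,
    table: ScoreTable,
    cov: CovarianceModel,
    coverage_min: float = 0.8,
    aggregate: str = "mean",
    allow_short: bool = False,
) -> CategoryEvaluation:
    """Rank predictors by per-target-normalized covariance-weighted penalty.

    Predictors must cover ≥ ``coverage_min`` of the category's targets;
    beyond that, skipped targets carry no additional penalty — the final
    statistic averages (or sums, ``aggregate="sum"``) normalized penalties
    over the targets actually submitted.
    """
    targets = table.targets
    n_targets = len(targets)
    min_targets = math.ceil(coverage_min * n_targets - 1e-9)
    covered = submissions.groupby("predictor")["target"].nunique()
    eligible = sorted(covered.index[covered >= min_targets])
    excluded = sorted(set(covered.index) - set(eligible))
    subs = submissions[submissions["predictor"].isin(eligible)]

    re_long = ranking_error_matrix(subs, table, metrics=cov.metrics, allow_short=allow_short)
    pw_rows = []
    for (p, t), grp in re_long.groupby(["predictor", "target"]):
        re_vec = dict(zip(grp["metric"], grp["re"]))
        pw_rows.append((p, t, weighted_penalty(re_vec, cov)))
    pw = pd.DataFrame(pw_rows, columns=["predictor", "target", "pw"])
    penalties = pw.pivot(index="predictor", columns="target", values="pw")

    normalized = penalties.copy()
    for t in penalties.columns:
        col = penalties[t].dropna()
        norm = minmax_normalize(dict(col))
        normalized[t] = pd.Series(norm)

    if aggregate == "mean":
        agg = normalized.mean(axis=1, skipna=True)
    elif aggregate == "sum":
        agg = normalized.sum(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    ranking = (
        agg.rename("mean_penalty")
        .reset_index()
        .sort_values(["mean_penalty", "predictor"], ignore_index=True)
    )
    ranking["rank"] = ranking["mean_penalty"].rank(method="min").astype(int)
    return CategoryEvaluation(
        penalties=penalties,
        normalized=normalized,
        ranking=ranking,
        eligible_predictors=eligible,
        excluded_predictors=excluded,
    )


def zscore_crosscheck(
    re_long: pd.DataFrame,
    cfg: ZConfig = ZConfig(exclusion_sd=3.0),
) -> pd.DataFrame:
    """Equal-weight two-pass Z ranking on negated REs, the penalty cross-check.

    ``re_long`` columns: predictor, target, metric, re. Per (metric, target)
    the CASP Z is computed across predictors on −RE; Z-sums pool all metrics
    and targets with equal weight; missing cells contribute 0.
    """
    required = {"predictor", "target", "metric", "re"}
    if not required.issubset(re_long.columns):
        raise ValueError(f"RE table needs columns {sorted(required)}")
    predictors = sorted(re_long["predictor"].unique())
    z_sum = {p: 0.0 for p in predictors}
    for (_, _), grp in re_long.groupby(["metric", "target"]):
        vals = dict(zip(grp["predictor"], -grp["re"].astype(float)))
        for p, zv in two_pass_z(vals, cfg).items():
            z_sum[p] += zv
    out = pd.DataFrame({"predictor": predictors, "z_sum": [z_sum[p] for p in predictors]})
    out = out.sort_values(["z_sum", "predictor"], ascending=[False, True], ignore_index=True)
    out["rank"] = out["z_sum"].rank(method="min", ascending=False).astype(int)
    return out


def best_selection_true_rank(
    submissions: pd.DataFrame,
    table: ScoreTable,
    metric: str = "tm_score",
) -> Dict[str, int]:
    """True rank of the best model any predictor selected, per target.

    Over the union of all selected models for a target, the model with the
    best value of ``metric`` is found; returned is its 1-based competition
    rank in the full pool sorted best-first (tied values share the best
    rank, so fully redundant pools always yield rank 1).
    """
    out: Dict[str, int] = {}
    higher = table.higher_better(metric)
    for t, grp in submissions.groupby("target"):
        pool = table.pool_scores(t, metric)
        selected = set(grp["model"])
        unknown = selected - set(pool)
        if unknown:
            raise ResolutionError(f"target {t!r}: selected models not in pool: {sorted(unknown)}")
        sign = 1.0 if higher else -1.0
        best_val = max(sign * pool[m] for m in selected)
        better = sum(1 for v in pool.values() if sign * v > best_val)
        out[t] = better + 1
    return out
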