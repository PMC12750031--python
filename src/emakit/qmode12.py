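"""Global (QMODE1) and local-interface (QMODE2) quality-estimate evaluation.

QMODE1 predictors submit two global estimates per model: SCORE (overall
topology, assessed against superposition-based reference metrics) and QSCORE
(interface quality, assessed against interface-centric metrics). QMODE2
predictors submit per-interface-residue local estimates, assessed both as a
classifier of true interface residues (ROC AUC) and against local accuracy
reference values.

Per reference metric r and predictor p, per-target statistics — Pearson P,
Spearman S, ROC AUC R and top-1 loss L — are turned into per-target Z-scores
across predictors (single-pass, negatives clamped, missing targets scoring
exactly 0) and summed; the ranking score combines them as

    RS(r, p) = 0.5·P + 0.5·S + R + L        (QMODE1; L negated before Z)
    RS(r, p) = 0.5·P + 0.5·S + R            (QMODE2)

and final rankings sum RS over the channel's reference metrics. Supporting
filters: the stoichiometry filter on model pools, the 80%-of-points /
80%-of-targets participation rule, and the reference-quality target
viability screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .lddt import interface_residues
from .rankstats import ZConfig, correlations, roc_auc, top1_loss, two_pass_z
from .structures import ChainMapping, Structure, stoichiometry_signature

QMODE1_CHANNELS: Dict[str, Tuple[str, ...]] = {
    "score": ("oligo_gdtts", "tm_score"),
    "qscore": ("qs_score", "dockq_wave"),
}
QMODE2_METRICS: Tuple[str, ...] = ("lddt", "cad", "patchqs", "patchdockq")

# z-config printed by the ranking-score formula: plain per-target Z, clamped
QMODE12_ZCONFIG = ZConfig(exclusion_sd=2.0, two_pass=False, clamp_negative=True)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    kept: List[Structure]
    removed: List[str]
    removed_fraction: float


def filter_models(pool: Sequence[Structure], target: Structure) -> FilterResult:
    """Drop models whose stoichiometry differs from the target's."""
    sig = stoichiometry_signature(target)
    kept, removed = [], []
    for m in pool:
        (kept if stoichiometry_signature(m) == sig else removed).append(m)
    kept_structs = [m for m in kept]
    if not kept_structs:
        raise ValueError(f"no models match the stoichiometry of target {target.id!r}")
    return FilterResult(
        kept=kept_structs,
        removed=[m.id for m in removed],
        removed_fraction=len(removed) / len(pool),
    )


def required_count(total: int, fraction: float) -> int:
    """Smallest integer count satisfying an 'at least fraction of total' rule."""
    return math.ceil(fraction * total - 1e-9)


def coverage_filter(
    returned: pd.DataFrame,
    expected: Mapping[str, int],
    n_targets: Optional[int] = None,
    min_point_fraction: float = 0.8,
    min_target_fraction: float = 0.8,
) -> Set[str]:
    """Predictors returning ≥ 80% of expected points on ≥ 80% of targets.

    ``returned`` columns: predictor, target, n_returned; ``expected`` maps
    target → expected point count (models for QMODE1, interface residues for
    QMODE2).
    """
    required = {"predictor", "target", "n_returned"}
    if not required.issubset(returned.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    if n_targets is None:
        n_targets = len(expected)
    target_min = required_count(n_targets, min_target_fraction)
    eligible: Set[str] = set()
    for p, grp in returned.groupby("predictor"):
        ok = 0
        for _, row in grp.iterrows():
            t = row["target"]
            if t not in expected:
                continue
            if row["n_returned"] >= required_count(int(expected[t]), min_point_fraction):
                ok += 1
        if ok >= target_min:
            eligible.add(p)
    return eligible


def viable_targets(
    reference: pd.DataFrame, metric: str, threshold: float = 0.6
) -> Set[str]:
    """Targets where at least one model reaches ``threshold`` on ``metric``."""
    required = {"target", "model", "metric", "value"}
    if not required.issubset(reference.columns):
        raise ValueError(f"reference table needs columns {sorted(required)}")
    sub = reference[reference["metric"] == metric]
    best = sub.groupby("target")["value"].max()
    return set(best.index[best >= threshold])


# ---------------------------------------------------------------------------
# Consensus baseline and interface ground truth
# ---------------------------------------------------------------------------


def ac_baseline(models: Sequence[str], pairwise_score) -> Dict[str, float]:
    """Assembly-consensus baseline: mean pairwise similarity to every other model."""
    if len(models) < 2:
        raise ValueError("consensus baseline needs at least 2 models")
    out: Dict[str, float] = {}
    for m in models:
        others = [float(pairwise_score(m, o)) for o in models if o != m]
        out[m] = float(np.mean(others))
    return out


def interface_truth_labels(
    model: Structure,
    target: Structure,
    mapping: ChainMapping,
    contact_distance: float = 5.0,
) -> Dict[Tuple[str, int], bool]:
    """Label each model interface residue as a true interface residue or not.

    A model interface residue is *true* iff its mapped target residue is an
    interface residue of the target. Residues without a mapped, resolved
    target counterpart are excluded from labeling.
    """
    model_iface = interface_residues(model, contact_distance)
    target_iface = interface_residues(target, contact_distance)
    target_residues = {
        (c.id, r.index) for c in target.chains for r in c.residues
    }
    labels: Dict[Tuple[str, int], bool] = {}
    for (mcid, mresi) in model_iface:
        tcid = mapping.pairs.get(mcid)
        if tcid is None:
            continue
        tresi = mapping.residue_map.get(mcid, {}).get(mresi)
        if tresi is None or (tcid, tresi) not in target_residues:
            continue
        labels[(mcid, mresi)] = (tcid, tresi) in target_iface
    return labels


# ---------------------------------------------------------------------------
# Per-target statistics and RS aggregation
# ---------------------------------------------------------------------------

STAT_COLUMNS = ["metric", "predictor", "target", "stat", "value"]


class ReferenceTableError(ValueError):
    """A required reference metric is missing from the supplied table."""


def qmode1_statistics(
    submissions: pd.DataFrame,
    reference: pd.DataFrame,
    channel: str = "score",
    label_threshold: float = 0.6,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-(metric, predictor, target) P/S/R/L statistics for QMODE1.

    ``submissions`` columns: predictor, target, model, score, qscore.
    ``reference``: long table target, model, metric, value. Only models the
    predictor actually scored enter each statistic (pairwise-complete). The
    ROC AUC binarizes the reference at ``label_threshold``; undefined
    statistics (too few pairs, one-class AUC, zero variance) are omitted and
    later contribute 0 through the missing-prediction rule.
    """
    if channel not in QMODE1_CHANNELS:
        raise ValueError(f"unknown QMODE1 channel {channel!r}")
    est_col = {"score": "score", "qscore": "qscore"}[channel]
    rows: List[tuple] = []
    ref_wide = reference.pivot_table(
        index=["target", "model"], columns="metric", values="value", aggfunc="first"
    )
    for metric in QMODE1_CHANNELS[channel]:
        if metric not in ref_wide.columns:
            raise ReferenceTableError(f"reference table lacks metric {metric!r}")
        for (p, t), grp in submissions.groupby(["predictor", "target"]):
            if t not in ref_wide.index.get_level_values(0):
                continue
            ref_t = ref_wide.xs(t, level="target")[metric].dropna()
            est = dict(zip(grp["model"], grp[est_col].astype(float)))
            shared = [m for m in est if m in ref_t.index]
            if not shared:
                continue
            pred = {m: est[m] for m in shared}
            ref = {m: float(ref_t[m]) for m in shared}
            if len(shared) >= min_pairs:
                pe, sp = correlations([pred[m] for m in shared], [ref[m] for m in shared])
                if not math.isnan(pe):
                    rows.append((metric, p, t, "P", pe))
                    rows.append((metric, p, t, "S", sp))
            labels = {m: int(ref[m] >= label_threshold) for m in shared}
            auc = roc_auc(pred, labels)
            if not math.isnan(auc):
                rows.append((metric, p, t, "R", auc))
            rows.append((metric, p, t, "L", top1_loss(pred, ref)))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)



def qmode2_statistics(
    submissions: pd.DataFrame,
    local_reference: pd.DataFrame,
    labels: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-(metric, predictor, target) P/S/R statistics for QMODE2.

    ``submissions`` columns: predictor, target, model, chain, residue_index,
    local_estimate. ``local_reference``: target, model, chain, residue_index,
    metric, value (per-residue accuracy reference values on interface
    residues). ``labels``: target, model, chain, residue_index, label — the
    true-interface ground truth. Correlations pool all scored interface
    residues of a target; R is the per-target classification AUC (identical
    across reference metrics, reflecting that the identification task does
    not depend on the accuracy metric).
    """
    key = ["target", "model", "chain", "residue_index"]
    sub = submissions.set_index(["predictor"] + key)["local_estimate"]
    lab = labels.set_index(key)["label"]

    auc_by_pt: Dict[Tuple[str, str], float] = {}
    for (p, t), grp in submissions.groupby(["predictor", "target"]):
        scores, ys = {}, {}
        for _, row in grp.iterrows():
            k = (row["target"], row["model"], row["chain"], row["residue_index"])
            if k in lab.index:
                item = (row["model"], row["chain"], row["residue_index"])
                scores[item] = float(row["local_estimate"])
                ys[item] = int(lab[k])
        if scores:
            auc = roc_auc(scores, ys)
            if not math.isnan(auc):
                auc_by_pt[(p, t)] = auc

    rows: List[tuple] = []
    ref = local_reference.set_index(["metric"] + key)["value"]
    for metric in QMODE2_METRICS:
        if metric not in local_reference["metric"].unique():
            raise ReferenceTableError(f"local reference table lacks metric {metric!r}")
        ref_m = ref.xs(metric, level="metric")
        for (p, t), grp in submissions.groupby(["predictor", "target"]):
            xs, ys = [], []
            for _, row in grp.iterrows():
                k = (row["target"], row["model"], row["chain"], row["residue_index"])
                if k in ref_m.index:
                    xs.append(float(row["local_estimate"]))
                    ys.append(float(ref_m[k]))
            if len(xs) >= min_pairs:
                pe, sp = correlations(xs, ys)
                if not math.isnan(pe):
                    rows.append((metric, p, t, "P", pe))
                    rows.append((metric, p, t, "S", sp))
            if (p, t) in auc_by_pt:
                rows.append((metric, p, t, "R", auc_by_pt[(p, t)]))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def aggregate_rs(
    stats: pd.DataFrame,
    mode: str,
    zconfig: ZConfig = QMODE12_ZCONFIG,
) -> pd.DataFrame:
    """Combine per-target statistics into ranking scores.

    Per (metric, stat, target) a Z across predictors is computed (loss L is
    negated first: lower loss is better), clamped at zero and summed over
    targets — absent entries add exactly 0. Ranking score per metric:
    0.5·P + 0.5·S + R (+ L for qmode1); the returned frame carries per-metric
    RS columns and their sum ``rs_total`` with ranks.
    """
    if mode not in ("qmode1", "qmode2"):
        raise ValueError(f"unknown mode {mode!r}")
    if stats.empty:
        raise ValueError("no statistics to aggregate")
    use_loss = mode == "qmode1"
    predictors = sorted(stats["predictor"].unique())
    metrics = sorted(stats["metric"].unique())

    zsum: Dict[Tuple[str, str, str], float] = {}  # (metric, stat, predictor) → Σ_t Z
    for (metric, stat, target), grp in stats.groupby(["metric", "stat", "target"]):
        vals = dict(zip(grp["predictor"], grp["value"].astype(float)))
        if stat == "L":
            if not use_loss:
                continue
            vals = {p: -v for p, v in vals.items()}
        z = two_pass_z(vals, zconfig)
        for p, zv in z.items():
            zsum[(metric, stat, p)] = zsum.get((metric, stat, p), 0.0) + zv

    records = []
    for p in predictors:
        rec: Dict[str, float] = {"predictor": p}
        total = 0.0
        for metric in metrics:
            rs = (
                0.5 * zsum.get((metric, "P", p), 0.0)
                + 0.5 * zsum.get((metric, "S", p), 0.0)
                + zsum.get((metric, "R", p), 0.0)
            )
            if use_loss:
                rs += zsum.get((metric, "L", p), 0.0)
            rec[f"rs_{metric}"] = rs
            total += rs
        rec["rs_total"] = total
        records.append(rec)
    out = pd.DataFrame(records).sort_values(
        ["rs_total", "predictor"], ascending=[False, True], ignore_index=True
    )
    out["rank"] = out["rs_total"].rank(method="min", ascending=False).astype(int)
    return out


def identification_ranking(
    submissions: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Interface-residue identification ranking: mean per-target ROC AUC."""
    key = ["target", "model", "chain", "residue_index"]
    lab = labels.set_index(key)["label"]
    rows = []
    for (p, t), grp in submissions.groupby(["predictor", "target"]):
        scores, ys = {}, {}
        for _, row in grp.iterrows():
            k = (row["target"], row["model"], row["chain"], row["residue_index"])
            if k in lab.index:
                item = (row["model"], row["chain"], row["residue_index"])
                scores[item] = float(row["local_estimate"])
                ys[item] = int(lab[k])
        if scores:
            auc = roc_auc(scores, ys)
            if not math.isnan(auc):
                rows.append((p, t, auc))
    per_pt = pd.DataFrame(rows, columns=["predictor", "target", "auc"])
    out = per_pt.groupby("predictor")["auc"].mean().rename("mean_auc").reset_index()
    out = out.sort_values(["mean_auc", "predictor"], ascending=[False, True], ignore_index=True)
    out["rank"] = out["mean_auc"].rank(method="min", ascending=False).astype(int)
    return out
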