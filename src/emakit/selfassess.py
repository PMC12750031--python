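"""Self-confidence (pLDDT) accuracy evaluation.

A predicted model stores its pLDDT (0–100) in the B-factor column, either per
residue (every atom of a residue shares one value) or per atom. Accuracy is
the RMSD between predicted and realized LDDT on the 0–100 scale, computed at
either granularity after "regraining": per-residue values are the unweighted
mean of a residue's atom values; per-atom values are the residue value
broadcast to each atom. Predictors are ranked by per-target CASP Z-scores on
negated RMSD (lower deviation is better), with missing targets contributing
exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Literal, Optional, Tuple

import pandas as pd

from .lddt import AtomKey, LddtResult, ResidueKey
from .rankstats import ZConfig, two_pass_z
from .structures import Structure

Granularity = Literal["per_atom", "per_residue"]


class PlddtScaleError(ValueError):
    pass


@dataclass
class PlddtVector:
    granularity: Granularity
    values: Dict[tuple, float]  # AtomKey (per_atom) or ResidueKey (per_residue) → 0–100
    source: str  # native_per_atom | native_per_residue

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not (0.0 <= v <= 100.0)]
        if bad:
            raise PlddtScaleError(f"pLDDT outside [0, 100] for {bad[:3]}...")


def extract_plddt(model: Structure, rescale_fraction: bool = False) -> PlddtVector:
    """Read per-atom pLDDT from the B-factor column.

    The vector's ``source`` records whether any residue carries non-identical
    atom values (native per-atom estimates) or not (per-residue estimates
    broadcast by the predictor). Values on a 0–1 scale trip a scale error
    unless ``rescale_fraction`` multiplies them by 100.
    """
    values: Dict[AtomKey, float] = {}
    native_atom = False
    for chain in model.chains:
        for res in chain.residues:
            vals = []
            for atom in res.atoms:
                v = atom.bfactor * 100.0 if rescale_fraction else atom.bfactor
                if not (0.0 <= v <= 100.0):
                    raise PlddtScaleError(
                        f"B-factor {atom.bfactor} outside [0, 100] at "
                        f"{chain.id}:{res.index}:{atom.name}; if values are on a 0–1 "
                        "scale pass rescale_fraction=True"
                    )
                values[(chain.id, res.index, atom.name)] = v
                vals.append(v)
            if any(abs(v - vals[0]) > 1e-9 for v in vals[1:]):
                native_atom = True
    return PlddtVector(
        granularity="per_atom",
        values=values,
        source="native_per_atom" if native_atom else "native_per_residue",
    )


def regrain(v: PlddtVector, to: Granularity, model: Structure) -> PlddtVector:
    """Convert between per-atom and per-residue pLDDT.

    per_residue ← unweighted mean over the residue's atoms;
    per_atom ← broadcast of the residue value to each atom.
    """
    if v.granularity == to:
        return PlddtVector(v.granularity, dict(v.values), v.source)
    if to == "per_residue":
        sums: Dict[ResidueKey, Tuple[float, int]] = {}
        for (cid, resi, _name), val in v.values.items():
            s, n = sums.get((cid, resi), (0.0, 0))
            sums[(cid, resi)] = (s + val, n + 1)
        return PlddtVector("per_residue", {k: s / n for k, (s, n) in sums.items()}, v.source)
    # per_residue → per_atom broadcast
    values: Dict[AtomKey, float] = {}
    for chain in model.chains:
        for res in chain.residues:
            rv = v.values.get((chain.id, res.index))
            if rv is None:
                continue
            for atom in res.atoms:
                values[(chain.id, res.index, atom.name)] = rv
    return PlddtVector("per_atom", values, v.source)


def plddt_rmsd(
    predicted: PlddtVector,
    actual: LddtResult,
    granularity: Granularity,
    model: Optional[Structure] = None,
    metric: Literal["rmsd", "mad"] = "rmsd",
) -> float:
    """Deviation between predicted and realized LDDT on the 0–100 scale.

    ``metric="rmsd"`` (default) is the root-mean-square deviation; ``"mad"``
    is the mean absolute deviation, retained because the two were observed to
    rank predictors near-identically. Keys with undefined realized LDDT are
    excluded; no overlap is an error.
    """
    if predicted.granularity != granularity:
        if model is None:
            raise ValueError("regraining to the requested granularity needs the model")
        predicted = regrain(predicted, granularity, model)
    realized = actual.per_atom if granularity == "per_atom" else actual.per_residue
    diffs = []
    for key, pv in predicted.values.items():
        av = realized.get(key)
        if av is None:
            continue
        diffs.append(pv - 100.0 * av)
    if not diffs:
        raise ValueError("no overlapping keys with defined LDDT")
    if metric == "mad":
        return float(sum(abs(d) for d in diffs) / len(diffs))
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def rank_selfassessment(
    rmsd_table: pd.DataFrame,
    participation_min: float = 0.8,
    zconfig: ZConfig = ZConfig(exclusion_sd=2.0),
    pooling: Literal["mean_then_z", "z_per_model"] = "mean_then_z",
) -> pd.DataFrame:
    """Rank predictors by summed per-target Z on negated pLDDT RMSD.

    ``rmsd_table`` columns: predictor, target, model, rmsd — all five models
    per target enter the evaluation. ``mean_then_z`` (default) averages a
    predictor's five per-model RMSDs per target before the per-target Z;
    ``z_per_model`` Z-scores each model slot separately and sums. Predictors
    covering fewer than ``participation_min`` of the targets are excluded;
    targets a predictor skipped contribute exactly 0.
    """
    required = {"predictor", "target", "model", "rmsd"}
    if not required.issubset(rmsd_table.columns):
        raise ValueError(f"rmsd table needs columns {sorted(required)}")
    targets = sorted(rmsd_table["target"].unique())
    n_targets = len(targets)
    min_targets = math.ceil(participation_min * n_targets - 1e-9)
    coverage = rmsd_table.groupby("predictor")["target"].nunique()
    eligible = sorted(coverage.index[coverage >= min_targets])
    table = rmsd_table[rmsd_table["predictor"].isin(eligible)]

    z_sum = {p: 0.0 for p in eligible}
    if pooling == "mean_then_z":
        per_pt = table.groupby(["target", "predictor"])["rmsd"].mean()
        for t in targets:
            vals = per_pt.xs(t, level="target") if t in per_pt.index.get_level_values(0) else None
            if vals is None or vals.empty:
                continue
            z = two_pass_z({p: -v for p, v in vals.items()}, zconfig)
            for p, zv in z.items():
                z_sum[p] += zv
    elif pooling == "z_per_model":
        for (t, m), grp in table.groupby(["target", "model"]):
            vals = dict(zip(grp["predictor"], grp["rmsd"]))
            z = two_pass_z({p: -v for p, v in vals.items()}, zconfig)
            for p, zv in z.items():
                z_sum[p] += zv
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    out = pd.DataFrame(
        {"predictor": eligible, "z_sum": [z_sum[p] for p in eligible]}
    ).sort_values(["z_sum", "predictor"], ascending=[False, True], ignore_index=True)
    out["rank"] = out["z_sum"].rank(method="min", ascending=False).astype(int)
    return out
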