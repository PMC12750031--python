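"""Synthetic targets, model pools, score tables and predictor submissions.

Everything downstream of the scoring machinery is testable without any
external archive: targets are smooth multimeric backbone traces, model pools
perturb the target with controllable coordinate noise (emulating large
sampled pools whose quality distribution ranges from tightly redundant to
broadly spread), and synthetic predictors observe true scores through
Gaussian noise of per-predictor "fidelity" before ranking or selecting.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .qmode3 import ScoreTable, category_metrics
from .structures import Atom, Chain, Residue, Structure

AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


class GenerationError(RuntimeError):
    """Chain packing failed within the retry budget."""


@dataclass(frozen=True)
class PoolSpec:
    """Noise recipe for a model pool.

    ``noise_profile`` gives one coordinate-noise sigma (Å) per model;
    ``redundancy_fraction`` overrides that fraction of the pool (from the
    front) with the first sigma, creating a cluster of near-identical models
    like the redundant regimes seen in large sampled pools.
    """

    n_models: int
    noise_profile: Tuple[float, ...]
    redundancy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "noise_profile", tuple(float(s) for s in self.noise_profile))
        if self.n_models < 6:
            raise ValueError("a pool needs at least 6 models")
        if len(self.noise_profile) != self.n_models:
            raise ValueError("noise_profile must list one sigma per model")
        if any(s < 0 for s in self.noise_profile):
            raise ValueError("noise sigmas must be non-negative")
        if not 0.0 <= self.redundancy_fraction <= 1.0:
            raise ValueError("redundancy_fraction must lie in [0, 1]")

    @classmethod
    def from_sigma_grid(
        cls, sigmas: Sequence[float], per_sigma: int, redundancy_fraction: float = 0.0, seed: int = 0
    ) -> "PoolSpec":
        profile = tuple(float(s) for s in sigmas for _ in range(per_sigma))
        return cls(len(profile), profile, redundancy_fraction, seed)


@dataclass(frozen=True)
class PredictorSpec:
    """Per-predictor score-observation noise ("fidelity") recipe.

    A sigma of 0 is an oracle predictor; ``math.inf`` destroys all signal by
    shuffling the observed scores (a label-permutation null).
    """

    n_predictors: int
    fidelity_sigmas: Tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fidelity_sigmas", tuple(float(s) for s in self.fidelity_sigmas)
        )
        if len(self.fidelity_sigmas) != self.n_predictors:
            raise ValueError("fidelity_sigmas must list one sigma per predictor")
        if any(s < 0 for s in self.fidelity_sigmas):
            raise ValueError("fidelity sigmas must be non-negative")

    @property
    def names(self) -> List[str]:
        return [f"pred_{i:02d}" for i in range(self.n_predictors)]


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


def _backbone_chain(chain_id: str, names: Sequence[str], start_index: int = 1) -> Chain:
    """Smooth helical backbone trace with CA, N, C, O per residue."""
    n = len(names)
    turn = math.radians(100.0)
    radius, rise = 2.3, 1.5
    ca = np.array(
        [
            (radius * math.cos(turn * i), radius * math.sin(turn * i), rise * i)
            for i in range(n)
        ]
    )
    residues = []
    for i, name in enumerate(names):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[min(i + 1, n - 1)] - ca[i])
        next_ca = ca[i + 1] if i < n - 1 else ca[i] + (ca[i] - ca[i - 1])
        tangent = next_ca - prev_ca
        tangent = tangent / np.linalg.norm(tangent)
        outward = ca[i] - np.array([0.0, 0.0, ca[i][2]])
        outward = outward / np.linalg.norm(outward)
        side = np.cross(tangent, outward)
        atoms = [
            Atom("N", ca[i] - 1.46 * tangent + 0.4 * outward, 100.0),
            Atom("CA", ca[i], 100.0),
            Atom("C", ca[i] + 1.52 * tangent + 0.3 * side, 100.0),
            Atom("O", ca[i] + 1.52 * tangent + 0.3 * side + 1.23 * outward, 100.0),
        ]
        residues.append(Residue(start_index + i, name, atoms))
    return Chain(chain_id, residues)


def _chain_coords(chain: Chain) -> np.ndarray:
    return np.array([a.position for r in chain.residues for a in r.atoms])


def _shift_chain(chain: Chain, offset: np.ndarray) -> None:
    for r in chain.residues:
        for a in r.atoms:
            a.position = a.position + offset


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min())


def make_target(
    n_chain_classes: int,
    copies_per_class: Sequence[int],
    residues_per_chain: int,
    seed: int = 0,
    target_gap: float = 4.5,
    max_retries: int = 20,
) -> Structure:
    """Deterministic toy multimeric target.

    Each sequence class gets a random residue-name sequence (identical across
    its copies); chains are stacked along x so that every chain forms at
    least one inter-chain contact within 5 Å with its neighbour.
    """
    if n_chain_classes < 1 or residues_per_chain < 5:
        raise ValueError("need ≥ 1 chain class and ≥ 5 residues per chain")
    if len(copies_per_class) != n_chain_classes or any(c < 1 for c in copies_per_class):
        raise ValueError("copies_per_class must list ≥ 1 copies for each class")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + i) for i in range(sum(copies_per_class))]
    sequences = [
        [AMINO3[k] for k in rng.integers(0, len(AMINO3), size=residues_per_chain)]
        for _ in range(n_chain_classes)
    ]
    chains: List[Chain] = []
    idx = 0
    for cls, copies in enumerate(copies_per_class):
        for _ in range(copies):
            chains.append(_backbone_chain(chain_ids[idx], sequences[cls]))
            idx += 1

    placed = [chains[0]]
    for chain in chains[1:]:
        prev = np.vstack([_chain_coords(c) for c in placed])
        base = _chain_coords(chain)
        # start beyond the placed assembly, then walk in until the gap closes
        offset = np.array([prev[:, 0].max() - base[:, 0].min() + 10.0, 0.0, 0.0])
        _shift_chain(chain, offset)
        ok = False
        for _ in range(max_retries):
            d = _min_dist(_chain_coords(chain), prev)
            if abs(d - target_gap) < 0.45:
                ok = True
                break
            step = min(d - target_gap, 3.0) if d > target_gap else (d - target_gap)
            _shift_chain(chain, np.array([-step, 0.0, 0.0]))
        if not ok:
            raise GenerationError("could not pack chains to the requested contact gap")
        placed.append(chain)
    return Structure(f"target_s{seed}", placed, role="reference")


# ---------------------------------------------------------------------------
# Model pools
# ---------------------------------------------------------------------------


def make_model_pool(target: Structure, spec: PoolSpec) -> List[Structure]:
    """Perturbed copies of the target with pLDDT written to B-factors.

    Model k applies per-chain rigid jitter (translation ≤ 1 Å, rotation ≤ 5°,
    both scaled by min(sigma, 1) so a sigma-0 model is bit-identical to the
    target) followed by isotropic Gaussian coordinate noise of sigma
    noise_profile[k]. Each atom's pLDDT is a deterministic decreasing
    function of its displacement: 100·exp(−d/2 Å).
    """
    rng = np.random.default_rng(spec.seed)
    sigmas = list(spec.noise_profile)
    n_red = int(round(spec.redundancy_fraction * spec.n_models))
    for k in range(n_red):
        sigmas[k] = spec.noise_profile[0]

    pool: List[Structure] = []
    for k, sigma in enumerate(sigmas):
        model = target.copy(new_id=f"model_{k:03d}", role="model")
        scale = min(sigma, 1.0)
        for chain in model.chains:
            coords = _chain_coords(chain)
            centroid = coords.mean(axis=0)
            if scale > 0:
                angle = math.radians(5.0) * scale * rng.random()
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(angle * axis)
                shift = rng.normal(size=3)
                shift = shift / np.linalg.norm(shift) * (scale * rng.random())
            else:
                rot, shift = None, np.zeros(3)
            for res in chain.residues:
                for atom in res.atoms:
                    pos = atom.position
                    if rot is not None:
                        pos = rot.apply(pos - centroid) + centroid
                    pos = pos + shift
                    if sigma > 0:
                        pos = pos + rng.normal(scale=sigma, size=3)
                    atom.position = np.asarray(pos)
        # pLDDT from realized displacement against the unperturbed target
        for tchain, mchain in zip(target.chains, model.chains):
            for tres, mres in zip(tchain.residues, mchain.residues):
                for tatom, matom in zip(tres.atoms, mres.atoms):
                    d = float(np.linalg.norm(matom.position - tatom.position))
                    matom.bfactor = round(100.0 * math.exp(-d / 2.0), 2)
        pool.append(model)
    return pool


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def make_score_table(
    n_targets: int,
    n_models: int,
    category: str = "monomer",
    seed: int = 0,
    metric_noise: float = 0.02,
) -> ScoreTable:
    """Synthetic per-category score table with realistically correlated metrics.

    Each model draws a latent quality q ∈ [0, 1]; every similarity metric is
    a noisy monotone transform of q (so metrics are strongly correlated, as
    real structural criteria are), and RMSD is a decreasing transform.
    """
    rng = np.random.default_rng(seed)
    metrics = category_metrics(category)
    rows = []
    for t in range(n_targets):
        # per-target difficulty: center and spread of the quality distribution
        center = rng.uniform(0.35, 0.85)
        spread = rng.uniform(0.05, 0.25)
        q = np.clip(rng.normal(center, spread, size=n_models), 0.0, 1.0)
        for metric in metrics:
            gain = rng.uniform(0.7, 1.0)
            offs = rng.uniform(0.0, 0.15)
            noisy = q * gain + offs + rng.normal(0.0, metric_noise, size=n_models)
            if metric == "rmsd":
                vals = np.clip((1.0 - q) * 12.0 + rng.normal(0.0, 0.3, size=n_models), 0.0, None)
            else:
                vals = np.clip(noisy, 0.0, 1.0)
            for m in range(n_models):
                rows.append((f"T{t:03d}", f"model_{m:03d}", metric, float(vals[m])))
    df = pd.DataFrame(rows, columns=["target", "model", "metric", "value"])
    return ScoreTable(values=df, category=category)


# ---------------------------------------------------------------------------
# Predictor submissions
# ---------------------------------------------------------------------------


def _observe(true: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(sigma):
        return true[rng.permutation(len(true))]
    if sigma == 0:
        return true.copy()
    return true + rng.normal(0.0, sigma, size=len(true))


def make_submissions(
    score_table,
    spec: PredictorSpec,
    mode: str,
    primary_metric: Optional[str] = None,
    qscore_metric: Optional[str] = None,
    n_slots: int = 5,
) -> pd.DataFrame:
    """Synthetic predictor submissions from a score table.

    Predictor p observes each true score through Gaussian noise of
    ``fidelity_sigmas[p]`` (∞ → shuffled scores) and submits:

    * ``qmode1`` — per-model noisy SCORE/QSCORE clipped to [0, 1]
      (``score_table``: ScoreTable or long DataFrame; SCORE truth from
      ``primary_metric``, QSCORE truth from ``qscore_metric``);
    * ``qmode2`` — per-residue noisy local estimates clipped to [0, 1]
      (``score_table``: DataFrame with target, model, chain, residue_index,
      value);
    * ``qmode3`` — the ``n_slots`` models with the best noisy primary score,
      best first.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.names

    if mode == "qmode2":
        df = score_table
        required = {"target", "model", "chain", "residue_index", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"qmode2 truth table needs columns {sorted(required)}")
        rows = []
        true = df["value"].to_numpy(dtype=float)
        for p, sigma in zip(names, spec.fidelity_sigmas):
            obs = np.clip(_observe(true, sigma, rng), 0.0, 1.0)
            for (_, row), v in zip(df.iterrows(), obs):
                rows.append(
                    (p, row["target"], row["model"], row["chain"], row["residue_index"], float(v))
                )
        return pd.DataFrame(
            rows,
            columns=["predictor", "target", "model", "chain", "residue_index", "local_estimate"],
        )

    table = score_table if isinstance(score_table, ScoreTable) else ScoreTable(score_table)
    if primary_metric is None:
        primary_metric = "tm_score" if "tm_score" in table.metrics else table.metrics[0]

    if mode == "qmode1":
        if qscore_metric is None:
            qscore_metric = (
                "qs_best" if "qs_best" in table.metrics
                else ("qs_score" if "qs_score" in table.metrics else primary_metric)
            )
        rows = []
        for t in table.targets:
            score_truth = table.pool_scores(t, primary_metric)
            qscore_truth = table.pool_scores(t, qscore_metric)
            models = sorted(score_truth)
            s_true = np.array([score_truth[m] for m in models])
            q_true = np.array([qscore_truth[m] for m in models])
            for p, sigma in zip(names, spec.fidelity_sigmas):
                s_obs = np.clip(_observe(s_true, sigma, rng), 0.0, 1.0)
                q_obs = np.clip(_observe(q_true, sigma, rng), 0.0, 1.0)
                for m, sv, qv in zip(models, s_obs, q_obs):
                    rows.append((p, t, m, float(sv), float(qv)))
        return pd.DataFrame(rows, columns=["predictor", "target", "model", "score", "qscore"])

    if mode == "qmode3":
        rows = []
        higher = table.higher_better(primary_metric)
        for t in table.targets:
            truth = table.pool_scores(t, primary_metric)
            models = sorted(truth)
            true = np.array([truth[m] for m in models])
            for p, sigma in zip(names, spec.fidelity_sigmas):
                obs = _observe(true, sigma, rng)
                order = np.argsort(-obs if higher else obs, kind="stable")
                for rank, mi in enumerate(order[:n_slots], start=1):
                    rows.append((p, t, rank, models[mi]))
        return pd.DataFrame(rows, columns=["predictor", "target", "rank", "model"])

    raise ValueError(f"unknown mode {mode!r}")
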