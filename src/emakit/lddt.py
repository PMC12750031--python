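"""LDDT score family, interface detection and superposition RMSD.

LDDT (local distance difference test) measures, without any superposition,
the fraction of reference interatomic distances that a model preserves within
a set of tolerance thresholds (default 0.5/1/2/4 Å, inclusion radius 15 Å,
intra-residue pairs excluded). Variants provided here:

* per-atom / per-residue / global fractions;
* ``interchain_only`` (iLDDT) restricted to inter-chain contacts;
* an ``augmented`` variant that additionally charges the model for contacts
  that exist only in the model (both atoms resolved in the reference but the
  pair beyond the inclusion radius there). Such model-only contacts are
  counted as unpreserved at every threshold — a pure penalty for hallucinated
  interfaces that plain LDDT cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structures import ChainMapping, Structure, identity_mapping, kabsch_transform

AtomKey = Tuple[str, int, str]  # (chain id, residue index, atom name) — reference frame
ResidueKey = Tuple[str, int]


class MappingError(ValueError):
    """A model chain or atom cannot be resolved through the chain mapping."""


class UndefinedScoreError(ValueError):
    """The contact set is empty; the score is undefined."""


@dataclass(frozen=True)
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    interchain_only: bool = False
    augmented: bool = False

    def __post_init__(self) -> None:
        th = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", th)
        if not th or any(t <= 0 for t in th) or list(th) != sorted(set(th)):
            raise ValueError("thresholds must be strictly increasing and positive")
        if self.inclusion_radius <= max(th):
            raise ValueError("inclusion radius must exceed the largest threshold")


@dataclass
class ContactSet:
    """Atom pairs to check, in the reference frame.

    ``pairs`` indexes into ``keys``; ``ref_dist`` is the reference-structure
    distance; ``model_only`` marks contacts contributed by the augmented
    variant (pair within the inclusion radius in the model alone).
    """

    keys: List[AtomKey]
    pairs: np.ndarray        # (n, 2) int indices into keys
    ref_dist: np.ndarray     # (n,) Å
    model_only: np.ndarray   # (n,) bool

    def __len__(self) -> int:
        return int(self.pairs.shape[0])

    def pair_keys(self) -> List[Tuple[AtomKey, AtomKey, float, str]]:
        return [
            (
                self.keys[i],
                self.keys[j],
                float(d),
                "model-only" if mo else "reference",
            )
            for (i, j), d, mo in zip(self.pairs, self.ref_dist, self.model_only)
        ]


@dataclass
class LddtResult:
    per_atom: Dict[AtomKey, Optional[float]]
    per_residue: Dict[ResidueKey, Optional[float]]
    global_: float
    n_pairs_checked: int


def _atom_table(s: Structure):
    keys: List[AtomKey] = []
    coords: List[np.ndarray] = []
    chain_idx: List[int] = []
    res_uid: List[int] = []
    uid = -1
    for ci, chain in enumerate(s.chains):
        for res in chain.residues:
            uid += 1
            for atom in res.atoms:
                keys.append((chain.id, res.index, atom.name))
                coords.append(atom.position)
                chain_idx.append(ci)
                res_uid.append(uid)
    return keys, np.asarray(coords), np.asarray(chain_idx), np.asarray(res_uid)


def _model_positions(
    keys: Sequence[AtomKey], model: Structure, mapping: ChainMapping
) -> np.ndarray:
    """Model coordinates aligned to reference atom keys (NaN where missing)."""
    lookup: Dict[AtomKey, np.ndarray] = {
        (cid, res.index, atom.name): atom.position for cid, res, atom in model.iter_atoms()
    }
    inv_pairs = mapping.inverse_pairs()
    inv_resmap = mapping.inverse_residue_map()
    out = np.full((len(keys), 3), np.nan)
    for k, (tch, tresi, aname) in enumerate(keys):
        mch = inv_pairs.get(tch)
        if mch is None:
            continue
        mresi = inv_resmap.get(tch, {}).get(tresi)
        if mresi is None:
            continue
        pos = lookup.get((mch, mresi, aname))
        if pos is not None:
            out[k] = pos
    return out


def _candidate_pairs(coords: np.ndarray, res_uid: np.ndarray, chain_idx: np.ndarray,
                     radius: float, interchain_only: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Upper-triangle distinct-residue pairs within ``radius``; (pairs, dist)."""
    n = coords.shape[0]
    if n == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    mask &= res_uid[:, None] != res_uid[None, :]
    if interchain_only:
        mask &= chain_idx[:, None] != chain_idx[None, :]
    mask &= dist < radius
    ii, jj = np.nonzero(mask)
    return np.column_stack([ii, jj]), dist[ii, jj]


def build_contacts(
    reference: Structure,
    model: Structure,
    mapping: Optional[ChainMapping] = None,
    params: LddtParams = LddtParams(),
) -> ContactSet:
    """Extract the contact set driving an LDDT evaluation.

    Reference contacts are all distinct-residue atom pairs within the
    inclusion radius in the reference (inter-chain only when requested).
    With ``params.augmented``, pairs within the radius in the model alone —
    both atoms mapping to reference atoms — are appended as model-only
    contacts carrying their (out-of-radius) reference distance.
    """
    if reference.n_atoms == 0 or model.n_atoms == 0:
        raise ValueError("structures must be non-empty")
    mapping = mapping if mapping is not None else identity_mapping(reference)
    for chain in model.chains:
        if chain.id not in mapping.pairs:
            raise MappingError(f"model chain {chain.id!r} is not mapped to the target")

    keys, coords, chain_idx, res_uid = _atom_table(reference)
    pairs, dist = _candidate_pairs(coords, res_uid, chain_idx, params.inclusion_radius,
                                   params.interchain_only)
    model_only = np.zeros(len(pairs), dtype=bool)

    if params.augmented:
        mpos = _model_positions(keys, model, mapping)
        present = np.all(np.isfinite(mpos), axis=1)
        # model-frame candidate pairs among atoms covered by the reference
        far = 1e6  # parks absent atoms far outside any inclusion radius
        mpairs, _ = _candidate_pairs(
            np.where(present[:, None], mpos, far),
            res_uid, chain_idx, params.inclusion_radius, params.interchain_only,
        )
        seen = {(int(i), int(j)) for i, j in pairs}
        extra = [
            (int(i), int(j)) for i, j in mpairs
            if (int(i), int(j)) not in seen and present[i] and present[j]
        ]
        if extra:
            eidx = np.array(extra, dtype=int)
            edist = np.linalg.norm(coords[eidx[:, 0]] - coords[eidx[:, 1]], axis=1)
            pairs = np.vstack([pairs, eidx]) if len(pairs) else eidx
            dist = np.concatenate([dist, edist])
            model_only = np.concatenate([model_only, np.ones(len(extra), dtype=bool)])

    return ContactSet(keys=keys, pairs=np.asarray(pairs, dtype=int).reshape(-1, 2),
                      ref_dist=dist, model_only=model_only)


def lddt_score(
    reference: Structure,
    model: Structure,
    mapping: Optional[ChainMapping] = None,
    params: LddtParams = LddtParams(),
    contacts: Optional[ContactSet] = None,
) -> LddtResult:
    """Score a model against a reference with the LDDT family.

    For every contact and threshold ``t`` the check passes iff
    ``|d_model − d_reference| < t``. Pairs with atoms missing from the model
    fail every threshold, as do model-only (augmented) contacts. Per-atom and
    per-residue fractions pool the checks of all pairs touching that atom or
    residue; entries with no contacts are ``None`` (undefined), never 0.
    """
    mapping = mapping if mapping is not None else identity_mapping(reference)
    if contacts is None:
        contacts = build_contacts(reference, model, mapping, params)
    if len(contacts) == 0:
        raise UndefinedScoreError("no contacts within the inclusion radius")

    keys = contacts.keys
    mpos = _model_positions(keys, model, mapping)
    i, j = contacts.pairs[:, 0], contacts.pairs[:, 1]
    d_model = np.linalg.norm(mpos[i] - mpos[j], axis=1)  # NaN when atoms missing
    delta = np.abs(d_model - contacts.ref_dist)

    T = len(params.thresholds)
    # NaN comparisons are False, so missing atoms fail every threshold.
    with np.errstate(invalid="ignore"):
        passed = np.zeros(len(contacts))
        for t in params.thresholds:
            passed += (delta < t).astype(float)
    passed[contacts.model_only] = 0.0  # pure penalty for hallucinated contacts

    n_atoms = len(keys)
    checks_atom = np.zeros(n_atoms)
    passed_atom = np.zeros(n_atoms)
    for col in (i, j):
        np.add.at(checks_atom, col, T)
        np.add.at(passed_atom, col, passed)

    res_keys: List[ResidueKey] = []
    res_index_of_atom = np.empty(n_atoms, dtype=int)
    seen: Dict[ResidueKey, int] = {}
    for a, k in enumerate(keys):
        rk = (k[0], k[1])
        if rk not in seen:
            seen[rk] = len(res_keys)
            res_keys.append(rk)
        res_index_of_atom[a] = seen[rk]
    checks_res = np.zeros(len(res_keys))
    passed_res = np.zeros(len(res_keys))
    for col in (i, j):
        np.add.at(checks_res, res_index_of_atom[col], T)
        np.add.at(passed_res, res_index_of_atom[col], passed)

    per_atom: Dict[AtomKey, Optional[float]] = {
        k: (float(passed_atom[a] / checks_atom[a]) if checks_atom[a] > 0 else None)
        for a, k in enumerate(keys)
    }
    per_residue: Dict[ResidueKey, Optional[float]] = {
        rk: (float(passed_res[r] / checks_res[r]) if checks_res[r] > 0 else None)
        for r, rk in enumerate(res_keys)
    }
    total_checks = len(contacts) * T
    return LddtResult(
        per_atom=per_atom,
        per_residue=per_residue,
        global_=float(passed.sum() / total_checks),
        n_pairs_checked=len(contacts),
    )


def interface_residues(s: Structure, contact_distance: float = 5.0) -> Set[ResidueKey]:
    """Residues with any atom within ``contact_distance`` of another chain."""
    if len(s.chains) < 2:
        return set()
    keys, coords, chain_idx, res_uid = _atom_table(s)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    close = (dist < contact_distance) & (chain_idx[:, None] != chain_idx[None, :])
    hit = np.any(close, axis=1)
    return {(keys[a][0], keys[a][1]) for a in np.nonzero(hit)[0]}


def superpose_rmsd(
    model: Structure, reference: Structure, mapping: Optional[ChainMapping] = None
) -> float:
    """CA RMSD after least-squares (Kabsch) rigid superposition."""
    mapping = mapping if mapping is not None else identity_mapping(model)
    mv, fx = [], []
    for mcid, tcid in mapping.pairs.items():
        mca = model.chain(mcid).ca_map()
        tca = reference.chain(tcid).ca_map()
        for mresi, tresi in mapping.residue_map[mcid].items():
            if mresi in mca and tresi in tca:
                mv.append(mca[mresi])
                fx.append(tca[tresi])
    if len(mv) < 3:
        raise ValueError("superposition needs at least 3 mapped CA pairs")
    _, _, _, rmsd = kabsch_transform(np.array(mv), np.array(fx))
    return rmsd
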