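"""Shared fixtures: random toy structures and an independent LDDT oracle."""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pytest

from emakit.structures import Atom, Chain, Residue, Structure

ATOM_NAMES = ("N", "CA", "C", "O")


def random_structure(
    rng: np.random.Generator,
    n_residues: int = 15,
    n_chains: int = 2,
    box: float = 18.0,
    structure_id: str = "rand",
) -> Structure:
    """Random positions in a box — geometry-free input for scoring oracles."""
    chains = []
    for c in range(n_chains):
        residues = []
        for i in range(1, n_residues + 1):
            center = rng.uniform(0, box, size=3)
            atoms = [
                Atom(name, center + rng.uniform(-0.8, 0.8, size=3), 80.0)
                for name in ATOM_NAMES
            ]
            residues.append(Residue(i, "ALA", atoms))
        chains.append(Chain(chr(ord("A") + c), residues))
    return Structure(structure_id, chains, role="reference")


def perturb(
    s: Structure,
    rng: np.random.Generator,
    sigma: float = 1.0,
    drop_fraction: float = 0.0,
    structure_id: str = "pert",
) -> Structure:
    """Noisy copy, optionally with atoms deleted (incomplete model)."""
    out = s.copy(new_id=structure_id, role="model")
    for chain in out.chains:
        for res in chain.residues:
            kept = []
            for atom in res.atoms:
                if drop_fraction and rng.random() < drop_fraction and atom.name != "CA":
                    continue
                atom.position = atom.position + rng.normal(scale=sigma, size=3)
                kept.append(atom)
            res.atoms = kept if kept else res.atoms[:1]
    return out


def brute_force_lddt(
    reference: Structure,
    model: Structure,
    radius: float = 15.0,
    thresholds: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    interchain_only: bool = False,
    augmented: bool = False,
) -> float:
    """All-pairs/all-thresholds re-derivation of global LDDT (identity mapping).

    Independent of the package's vectorized path: plain Python loops over
    every atom pair. Model-only contacts of the augmented variant contribute
    checks but no passes.
    """
    ref_atoms = [
        (cid, res.index, atom.name, atom.position)
        for cid, res, atom in reference.iter_atoms()
    ]
    mpos: Dict[Tuple[str, int, str], np.ndarray] = {
        (cid, res.index, atom.name): atom.position for cid, res, atom in model.iter_atoms()
    }
    checks = 0
    passed = 0
    for i in range(len(ref_atoms)):
        ci, ri, ni, pi = ref_atoms[i]
        for j in range(i + 1, len(ref_atoms)):
            cj, rj, nj, pj = ref_atoms[j]
            if (ci, ri) == (cj, rj):
                continue
            if interchain_only and ci == cj:
                continue
            dref = float(np.linalg.norm(pi - pj))
            in_reference = dref < radius
            model_only = False
            if not in_reference:
                if not augmented:
                    continue
                ki, kj = (ci, ri, ni), (cj, rj, nj)
                if ki in mpos and kj in mpos:
                    if float(np.linalg.norm(mpos[ki] - mpos[kj])) < radius:
                        model_only = True
                if not model_only:
                    continue
            checks += len(thresholds)
            if model_only:
                continue
            ki, kj = (ci, ri, ni), (cj, rj, nj)
            if ki not in mpos or kj not in mpos:
                continue  # missing atoms fail every threshold
            dm = float(np.linalg.norm(mpos[ki] - mpos[kj]))
            for t in thresholds:
                if abs(dm - dref) < t:
                    passed += 1
    if checks == 0:
        raise ValueError("empty contact set")
    return passed / checks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def dimer(rng) -> Structure:
    return random_structure(rng, n_residues=10, n_chains=2, structure_id="dimer")
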