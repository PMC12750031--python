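"""Structure data model, PDB I/O, stoichiometry signatures and chain mapping.

The in-memory model is a plain chain → residue → atom hierarchy carrying
coordinates (Å) and the B-factor channel, which by CASP convention holds the
predicted LDDT (pLDDT, 0–100) in submitted models. The PDB dialect is
deliberately narrow: single-model files, ``ATOM`` records only, blank or 'A'
altlocs, no insertion codes — the clean numbering used for CASP-style
submissions and for the synthetic fixtures in this package.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.transform import Rotation


class PDBParseError(ValueError):
    """A PDB record could not be interpreted."""


class PDBFormatError(ValueError):
    """A structure cannot be serialized to fixed-column PDB."""


class EmptyStructureError(PDBParseError):
    """No atoms were found."""


class StoichiometryError(ValueError):
    """Model and target chain compositions differ."""


class AtomRecord(NamedTuple):
    """Flat view of one atom: the unit the PDB reader/writer works in."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: Tuple[float, float, float]
    bfactor: float


@dataclass
class Atom:
    name: str
    position: np.ndarray  # shape (3,), Å
    bfactor: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (
            self.name == other.name
            and bool(np.array_equal(self.position, other.position))
            and self.bfactor == other.bfactor
        )


@dataclass
class Residue:
    index: int
    name: str
    atoms: List[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    def ca_map(self) -> Dict[int, np.ndarray]:
        """Residue index → CA position for residues that have a CA atom."""
        out: Dict[int, np.ndarray] = {}
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.index] = ca.position
        return out


@dataclass
class Structure:
    id: str
    chains: List[Chain] = field(default_factory=list)
    role: str = "model"  # "reference" | "model"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"structure {self.id!r}: duplicate chain ids")

    # -- iteration helpers -------------------------------------------------
    def iter_atoms(self) -> Iterator[Tuple[str, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain.id, res, atom

    def records(self) -> List[AtomRecord]:
        return [
            AtomRecord(cid, res.index, res.name, atom.name, tuple(atom.position), atom.bfactor)
            for cid, res, atom in self.iter_atoms()
        ]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.records() == other.records()

    def copy(self, new_id: Optional[str] = None, role: Optional[str] = None) -> "Structure":
        chains = [
            Chain(
                c.id,
                [
                    Residue(r.index, r.name, [Atom(a.name, a.position.copy(), a.bfactor) for a in r.atoms])
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return Structure(new_id if new_id is not None else self.id, chains, role if role is not None else self.role)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def parse_pdb(text: str, structure_id: str = "structure", role: str = "model") -> Structure:
    """Parse fixed-column ``ATOM`` records into a :class:`Structure`.

    HETATM records and altlocs other than blank/'A' are dropped; insertion
    codes and out-of-order residue numbering are rejected with the offending
    line number. Coordinates and B-factors are kept at full printed precision.
    """
    chains: Dict[str, Chain] = {}
    order: List[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 66:
            raise PDBParseError(f"line {lineno}: ATOM record shorter than 66 columns")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        if line[26] != " ":
            raise PDBParseError(f"line {lineno}: insertion codes are not supported")
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21]
        try:
            residue_index = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            bfactor = float(line[60:66])
        except ValueError:
            raise PDBParseError(f"line {lineno}: malformed ATOM record") from None
        if not atom_name:
            raise PDBParseError(f"line {lineno}: blank atom name")

        chain = chains.get(chain_id)
        if chain is None:
            chain = Chain(chain_id)
            chains[chain_id] = chain
            order.append(chain_id)
        if chain.residues and chain.residues[-1].index == residue_index:
            residue = chain.residues[-1]
            if residue.name != residue_name:
                raise PDBParseError(
                    f"line {lineno}: residue {chain_id}:{residue_index} renamed "
                    f"{residue.name!r} → {residue_name!r}"
                )
        else:
            if chain.residues and chain.residues[-1].index >= residue_index:
                raise PDBParseError(
                    f"line {lineno}: residue indices must be strictly increasing in chain {chain_id!r}"
                )
            residue = Residue(residue_index, residue_name)
            chain.residues.append(residue)
        if residue.atom(atom_name) is not None:
            raise PDBParseError(
                f"line {lineno}: duplicate atom {atom_name!r} in residue {chain_id}:{residue_index}"
            )
        residue.atoms.append(Atom(atom_name, (x, y, z), bfactor))

    structure = Structure(structure_id, [chains[cid] for cid in order], role)
    if structure.n_atoms == 0:
        raise EmptyStructureError("no ATOM records found")
    return structure


def _element_guess(atom_name: str) -> str:
    letters = [c for c in atom_name if c.isalpha()]
    return letters[0].upper() if letters else ""


def write_pdb(s: Structure) -> str:
    """Serialize a structure to fixed-column PDB (ATOM/TER/END)."""
    if s.n_atoms == 0:
        raise PDBFormatError("cannot write an empty structure")
    lines: List[str] = []
    serial = 1
    for chain in s.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = (float(v) for v in atom.position)
                for v in (x, y, z):
                    if abs(v) > 9999.999:
                        raise PDBFormatError(
                            f"coordinate {v:.3f} exceeds the ±9999.999 Å PDB field width"
                        )
                name4 = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name4:<4s} {res.name:>3s} {chain.id}"
                    f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}"
                    f"{atom.bfactor:6.2f}          {_element_guess(atom.name):>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(f"TER   {serial:5d}      {last.name:>3s} {chain.id}{last.index:4d}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Stoichiometry and chain mapping
# ---------------------------------------------------------------------------

Signature = Tuple[Tuple[Tuple[str, ...], int], ...]


def stoichiometry_signature(s: Structure) -> Signature:
    """Multiset of chain sequence classes, canonically ordered.

    Chains with identical residue-name sequences collapse into one class with
    a copy count, so the signature is invariant under chain reordering and
    relabeling — the unit the stoichiometry filter compares.
    """
    if s.n_atoms == 0:
        raise EmptyStructureError("cannot compute the signature of an empty structure")
    counts = Counter(tuple(r.name for r in chain.residues) for chain in s.chains)
    return tuple(sorted(counts.items()))


@dataclass
class ChainMapping:
    """Model → target chain assignment plus per-chain residue index maps."""

    pairs: Dict[str, str]
    residue_map: Dict[str, Dict[int, int]]
    mismatches: Set[Tuple[str, int]] = field(default_factory=set)

    def inverse_pairs(self) -> Dict[str, str]:
        return {t: m for m, t in self.pairs.items()}

    def inverse_residue_map(self) -> Dict[str, Dict[int, int]]:
        """Target chain → (target residue index → model residue index)."""
        inv: Dict[str, Dict[int, int]] = {}
        for mchain, tchain in self.pairs.items():
            inv[tchain] = {t: m for m, t in self.residue_map[mchain].items()}
        return inv


def identity_mapping(s: Structure) -> ChainMapping:
    return ChainMapping(
        pairs={c.id: c.id for c in s.chains},
        residue_map={c.id: {r.index: r.index for r in c.residues} for c in s.chains},
    )


def kabsch_transform(moving: np.ndarray, fixed: np.ndarray):
    """Optimal rigid transform of ``moving`` onto ``fixed`` (least squares).

    Returns ``(rotation, moving_centroid, fixed_centroid, rmsd)``; apply as
    ``rotation.apply(x - moving_centroid) + fixed_centroid``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[0] < 3:
        raise ValueError("superposition needs ≥ 3 paired points of equal shape")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fixed - fc, moving - mc)
    return rot, mc, fc, float(rssd) / np.sqrt(moving.shape[0])


def _class_groups(s: Structure) -> Dict[Tuple[str, ...], List[Chain]]:
    groups: Dict[Tuple[str, ...], List[Chain]] = {}
    for chain in s.chains:
        groups.setdefault(tuple(r.name for r in chain.residues), []).append(chain)
    return groups


def _pair_cost(model_ca: Dict[int, np.ndarray], target_ca: Dict[int, np.ndarray], transform) -> float:
    shared = sorted(set(model_ca) & set(target_ca))
    if not shared:
        return float("inf")
    rot, mc, fc, _ = transform
    m = rot.apply(np.array([model_ca[i] for i in shared]) - mc) + fc
    t = np.array([target_ca[i] for i in shared])
    return float(np.mean(np.sum((m - t) ** 2, axis=1)))


def map_chains(model: Structure, target: Structure, exhaustive_limit: int = 4) -> ChainMapping:
    """Assign model chains to target chains of the same sequence class.

    Unique classes map directly. Within a class of several copies the
    assignment minimizing summed CA distance after a whole-complex
    superposition is chosen — exhaustively for up to ``exhaustive_limit``
    copies, greedily above. Residues are matched by identical author index;
    index-matched residues with differing names are flagged, not remapped.
    """
    if stoichiometry_signature(model) != stoichiometry_signature(target):
        raise StoichiometryError(
            f"model {model.id!r} stoichiometry differs from target {target.id!r}"
        )
    model_groups = _class_groups(model)
    target_groups = _class_groups(target)

    def assignment_rmsd(pairing: Dict[str, str]) -> float:
        mv, fx = [], []
        for mcid, tcid in pairing.items():
            mca = model.chain(mcid).ca_map()
            tca = target.chain(tcid).ca_map()
            for i in sorted(set(mca) & set(tca)):
                mv.append(mca[i])
                fx.append(tca[i])
        if len(mv) < 3:
            return 0.0
        return kabsch_transform(np.array(mv), np.array(fx))[3]

    naive: Dict[str, str] = {}
    for seq, mchains in model_groups.items():
        for mc_, tc_ in zip(mchains, target_groups[seq]):
            naive[mc_.id] = tc_.id

    pairs: Dict[str, str] = dict(naive)
    for seq, mchains in model_groups.items():
        tchains = target_groups[seq]
        n = len(mchains)
        if n == 1:
            continue
        if n <= exhaustive_limit:
            # each candidate is judged by its own whole-complex superposition,
            # otherwise the cost is biased toward the provisional pairing
            best_perm, best_cost = None, np.inf
            for perm in itertools.permutations(range(n)):
                candidate = dict(pairs)
                for i, mc_ in enumerate(mchains):
                    candidate[mc_.id] = tchains[perm[i]].id
                cost = assignment_rmsd(candidate)
                if cost < best_cost:
                    best_perm, best_cost = perm, cost
            for i, mc_ in enumerate(mchains):
                pairs[mc_.id] = tchains[best_perm[i]].id
        else:  # greedy under the provisional superposition
            mv, fx = [], []
            for mcid, tcid in pairs.items():
                mca = model.chain(mcid).ca_map()
                tca = target.chain(tcid).ca_map()
                for i in sorted(set(mca) & set(tca)):
                    mv.append(mca[i])
                    fx.append(tca[i])
            transform = kabsch_transform(np.array(mv), np.array(fx)) if len(mv) >= 3 else None
            if transform is None:
                continue
            cost = np.array(
                [
                    [_pair_cost(mc_.ca_map(), tc_.ca_map(), transform) for tc_ in tchains]
                    for mc_ in mchains
                ]
            )
            free_m, free_t = set(range(n)), set(range(n))
            while free_m:
                i, j = min(
                    ((i, j) for i in free_m for j in free_t), key=lambda ij: cost[ij[0], ij[1]]
                )
                pairs[mchains[i].id] = tchains[j].id
                free_m.discard(i)
                free_t.discard(j)

    residue_map: Dict[str, Dict[int, int]] = {}
    mismatches: Set[Tuple[str, int]] = set()
    for mcid, tcid in pairs.items():
        mres = {r.index: r.name for r in model.chain(mcid).residues}
        tres = {r.index: r.name for r in target.chain(tcid).residues}
        shared = sorted(set(mres) & set(tres))
        residue_map[mcid] = {i: i for i in shared}
        for i in shared:
            if mres[i] != tres[i]:
                mismatches.add((mcid, i))
    return ChainMapping(pairs=pairs, residue_map=residue_map, mismatches=mismatches)
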