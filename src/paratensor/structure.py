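"""Molecular structures: multi-model PDB ingestion and per-atom metadata.

Coordinates are converted from the PDB's Angstrom convention to metres at
parse time.  Each atom carries the gyromagnetic ratio of its default
NMR-active isotope (H -> 1H, N -> 15N, C -> 13C, configurable) and may
carry a chemical-shift-anisotropy (CSA) tensor in ppm.  Default CSA
tensors for backbone amide 1H, amide 15N and carbonyl 13C spins are
parameterised in the package configuration and oriented from the local
peptide geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .config import Config, csa_parameters, default_config
from .constants import ANGSTROM

__all__ = [
    "AtomRecord",
    "StructureEnsemble",
    "read_pdb",
    "write_pdb",
    "default_csa",
    "attach_default_csas",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model: identity, coordinates (m) and NMR metadata."""

    model_index: int
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    gamma: float | None = None
    csa: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))

    @property
    def identity(self) -> tuple:
        """Model-independent identity used to match atoms across models."""
        return (self.chain, self.residue_number, self.atom_name)


class StructureEnsemble:
    """A (possibly multi-model) structure as a flat table of atom records."""

    def __init__(self, atoms):
        self.atoms: list[AtomRecord] = list(atoms)
        self._index: dict[tuple, dict[int, int]] = {}
        models = set()
        for i, a in enumerate(self.atoms):
            models.add(a.model_index)
            slot = self._index.setdefault(a.identity, {})
            if a.model_index in slot:
                raise ValueError(
                    f"duplicate atom identity {a.identity} in model {a.model_index}"
                )
            slot[a.model_index] = i
        self.model_indices = sorted(models)

    @property
    def model_count(self) -> int:
        return len(self.model_indices)

    def model(self, model_index: int) -> "StructureEnsemble":
        return StructureEnsemble(
            [a for a in self.atoms if a.model_index == model_index]
        )

    def get(self, identity: tuple, model_index: int) -> AtomRecord | None:
        slot = self._index.get(tuple(identity))
        if slot is None or model_index not in slot:
            return None
        return self.atoms[slot[model_index]]

    def across_models(self, identity: tuple) -> list[AtomRecord]:
        """All model copies of an atom identity (possibly fewer than
        model_count if the atom is missing from some models)."""
        slot = self._index.get(tuple(identity), {})
        return [self.atoms[slot[m]] for m in sorted(slot)]

    def find(self, residue_number: int, atom_name: str,
             chain: str | None = None) -> list[AtomRecord]:
        """Model copies of an atom addressed the way data files address it
        (residue number + atom name, chain optional)."""
        out = []
        for ident, slot in self._index.items():
            c, rnum, aname = ident
            if rnum == residue_number and aname == atom_name and (
                chain is None or c == chain
            ):
                out.extend(self.atoms[slot[m]] for m in sorted(slot))
        return out

    def identities(self) -> list[tuple]:
        return list(self._index)

    def replace_atom(self, index: int, **changes) -> None:
        self.atoms[index] = replace(self.atoms[index], **changes)


def _pick_altloc(atom):
    """Highest-occupancy altloc; ties broken by first altloc id."""
    if not isinstance(atom, DisorderedAtom):
        return atom
    children = [atom.child_dict[k] for k in sorted(atom.child_dict)]
    best = children[0]
    for c in children[1:]:
        occ_c = c.get_occupancy() or 0.0
        occ_b = best.get_occupancy() or 0.0
        if occ_c > occ_b:
            best = c
    return best


def read_pdb(path, config: Config | None = None) -> StructureEnsemble:
    """Read all MODEL blocks of a PDB file into a StructureEnsemble.

    HETATM records (metal ions in particular) are retained so the
    paramagnetic centre can be placed on any atom of the file.
    """
    cfg = config or default_config()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pdb", str(path))
    records = []
    for model in structure:
        for chain in model:
            for residue in chain:
                seen = set()
                for atom in residue:
                    atom = _pick_altloc(atom)
                    name = atom.get_name().strip()
                    if name in seen:
                        continue
                    seen.add(name)
                    element = (atom.element or "").strip().capitalize()
                    records.append(
                        AtomRecord(
                            model_index=model.id,
                            chain=chain.id.strip() or "A",
                            residue_number=residue.id[1],
                            residue_name=residue.get_resname().strip(),
                            atom_name=name,
                            element=element,
                            coords=np.asarray(atom.get_coord(), dtype=float)
                            * ANGSTROM,
                            gamma=cfg.gamma(element),
                        )
                    )
    return StructureEnsemble(records)


def write_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write a minimal, standard-conforming multi-model PDB file."""
    lines = []
    multi = ensemble.model_count > 1
    for serial_model, m in enumerate(ensemble.model_indices, start=1):
        if multi:
            lines.append(f"MODEL     {serial_model:4d}")
        serial = 0
        for a in ensemble.atoms:
            if a.model_index != m:
                continue
            serial += 1
            x, y, z = a.coords / ANGSTROM
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            record = "HETATM" if a.residue_name in ("HOH",) or len(a.element) == 2 \
                else "ATOM  "
            lines.append(
                f"{record}{serial:5d} {name:<4s}{a.residue_name:>4s} "
                f"{a.chain:1s}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# default CSA tensors


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _frame_from(z0: np.ndarray, inplane: np.ndarray, beta: float):
    """Orthonormal frame with z tilted by beta from z0 within the
    (z0, inplane) plane; returns a 3x3 matrix with axis columns."""
    z0 = z0 / np.linalg.norm(z0)
    y = np.cross(z0, inplane)
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise ValueError("degenerate CSA geometry")
    y = y / ny
    z = _rotation_about(y, beta) @ z0
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def _neighbour(ens: StructureEnsemble, atom: AtomRecord, resnum: int, name: str):
    rec = ens.get((atom.chain, resnum, name), atom.model_index)
    return None if rec is None else rec.coords


def default_csa(ensemble: StructureEnsemble, atom: AtomRecord,
                config: Config | None = None) -> np.ndarray | None:
    """Literature-parameterised CSA tensor (ppm, molecular frame) for a
    backbone amide 1H/15N or carbonyl 13C spin; None for other atoms or
    when the orienting geometry atoms are missing.
    """
    cfg = config or default_config()
    kind = None
    if atom.atom_name == "H" and atom.element == "H":
        kind = "H"
    elif atom.atom_name == "N" and atom.element == "N":
        kind = "N"
    elif atom.atom_name == "C" and atom.element == "C":
        kind = "C"
    if kind is None:
        return None
    params = csa_parameters(kind, cfg)
    if params is None:
        return None
    pas, beta = params

    try:
        if kind in ("H", "N"):
            n = _neighbour(ensemble, atom, atom.residue_number, "N")
            h = _neighbour(ensemble, atom, atom.residue_number, "H")
            cprev = _neighbour(ensemble, atom, atom.residue_number - 1, "C")
            if n is None or h is None or cprev is None:
                raise ValueError("missing geometry atoms")
            if kind == "H":
                z0 = n - h  # zz along the H->N bond, tilted by beta
            else:
                z0 = h - n  # zz tilted from the N->H bond
            frame = _frame_from(z0, cprev - n, beta)
        else:  # carbonyl C'
            c = _neighbour(ensemble, atom, atom.residue_number, "C")
            o = _neighbour(ensemble, atom, atom.residue_number, "O")
            nnext = _neighbour(ensemble, atom, atom.residue_number + 1, "N")
            if c is None or o is None or nnext is None:
                raise ValueError("missing geometry atoms")
            # zz perpendicular to the sp2 plane, xx tilted from C->O in-plane
            xo = o - c
            normal = np.cross(xo, nnext - c)
            if np.linalg.norm(normal) < 1e-12:
                raise ValueError("collinear carbonyl geometry")
            z = normal / np.linalg.norm(normal)
            x = _rotation_about(z, beta) @ (xo / np.linalg.norm(xo))
            frame = np.column_stack([x, np.cross(z, x), z])
    except ValueError as exc:
        warnings.warn(
            f"no default CSA for {atom.identity}: {exc}", stacklevel=2
        )
        return None
    return frame @ np.diag(pas) @ frame.T


def attach_default_csas(ensemble: StructureEnsemble,
                        config: Config | None = None) -> int:
    """Attach default CSA tensors in place; returns the number attached.
    Atoms that already carry a user-supplied tensor are left untouched."""
    count = 0
    for i, atom in enumerate(ensemble.atoms):
        if atom.csa is not None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tensor = default_csa(ensemble, atom, config)
        if tensor is not None:
            ensemble.replace_atom(i, csa=tensor)
            count += 1
    return count
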