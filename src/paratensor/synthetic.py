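"""Synthetic structures and observable tables from known ground truth.

Every fitting path in the package is testable offline: this module builds
small idealised peptide-like structures (standard local geometry, varied
amide bond orientations) and forward-calculates PCS/RDC/PRE/CCR tables
from a known susceptibility tensor, optionally with corrections and
seeded Gaussian noise.  Identical (spec, seed) inputs give identical
outputs.

The generated chains use standard bond lengths (N-H 1.02 A, N-CA 1.47 A,
C'-N 1.33 A) but deliberately varied orientations rather than a real
secondary structure: well-spread N-H directions keep alignment-tensor
fits well-conditioned, which regular helices would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM
from .fitting import ObservableTable
from .forward import pcs, racs_correction, rads_correction, rdc
from .relaxation import ccr_curie_dd, pre_curie_csa, pre_sbm
from .structure import AtomRecord, StructureEnsemble, attach_default_csas
from .tensors import (
    ChiTensor,
    ExperimentContext,
    ParamagneticCentre,
    alignment_from_chi,
)
from .config import default_config

__all__ = ["make_structure", "make_observables", "FixtureSpec"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture (documented defaults of the
    generator; see docs/methods.md)."""

    n_residues: int = 12
    n_models: int = 1
    jitter: float = 0.0          # per-model coordinate noise, Angstrom
    mode: str = "jitter"         # "jitter" | "dimer"
    seed: int = 0


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _unit(v):
    return v / np.linalg.norm(v)


def make_structure(n_residues: int = 12, n_models: int = 1,
                   jitter: float = 0.0, mode: str = "jitter", seed: int = 0,
                   nh_directions=None, metal_position=None,
                   metal_element: str = "Tb") -> StructureEnsemble:
    """Idealised peptide-like chain with N, H, CA, C' (+O) atoms.

    ``mode`` "jitter" adds seeded Gaussian coordinate noise of ``jitter``
    Angstrom to models beyond the first; "dimer" produces exactly two
    models related by a 180 degree rotation about z (a C2 multimer).
    ``nh_directions`` optionally overrides the N-H unit vector per model
    (one 3-vector per model, applied to every residue) to construct
    specific bond-orientation scenarios.  A HETATM metal ion is appended
    to every model when ``metal_position`` (Angstrom) is given.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    cfg = default_config()
    rng = np.random.default_rng(seed)

    # backbone trace: points on a gentle spiral with randomised offsets so
    # inter-atomic directions are well distributed on the sphere
    base = []
    for i in range(n_residues):
        t = 0.8 * i
        centre = np.array([
            6.0 * math.cos(t), 6.0 * math.sin(t), 1.8 * i - 0.9 * n_residues,
        ])
        base.append(centre + rng.normal(scale=1.0, size=3))

    def residue_atoms(i, n_pos, nh_dir):
        # local frame from the chain direction
        ref = base[(i + 1) % n_residues] - base[i - 1]
        if np.linalg.norm(ref) < 1e-9:  # 2-residue chains fold onto a point
            ref = np.array([0.267, 0.535, 0.802])
        ref = _unit(ref)
        perp = np.cross(nh_dir, ref)
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(nh_dir, np.array([0.557, -0.743, 0.37]))
        perp = _unit(perp)
        h = n_pos + 1.02 * nh_dir
        ca = n_pos + 1.47 * _unit(ref + 0.3 * perp)
        c = ca + 1.53 * _unit(ref - 0.4 * perp)
        o = c + 1.23 * _unit(perp + 0.2 * ref)
        return {"N": n_pos, "H": h, "CA": ca, "C": c, "O": o}

    if mode == "dimer":
        n_models = 2

    models_atoms = []
    nh_base = [_unit(rng.normal(size=3)) for _ in range(n_residues)]
    for m in range(n_models):
        records = []
        for i in range(n_residues):
            nh = np.asarray(nh_directions[m], dtype=float) \
                if nh_directions is not None else nh_base[i]
            atoms = residue_atoms(i, np.array(base[i]), _unit(nh))
            for name, pos in atoms.items():
                if mode == "jitter" and m > 0 and jitter > 0:
                    pos = pos + rng.normal(scale=jitter, size=3)
                elif mode == "dimer" and m == 1:
                    pos = _rotation_z(math.pi) @ pos
                records.append(AtomRecord(
                    model_index=m, chain="A", residue_number=i + 1,
                    residue_name="ALA", atom_name=name,
                    element=name[0], coords=pos * ANGSTROM,
                    gamma=cfg.gamma(name[0]),
                ))
        if metal_position is not None:
            mp = np.asarray(metal_position, dtype=float)
            if mode == "dimer" and m == 1:
                mp = _rotation_z(math.pi) @ mp
            records.append(AtomRecord(
                model_index=m, chain="A", residue_number=n_residues + 1,
                residue_name=metal_element.upper(), atom_name=metal_element.upper(),
                element=metal_element.capitalize(), coords=mp * ANGSTROM,
                gamma=None,
            ))
        models_atoms.extend(records)
    return StructureEnsemble(models_atoms)


def make_observables(ensemble: StructureEnsemble, centre: ParamagneticCentre,
                     effect_kind: str, corrections=(), noise: float = 0.0,
                     seed: int = 0, atom_name: str = "H",
                     partner_name: str = "N", residues=None,
                     rate_kind: str = "R2", theory: str = "sbm",
                     ensemble_reduce: str = "mean") -> ObservableTable:
    """Forward-calculate an observable table from a known tensor.

    ``corrections`` may contain "racs", "rads" and/or "csa" (PCS
    corrections need CSA tensors on the atoms, which are attached
    on demand).  ``noise`` adds seeded Gaussian noise of that scale
    (units of the effect).  Multi-model ensembles are reduced with the
    mean ("mean") or sum ("sum") of per-model values.
    """
    kind = effect_kind.upper()
    rng = np.random.default_rng(seed)
    if "racs" in corrections or "csa" in corrections:
        attach_default_csas(ensemble)
    chi, ctx = centre.chi, centre.ctx
    align = alignment_from_chi(chi, ctx)
    if residues is None:
        residues = sorted({a.residue_number for a in ensemble.atoms
                           if a.atom_name == atom_name})
    records = []
    for resnum in residues:
        per_model = []
        pair = kind in ("RDC", "CCR")
        skip = False
        for m in ensemble.model_indices:
            atom = ensemble.get(("A", resnum, atom_name), m)
            if atom is None:
                skip = True
                break
            if pair:
                partner = ensemble.get(("A", resnum, partner_name), m)
                if partner is None:
                    skip = True
                    break
            if kind == "PCS":
                val = pcs(chi, atom.coords)
                if "racs" in corrections and atom.csa is not None:
                    val += racs_correction(atom.csa, align)
                if "rads" in corrections:
                    val += rads_correction(chi, atom.coords, ctx)
            elif kind == "RDC":
                val = rdc(align, atom, partner)
            elif kind == "PRE":
                if theory == "sbm":
                    val = pre_sbm(atom, centre, rate_kind)
                elif theory == "curie_csa":
                    val = pre_curie_csa(chi, atom, ctx, rate_kind)
                else:
                    raise ValueError(f"unknown PRE theory {theory!r}")
            elif kind == "CCR":
                val = ccr_curie_dd(chi, atom, partner, ctx)
            else:
                raise ValueError(f"unknown effect kind {effect_kind!r}")
            per_model.append(val)
        if skip or not per_model:
            continue
        value = float(np.mean(per_model)) if ensemble_reduce == "mean" \
            else float(np.sum(per_model))
        if pair:
            records.append((resnum, atom_name, resnum, partner_name, value))
        else:
            records.append((resnum, atom_name, value))
    table = ObservableTable.from_records(kind, records)
    if noise > 0:
        table.frame["value"] += rng.normal(scale=noise,
                                           size=len(table.frame))
        table.frame["uncertainty"] = noise
    return table
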