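"""Data-file parsing and writing, tensor text files, CCP4 map export and
plot-data helpers.

Data dialect (whitespace-delimited, '#' comments):

* PCS / PRE:   residue_number atom_name value [uncertainty]
* RDC / CCR:   residue1 atom1 residue2 atom2 value [uncertainty]

Values are ppm (PCS), Hz (RDC) or s^-1 (PRE, CCR).  A missing uncertainty
column defaults to 1.0 with a warning.  Tensor files are round-trip-safe
key-value blocks in display units (1e-32 m^3, Angstrom, degrees, ppm,
tesla, kelvin, seconds).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .constants import ANGSTROM, CHI_UNIT
from .fitting import ObservableTable
from .forward import pcs
from .relaxation import _dipolar_sigma_ppm, pre_curie
from .structure import AtomRecord
from .tensors import (
    ChiTensor,
    ExperimentContext,
    ParamagneticCentre,
    TensorParameters,
    from_parameters,
    to_utr,
)

__all__ = [
    "parse_data",
    "write_data",
    "read_tensor",
    "write_tensor",
    "write_map",
    "axis_scatter_data",
]

_PAIR_KINDS = ("RDC", "CCR")


class DataParseError(ValueError):
    pass


def parse_data(path, kind: str) -> ObservableTable:
    """Parse a whitespace-delimited observable file into a table."""
    kind = kind.upper()
    pair = kind in _PAIR_KINDS
    base = 4 if pair else 2
    records = []
    missing_unc = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < base + 1:
                raise DataParseError(
                    f"{path}:{lineno}: expected at least {base + 1} fields, "
                    f"got {len(tok)}"
                )
            try:
                if pair:
                    rec = [int(tok[0]), tok[1], int(tok[2]), tok[3],
                           float(tok[4])]
                    unc = float(tok[5]) if len(tok) > 5 else None
                else:
                    rec = [int(tok[0]), tok[1], float(tok[2])]
                    unc = float(tok[3]) if len(tok) > 3 else None
            except ValueError as exc:
                raise DataParseError(f"{path}:{lineno}: {exc}") from None
            if unc is None:
                missing_unc = True
                unc = 1.0
            records.append((*rec, unc))
    if missing_unc:
        warnings.warn(
            f"{path}: missing uncertainty column, defaulting to 1.0",
            stacklevel=2,
        )
    if pair:
        cols = ["residue", "atom", "residue2", "atom2", "value", "uncertainty"]
    else:
        cols = ["residue", "atom", "value", "uncertainty"]
    frame = pd.DataFrame(records, columns=cols)
    frame["use"] = True
    return ObservableTable(kind, frame)


def write_data(table: ObservableTable, path, calc=None) -> None:
    """Write a table in the same dialect; optionally append a
    back-calculated column as a trailing comment."""
    pair = table.kind in _PAIR_KINDS
    with open(path, "w") as fh:
        fh.write(f"# {table.kind}: "
                 + ("res1 atom1 res2 atom2" if pair else "residue atom")
                 + " value uncertainty\n")
        for j, (_, rec) in enumerate(table.frame.iterrows()):
            if pair:
                fields = (f"{int(rec['residue']):4d} {rec['atom']:<4s} "
                          f"{int(rec['residue2']):4d} {rec['atom2']:<4s}")
            else:
                fields = f"{int(rec['residue']):4d} {rec['atom']:<4s}"
            line = f"{fields} {rec['value']: .8e} {rec['uncertainty']: .3e}"
            if calc is not None:
                line += f"  # calc {calc[j]: .8e}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# tensor text files


_TENSOR_KEYS = ("ax", "rh", "x", "y", "z", "a", "b", "g", "mueff", "shift",
                "B0", "temp", "t1e", "taur")


def write_tensor(path, params: TensorParameters,
                 ctx: ExperimentContext | None = None,
                 shift: float = 0.0) -> None:
    """Write a tensor (+ optional experiment context) as key-value text in
    display units."""
    lines = {
        "ax": params.axial / CHI_UNIT,
        "rh": params.rhombic / CHI_UNIT,
        "x": params.position[0] / ANGSTROM,
        "y": params.position[1] / ANGSTROM,
        "z": params.position[2] / ANGSTROM,
        "a": math.degrees(params.euler_alpha),
        "b": math.degrees(params.euler_beta),
        "g": math.degrees(params.euler_gamma),
        "shift": shift,
    }
    if ctx is not None:
        lines.update({
            "mueff": ctx.mu_eff, "B0": ctx.B0, "temp": ctx.temperature,
            "t1e": ctx.t1e, "taur": ctx.tau_r,
        })
    with open(path, "w") as fh:
        fh.write("# paratensor tensor file (ax/rh 1e-32 m^3, x/y/z A, "
                 "a/b/g deg ZYZ, shift ppm, B0 T, temp K, t1e/taur s)\n")
        for key, val in lines.items():
            fh.write(f"{key:<6s} {float(val):.17g}\n")


def read_tensor(path):
    """Read a tensor file; returns (TensorParameters, ExperimentContext or
    None, shift)."""
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) != 2 or tok[0] not in _TENSOR_KEYS:
                raise DataParseError(f"{path}:{lineno}: bad tensor line {raw!r}")
            values[tok[0]] = float(tok[1])
    params = TensorParameters(
        axial=values.get("ax", 0.0) * CHI_UNIT,
        rhombic=values.get("rh", 0.0) * CHI_UNIT,
        euler_alpha=math.radians(values.get("a", 0.0)),
        euler_beta=math.radians(values.get("b", 0.0)),
        euler_gamma=math.radians(values.get("g", 0.0)),
        position=np.array([values.get(k, 0.0) for k in ("x", "y", "z")])
        * ANGSTROM,
    )
    ctx = None
    if "B0" in values:
        ctx = ExperimentContext(
            B0=values["B0"],
            temperature=values.get("temp", 298.0),
            tau_r=values.get("taur", 4.0e-9),
            t1e=values.get("t1e", 1.0e-13),
            mu_eff=values.get("mueff", 0.0),
        )
    return params, ctx, values.get("shift", 0.0)


# ---------------------------------------------------------------------------
# CCP4 map export


def write_map(chi: ChiTensor, path, effect: str = "PCS",
              ctx: ExperimentContext | None = None, gamma: float | None = None,
              grid_spacing: float = 1.0, bounds=((-20, 20),) * 3) -> None:
    """Sample the scalar PCS (ppm) or PRE (s^-1) field of a tensor on a
    regular grid and write a CCP4/MRC volume (mode 2, P1, orthogonal
    Angstrom grid) for molecular-graphics programs.

    ``grid_spacing`` in Angstrom; ``bounds`` are ((xmin, xmax), ...) in
    Angstrom and should enclose the structure.  The voxel containing the
    metal is set to zero to guard the singularity.
    """
    import gemmi

    effect = effect.upper()
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if effect == "PRE" and (ctx is None or gamma is None):
        raise ValueError("PRE maps need an ExperimentContext and gamma")
    starts = [int(math.floor(lo / grid_spacing)) for lo, _ in bounds]
    stops = [int(math.ceil(hi / grid_spacing)) for _, hi in bounds]
    counts = [stop - start + 1 for start, stop in zip(starts, stops)]
    values = np.zeros(counts, dtype=np.float32)
    metal_idx = np.round(chi.position / ANGSTROM / grid_spacing).astype(int)
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                idx = np.array([starts[0] + i, starts[1] + j, starts[2] + k])
                if np.all(idx == metal_idx):
                    values[i, j, k] = 0.0
                    continue
                pos = idx * grid_spacing * ANGSTROM
                if effect == "PCS":
                    values[i, j, k] = pcs(chi, pos)
                elif effect == "PRE":
                    atom = AtomRecord(0, "A", 0, "MAP", "X", "H", pos,
                                      gamma=gamma)
                    sig = _dipolar_sigma_ppm(chi, atom)
                    values[i, j, k] = pre_curie(sig, ctx, "R2", gamma)
                else:
                    raise ValueError(f"unknown map effect {effect!r}")
    cell_a = counts[0] * grid_spacing
    cell_b = counts[1] * grid_spacing
    cell_c = counts[2] * grid_spacing
    grid = gemmi.FloatGrid(values)
    grid.unit_cell = gemmi.UnitCell(cell_a, cell_b, cell_c, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    for axis, start in enumerate(starts):  # NXSTART/NYSTART/NZSTART
        ccp4.set_header_i32(5 + axis, start)
    ccp4.write_ccp4_map(str(path))


def read_map_values(path):
    """Read back a CCP4 map written by :func:`write_map`; returns
    (values array, voxel index origin, spacing in Angstrom)."""
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    arr = np.array(ccp4.grid, copy=True)
    starts = [ccp4.header_i32(5 + axis) for axis in range(3)]
    spacing = ccp4.grid.unit_cell.a / ccp4.grid.nu
    return arr, np.array(starts), spacing


# ---------------------------------------------------------------------------
# principal-axis scatter data (Sanson-Flamsteed projections)


def axis_scatter_data(tensors) -> pd.DataFrame:
    """Longitude/latitude (degrees) of the three principal axes of each
    tensor, for sinusoidal-projection scatter plots of uncertainty
    repeats.  Antipodal ambiguity is resolved to the +z hemisphere."""
    tensors = list(tensors)
    if not tensors:
        raise ValueError("no tensors supplied")
    rows = []
    for t in tensors:
        if isinstance(t, TensorParameters):
            chi = from_parameters(t)
        else:
            chi = t
        utr = to_utr(chi)
        from .tensors import euler_zyz_to_matrix

        rot = euler_zyz_to_matrix(utr.euler_alpha, utr.euler_beta,
                                  utr.euler_gamma)
        for label, axis in zip(("x", "y", "z"), rot.T):
            if axis[2] < 0:
                axis = -axis
            lat = math.degrees(math.asin(max(-1.0, min(1.0, axis[2]))))
            lon = math.degrees(math.atan2(axis[1], axis[0]))
            rows.append((label, lon, lat))
    return pd.DataFrame(rows, columns=["axis", "longitude", "latitude"])
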