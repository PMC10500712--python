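"""Back-calculation of PCS and RDC from a susceptibility tensor.

The pseudocontact shift is the trace of the dipolar shielding tensor the
paramagnetic centre creates at the nucleus; only the traceless part of chi
contributes.  Under the weak molecular alignment induced by the same
anisotropy, orientational averaging of anisotropic tensors is incomplete,
producing residual dipolar couplings between nuclear pairs and small
residual-shift corrections to the PCS: RACS (from the nuclear CSA tensor)
and RADS (from the dipolar shielding tensor itself).
"""

from __future__ import annotations

import math

import numpy as np

from .constants import HBAR, MU0
from .structure import AtomRecord
from .tensors import (
    AlignmentTensor,
    ChiTensor,
    DegenerateGeometryError,
    ExperimentContext,
    alignment_from_chi,
    dipolar_shielding_matrix,
)

__all__ = [
    "dipolar_shielding_ppm",
    "pcs",
    "pcs_linear_coefficients",
    "pcs_linear",
    "racs_correction",
    "rads_correction",
    "rdc",
    "rdc_linear_coefficients",
    "rdc_prefactor",
    "apply_offset",
]

_I3 = np.eye(3)


def dipolar_shielding_ppm(chi: ChiTensor, position) -> np.ndarray:
    """Dipolar shielding tensor in ppm at an absolute position (m)."""
    r_vec = np.asarray(position, dtype=float) - chi.position
    return dipolar_shielding_matrix(chi, r_vec) * 1e6


def pcs(chi: ChiTensor, position) -> float:
    """Pseudocontact shift (ppm) at an absolute position (m):
    delta = Tr(sigma)/3."""
    return float(np.trace(dipolar_shielding_ppm(chi, position))) / 3.0


def pcs_linear_coefficients(r_vec) -> np.ndarray:
    """Row vector c such that delta(ppm) = c . [dxx, dyy, dxy, dxz, dyz]
    for the traceless susceptibility components in m^3 (r_vec in m).

    This is the explicit 5-parameter linear form of the PCS equation and
    the building block of the SVD fit design matrix.
    """
    x, y, z = np.asarray(r_vec, dtype=float)
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        raise DegenerateGeometryError("nucleus coincides with the paramagnetic centre")
    pref = 1e6 / (4.0 * math.pi * r**5)
    return pref * np.array(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def pcs_linear(chi: ChiTensor, position) -> float:
    """PCS (ppm) via the 5-parameter linear route; equal to :func:`pcs`."""
    aniso = chi.anisotropy
    comps = np.array(
        [aniso[0, 0], aniso[1, 1], aniso[0, 1], aniso[0, 2], aniso[1, 2]]
    )
    r_vec = np.asarray(position, dtype=float) - chi.position
    return float(pcs_linear_coefficients(r_vec) @ comps)


def _residual_shift(sigma_ppm: np.ndarray, a: AlignmentTensor) -> float:
    """Residual shift (ppm) of a shielding tensor under alignment A.

    Second-moment Boltzmann averaging of the molecular orientation gives
    <b_i b_j> = delta_ij/3 + A_ij, so the observed shift exceeds the
    isotropic average by sum_ij A_ij sigma_ij (equivalently
    (2/3) sum_ij S_ij sigma_ij with the Saupe matrix S = 3A/2).  Only the
    symmetric traceless part of sigma survives the contraction.
    """
    sym = 0.5 * (sigma_ppm + sigma_ppm.T)
    traceless = sym - np.trace(sym) / 3.0 * _I3
    return float(np.sum(a.matrix * traceless))


def racs_correction(csa_ppm: np.ndarray, a: AlignmentTensor) -> float:
    """Residual anisotropic chemical shift (ppm) of a CSA tensor under
    alignment.  The returned value is *added* to the back-calculated PCS
    before comparison with experiment."""
    return _residual_shift(np.asarray(csa_ppm, dtype=float), a)


def rads_correction(chi: ChiTensor, position, ctx: ExperimentContext) -> float:
    """Residual anisotropic dipolar shift (ppm): the RACS-type correction
    computed with the metal's own dipolar shielding tensor.  Added to the
    back-calculated PCS, like RACS."""
    a = alignment_from_chi(chi, ctx)
    return _residual_shift(dipolar_shielding_ppm(chi, position), a)


def rdc_prefactor(gamma1: float, gamma2: float, r_ab: float) -> float:
    """Scalar prefactor 3 gA gB mu0 hbar / (8 pi^2 rAB^3) in Hz (the r^-5
    of the matrix form absorbs two powers of rAB into the unit vectors)."""
    return 3.0 * gamma1 * gamma2 * MU0 * HBAR / (8.0 * math.pi**2 * r_ab**3)


def rdc(a: AlignmentTensor, atom1: AtomRecord, atom2: AtomRecord) -> float:
    """Residual dipolar coupling (Hz) of a nuclear pair under alignment A:
    RDC = 3 gA gB mu0 hbar / (8 pi^2 rAB^5) rAB^T A rAB."""
    if atom1.gamma is None or atom2.gamma is None:
        raise ValueError("both atoms need a known gyromagnetic ratio")
    vec = atom2.coords - atom1.coords
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        raise DegenerateGeometryError("zero-length internuclear vector")
    u = vec / dist
    return rdc_prefactor(atom1.gamma, atom2.gamma, dist) * float(u @ a.matrix @ u)


def rdc_linear_coefficients(atom1: AtomRecord, atom2: AtomRecord) -> np.ndarray:
    """Row vector c with RDC(Hz) = c . [Axx, Ayy, Axy, Axz, Ayz]; the
    5-vector expansion of the matrix form."""
    if atom1.gamma is None or atom2.gamma is None:
        raise ValueError("both atoms need a known gyromagnetic ratio")
    vec = atom2.coords - atom1.coords
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        raise DegenerateGeometryError("zero-length internuclear vector")
    x, y, z = vec / dist
    pref = rdc_prefactor(atom1.gamma, atom2.gamma, dist)
    return pref * np.array(
        [x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def apply_offset(pcs_values, offset: float) -> np.ndarray:
    """Uniform additive offset (ppm), modelling referencing differences
    between the paramagnetic and diamagnetic spectra."""
    return np.asarray(pcs_values, dtype=float) + offset
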