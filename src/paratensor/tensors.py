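"""Magnetic susceptibility tensor algebra.

A paramagnetic centre is described by its magnetic susceptibility tensor
chi (a symmetric 3x3 volume-susceptibility matrix, SI units m^3) anchored
at a position in space.  The traceless part of chi (the anisotropy, "delta
chi") is what produces pseudocontact shifts and molecular alignment; the
isotropic part drives Curie-spin relaxation.  This module holds the tensor
representations, the unique tensor representation (UTR) used for reporting,
the dipolar shielding tensor, the induced alignment/Saupe tensors, and the
small amount of magnetochemistry needed to predict isotropic
susceptibilities from effective magnetic moments.

Internal units are SI throughout (m, m^3, s, T, K, rad).  Display units
(Angstrom, 1e-32 m^3, degrees) appear only at the I/O surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import CHI_UNIT, KB, MU0, MUB

__all__ = [
    "ChiTensor",
    "TensorParameters",
    "ExperimentContext",
    "AlignmentTensor",
    "ParamagneticCentre",
    "dipolar_shielding_matrix",
    "alignment_from_chi",
    "saupe_from_alignment",
    "alignment_from_saupe",
    "effective_moment",
    "chi_iso_from_moment",
    "euler_zyz_to_matrix",
    "to_utr",
    "from_parameters",
    "average_tensors",
]

_I3 = np.eye(3)


class DegenerateGeometryError(ValueError):
    """Raised when a geometric quantity (inter-atomic vector) vanishes."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChiTensor:
    """Symmetric magnetic susceptibility tensor (m^3) at a position (m)."""

    matrix: np.ndarray
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        p = np.asarray(self.position, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("chi matrix must be 3x3")
        scale = np.max(np.abs(m))
        if scale > 0 and np.max(np.abs(m - m.T)) > 1e-12 * scale:
            raise ValueError("chi matrix must be symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))
        object.__setattr__(self, "position", p)

    @property
    def iso(self) -> float:
        """Isotropic susceptibility, Tr(chi)/3 (m^3)."""
        return float(np.trace(self.matrix)) / 3.0

    @property
    def anisotropy(self) -> np.ndarray:
        """Traceless (delta chi) part of the matrix (m^3)."""
        return self.matrix - self.iso * _I3

    def with_position(self, position) -> "ChiTensor":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass(frozen=True)
class TensorParameters:
    """Axial/rhombic parameterisation of a susceptibility tensor.

    ``axial`` and ``rhombic`` are the anisotropy components
    ax = chi_zz - (chi_xx + chi_yy)/2 and rh = chi_xx - chi_yy of the
    traceless part, in m^3.  Euler angles follow the ZYZ convention
    (radians).  ``isotropic`` is Tr(chi)/3.
    """

    axial: float
    rhombic: float
    euler_alpha: float
    euler_beta: float
    euler_gamma: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    isotropic: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float)
        )

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal values (xx, yy, zz) of the traceless part."""
        ax, rh = self.axial, self.rhombic
        return np.array([-ax / 3.0 + rh / 2.0, -ax / 3.0 - rh / 2.0, 2.0 * ax / 3.0])


@dataclass(frozen=True)
class ExperimentContext:
    """Field, temperature and dynamics of a paramagnetic NMR experiment.

    B0 in tesla, temperature in kelvin, tau_r (rotational correlation
    time) and t1e (electronic relaxation time) in seconds, mu_eff in
    multiples of the Bohr magneton.
    """

    B0: float
    temperature: float = 298.0
    tau_r: float = 4.0e-9
    t1e: float = 1.0e-13
    mu_eff: float = 0.0

    @property
    def tau_c(self) -> float:
        """Effective correlation time, 1/tau_c = 1/tau_r + 1/T1e."""
        return 1.0 / (1.0 / self.tau_r + 1.0 / self.t1e)


@dataclass(frozen=True)
class AlignmentTensor:
    """Dimensionless, symmetric, traceless molecular alignment tensor."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("alignment matrix must be 3x3")
        scale = np.max(np.abs(m))
        if scale > 0 and abs(np.trace(m)) > 1e-12 * scale:
            raise ValueError("alignment tensor must be traceless")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))


@dataclass(frozen=True)
class ParamagneticCentre:
    """A susceptibility tensor together with its experimental context."""

    chi: ChiTensor
    ctx: ExperimentContext


# ---------------------------------------------------------------------------
# operations


def dipolar_shielding_matrix(chi: ChiTensor, r_vec) -> np.ndarray:
    """Dipolar shielding tensor (dimensionless fraction) at displacement
    ``r_vec`` (m, pointing from the metal to the nucleus).

    sigma = (1/4pi) (3 r r^T / r^5 - I/r^3) . chi

    The result is in general non-symmetric; multiply by 1e6 for ppm.
    """
    r = np.asarray(r_vec, dtype=float)
    dist = float(np.linalg.norm(r))
    if dist == 0.0:
        raise DegenerateGeometryError("nucleus coincides with the paramagnetic centre")
    geom = 3.0 * np.outer(r, r) / dist**5 - _I3 / dist**3
    return geom @ chi.matrix / (4.0 * math.pi)


def alignment_from_chi(chi: ChiTensor, ctx: ExperimentContext) -> AlignmentTensor:
    """Alignment tensor induced by the susceptibility anisotropy:
    A = B0^2 / (15 mu0 kB T) . delta-chi."""
    if ctx.B0 <= 0 or ctx.temperature <= 0:
        raise ValueError("B0 and temperature must be positive")
    scale = ctx.B0**2 / (15.0 * MU0 * KB * ctx.temperature)
    return AlignmentTensor(scale * chi.anisotropy)


def saupe_from_alignment(a: AlignmentTensor) -> np.ndarray:
    """Saupe order matrix, S = (3/2) A (package convention)."""
    return 1.5 * a.matrix


def alignment_from_saupe(s) -> AlignmentTensor:
    return AlignmentTensor(np.asarray(s, dtype=float) / 1.5)


def effective_moment(g_factor: float, J: float) -> float:
    """Effective magnetic moment mu_eff = g sqrt(J(J+1)), in Bohr magnetons."""
    if J < 0:
        raise ValueError("J must be non-negative")
    return g_factor * math.sqrt(J * (J + 1.0))


def chi_iso_from_moment(mu_eff: float, temperature: float) -> float:
    """Isotropic susceptibility from the effective moment (Curie law):
    chi_iso = mu0 (mu_eff muB)^2 / (3 kB T), in m^3."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return MU0 * (mu_eff * MUB) ** 2 / (3.0 * KB * temperature)


# ---------------------------------------------------------------------------
# UTR and parameter conversions


def euler_zyz_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix R = Rz(alpha) Ry(beta) Rz(gamma)."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    rz_a = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry_b = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rz_g = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    return rz_a @ ry_b @ rz_g


def _matrix_to_euler_zyz(r: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles with beta in [0, pi], alpha/gamma in (-pi, pi]."""
    beta = math.acos(max(-1.0, min(1.0, r[2, 2])))
    if abs(math.sin(beta)) > 1e-10:
        alpha = math.atan2(r[1, 2], r[0, 2])
        gamma = math.atan2(r[2, 1], -r[2, 0])
    else:
        # gimbal lock: only alpha +/- gamma is defined; put it all in alpha
        gamma = 0.0
        if r[2, 2] > 0:
            alpha = math.atan2(r[1, 0], r[0, 0])
        else:
            alpha = math.atan2(-r[1, 0], -r[0, 0])
    return alpha, beta, gamma


# proper rotations that leave a diagonal tensor invariant (pi flips about
# the principal axes); used to steer all Euler angles into [0, pi]
_TENSOR_SYMMETRIES = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]

_ANGLE_TOL = 1e-12


def _unique_angles(rot: np.ndarray) -> tuple[float, float, float]:
    """Euler angles in [0, pi]^3 for the frame rotation of a symmetric
    tensor, exploiting the tensor's axis-flip symmetry."""
    best = None
    for f in _TENSOR_SYMMETRIES:
        a, b, g = _matrix_to_euler_zyz(rot @ f)
        # map boundary values exactly
        if a < -_ANGLE_TOL or a > math.pi + _ANGLE_TOL:
            continue
        if g < -_ANGLE_TOL or g > math.pi + _ANGLE_TOL:
            continue
        cand = (min(max(a, 0.0), math.pi), min(max(b, 0.0), math.pi),
                min(max(g, 0.0), math.pi))
        if best is None or cand < best:
            best = cand
    if best is None:  # numerically pathological; fall back to raw angles
        a, b, g = _matrix_to_euler_zyz(rot)
        best = (a % math.pi, b, g % math.pi)
    return best


def to_utr(chi: ChiTensor) -> TensorParameters:
    """Unique tensor representation: principal values of the anisotropy
    ordered |zz| >= |yy| >= |xx|, ZYZ Euler angles each in [0, pi]."""
    aniso = chi.anisotropy
    vals, vecs = np.linalg.eigh(aniso)
    order = np.argsort(np.abs(vals))  # |xx| <= |yy| <= |zz|
    vals = vals[order]
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    xx, yy, zz = vals
    ax = zz - (xx + yy) / 2.0
    rh = xx - yy
    if abs(rh) <= 1e-12 * max(abs(ax), 1e-300):
        # axially symmetric: gamma is unobservable, fix it to zero by
        # extracting only the z-axis direction
        z = vecs[:, 2]
        if z[2] < 0:
            z = -z
        beta = math.acos(max(-1.0, min(1.0, z[2])))
        alpha = math.atan2(z[1], z[0]) if abs(math.sin(beta)) > 1e-10 else 0.0
        if alpha < 0:
            alpha += math.pi
            beta = math.pi - beta  # flip z through the origin: same axis
        angles = (alpha, beta, 0.0)
    else:
        angles = _unique_angles(vecs)
    return TensorParameters(
        axial=float(ax),
        rhombic=float(rh),
        euler_alpha=angles[0],
        euler_beta=angles[1],
        euler_gamma=angles[2],
        position=chi.position,
        isotropic=chi.iso,
    )


def from_parameters(params: TensorParameters) -> ChiTensor:
    """Rebuild the full chi matrix from axial/rhombic/Euler parameters."""
    rot = euler_zyz_to_matrix(
        params.euler_alpha, params.euler_beta, params.euler_gamma
    )
    diag = np.diag(params.eigenvalues)
    matrix = rot @ diag @ rot.T + params.isotropic * _I3
    return ChiTensor(matrix, params.position)


def average_tensors(tensors) -> ChiTensor:
    """Element-wise mean of susceptibility matrices (and positions).

    Averaging is done on the Cartesian matrices, never on
    (axial, rhombic, angle) parameter sets, so mixing prolate and oblate
    tensors with different principal-axis labels introduces no artefacts.
    """
    tensors = list(tensors)
    if not tensors:
        raise ValueError("cannot average an empty list of tensors")
    matrix = np.mean([t.matrix for t in tensors], axis=0)
    position = np.mean([t.position for t in tensors], axis=0)
    return ChiTensor(matrix, position)
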