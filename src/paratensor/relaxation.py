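"""Paramagnetic relaxation: SBM and Curie-spin theory, cross terms, CCR.

Two mechanisms drive nuclear relaxation near a paramagnetic centre:

* dipolar coupling to the fluctuating electron moment
  (Solomon-Bloembergen-Morgan, correlation time
  1/tau_c = 1/tau_r + 1/T1e), optionally generalised to an anisotropic
  spectral power density tensor G(omega);
* the static (Curie) component of the electron moment, whose dipolar
  shielding tensor is modulated by molecular tumbling alone (tau_r).

Because the Curie rates are quadratic forms in the total shielding tensor,
adding a CSA tensor or the dipolar field of a scalar-coupled partner spin
produces cross terms: the Curie x CSA contribution to the PRE (which can
be negative) and Curie x dipole-dipole cross-correlated relaxation (CCR),
observed as differential line broadening of doublet components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import GE, HBAR, MU0, MUB, PPM
from .structure import AtomRecord, StructureEnsemble
from .tensors import (
    ChiTensor,
    DegenerateGeometryError,
    ExperimentContext,
    ParamagneticCentre,
    chi_iso_from_moment,
    dipolar_shielding_matrix,
)

__all__ = [
    "SpectralDensityTensor",
    "pre_sbm",
    "pre_sbm_aniso",
    "curie_invariants",
    "pre_curie",
    "pre_curie_csa",
    "ccr_curie_dd",
    "fit_relaxation",
    "RelaxationFitResult",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class SpectralDensityTensor:
    """Anisotropic dipolar spectral power density: G(0) and G(omega), s."""

    g_zero: np.ndarray
    g_omega: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "g_zero", np.asarray(self.g_zero, dtype=float))
        object.__setattr__(self, "g_omega", np.asarray(self.g_omega, dtype=float))


def _larmor(gamma: float, B0: float) -> float:
    return abs(gamma) * B0


def _electron_larmor(B0: float) -> float:
    return GE * MUB * B0 / HBAR


def _metal_vector(atom: AtomRecord, chi: ChiTensor) -> np.ndarray:
    v = atom.coords - chi.position
    if np.linalg.norm(v) == 0.0:
        raise DegenerateGeometryError("nucleus coincides with the paramagnetic centre")
    return v


def pre_sbm(atom: AtomRecord, centre: ParamagneticCentre, rate_kind: str) -> float:
    """Isotropic SBM PRE (s^-1) for R1 or R2.

    R1 = (2/15) [(mu0/4pi) gamma mu_eff / r^3]^2
         [3 tau_c/(1+tau_c^2 w^2) + 7 tau_c/(1+tau_c^2 wS^2)]
    R2 = (1/15) [...]^2 [4 tau_c + 3 tau_c/(1+tau_c^2 w^2)
         + 13 tau_c/(1+tau_c^2 wS^2)]
    """
    if atom.gamma is None:
        raise ValueError(f"atom {atom.identity} has no gyromagnetic ratio")
    ctx = centre.ctx
    r = float(np.linalg.norm(_metal_vector(atom, centre.chi)))
    mu = ctx.mu_eff * MUB
    k = (MU0 / (4.0 * math.pi) * atom.gamma * mu / r**3) ** 2
    tc = ctx.tau_c
    w = _larmor(atom.gamma, ctx.B0)
    ws = _electron_larmor(ctx.B0)
    jw = tc / (1.0 + tc * tc * w * w)
    jws = tc / (1.0 + tc * tc * ws * ws)
    if rate_kind == "R1":
        return (2.0 / 15.0) * k * (3.0 * jw + 7.0 * jws)
    if rate_kind == "R2":
        return (1.0 / 15.0) * k * (4.0 * tc + 3.0 * jw + 13.0 * jws)
    raise ValueError("rate_kind must be 'R1' or 'R2'")


def pre_sbm_aniso(atom: AtomRecord, position, g: SpectralDensityTensor,
                  rate_kind: str) -> float:
    """Anisotropic SBM PRE (s^-1): trace contraction of (3 rr^T - I)^2
    with the spectral power density tensor.

    R1 = (2/3) [(mu0/4pi) gamma / r^3]^2 Tr[(3 rr^T - I)^2 . G(omega)]
    R2 = (1/3) [...]^2 Tr[(3 rr^T - I)^2 . (G(0) + G(omega))]
    """
    if atom.gamma is None:
        raise ValueError(f"atom {atom.identity} has no gyromagnetic ratio")
    v = atom.coords - np.asarray(position, dtype=float)
    r = float(np.linalg.norm(v))
    if r == 0.0:
        raise DegenerateGeometryError("nucleus coincides with the paramagnetic centre")
    u = v / r
    d = 3.0 * np.outer(u, u) - _I3
    k = (MU0 / (4.0 * math.pi) * atom.gamma / r**3) ** 2
    d2 = d @ d
    if rate_kind == "R1":
        return (2.0 / 3.0) * k * float(np.trace(d2 @ g.g_omega))
    if rate_kind == "R2":
        return (1.0 / 3.0) * k * float(np.trace(d2 @ (g.g_zero + g.g_omega)))
    raise ValueError("rate_kind must be 'R1' or 'R2'")


def curie_invariants(sigma: np.ndarray) -> tuple[float, float]:
    """First and second shielding-tensor invariants (Lambda^2, Delta^2).

    Lambda^2 collects the antisymmetric part; Delta^2 the symmetric
    anisotropy.  Units are the square of whatever sigma carries.
    """
    s = np.asarray(sigma, dtype=float)
    lam2 = (
        (s[0, 1] - s[1, 0]) ** 2
        + (s[0, 2] - s[2, 0]) ** 2
        + (s[1, 2] - s[2, 1]) ** 2
    )
    delta2 = (
        s[0, 0] ** 2 + s[1, 1] ** 2 + s[2, 2] ** 2
        - s[0, 0] * s[1, 1] - s[0, 0] * s[2, 2] - s[1, 1] * s[2, 2]
        + 0.75 * (
            (s[0, 1] + s[1, 0]) ** 2
            + (s[0, 2] + s[2, 0]) ** 2
            + (s[1, 2] + s[2, 1]) ** 2
        )
    )
    return float(lam2), float(delta2)


def pre_curie(sigma_ppm: np.ndarray, ctx: ExperimentContext, rate_kind: str,
              gamma: float) -> float:
    """Curie-spin PRE (s^-1) from a shielding tensor (ppm).

    R1 = (1/2) L^2 w^2 tau_r/(1+9 tau_r^2 w^2)
         + (2/15) D^2 w^2 tau_r/(1+w^2 tau_r^2)
    R2 = (1/4) L^2 w^2 tau_r/(1+9 tau_r^2 w^2)
         + (1/45) D^2 w^2 [4 tau_r + 3 tau_r/(1+tau_r^2 w^2)]

    The shielding tensor must contain every orientation-dependent shift
    contribution of interest (the dipolar tensor of the full chi including
    its isotropic part, plus any CSA).  tau_r is used throughout: the
    Curie spin is modulated by molecular tumbling, not electron
    relaxation.
    """
    lam2, delta2 = curie_invariants(np.asarray(sigma_ppm, dtype=float) * PPM)
    w = _larmor(gamma, ctx.B0)
    tr = ctx.tau_r
    j_lam = tr / (1.0 + 9.0 * tr * tr * w * w)
    j_del = tr / (1.0 + tr * tr * w * w)
    if rate_kind == "R1":
        return 0.5 * lam2 * w * w * j_lam + (2.0 / 15.0) * delta2 * w * w * j_del
    if rate_kind == "R2":
        return 0.25 * lam2 * w * w * j_lam + (1.0 / 45.0) * delta2 * w * w * (
            4.0 * tr + 3.0 * j_del
        )
    raise ValueError("rate_kind must be 'R1' or 'R2'")


def _dipolar_sigma_ppm(chi: ChiTensor, atom: AtomRecord) -> np.ndarray:
    return dipolar_shielding_matrix(chi, _metal_vector(atom, chi)) / PPM


def pre_curie_csa(chi: ChiTensor, atom: AtomRecord, ctx: ExperimentContext,
                  rate_kind: str) -> float:
    """Curie PRE including CSA cross-correlation (s^-1):
    R = R_Curie(sigma_dip + sigma_CSA) - R_Curie(sigma_CSA).

    The CSA auto-relaxation present in both the paramagnetic and
    diamagnetic samples cancels in the difference; the surviving
    Curie x CSA cross term can make the total negative.  Without a CSA
    tensor on the atom this reduces to the pure Curie rate.
    """
    if atom.gamma is None:
        raise ValueError(f"atom {atom.identity} has no gyromagnetic ratio")
    sig_dip = _dipolar_sigma_ppm(chi, atom)
    if atom.csa is None:
        return pre_curie(sig_dip, ctx, rate_kind, atom.gamma)
    return pre_curie(sig_dip + atom.csa, ctx, rate_kind, atom.gamma) - pre_curie(
        atom.csa, ctx, rate_kind, atom.gamma
    )


def partner_dipolar_shielding_ppm(atom_obs: AtomRecord, atom_partner: AtomRecord,
                                  B0: float, spin: float = 0.5) -> np.ndarray:
    """Shielding tensor (ppm) at the observed spin due to the dipolar field
    of a spin-1/2 partner in one polarisation state:

    sigma_N = (1/B0) (mu0/4pi) gamma_N hbar I (3 rr^T/r^5 - I/r^3)

    Dividing by B0 expresses the partner's field in shielding (ppm) units
    so it can be added to the Curie shielding tensor.
    """
    if atom_partner.gamma is None:
        raise ValueError("partner spin needs a known gyromagnetic ratio")
    if B0 <= 0:
        raise ValueError("B0 must be positive")
    vec = atom_partner.coords - atom_obs.coords
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        raise DegenerateGeometryError("coincident atoms in a spin pair")
    geom = 3.0 * np.outer(vec, vec) / dist**5 - _I3 / dist**3
    return (
        MU0 / (4.0 * math.pi) * atom_partner.gamma * HBAR * spin / B0
    ) * geom / PPM


def ccr_curie_dd(chi: ChiTensor, atom_obs: AtomRecord, atom_partner: AtomRecord,
                 ctx: ExperimentContext) -> float:
    """Curie x dipole-dipole CCR (s^-1): differential R2 line broadening
    of the two doublet components of the observed spin.

    R = R2_Curie(sigma + sigma_N) - R2_Curie(sigma - sigma_N)

    where sigma is the Curie dipolar shielding tensor at the observed spin
    (full chi, isotropic part included) and sigma_N the partner-spin
    dipolar tensor.  The auto-correlated terms cancel in the difference,
    leaving 4x the pure cross quadratic form, exactly linear in chi.
    """
    if atom_obs.gamma is None:
        raise ValueError("observed spin needs a known gyromagnetic ratio")
    sigma = _dipolar_sigma_ppm(chi, atom_obs)
    sigma_n = partner_dipolar_shielding_ppm(atom_obs, atom_partner, ctx.B0)
    up = pre_curie(sigma + sigma_n, ctx, "R2", atom_obs.gamma)
    down = pre_curie(sigma - sigma_n, ctx, "R2", atom_obs.gamma)
    return up - down


# ---------------------------------------------------------------------------
# non-linear fitting of relaxation data


@dataclass
class RelaxationFitResult:
    centre: ParamagneticCentre
    cost: float
    converged: bool
    n_iter: int
    back_calculated: np.ndarray
    free_params: tuple


_SCALES = {  # descent works on O(1) parameters
    "x": 1e-10, "y": 1e-10, "z": 1e-10,  # Angstrom -> m
    "mueff": 1.0,
    "taur": 1e-9,       # ns
    "t1e": 1e-13,
    "ax": 1e-32, "rh": 1e-32,
    "cxx": 1e-32, "cyy": 1e-32, "cxy": 1e-32, "cxz": 1e-32, "cyz": 1e-32,
}


def _centre_from_params(values: dict, base: ParamagneticCentre) -> ParamagneticCentre:
    chi, ctx = base.chi, base.ctx
    pos = chi.position.copy()
    for i, key in enumerate(("x", "y", "z")):
        if key in values:
            pos[i] = values[key]
    ctx_kw = dict(
        B0=ctx.B0, temperature=ctx.temperature, tau_r=ctx.tau_r,
        t1e=ctx.t1e, mu_eff=ctx.mu_eff,
    )
    if "mueff" in values:
        ctx_kw["mu_eff"] = values["mueff"]
    if "taur" in values:
        ctx_kw["tau_r"] = values["taur"]
    if "t1e" in values:
        ctx_kw["t1e"] = values["t1e"]
    new_ctx = ExperimentContext(**ctx_kw)
    aniso = chi.anisotropy
    comps = {
        "cxx": aniso[0, 0], "cyy": aniso[1, 1], "cxy": aniso[0, 1],
        "cxz": aniso[0, 2], "cyz": aniso[1, 2],
    }
    comps.update({k: values[k] for k in comps if k in values})
    m = np.array([
        [comps["cxx"], comps["cxy"], comps["cxz"]],
        [comps["cxy"], comps["cyy"], comps["cyz"]],
        [comps["cxz"], comps["cyz"], -comps["cxx"] - comps["cyy"]],
    ])
    if new_ctx.mu_eff > 0:
        iso = chi_iso_from_moment(new_ctx.mu_eff, new_ctx.temperature)
    else:
        iso = chi.iso
    return ParamagneticCentre(ChiTensor(m + iso * np.eye(3), pos), new_ctx)


def _initial_values(centre: ParamagneticCentre) -> dict:
    aniso = centre.chi.anisotropy
    return {
        "x": centre.chi.position[0], "y": centre.chi.position[1],
        "z": centre.chi.position[2],
        "mueff": centre.ctx.mu_eff, "taur": centre.ctx.tau_r,
        "t1e": centre.ctx.t1e,
        "cxx": aniso[0, 0], "cyy": aniso[1, 1], "cxy": aniso[0, 1],
        "cxz": aniso[0, 2], "cyz": aniso[1, 2],
    }


_FREE_PARAM_GROUPS = {
    "position": ("x", "y", "z"),
    "tensor": ("cxx", "cyy", "cxy", "cxz", "cyz"),
}


def expand_free_params(free_params) -> tuple:
    out: list[str] = []
    for name in free_params:
        out.extend(_FREE_PARAM_GROUPS.get(name, (name,)))
    unknown = [p for p in out if p not in _SCALES]
    if unknown:
        raise ValueError(f"unknown free parameters: {unknown}")
    return tuple(dict.fromkeys(out))


def fit_relaxation(data, ensemble: StructureEnsemble, initial: ParamagneticCentre,
                   free_params, theory: str = "sbm", rate_kind: str = "R1",
                   gtol: float = 1e-13, max_iter: int = 10000,
                   ) -> RelaxationFitResult:
    """Non-linear least-squares fit of relaxation data (PRE or CCR).

    ``data`` is an ObservableTable of kind PRE (theory "sbm", "curie" or
    "curie_csa") or CCR (theory "ccr"), or a list of tables fitted
    jointly.  ``rate_kind`` may then be a matching list (e.g. R1 and R2
    tables together, which makes mu_eff and tau_r separately identifiable
    where a single rate type at one field would leave them degenerate).
    ``free_params`` names the parameters allowed to move: any of
    "position", "mueff", "taur", "t1e", "tensor" (the five anisotropy
    components).  The quasi-Newton (BFGS) descent minimises
    sum_i (calc_i - exp_i)^2 / S_i^2; weighting uses the per-datum
    experimental uncertainties.
    """
    from .fitting import match_rows  # late import to avoid a cycle

    free = expand_free_params(free_params)
    if not free:
        raise ValueError("no free parameters requested")
    datasets = data if isinstance(data, (list, tuple)) else [data]
    rate_kinds = rate_kind if isinstance(rate_kind, (list, tuple)) \
        else [rate_kind] * len(datasets)
    rows = []
    for table, rk in zip(datasets, rate_kinds):
        rows.extend((row, rk) for row in match_rows(table, ensemble))
    n_data = len(rows)
    if n_data < len(free):
        raise ValueError(
            f"underdetermined fit: {n_data} data for free parameters {free}"
        )
    values = _initial_values(initial)
    exp = np.array([r.value for r, _ in rows])
    weights = np.array([1.0 / r.uncertainty for r, _ in rows])

    def back_calc(centre: ParamagneticCentre) -> np.ndarray:
        out = np.empty(n_data)
        for i, (row, rk) in enumerate(rows):
            per_model = []
            for atoms in row.model_atoms:
                if theory == "sbm":
                    per_model.append(pre_sbm(atoms[0], centre, rk))
                elif theory == "curie":
                    sig = _dipolar_sigma_ppm(centre.chi, atoms[0])
                    per_model.append(
                        pre_curie(sig, centre.ctx, rk, atoms[0].gamma)
                    )
                elif theory == "curie_csa":
                    per_model.append(
                        pre_curie_csa(centre.chi, atoms[0], centre.ctx, rk)
                    )
                elif theory == "ccr":
                    per_model.append(
                        ccr_curie_dd(centre.chi, atoms[0], atoms[1], centre.ctx)
                    )
                else:
                    raise ValueError(f"unknown theory {theory!r}")
            # ensemble reduction: plain sum over models (see docs/methods)
            out[i] = float(np.sum(per_model))
        return out

    scales = np.array([_SCALES[p] for p in free])
    x0 = np.array([values[p] for p in free]) / scales

    def cost(x: np.ndarray) -> float:
        trial = dict(values)
        trial.update({p: v * s for p, v, s in zip(free, x, scales)})
        centre = _centre_from_params(trial, initial)
        resid = (back_calc(centre) - exp) * weights
        return float(resid @ resid)

    res = minimize(cost, x0, method="BFGS", jac="3-point",
                   options={"gtol": gtol, "maxiter": max_iter})
    # polish: quasi-Newton restarts reset the Hessian estimate and recover
    # the last decimals near ill-conditioned minima
    for _ in range(2):
        if max_iter == 0:
            break
        res2 = minimize(cost, res.x, method="BFGS", jac="3-point",
                        options={"gtol": gtol, "maxiter": max_iter})
        if res2.fun >= res.fun:
            break
        res = res2
    best = dict(values)
    best.update({p: v * s for p, v, s in zip(free, res.x, scales)})
    centre = _centre_from_params(best, initial)
    return RelaxationFitResult(
        centre=centre,
        cost=float(res.fun),
        converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-5),
        n_iter=int(res.nit),
        back_calculated=back_calc(centre),
        free_params=free,
    )
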