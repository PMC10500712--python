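"""Tensor fitting: SVD grid search, quasi-Newton refinement, ensemble and
multimer modes, uncertainty estimation and Q factors.

The PCS of the traceless susceptibility is linear in the five independent
anisotropy components at a fixed metal position, so the best-fitting
tensor at a position is a (weighted) linear least-squares solution via the
pseudo-inverse of the design matrix.  Scanning that solution over a cubic
grid of candidate positions inside a sphere gives a robust global initial
guess; a BFGS descent then refines tensor and position together.  RDC
fitting is the same linear algebra without the position parameters.

Ensemble handling follows the convention that calculated values of atoms
shared between models are *summed* (design-matrix rows are summed before
decomposition); see docs/methods.md for the consequences, in particular
the n-fold rescaling applied when fitting symmetric multimers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .constants import ANGSTROM, CHI_UNIT
from .forward import (
    pcs_linear_coefficients,
    racs_correction,
    rads_correction,
    rdc_linear_coefficients,
)
from .structure import AtomRecord, StructureEnsemble
from .tensors import (
    AlignmentTensor,
    ChiTensor,
    ExperimentContext,
    TensorParameters,
    alignment_from_chi,
    average_tensors,
    from_parameters,
    to_utr,
)

__all__ = [
    "ObservableTable",
    "FitResult",
    "UncertaintyResult",
    "match_rows",
    "svd_fit_pcs",
    "svd_grid_search",
    "nlr_refine",
    "svd_fit_rdc",
    "dchi_from_alignment",
    "ensemble_average_fit",
    "fit_multimer",
    "uncertainty",
    "q_factor",
]

_PAIR_KINDS = ("RDC", "CCR")


# ---------------------------------------------------------------------------
# observable tables


@dataclass
class ObservableTable:
    """Per-atom (or per-pair) experimental values with uncertainties.

    ``frame`` columns: residue, atom [, residue2, atom2], value,
    uncertainty, use.  ``kind`` is one of PCS, RDC, PRE, CCR; PCS values
    are ppm, RDC Hz, PRE and CCR s^-1.
    """

    kind: str
    frame: pd.DataFrame

    def __post_init__(self):
        self.kind = self.kind.upper()
        required = ["residue", "atom", "value"]
        if self.kind in _PAIR_KINDS:
            required = ["residue", "atom", "residue2", "atom2", "value"]
        for col in required:
            if col not in self.frame.columns:
                raise ValueError(f"missing column {col!r} for kind {self.kind}")
        if "uncertainty" not in self.frame.columns:
            self.frame["uncertainty"] = 1.0
        if "use" not in self.frame.columns:
            self.frame["use"] = True

    @classmethod
    def from_records(cls, kind, records, uncertainties=None):
        kind = kind.upper()
        if kind in _PAIR_KINDS:
            cols = ["residue", "atom", "residue2", "atom2", "value"]
        else:
            cols = ["residue", "atom", "value"]
        frame = pd.DataFrame(records, columns=cols)
        frame["uncertainty"] = 1.0 if uncertainties is None else uncertainties
        frame["use"] = True
        return cls(kind, frame)

    def used(self) -> pd.DataFrame:
        return self.frame[self.frame["use"]]

    def copy(self) -> "ObservableTable":
        return ObservableTable(self.kind, self.frame.copy())


@dataclass
class MatchedRow:
    index: int                    # row label in the source frame
    value: float
    uncertainty: float
    model_atoms: list             # one tuple of AtomRecord per model


def match_rows(data: ObservableTable, ensemble: StructureEnsemble,
               warn_unmatched: bool = True) -> list[MatchedRow]:
    """Match used data rows to structure atoms across all models.

    Rows whose atoms cannot be found in any model are reported with a
    warning and skipped (not a fatal error).
    """
    pair = data.kind in _PAIR_KINDS
    rows = []
    for idx, rec in data.used().iterrows():
        per_model = []
        for m in ensemble.model_indices:
            atoms1 = [a for a in ensemble.find(int(rec["residue"]), rec["atom"])
                      if a.model_index == m]
            if not atoms1:
                continue
            if pair:
                atoms2 = [a for a in
                          ensemble.find(int(rec["residue2"]), rec["atom2"])
                          if a.model_index == m]
                if not atoms2:
                    continue
                per_model.append((atoms1[0], atoms2[0]))
            else:
                per_model.append((atoms1[0],))
        if not per_model:
            if warn_unmatched:
                label = f"{int(rec['residue'])}.{rec['atom']}"
                if pair:
                    label += f"-{int(rec['residue2'])}.{rec['atom2']}"
                warnings.warn(f"no structure atom matches datum {label}",
                              stacklevel=2)
            continue
        rows.append(MatchedRow(idx, float(rec["value"]),
                               float(rec["uncertainty"]), per_model))
    return rows


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Outcome of a tensor fit.

    ``tensors`` holds one UTR parameter set per dataset; positions are in
    metres inside the parameter objects.  ``back_calculated`` parallels
    the used rows of each input table.
    """

    tensors: list
    position: np.ndarray
    cost: float
    q: float
    back_calculated: list
    offsets: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    alignment: AlignmentTensor | None = None
    uncertainty: "UncertaintyResult | None" = None

    @property
    def tensor(self) -> TensorParameters:
        return self.tensors[0]


@dataclass
class UncertaintyResult:
    method: str
    tensors: list                 # TensorParameters per repeat
    std: dict                     # per-parameter standard deviations


# ---------------------------------------------------------------------------
# SVD fitting of PCS data


def _chi_from_x5(x5_si: np.ndarray, position, isotropic: float = 0.0) -> ChiTensor:
    dxx, dyy, dxy, dxz, dyz = x5_si
    m = np.array([
        [dxx, dxy, dxz],
        [dxy, dyy, dyz],
        [dxz, dyz, -dxx - dyy],
    ]) + isotropic * np.eye(3)
    return ChiTensor(m, np.asarray(position, dtype=float))


def _racs_coefficients(csa_ppm: np.ndarray, ctx: ExperimentContext) -> np.ndarray:
    """Linear coefficients adding the RACS shift to a design-matrix row:
    RACS = scale * sum_ij dchi_ij sigma_t,ij is linear in the anisotropy."""
    from .constants import KB, MU0
    sym = 0.5 * (csa_ppm + csa_ppm.T)
    st = sym - np.trace(sym) / 3.0 * np.eye(3)
    scale = ctx.B0**2 / (15.0 * MU0 * KB * ctx.temperature)
    return scale * np.array([
        st[0, 0] - st[2, 2], st[1, 1] - st[2, 2],
        2 * st[0, 1], 2 * st[0, 2], 2 * st[1, 2],
    ])


def _pcs_design(rows: list[MatchedRow], position: np.ndarray,
                racs: bool = False, ctx: ExperimentContext | None = None):
    """Design matrix (rows summed over models) and data vector, in scaled
    units (susceptibility in 1e-32 m^3)."""
    n = len(rows)
    a = np.zeros((n, 5))
    b = np.empty(n)
    for i, row in enumerate(rows):
        for atoms in row.model_atoms:
            atom = atoms[0]
            a[i] += pcs_linear_coefficients(atom.coords - position)
            if racs and atom.csa is not None:
                a[i] += _racs_coefficients(atom.csa, ctx)
        b[i] = row.value
    return a * CHI_UNIT, b


def svd_fit_pcs(data: ObservableTable, ensemble: StructureEnsemble, position,
                weighted: bool = True, racs: bool = False,
                ctx: ExperimentContext | None = None):
    """Least-squares susceptibility anisotropy at a fixed metal position.

    Solves x = A+ . b (or the row-weighted variant with W_ii = 1/S_i) for
    the five anisotropy components; rank-deficient design matrices fall
    back to the minimum-norm solution.  Returns (ChiTensor, cost).
    """
    position = np.asarray(position, dtype=float)
    if racs and ctx is None:
        raise ValueError("RACS correction requires an ExperimentContext")
    rows = match_rows(data, ensemble)
    if len(rows) < 5:
        raise ValueError(f"need at least 5 usable data, got {len(rows)}")
    a, b = _pcs_design(rows, position, racs=racs, ctx=ctx)
    w = np.array([1.0 / r.uncertainty for r in rows]) if weighted \
        else np.ones(len(rows))
    x = np.linalg.pinv(w[:, None] * a, rcond=1e-12) @ (w * b)
    resid = (a @ x - b) * w
    chi = _chi_from_x5(x * CHI_UNIT, position)
    return chi, float(resid @ resid)


def _sphere_grid(origin: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Cubic lattice clipped to the sphere, centred on the origin, in
    lexicographic (x, y, z) order.  radius 0 yields the origin alone."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if radius < 0:
        raise ValueError("grid radius must be non-negative")
    n = int(math.floor(radius / spacing))
    offsets = np.arange(-n, n + 1) * spacing
    pts = []
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                if dx * dx + dy * dy + dz * dz <= radius * radius + 1e-30:
                    pts.append((dx, dy, dz))
    if not pts:
        raise ValueError("empty search grid")
    return origin + np.asarray(pts)


@dataclass
class GridSearchResult:
    position: np.ndarray
    tensors: list
    cost: float
    n_points: int


def svd_grid_search(datasets, ensemble: StructureEnsemble, origin,
                    radius: float, spacing: float, weighted: bool = True,
                    racs: bool = False, ctx: ExperimentContext | None = None,
                    ) -> GridSearchResult:
    """SVD fit at every cubic-grid point inside a sphere; the returned
    position minimises the total cost.  Several datasets (different metals
    at a common site) are fitted independently at each point and their
    costs summed.  Ties go to the lexicographically lowest point."""
    if isinstance(datasets, ObservableTable):
        datasets = [datasets]
    origin = np.asarray(origin, dtype=float)
    grid = _sphere_grid(origin, radius, spacing)
    matched = [match_rows(d, ensemble) for d in datasets]
    for rows in matched:
        if len(rows) < 5:
            raise ValueError("need at least 5 usable data per dataset")
    best = None
    for point in grid:
        total = 0.0
        tensors = []
        for rows in matched:
            a, b = _pcs_design(rows, point, racs=racs, ctx=ctx)
            w = np.array([1.0 / r.uncertainty for r in rows]) if weighted \
                else np.ones(len(rows))
            x = np.linalg.pinv(w[:, None] * a, rcond=1e-12) @ (w * b)
            resid = (a @ x - b) * w
            total += float(resid @ resid)
            tensors.append(_chi_from_x5(x * CHI_UNIT, point))
        if best is None or total < best[0]:
            best = (total, point, tensors)
    cost, position, tensors = best
    return GridSearchResult(position=position, tensors=tensors, cost=cost,
                            n_points=len(grid))


# ---------------------------------------------------------------------------
# non-linear refinement (PCS)


def nlr_refine(datasets, ensemble: StructureEnsemble, initial,
               free_params=("tensor", "position"), weighted: bool = True,
               racs: bool = False, rads: bool = False,
               ctx: ExperimentContext | None = None,
               initial_offsets=None, gtol: float = 1e-14,
               max_iter: int = 10000) -> FitResult:
    """Quasi-Newton (BFGS) refinement of tensor(s), shared position and
    optional per-dataset offsets against PCS data.

    ``initial`` is a ChiTensor or TensorParameters (or one per dataset;
    the first provides the shared starting position).  ``free_params`` is
    a subset of {"tensor", "position", "offset"}.  Minimises
    sum_i ((calc_i - exp_i)/S_i)^2, with ensemble sums over models for
    atoms present in several models.
    """
    if isinstance(datasets, ObservableTable):
        datasets = [datasets]
    n_sets = len(datasets)
    if not isinstance(initial, (list, tuple)):
        initial = [initial] * n_sets
    chis = [t if isinstance(t, ChiTensor) else from_parameters(t)
            for t in initial]
    free = set(free_params)
    unknown = free - {"tensor", "position", "offset"}
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if (racs or rads) and ctx is None:
        raise ValueError("RACS/RADS corrections require an ExperimentContext")

    matched = [match_rows(d, ensemble) for d in datasets]
    exps = [np.array([r.value for r in rows]) for rows in matched]
    wts = [np.array([1.0 / r.uncertainty for r in rows]) if weighted
           else np.ones(len(rows)) for rows in matched]
    offsets0 = list(initial_offsets) if initial_offsets is not None \
        else [0.0] * n_sets

    # parameter packing: [5 tensor comps per dataset][3 position][offsets]
    x0 = []
    if "tensor" in free:
        for chi in chis:
            an = chi.anisotropy / CHI_UNIT
            x0.extend([an[0, 0], an[1, 1], an[0, 1], an[0, 2], an[1, 2]])
    if "position" in free:
        x0.extend(chis[0].position / ANGSTROM)
    if "offset" in free:
        x0.extend(offsets0)
    x0 = np.asarray(x0, dtype=float)
    if x0.size == 0:
        raise ValueError("no free parameters requested")
    n_data = sum(len(r) for r in matched)
    if n_data < x0.size:
        raise ValueError(
            f"underdetermined fit: {n_data} data for {x0.size} free "
            f"parameters ({sorted(free)})"
        )

    def unpack(x):
        k = 0
        out_chis = list(chis)
        position = chis[0].position
        offs = list(offsets0)
        if "tensor" in free:
            for d in range(n_sets):
                x5 = x[k:k + 5] * CHI_UNIT
                out_chis[d] = _chi_from_x5(x5, position, chis[d].iso)
                k += 5
        if "position" in free:
            position = x[k:k + 3] * ANGSTROM
            k += 3
        out_chis = [c.with_position(position) for c in out_chis]
        if "offset" in free:
            offs = list(x[k:k + n_sets])
        return out_chis, position, offs

    def back_calc(chi: ChiTensor, rows):
        vals = np.zeros(len(rows))
        align = alignment_from_chi(chi, ctx) if racs else None
        for i, row in enumerate(rows):
            for atoms in row.model_atoms:
                atom = atoms[0]
                rel = atom.coords - chi.position
                comps = chi.anisotropy
                c = pcs_linear_coefficients(rel)
                vals[i] += float(c @ np.array(
                    [comps[0, 0], comps[1, 1], comps[0, 1],
                     comps[0, 2], comps[1, 2]]
                ))
                if racs and atom.csa is not None:
                    vals[i] += racs_correction(atom.csa, align)
                if rads:
                    vals[i] += rads_correction(chi, atom.coords, ctx)
        return vals

    def cost(x):
        out_chis, _, offs = unpack(x)
        total = 0.0
        for d in range(n_sets):
            resid = (back_calc(out_chis[d], matched[d]) + offs[d]
                     - exps[d]) * wts[d]
            total += float(resid @ resid)
        return total

    res = minimize(cost, x0, method="BFGS", jac="3-point",
                   options={"gtol": gtol, "maxiter": max_iter})
    out_chis, position, offs = unpack(res.x)
    backs = [back_calc(out_chis[d], matched[d]) + offs[d]
             for d in range(n_sets)]
    exp_all = np.concatenate(exps) if exps else np.array([])
    calc_all = np.concatenate(backs) if backs else np.array([])
    q = q_factor(exp_all, calc_all) if exp_all.size else float("nan")
    return FitResult(
        tensors=[to_utr(c) for c in out_chis],
        position=position,
        cost=float(res.fun),
        q=q,
        back_calculated=backs,
        offsets=offs,
        converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-5),
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# RDC fitting


def svd_fit_rdc(data: ObservableTable, ensemble: StructureEnsemble,
                weighted: bool = True,
                ctx: ExperimentContext | None = None):
    """Least-squares alignment tensor from RDC data via the pseudo-inverse
    of the 5-column design matrix (rows summed over models).

    Returns (AlignmentTensor, cost).  A rank-deficient design (e.g. all
    bond vectors parallel) produces the minimum-norm solution and a
    degeneracy warning.  If ``ctx`` is given, the corresponding
    susceptibility anisotropy is available via :func:`dchi_from_alignment`.
    """
    rows = match_rows(data, ensemble)
    if len(rows) < 5:
        raise ValueError(f"need at least 5 usable pairs, got {len(rows)}")
    n = len(rows)
    a = np.zeros((n, 5))
    b = np.empty(n)
    for i, row in enumerate(rows):
        for atom1, atom2 in row.model_atoms:
            a[i] += rdc_linear_coefficients(atom1, atom2)
        b[i] = row.value
    w = np.array([1.0 / r.uncertainty for r in rows]) if weighted \
        else np.ones(n)
    aw = w[:, None] * a
    rank = np.linalg.matrix_rank(aw, tol=None)
    if rank < 5:
        warnings.warn(
            f"rank-deficient RDC design matrix (rank {rank} < 5); "
            "returning the minimum-norm solution", stacklevel=2
        )
    x = np.linalg.pinv(aw, rcond=1e-12) @ (w * b)
    resid = (a @ x - b) * w
    axx, ayy, axy, axz, ayz = x
    matrix = np.array([
        [axx, axy, axz],
        [axy, ayy, ayz],
        [axz, ayz, -axx - ayy],
    ])
    return AlignmentTensor(matrix), float(resid @ resid)


def dchi_from_alignment(a: AlignmentTensor, ctx: ExperimentContext) -> ChiTensor:
    """Invert the induced-alignment relation to recover the susceptibility
    anisotropy implied by an alignment tensor."""
    from .constants import KB, MU0
    scale = 15.0 * MU0 * KB * ctx.temperature / ctx.B0**2
    return ChiTensor(scale * a.matrix)


# ---------------------------------------------------------------------------
# ensemble and multimer fitting


def ensemble_average_fit(data: ObservableTable, ensemble: StructureEnsemble,
                         mode: str, position=None, refine: bool = False,
                         weighted: bool = True, racs: bool = False,
                         ctx: ExperimentContext | None = None) -> FitResult:
    """Fit a tensor to a multi-model structure.

    mode "average-models": fit each model independently and average the
    resulting chi matrices element-wise (never the axial/rhombic/angle
    parameters); scalar by-products are averaged conventionally.

    mode "ensemble-average": one fit in which design-matrix rows (SVD) or
    calculated values (refinement) of atoms shared between models are
    summed before the cost is evaluated.
    """
    if data.kind == "RDC":
        return _ensemble_fit_rdc(data, ensemble, mode, weighted)
    if position is None:
        raise ValueError("PCS ensemble fitting requires a metal position")
    position = np.asarray(position, dtype=float)
    if mode == "ensemble-average":
        chi, cost = svd_fit_pcs(data, ensemble, position, weighted=weighted,
                                racs=racs, ctx=ctx)
        if refine:
            return nlr_refine(data, ensemble, chi, weighted=weighted,
                              racs=racs, ctx=ctx)
        calc = _svd_back_calc(data, ensemble, chi, racs=racs, ctx=ctx)
        exp = np.array([r.value for r in match_rows(data, ensemble,
                                                    warn_unmatched=False)])
        return FitResult([to_utr(chi)], position, cost,
                         q_factor(exp, calc), [calc])
    if mode == "average-models":
        results = []
        for m in ensemble.model_indices:
            sub = ensemble.model(m)
            chi, cost = svd_fit_pcs(data, sub, position, weighted=weighted,
                                    racs=racs, ctx=ctx)
            if refine:
                fr = nlr_refine(data, sub, chi, weighted=weighted,
                                racs=racs, ctx=ctx)
                results.append((from_parameters(fr.tensor), fr.cost, fr.q))
            else:
                calc = _svd_back_calc(data, sub, chi, racs=racs, ctx=ctx)
                exp = np.array([r.value for r in
                                match_rows(data, sub, warn_unmatched=False)])
                results.append((chi, cost, q_factor(exp, calc)))
        mean_chi = average_tensors([r[0] for r in results])
        return FitResult(
            tensors=[to_utr(mean_chi)],
            position=mean_chi.position,
            cost=float(np.mean([r[1] for r in results])),
            q=float(np.mean([r[2] for r in results])),
            back_calculated=[],
        )
    raise ValueError(f"unknown ensemble mode {mode!r}")


def _svd_back_calc(data, ensemble, chi: ChiTensor, racs=False, ctx=None):
    rows = match_rows(data, ensemble, warn_unmatched=False)
    a, _ = _pcs_design(rows, chi.position, racs=racs, ctx=ctx)
    an = chi.anisotropy / CHI_UNIT
    x = np.array([an[0, 0], an[1, 1], an[0, 1], an[0, 2], an[1, 2]])
    return a @ x


def _ensemble_fit_rdc(data, ensemble, mode, weighted) -> FitResult:
    if mode == "ensemble-average":
        align, cost = svd_fit_rdc(data, ensemble, weighted=weighted)
        rows = match_rows(data, ensemble, warn_unmatched=False)
        calc = np.array([
            sum(float(rdc_linear_coefficients(a1, a2) @ _align_x5(align))
                for a1, a2 in r.model_atoms) for r in rows
        ])
        exp = np.array([r.value for r in rows])
        return FitResult([], np.zeros(3), cost, q_factor(exp, calc), [calc],
                         alignment=align)
    if mode == "average-models":
        mats, costs = [], []
        for m in ensemble.model_indices:
            align, cost = svd_fit_rdc(data, ensemble.model(m), weighted=weighted)
            mats.append(align.matrix)
            costs.append(cost)
        align = AlignmentTensor(np.mean(mats, axis=0))
        return FitResult([], np.zeros(3), float(np.mean(costs)), float("nan"),
                         [], alignment=align)
    raise ValueError(f"unknown ensemble mode {mode!r}")


def _align_x5(a: AlignmentTensor) -> np.ndarray:
    m = a.matrix
    return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])


def fit_multimer(data: ObservableTable, ensemble: StructureEnsemble,
                 n_monomers: int, position, refine: bool = False,
                 weighted: bool = True, scale: bool = True) -> FitResult:
    """Fit one monomer's tensor to a symmetric multimer whose monomers are
    supplied as models of one ensemble.

    The ensemble-sum fit spreads the (site-averaged) experimental signal
    over the n symmetry copies, so the fitted anisotropy is rescaled
    n-fold on output (disable with ``scale=False``).
    """
    if n_monomers < 2:
        warnings.warn("fit_multimer with n_monomers < 2 is an ordinary fit",
                      stacklevel=2)
    result = ensemble_average_fit(data, ensemble, "ensemble-average",
                                  position=position, refine=refine,
                                  weighted=weighted)
    if scale and n_monomers >= 1:
        scaled = [
            to_utr(ChiTensor(from_parameters(t).matrix * n_monomers,
                             t.position))
            for t in result.tensors
        ]
        result.tensors = scaled
    return result


# ---------------------------------------------------------------------------
# uncertainty estimation


_UTR_KEYS = ("axial", "rhombic", "euler_alpha", "euler_beta", "euler_gamma",
             "x", "y", "z")


def _params_vector(t: TensorParameters) -> np.ndarray:
    return np.array([
        t.axial, t.rhombic, t.euler_alpha, t.euler_beta, t.euler_gamma,
        t.position[0], t.position[1], t.position[2],
    ])


def uncertainty(fit_fn, data: ObservableTable, method: str,
                repeats: int = 50, fraction: float = 0.8,
                noise_scales=0.0, seed: int = 0,
                ensemble: StructureEnsemble | None = None) -> UncertaintyResult:
    """Robustness of a fit by repeat fitting.

    ``fit_fn(table, ensemble) -> TensorParameters`` re-runs the fit of
    interest.  Methods:

    * "structure": one fit per model of a multi-model ensemble;
    * "bootstrap": ``repeats`` fits, each on a random subset of the data
      of size fraction*n, sampled without replacement;
    * "montecarlo": ``repeats`` fits on the full data with added noise
      drawn uniformly from [-s, +s] per datum (``noise_scales`` scalar or
      per-datum array).

    Reports the per-repeat tensors and standard deviations of the UTR
    parameters and position.
    """
    tensors = []
    if method == "structure":
        if ensemble is None or ensemble.model_count < 2:
            raise ValueError("structure method needs a multi-model ensemble")
        for m in ensemble.model_indices:
            tensors.append(fit_fn(data, ensemble.model(m)))
    elif method == "bootstrap":
        if repeats < 2:
            raise ValueError("need at least 2 repeats")
        if not 0.0 < fraction <= 1.0:
            raise ValueError("bootstrap fraction must be in (0, 1]")
        rng = np.random.default_rng(seed)
        used = data.used().index.to_numpy()
        k = max(1, int(round(fraction * len(used))))
        for _ in range(repeats):
            pick = rng.choice(used, size=k, replace=False)
            sub = data.copy()
            sub.frame["use"] = sub.frame.index.isin(pick) & data.frame["use"]
            tensors.append(fit_fn(sub, ensemble))
    elif method == "montecarlo":
        if repeats < 2:
            raise ValueError("need at least 2 repeats")
        rng = np.random.default_rng(seed)
        scales = np.broadcast_to(np.asarray(noise_scales, dtype=float),
                                 (len(data.frame),))
        for _ in range(repeats):
            sub = data.copy()
            noise = rng.uniform(-1.0, 1.0, size=len(sub.frame)) * scales
            sub.frame["value"] = sub.frame["value"] + noise
            tensors.append(fit_fn(sub, ensemble))
    else:
        raise ValueError(f"unknown uncertainty method {method!r}")

    vecs = np.array([_params_vector(t) for t in tensors])
    std = dict(zip(_UTR_KEYS, vecs.std(axis=0, ddof=0)))
    return UncertaintyResult(method=method, tensors=tensors, std=std)


# ---------------------------------------------------------------------------
# quality factors


def q_factor(exp_values, calc_values, variant: str = "default") -> float:
    """Normalised root-sum-square misfit between experiment and
    back-calculation.

    default:  Q = sqrt( sum_im (exp_i - calc_mi)^2 / sum_im exp_i^2 )
    clore:    denominator sum_im (exp_i + calc_mi)^2 (tends to be twice
              smaller in the small-residual limit)

    ``calc_values`` may be 1-D (one value per datum) or 2-D with one row
    per ensemble model (the inner sum over m).
    """
    exp = np.asarray(exp_values, dtype=float)
    calc = np.asarray(calc_values, dtype=float)
    if calc.ndim == 1:
        calc = calc[None, :]
    if calc.shape[1] != exp.shape[0]:
        raise ValueError("experimental and calculated tables are not parallel")
    exp2 = np.broadcast_to(exp, calc.shape)
    num = float(np.sum((exp2 - calc) ** 2))
    if variant == "default":
        den = float(np.sum(exp2**2))
    elif variant == "clore":
        den = float(np.sum((exp2 + calc) ** 2))
    else:
        raise ValueError(f"unknown Q-factor variant {variant!r}")
    if den == 0.0:
        raise ZeroDivisionError("zero denominator in Q factor")
    return math.sqrt(num / den)
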