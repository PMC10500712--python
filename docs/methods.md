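# Methods

This note records the physical models implemented in `paratensor`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Units and constants

Internal computation is SI throughout: metres, m³ (susceptibility),
seconds, tesla, kelvin, radians. Display and file formats use the field's
conventional units — Å, 10⁻³² m³, ppm, Hz, s⁻¹, degrees — converted only
at the I/O surface. Physical constants (μ₀, k_B, μ_B, ħ, g_e) are CODATA
2018 values frozen in `constants.py` so results are bit-stable across
environments; the free-electron g-factor g_e = 2.00231930436256 is used
for the electron Larmor frequency in the SBM spectral densities, the
dominant convention in SBM practice.

## Forward models

**PCS.** The dipolar shielding tensor σ = (1/4π)(3rrᵀ/r⁵ − I/r³)·χ is a
product of two symmetric matrices and is therefore not symmetric in
general; the PCS is Tr σ/3 and depends only on the traceless anisotropy
Δχ. Two algebraically equivalent routes are implemented (trace of σ, and
the explicit 5-parameter linear form) and cross-checked; the linear form
provides the rows of the SVD design matrix. Fermi-contact shifts are out
of scope.

**Alignment, RDC, Saupe.** A = B₀²/(15 μ₀ k_B T)·Δχ. The Saupe matrix is
defined here as S = (3/2)A; this scaling is a package convention — the
relation between the two representations is stated in different ways
across the literature, so every Saupe value printed by this package should
be read against this definition. RDCs follow the r_ABᵀ·A·r_AB quadratic
form in Hz, with an equivalent 5-vector expansion used for the linear fit.

**RACS and RADS.** A shielding tensor σ (CSA, or the dipolar tensor
itself) no longer averages to its isotropic value under molecular
alignment. Expanding the Boltzmann orientation distribution to first order
gives ⟨b_i b_j⟩ = δ_ij/3 + A_ij with exactly the alignment tensor of the
equation above, hence a residual shift Σ_ij A_ij σ̄_ij (σ̄ = symmetric
traceless part), equivalently (2/3)Σ S_ij σ̄_ij in the Saupe convention.
This contraction was validated against a brute-force Boltzmann-weighted
orientational average on a 10⁶-point sphere quadrature (the acceptance
suite re-runs that oracle); the residual deviations, ~0.2% of the RMS
residual shift at lanthanide-scale anisotropies, are genuine second-order
alignment terms that the first-order contraction does not model. Both
corrections are *added* to the back-calculated PCS before comparison with
experiment. RACS is linear in Δχ and is folded into the SVD design matrix
when requested; RADS is quadratic in Δχ (alignment × dipolar shielding)
and available in the non-linear path. The RADS contraction uses σ built
from the full χ; only its traceless projection survives.

**PRE.** Isotropic SBM rates use the standard two-spectral-density forms
with 1/τ_c = 1/τ_r + 1/T_1e, ω = |γ|B₀ and ω_S = g_e μ_B B₀/ħ. The
anisotropic extension contracts (3r̂r̂ᵀ − I)² with a user-supplied
spectral power density tensor G (fitting G is exposed through the library
API only). Curie rates are computed from the first and second invariants
(Λ², Δ²) of the shielding tensor built from the *full* χ including the
isotropic part predicted by the Curie law χ_iso = μ₀(μ_eff μ_B)²/(3k_B T).
The Λ² spectral density is implemented as τ_r/(1 + 9τ_r²ω²) exactly as
adopted here; note that rank-1 relaxation expressions elsewhere in the
literature carry an extra factor 3 in the numerator — the forms used here
are applied consistently on both sides of every difference (cross-term)
computation, where any common prefactor of Λ² cancels. The Curie
equations use τ_r, not τ_c: the thermally averaged electron moment is
modulated by molecular tumbling, not by electron relaxation.

**Cross terms.** Curie×CSA PRE is the difference
R(σ_dip + σ_CSA) − R(σ_CSA): CSA auto-relaxation cancels and the
surviving cross term is linear (odd) in χ, so the total may be negative.
Curie×DD CCR is R₂(σ + σ_N) − R₂(σ − σ_N) with σ_N the partner-spin
dipolar tensor expressed in ppm through the 1/B₀ conversion; the
difference equals 4× the cross quadratic form and is exactly linear in χ.
For isotropic χ the implementation reduces analytically to the classical
(3cos²θ − 1)/(r_M³ r_HN³) cross-correlation expression; the test suite
verifies this equivalence to 1e-8 relative through an independently coded
closed form, using the identity Δ²(a,b) = (3/2)Tr(ab) for symmetric
traceless tensors.

## Fitting

At fixed metal position the PCS (and the RDC, always) is linear in the
five anisotropy components, so the best-fit tensor is x = A⁺b, or
(WA)⁺(Wb) with W_ii = 1/S_i when uncertainties are supplied; the
pseudo-inverse returns the minimum-norm solution for rank-deficient
designs (e.g. all-parallel bonds, which trigger a degeneracy warning).
The weighted cost is used consistently whenever uncertainties exist. The
grid search evaluates this solution on a cubic lattice clipped to a
sphere (lexicographic tie-break, radius 0 = single point), summing costs
across datasets that share a position. Non-linear refinement uses BFGS
with 3-point finite-difference gradients; free parameters are grouped
("tensor" = the five Cartesian anisotropy components, "position",
"offset", and for relaxation "mueff"/"taur"/"t1e"). The Cartesian
parameterisation avoids Euler-angle degeneracies during descent; results
are converted to the unique representation only on output. Parameters are
scaled to O(1–10) (10⁻³² m³, Å, ns) for quasi-Newton conditioning, with
gradient tolerance 1e-13…1e-14 and up to two descent restarts to polish
ill-conditioned minima.

**Identifiability.** A single PRE rate type at one field constrains only
the product of μ_eff² with one spectral-density scalar, so μ_eff and τ_r
cannot be separated from such data; `fit_relaxation` accepts several
datasets with per-dataset rate kinds (R1 + R2 jointly pins both), and the
recovery tests use that construction.

**Ensembles.** Calculated values of atoms shared between models are
*summed* (not averaged): SVD design-matrix rows are summed over models
before decomposition, and the non-linear cost compares Σ_m calc_m,i with
exp_i. With one model this reduces exactly to the plain weighted sum of
squares. The convention has a visible consequence: fitting site-averaged
data for a symmetric n-mer (monomers supplied as models) yields 1/n of
the per-monomer tensor, and `fit_multimer` rescales the result n-fold
(flag to disable). For conventional NMR ensembles the alternative
"average-models" mode fits every model independently and averages the χ
matrices element-wise — never the (axial, rhombic, angle) parameters, so
mixing prolate and oblate solutions introduces no artefacts. Atoms are
matched across models by (chain, residue number, atom name); PDB serial
numbers are not stable across files and are not used.

**Uncertainty.** Three repeat-fit schemes: one fit per model
(structure-sourced); bootstrap on a random subset of size fraction·n,
sampled *without replacement* (the classical with-replacement bootstrap
is deliberately not used — the scheme reproduces "fit a stated proportion
of the data"); Monte-Carlo with per-datum noise drawn uniformly from
[−s, +s]. Reported spreads are naive standard deviations of the UTR
parameters and position; Euler-angle spreads are not circular statistics
and should be read qualitatively near wrap-around.

**Q factors.** Q = √(Σ_i Σ_m (exp_i − calc_m,i)² / Σ_i Σ_m exp_i²); the
inner sum runs over ensemble models as printed, i.e. groups with unequal
sizes are summed, not averaged. The Clore variant replaces the
denominator with Σ(exp + calc)² and tends to half the default Q in the
small-residual limit.

## Unique tensor representation

Eigen-decomposition of Δχ with principal values ordered
|Δχzz| ≥ |Δχyy| ≥ |Δχxx|; axial = Δχzz − (Δχxx + Δχyy)/2, rhombic =
Δχxx − Δχyy. The proper π-flips about the principal axes (the tensor's
D₂ symmetry) are enumerated to choose ZYZ Euler angles all in [0, π];
ties resolve to the lexicographically smallest triple. Axially symmetric
tensors (rhombic = 0) have an unobservable γ, fixed to 0; the same
applies at the β = 0 gimbal lock.

## Default CSA tensors and ion templates

Backbone amide ¹H/¹⁵N and carbonyl ¹³C CSA tensors ship as editable
configuration (`data/defaults.toml`): traceless principal components in
ppm plus an in-plane tilt of the unique axis relative to a reference bond
(N–H for amides, C→O for the carbonyl, whose zz axis is the sp² plane
normal). The magnitudes are literature-flavoured defaults intended to be
adjusted; tests assert only symmetry, principal-value consistency with
the configuration and rotation covariance, never the absolute numbers.
The same file holds lanthanide templates: Hund's-rules (g, J), placeholder
anisotropy magnitudes of the kind reported for lanthanide-tagged
calbindin-like systems, and representative T_1e values — convenience
starting points, not reference data. Default isotopes are ¹H, ¹⁵N, ¹³C
(overridable); elements without an entry carry no γ and are excluded from
RDC/relaxation operations.

## Synthetic data generator

`make_structure` builds small peptide-like chains with standard local
bond lengths (N–H 1.02 Å, N–CA 1.47 Å, C–O 1.23 Å) threaded along a
gentle spiral with seeded random offsets, deliberately *not* a real
secondary structure: well-spread N–H orientations keep the 5-parameter
alignment fit full-rank, where an ideal helix (near-parallel bonds) would
be degenerate. Options: per-model Gaussian coordinate jitter, an exact C2
dimer (model 2 = 180° rotation about z), per-model override of N–H
directions (used to build the opposed-bond RDC fixtures), and an optional
HETATM lanthanide. `make_observables` forward-calculates any of the four
effects from a known tensor, optionally with RACS/RADS corrections, and
adds seeded *Gaussian* noise — deliberately distinct from the uniform
noise of the Monte-Carlo uncertainty scheme, since the former emulates
experimental scatter while the latter reproduces the stated
error-simulation recipe. Identical (parameters, seed) inputs give
byte-identical files.

Default study conditions used across tests and the acceptance script:
B₀ = 18.8 T, T = 298 K, τ_r = 4 ns, T_1e = 10⁻¹³ s, μ_eff = 9.72 μ_B
(Tb-like), axial/rhombic anisotropy 30/8 ×10⁻³² m³, 40–50 amide ¹H data.
These are typical of lanthanide-tagged small-protein work; problem sizes
(50 spins, ≤10 Å grids, ≤40 uncertainty repeats, 10⁶-point oracle
quadrature) were chosen so the whole validation chain runs in seconds
while leaving every comparison far from its tolerance.

What passing these tests shows — and does not. The synthetic fixtures
have exact geometry, complete data, and noise that matches the assumed
model, so round-trip recoveries demonstrate the correctness of the
algebra, the optimisation and the conventions, not robustness to
structural error, incomplete assignments, conformational averaging of
side chains or wrong CSA parameterisations in real data.

## Numerical choices and degenerate inputs

Pseudo-inverse cutoff 1e-12 (relative); design matrices are built in
scaled units so entries are O(1–100). Zero-length metal–nucleus or
internuclear vectors raise degenerate-geometry errors; the map writer
zeroes the voxel containing the metal (the field diverges there).
Symmetry/tracelessness of tensor inputs is validated to 1e-12 relative.
CCP4 volumes are written in mode 2 (float32), P1, orthogonal Å grid, with
NXSTART-style origin indices. Principal-axis scatter data resolve the
antipodal ambiguity of tensor axes to the +z hemisphere before computing
longitude/latitude.

## Known limitations

No Fermi-contact shifts or contact relaxation; no zero-field-splitting
effects; no cross-correlation between SBM dipole–dipole and CSA
relaxation; one paramagnetic centre per fit (no multi-site fitting); no
structure refinement against paramagnetic restraints; no mmCIF input or
hydrogen building; Curie equations as adopted here (see the Λ² note
above) should be compared carefully against other programs when absolute
Λ²-driven rates of strongly antisymmetric shielding tensors matter.
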