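"""SVD/NLR fitting, ensemble and multimer modes, uncertainty, Q factors."""

import math
import warnings

import numpy as np
import pytest

from paratensor.constants import ANGSTROM, CHI_UNIT
from paratensor.fitting import (
    ObservableTable,
    ensemble_average_fit,
    fit_multimer,
    match_rows,
    nlr_refine,
    q_factor,
    svd_fit_pcs,
    svd_fit_rdc,
    svd_grid_search,
    uncertainty,
)
from paratensor.forward import rdc
from paratensor.synthetic import make_observables, make_structure
from paratensor.tensors import (
    ChiTensor,
    ExperimentContext,
    ParamagneticCentre,
    TensorParameters,
    alignment_from_chi,
    from_parameters,
    to_utr,
)


class TestSVDPCS:
    def test_forward_then_fit_round_trip(self, structure, truth_chi,
                                         pcs_table):
        chi, cost = svd_fit_pcs(pcs_table, structure, truth_chi.position)
        np.testing.assert_allclose(chi.anisotropy, truth_chi.anisotropy,
                                   rtol=1e-10)
        assert cost < 1e-18

    def test_equal_weights_match_unweighted(self, structure, truth_chi,
                                            pcs_table):
        noisy = pcs_table.copy()
        rng = np.random.default_rng(0)
        noisy.frame["value"] += rng.normal(scale=0.1, size=len(noisy.frame))
        noisy.frame["uncertainty"] = 0.25
        chi_w, _ = svd_fit_pcs(noisy, structure, truth_chi.position,
                               weighted=True)
        chi_u, _ = svd_fit_pcs(noisy, structure, truth_chi.position,
                               weighted=False)
        np.testing.assert_allclose(chi_w.matrix, chi_u.matrix, rtol=1e-10)

    def test_scaling_all_uncertainties_leaves_fit_unchanged(
            self, structure, truth_chi, pcs_table):
        noisy = pcs_table.copy()
        rng = np.random.default_rng(1)
        noisy.frame["value"] += rng.normal(scale=0.1, size=len(noisy.frame))
        noisy.frame["uncertainty"] = rng.uniform(0.05, 0.5,
                                                 size=len(noisy.frame))
        chi_1, _ = svd_fit_pcs(noisy, structure, truth_chi.position)
        noisy.frame["uncertainty"] *= 7.3
        chi_2, _ = svd_fit_pcs(noisy, structure, truth_chi.position)
        np.testing.assert_allclose(chi_1.matrix, chi_2.matrix, rtol=1e-10)

    def test_zero_data_gives_zero_tensor(self, structure, truth_chi,
                                         pcs_table):
        zero = pcs_table.copy()
        zero.frame["value"] = 0.0
        chi, _ = svd_fit_pcs(zero, structure, truth_chi.position)
        assert np.allclose(chi.matrix, 0.0)

    def test_too_few_data_raises(self, structure, truth_chi, pcs_table):
        small = pcs_table.copy()
        small.frame = small.frame.iloc[:4]
        with pytest.raises(ValueError, match="at least 5"):
            svd_fit_pcs(small, structure, truth_chi.position)


class TestGridSearch:
    def test_radius_zero_single_point(self, structure, truth_chi, pcs_table):
        origin = truth_chi.position + np.array([1, 1, 1]) * ANGSTROM
        res = svd_grid_search(pcs_table, structure, origin, 0.0,
                              2 * ANGSTROM)
        assert res.n_points == 1
        np.testing.assert_allclose(res.position, origin)

    def test_recovers_position_within_spacing(self, structure, truth_chi,
                                              pcs_table):
        origin = truth_chi.position + np.array([5, 0, 0]) * ANGSTROM
        res = svd_grid_search(pcs_table, structure, origin, 10 * ANGSTROM,
                              1 * ANGSTROM)
        assert np.linalg.norm(res.position - truth_chi.position) \
            <= 1.0 * ANGSTROM + 1e-15

    def test_minimum_is_exhaustive_on_small_grid(self, structure, truth_chi,
                                                 pcs_table):
        # brute-force enumeration oracle: returned cost <= all grid costs
        origin = truth_chi.position + np.array([2, -1, 1]) * ANGSTROM
        radius, spacing = 4 * ANGSTROM, 2 * ANGSTROM
        res = svd_grid_search(pcs_table, structure, origin, radius, spacing)
        n = int(radius / spacing)
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                for k in range(-n, n + 1):
                    d = np.array([i, j, k]) * spacing
                    if np.dot(d, d) > radius**2:
                        continue
                    _, cost = svd_fit_pcs(pcs_table, structure, origin + d)
                    assert res.cost <= cost + 1e-25

    def test_joint_two_dataset_search_shares_position(self, structure,
                                                      truth_chi):
        ctx = ExperimentContext(B0=18.8)
        other = TensorParameters(-12e-32, -6e-32, 1.2, 0.7, 2.1,
                                 truth_chi.position)
        chi2 = from_parameters(other)
        t1 = make_observables(structure,
                              ParamagneticCentre(truth_chi, ctx), "PCS",
                              noise=0.02, seed=11)
        t2 = make_observables(structure,
                              ParamagneticCentre(chi2, ctx), "PCS",
                              noise=0.02, seed=12)
        origin = truth_chi.position + np.array([3, 2, -2]) * ANGSTROM
        joint = svd_grid_search([t1, t2], structure, origin, 6 * ANGSTROM,
                                1 * ANGSTROM)
        assert np.linalg.norm(joint.position - truth_chi.position) \
            <= 1.5 * ANGSTROM
        assert len(joint.tensors) == 2


class TestNLR:
    def test_start_at_truth_stays_at_truth(self, structure, truth_chi,
                                           truth_params, pcs_table):
        res = nlr_refine(pcs_table, structure, truth_chi)
        assert res.cost < 1e-15
        assert np.linalg.norm(res.position - truth_chi.position) \
            < 1e-6 * ANGSTROM

    def test_eight_parameter_recovery_with_noise(self, structure, truth_chi,
                                                 truth_params, centre):
        # Monte-Carlo calibration: with 1% value noise the fitted
        # parameters stay within 3 simulated-sigma of the truth
        rng_scale = 0.01 * 20  # ~1% of a typical |PCS| of tens of ppm
        fits = []
        for seed in range(6):
            table = make_observables(structure, centre, "PCS",
                                     noise=rng_scale, seed=100 + seed)
            gs = svd_grid_search(table, structure, truth_chi.position,
                                 3 * ANGSTROM, 1.5 * ANGSTROM)
            fr = nlr_refine(table, structure, gs.tensors[0])
            fits.append([fr.tensor.axial, fr.tensor.rhombic,
                         *fr.position])
        fits = np.array(fits)
        mean = fits.mean(axis=0)
        sigma = fits.std(axis=0, ddof=1) / math.sqrt(len(fits))
        target = np.array([truth_params.axial, truth_params.rhombic,
                           *truth_chi.position])
        for m, s, t in zip(mean, sigma, target):
            assert abs(m - t) < 4 * s + 1e-12 * abs(t)

    def test_underdetermined_raises(self, structure, truth_chi, pcs_table):
        small = pcs_table.copy()
        small.frame = small.frame.iloc[:6]
        with pytest.raises(ValueError, match="underdetermined"):
            nlr_refine(small, structure, truth_chi,
                       free_params=("tensor", "position"))


class TestSVDRDC:
    def test_round_trip(self, structure, truth_chi, ctx, rdc_table):
        align, cost = svd_fit_rdc(rdc_table, structure)
        true_a = alignment_from_chi(truth_chi, ctx)
        np.testing.assert_allclose(align.matrix, true_a.matrix, rtol=1e-10)
        assert cost < 1e-16

    def test_zero_rdcs_give_zero_tensor(self, structure, rdc_table):
        zero = rdc_table.copy()
        zero.frame["value"] = 0.0
        align, _ = svd_fit_rdc(zero, structure)
        assert np.allclose(align.matrix, 0.0)

    def test_parallel_bonds_degenerate_warns(self, ctx, truth_chi):
        ens = make_structure(n_residues=10, seed=13,
                             nh_directions=[np.array([0.0, 0.0, 1.0])])
        table = make_observables(
            ens, ParamagneticCentre(truth_chi, ctx), "RDC")
        with pytest.warns(UserWarning, match="rank-deficient"):
            align, _ = svd_fit_rdc(table, ens)

    def test_too_few_pairs_raises(self, structure, rdc_table):
        small = rdc_table.copy()
        small.frame = small.frame.iloc[:4]
        with pytest.raises(ValueError, match="at least 5"):
            svd_fit_rdc(small, structure)


class TestEnsemble:
    def test_average_models_identical_models_equal_single_fit(
            self, truth_chi, ctx):
        ens = make_structure(n_residues=20, n_models=3, jitter=0.0, seed=14)
        centre = ParamagneticCentre(truth_chi, ctx)
        table = make_observables(ens, centre, "PCS")
        multi = ensemble_average_fit(table, ens, "average-models",
                                     position=truth_chi.position)
        single = svd_fit_pcs(table, ens.model(0), truth_chi.position)[0]
        np.testing.assert_allclose(
            from_parameters(multi.tensor).anisotropy, single.anisotropy,
            rtol=1e-10,
        )

    def test_ensemble_average_single_model_reduces_to_plain_fit(
            self, structure, truth_chi, pcs_table):
        plain_chi, plain_cost = svd_fit_pcs(pcs_table, structure,
                                            truth_chi.position)
        ens = ensemble_average_fit(pcs_table, structure, "ensemble-average",
                                   position=truth_chi.position)
        np.testing.assert_allclose(
            from_parameters(ens.tensor).anisotropy, plain_chi.anisotropy,
            rtol=1e-12,
        )
        assert ens.cost == pytest.approx(plain_cost, abs=1e-24)

    def test_ensemble_cost_single_model_matches_direct_sum(
            self, structure, truth_chi, pcs_table):
        # the ensemble cost with one model is exactly the plain
        # sum-of-squares cost
        noisy = pcs_table.copy()
        rng = np.random.default_rng(2)
        noisy.frame["value"] += rng.normal(scale=0.05, size=len(noisy.frame))
        noisy.frame["uncertainty"] = 0.05
        res = nlr_refine(noisy, structure, truth_chi, free_params=("tensor",),
                         max_iter=0)
        chi0 = from_parameters(res.tensor)
        direct = 0.0
        from paratensor.forward import pcs as pcs_fn

        for row in match_rows(noisy, structure):
            calc = pcs_fn(chi0, row.model_atoms[0][0].coords)
            direct += ((calc - row.value) / row.uncertainty) ** 2
        assert res.cost == pytest.approx(direct, rel=1e-9)

    def test_opposed_bonds_ensemble_rdc_cancels(self, ctx):
        # two models whose N-H orientations produce equal and opposite
        # RDCs: the ensemble average vanishes although each single-model
        # RDC is large
        theta = math.acos(math.sqrt(2.0 / 3.0))
        u1 = np.array([1.0, 0.0, 0.0])
        u2 = np.array([math.sin(theta), 0.0, math.cos(theta)])
        ens = make_structure(n_residues=10, n_models=2, seed=15,
                             nh_directions=[u1, u2])
        ax = 30e-32
        chi = ChiTensor(np.diag([-ax / 3, -ax / 3, 2 * ax / 3]))
        align = alignment_from_chi(chi, ctx)
        rows = match_rows(
            make_observables(ens, ParamagneticCentre(chi, ctx), "RDC"), ens
        )
        for row in rows:
            per_model = [rdc(align, a1, a2) for a1, a2 in row.model_atoms]
            mean_val = np.mean(per_model)
            assert abs(mean_val) < 0.01 * abs(per_model[0])

    def test_inconsistent_identity_sets_error(self, truth_chi, ctx):
        ens = make_structure(n_residues=8, n_models=2, seed=16)
        # drop one atom from model 1 only
        ens2 = type(ens)([a for a in ens.atoms
                          if not (a.model_index == 1
                                  and a.residue_number == 3
                                  and a.atom_name == "H")])
        table = make_observables(ens.model(0),
                                 ParamagneticCentre(truth_chi, ctx), "PCS")
        rows = match_rows(table, ens2, warn_unmatched=False)
        short = [r for r in rows if len(r.model_atoms) == 1]
        assert len(short) == 1  # the missing atom is matched in one model


class TestMultimer:
    def test_c2_dimer_recovers_monomer_tensor(self, ctx, truth_params):
        chi = from_parameters(truth_params)
        dimer = make_structure(n_residues=20, mode="dimer", seed=17)
        centre = ParamagneticCentre(chi, ctx)
        # experimental data: average of the PCS generated by the two sites
        table = make_observables(dimer, centre, "PCS",
                                 ensemble_reduce="mean")
        res = fit_multimer(table, dimer, 2, chi.position)
        fitted = res.tensor
        assert fitted.axial == pytest.approx(truth_params.axial, rel=0.01)
        assert fitted.rhombic == pytest.approx(truth_params.rhombic,
                                               rel=0.01)

    def test_scaling_flag_off_is_exactly_one_over_n(self, ctx, truth_params):
        chi = from_parameters(truth_params)
        dimer = make_structure(n_residues=15, mode="dimer", seed=18)
        table = make_observables(dimer, ParamagneticCentre(chi, ctx), "PCS",
                                 ensemble_reduce="mean")
        on = fit_multimer(table, dimer, 2, chi.position, scale=True)
        off = fit_multimer(table, dimer, 2, chi.position, scale=False)
        np.testing.assert_allclose(
            from_parameters(off.tensor).matrix,
            from_parameters(on.tensor).matrix / 2.0, rtol=1e-12,
        )

    def test_n1_warns_and_matches_plain_fit(self, structure, truth_chi,
                                            pcs_table):
        with pytest.warns(UserWarning, match="ordinary fit"):
            res = fit_multimer(pcs_table, structure, 1, truth_chi.position)
        plain, _ = svd_fit_pcs(pcs_table, structure, truth_chi.position)
        np.testing.assert_allclose(from_parameters(res.tensor).anisotropy,
                                   plain.anisotropy, rtol=1e-10)


class TestUncertainty:
    @staticmethod
    def refit(position):
        def fn(table, ensemble):
            chi, _ = svd_fit_pcs(table, ensemble, position)
            return to_utr(chi)
        return fn

    def test_montecarlo_zero_noise_zero_spread(self, structure, truth_chi,
                                               pcs_table):
        res = uncertainty(self.refit(truth_chi.position), pcs_table,
                          "montecarlo", repeats=10, noise_scales=0.0,
                          seed=1, ensemble=structure)
        # all repeats are identical; the spread is zero up to the 1-ulp
        # rounding of the mean inside the std computation
        assert res.std["axial"] < 1e-12 * abs(res.tensors[0].axial)
        assert res.std["rhombic"] < 1e-12 * abs(res.tensors[0].axial)

    def test_montecarlo_spread_monotone_in_noise(self, structure, truth_chi,
                                                 pcs_table):
        spreads = []
        for scale in (0.01, 0.05, 0.1):
            res = uncertainty(self.refit(truth_chi.position), pcs_table,
                              "montecarlo", repeats=40, noise_scales=scale,
                              seed=2, ensemble=structure)
            spreads.append(res.std["axial"])
        assert spreads[0] < spreads[1] < spreads[2]

    def test_bootstrap_fraction_one_degenerate(self, structure, truth_chi,
                                               pcs_table):
        res = uncertainty(self.refit(truth_chi.position), pcs_table,
                          "bootstrap", repeats=5, fraction=1.0, seed=3,
                          ensemble=structure)
        assert res.std["axial"] == pytest.approx(0.0, abs=1e-45)

    def test_structure_method_needs_models(self, structure, truth_chi,
                                           pcs_table):
        with pytest.raises(ValueError, match="multi-model"):
            uncertainty(self.refit(truth_chi.position), pcs_table,
                        "structure", ensemble=structure)

    def test_repeats_too_few_raises(self, structure, truth_chi, pcs_table):
        with pytest.raises(ValueError, match="repeats"):
            uncertainty(self.refit(truth_chi.position), pcs_table,
                        "montecarlo", repeats=1, ensemble=structure)


class TestQFactor:
    def test_perfect_fit_is_zero(self):
        exp = np.array([1.0, -2.0, 3.0])
        assert q_factor(exp, exp) == 0.0
        assert q_factor(exp, exp, variant="clore") == 0.0

    def test_zero_calculation_is_one(self):
        exp = np.array([1.0, -2.0, 3.0])
        assert q_factor(exp, np.zeros(3)) == pytest.approx(1.0, rel=1e-15)

    def test_default_over_clore_ratio_two_in_small_residual_limit(self):
        exp = np.array([1.0, -2.0, 3.0, 0.5])
        for eps in (1e-3, 1e-5, 1e-7):
            calc = exp * (1 + eps)
            ratio = q_factor(exp, calc) / q_factor(exp, calc,
                                                   variant="clore")
            assert ratio == pytest.approx(2.0, rel=10 * eps + 1e-9)

    def test_ensemble_groups_inner_sum(self):
        exp = np.array([1.0, 2.0])
        calc = np.array([[1.0, 2.0], [0.0, 0.0]])  # two models
        # numerator: model 2 misses everything; denominator doubles
        expected = math.sqrt((1 + 4) / (2 * (1 + 4)))
        assert q_factor(exp, calc) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            q_factor(np.zeros(3), np.zeros(3))


class TestRACSInFit:
    def test_fitting_with_racs_improves_racs_generated_data(
            self, ctx, truth_chi):
        ens = make_structure(n_residues=30, seed=19)
        centre = ParamagneticCentre(truth_chi, ctx)
        table = make_observables(ens, centre, "PCS", corrections=("racs",))
        plain_cost = svd_fit_pcs(table, ens, truth_chi.position)[1]
        racs_cost = svd_fit_pcs(table, ens, truth_chi.position,
                                racs=True, ctx=ctx)[1]
        assert racs_cost <= plain_cost
        assert racs_cost < 1e-12
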