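"""Exchange populations, dipolar rates, generator assembly, propagation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from stdepitope import (
    ExchangeModel,
    GeneratorBasis,
    ProtonSet,
    SpinSystem,
    assemble_generator,
    average_equivalent,
    dipolar_rates,
    distance_matrix,
    equilibrium_populations,
    predict_for_structure,
    simulate_std,
)
from stdepitope.relaxation import DIPOLAR_Q, _spectral_density
from conftest import site


def model(**kw):
    base = dict(kd=100e-6, k_off=100.0, p_total=50e-6, l_total=2e-3,
                tau_c_free=0.2, tau_c_bound=15.0, larmor=500.0)
    base.update(kw)
    return ExchangeModel(**base)


class TestEquilibrium:
    def test_weak_binding_limit(self):
        pops = equilibrium_populations(model(kd=1e3))
        assert pops.pl_bound == pytest.approx(0.0, abs=1e-9)

    def test_stoichiometric_limit(self):
        pops = equilibrium_populations(model(kd=1e-12, l_total=5e-3, p_total=50e-6))
        assert pops.pl_bound == pytest.approx(50e-6, rel=1e-6)

    def test_millimolar_kd_against_root_finder(self):
        m = model(kd=1.341e-3, l_total=5e-3, p_total=50e-6)
        pops = equilibrium_populations(m)
        # independent oracle: solve Kd = (P_t - x)(L_t - x)/x numerically
        f = lambda x: (m.p_total - x) * (m.l_total - x) / x - m.kd
        x = brentq(f, 1e-15, min(m.p_total, m.l_total) - 1e-15, xtol=1e-18)
        assert pops.pl_bound == pytest.approx(x, rel=1e-9)
        assert pops.f_bound_ligand == pytest.approx(0.0079, abs=2e-4)

    def test_kd_only_defaults_koff_and_derives_kon(self):
        m = model(kd=100e-6, k_off=None)
        assert m.k_off == 100.0
        assert m.k_on == pytest.approx(1e6)
        m2 = ExchangeModel(k_on=1e6, k_off=50.0, p_total=50e-6, l_total=2e-3,
                           tau_c_free=0.2, tau_c_bound=15.0, larmor=500.0)
        assert m2.kd == pytest.approx(5e-5)


class TestDipolarRates:
    def test_r_minus_six_law(self):
        d1 = np.array([[0.0, 2.0], [2.0, 0.0]])
        s1, _ = dipolar_rates(d1, 10.0, 500.0)
        s2, _ = dipolar_rates(2 * d1, 10.0, 500.0)
        assert s1[0, 1] / s2[0, 1] == pytest.approx(64.0, rel=1e-12)

    def test_extreme_narrowing_ratio_and_sign(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        sigma, rho = dipolar_rates(d, 1e-3, 500.0)  # tau_c = 1 ps
        pair = DIPOLAR_Q * (2.5e-10) ** -6
        tau = 1e-12
        rho_pair = pair * 10 * tau  # narrowing: all J -> tau_c
        assert sigma[0, 1] > 0
        assert sigma[0, 1] / rho_pair == pytest.approx(0.5, rel=1e-3)

    def test_spin_diffusion_limit_sigma_negative(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        sigma, _ = dipolar_rates(d, 15.0, 500.0)  # w0*tau_c ~ 47
        assert sigma[0, 1] < 0

    def test_zero_distance_is_an_error(self):
        with pytest.raises(ValueError):
            dipolar_rates(np.zeros((2, 2)), 10.0, 500.0)

    def test_leak_adds_to_auto_rate_only(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        s0, r0 = dipolar_rates(d, 5.0, 500.0, leak_rate=0.0)
        s1, r1 = dipolar_rates(d, 5.0, 500.0, leak_rate=0.7)
        np.testing.assert_allclose(s0, s1)
        np.testing.assert_allclose(r1, r0 + 0.7)


class TestAssembleGenerator:
    def toy_system(self):
        ps = ProtonSet(
            [site("L1", (0, 0, 0), "ligand"), site("P1", (2.5, 0, 0), "protein")]
        )
        return SpinSystem(bound_protons=ps, saturated_ids=frozenset({"P1"}))

    def test_hand_assembled_three_by_three(self, toy_model):
        sys_ = self.toy_system()
        D, basis = assemble_generator(sys_, toy_model)
        pops = equilibrium_populations(toy_model)
        sigma, rho = dipolar_rates(
            distance_matrix(sys_.bound_protons), 15.0, 500.0
        )
        k_bf = toy_model.k_off
        k_fb = toy_model.k_on * pops.p_free
        expected = np.array(
            [
                [rho[0] + k_bf, sigma[0, 1], -k_bf],
                [sigma[1, 0], rho[1], 0.0],
                [-k_fb, 0.0, k_fb],  # single free proton: leak=0 auto rate
            ]
        )
        np.testing.assert_allclose(D, expected, rtol=1e-12)
        assert basis.labels == (("L1", "bound"), ("P1", "bound"), ("L1", "free"))

    def test_zero_koff_decouples_blocks(self):
        D, _ = assemble_generator(self.toy_system(), model(k_off=0.0))
        assert np.all(D[:2, 2:] == 0) and np.all(D[2:, :2] == 0)

    def test_detailed_balance_of_exchange_fluxes(self, toy_model):
        _, basis = assemble_generator(self.toy_system(), toy_model)
        pops = equilibrium_populations(toy_model)
        flux_bf = pops.f_bound_ligand * toy_model.k_off
        flux_fb = (1 - pops.f_bound_ligand) * toy_model.k_on * pops.p_free
        assert flux_bf == pytest.approx(flux_fb, rel=1e-10)
        assert basis.f_bound == pytest.approx(pops.f_bound_ligand)

    def test_no_ligand_protons_is_an_error(self, toy_model):
        ps = ProtonSet([site("P1", (0, 0, 0), "protein")])
        with pytest.raises(ValueError, match="ligand"):
            assemble_generator(SpinSystem(ps, frozenset({"P1"})), toy_model)

    def test_saturating_a_ligand_proton_is_an_error(self):
        ps = ProtonSet([site("L1", (0, 0, 0), "ligand")])
        with pytest.raises(ValueError, match="not protein"):
            SpinSystem(bound_protons=ps, saturated_ids=frozenset({"L1"}))


class TestSimulateStd:
    def test_zero_time_and_empty_saturated_set(self, two_spin_pair, toy_model):
        ps, basis = two_spin_pair
        sigma, rho = dipolar_rates(distance_matrix(ps), 15.0, 500.0)
        D = sigma.copy()
        np.fill_diagonal(D, rho)
        pred = simulate_std(D, basis, {"P1"}, [0.0, 1.0, 4.0])
        assert pred.values.iloc[0, 0] == 0.0
        assert pred.values.iloc[0, -1] > 0
        empty = simulate_std(D, basis, set(), [0.0, 1.0, 4.0])
        assert np.all(empty.values.to_numpy() == 0.0)

    def test_bounded_and_monotone_two_spin(self, two_spin_pair):
        ps, basis = two_spin_pair
        sigma, rho = dipolar_rates(distance_matrix(ps), 15.0, 500.0)
        D = sigma.copy()
        np.fill_diagonal(D, rho)
        t = np.linspace(0, 10, 200)
        pred = simulate_std(D, basis, {"P1"}, t)
        s = pred.values.to_numpy().ravel()
        assert np.all(s >= -1e-12) and np.all(s <= 100 + 1e-12)
        assert np.all(np.diff(s) >= -1e-10)


class TestPipeline:
    def toy_complex(self):
        return ProtonSet(
            [
                site("L1", (0, 0, 0), "ligand"),
                site("L2", (2.5, 0, 0), "ligand"),
                site("P1", (-2.5, 0, 0), "protein", shift=0.8),
                site("P2", (-5.0, 0.3, 0), "protein", shift=0.9),
                site("HN", (-4.0, 2.0, 0), "protein", exchangeable=True, shift=8.1),
            ]
        )

    def test_pipeline_matches_manual_stage_composition(self, toy_model):
        from stdepitope import (assign_saturated_set, filter_exchangeable,
                                select_binding_site)

        ps = self.toy_complex()
        pred = predict_for_structure(ps, toy_model, cutoff=50.0, t_sats=[0.5, 2.0])
        manual = filter_exchangeable(ps)
        manual = select_binding_site(manual, 50.0)
        sat = assign_saturated_set(manual)
        D, basis = assemble_generator(SpinSystem(manual, frozenset(sat)), toy_model)
        expected = simulate_std(D, basis, sat, [0.5, 2.0])
        np.testing.assert_allclose(
            pred.values.to_numpy(), expected.values.to_numpy(), rtol=1e-12
        )
        assert pred.metadata["n_saturated"] == 2  # exchangeable HN excluded

    def test_cutoff_excluding_all_protein_protons_is_an_error(self, toy_model):
        with pytest.raises(ValueError, match="no saturated protein"):
            predict_for_structure(self.toy_complex(), toy_model, cutoff=1.0)

    def test_geometry_doubling_scales_initial_slope_by_64(self, toy_model):
        # two-spin complex; S'(0) = -100 f_b sigma, and sigma ~ r^-6
        def slope(scale):
            ps = ProtonSet(
                [
                    site("L1", (0, 0, 0), "ligand"),
                    site("P1", (scale * 2.5, 0, 0), "protein", shift=0.8),
                ]
            )
            t0 = 1e-5
            pred = predict_for_structure(ps, toy_model, cutoff=1e4, t_sats=[t0])
            return pred.values.iloc[0, 0] / t0

        assert slope(1.0) / slope(2.0) == pytest.approx(64.0, rel=1e-3)

    def test_equivalence_group_averaging(self, toy_model):
        pred = predict_for_structure(self.toy_complex(), toy_model,
                                     cutoff=50.0, t_sats=[1.0, 2.0])
        avg = average_equivalent(pred, {"Lmean": ["L1", "L2"]})
        np.testing.assert_allclose(
            avg.values.loc["Lmean"],
            pred.values.loc[["L1", "L2"]].mean(axis=0),
        )
        with pytest.raises(KeyError):
            average_equivalent(pred, {"g": ["L1", "NOPE"]})
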