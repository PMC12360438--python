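"""Cancer / immune / vascular population dynamics and oxygen balance."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sonomech._radial import RadialGrid
from sonomech.tme_dynamics import (HOST_OXYGEN, AngiogenicFactors,
                                   CellPopulations, GrowthParams, cancer_rhs,
                                   effector_activity, hypoxia_percent,
                                   immune_rhs, oxygen_rhs, solve_oxygen,
                                   tam_polarization, vascular_rhs)

N = 8


def pops(**kw):
    return CellPopulations.uniform(N, kw)


def host_ox():
    return np.full(N, HOST_OXYGEN)


class TestCancer:
    def test_extinction_fixed_point(self):
        p = pops()
        out = cancer_rhs(p, host_ox(), np.zeros(N), GrowthParams())
        for d in out:
            assert np.allclose(d, 0.0)

    def test_anoxia_stops_proliferation(self):
        p = pops(cc=0.4, scc=0.1)
        params = GrowthParams(scc_differentiation=0.0)
        d_cc, d_scc, d_icc, growth = cancer_rhs(p, np.zeros(N), np.zeros(N),
                                                params)
        assert np.allclose(d_cc, 0.0)
        assert np.allclose(d_scc, 0.0)
        assert np.allclose(growth, 0.0)

    def test_density_matches_closed_form_logistic(self):
        """A single population with no drug or immune pressure follows
        the logistic closed form."""
        params = GrowthParams(scc_differentiation=0.0)
        r = params.k_1 * HOST_OXYGEN
        c0 = 0.05

        def rhs(t, y):
            p = pops(cc=y[0])
            return [cancer_rhs(p, host_ox(), np.zeros(N), params)[0][0]]

        sol = solve_ivp(rhs, (0.0, 400.0), [c0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        for t in (50.0, 150.0, 400.0):
            exact = c0 * np.exp(r * t) / (1.0 + c0 * (np.exp(r * t) - 1.0))
            assert sol.sol(t)[0] == pytest.approx(exact, rel=1e-6)

    def test_interconversions_conserve_cells(self):
        """SCC->CC differentiation and CC->ICC conversion move cells
        between compartments without changing the total."""
        params = GrowthParams(k_1=0.0, drug_kill=0.0, immune_kill=0.0,
                              icc_death=0.0)
        p = pops(cc=0.3, scc=0.2, icc=0.1)
        d_cc, d_scc, d_icc, growth = cancer_rhs(p, host_ox(),
                                                np.full(N, 0.5), params)
        assert np.allclose(d_cc + d_scc + d_icc, 0.0, atol=1e-14)
        assert np.allclose(growth, 0.0, atol=1e-14)

    def test_drug_kill_reduces_growth(self):
        params = GrowthParams()
        p = pops(cc=0.5)
        *_, g_clean = cancer_rhs(p, host_ox(), np.zeros(N), params)
        *_, g_drug = cancer_rhs(p, host_ox(), np.full(N, 0.5), params)
        assert (g_drug < g_clean).all()


class TestImmune:
    params = GrowthParams()

    def test_source_death_steady_state(self):
        """With full oxygenation and baselines, the analytic sigma/m
        fixed point has zero derivatives."""
        pr = self.params
        p = pops(nk=pr.sigma_nk / pr.m_nk, t8=pr.sigma_t8 / pr.m_t8,
                 t4=pr.sigma_t4 / pr.m_t4, treg=pr.sigma_treg / pr.m_reg,
                 tam_m1=pr.sigma_m1 / pr.m_tam, tam_m2=pr.sigma_m2 / pr.m_tam)
        # zero polarization drive isolates the source/death balance
        params = GrowthParams(polarization_rate=0.0)
        out = immune_rhs(p, host_ox(), pr.sigma_t8, pr.m_reg, np.zeros(N),
                         np.zeros(N), params)
        for d in out:
            assert np.allclose(d, 0.0, atol=1e-14)

    def test_anti_pd1_strictly_raises_t8_derivative(self):
        p = pops(t8=0.02)
        base = immune_rhs(p, host_ox(), self.params.sigma_t8,
                          self.params.m_reg, np.zeros(N), np.zeros(N),
                          self.params)[1]
        boosted = immune_rhs(p, host_ox(), 3.0 * self.params.sigma_t8,
                             self.params.m_reg, np.zeros(N), np.zeros(N),
                             self.params)[1]
        assert (boosted > base).all()

    def test_doubled_treg_mortality_halves_steady_state(self):
        pr = self.params
        # linear balance: sigma = m * treg_ss
        treg_ss = pr.sigma_treg / pr.m_reg
        d = immune_rhs(pops(treg=treg_ss / 2.0), host_ox(), pr.sigma_t8,
                       2.0 * pr.m_reg, np.zeros(N), np.zeros(N), pr)[3]
        assert np.allclose(d, 0.0, atol=1e-14)

    def test_baseline_activity_is_the_healthy_polarized_fixed_point(self):
        """The kill threshold equals the effector activity of the
        oxygenated, VEGF-free steady state, so the healthy set point
        itself generates no kill."""
        pr = self.params
        pol0 = pr.polarization_rate * (1.0 - pr.polarization_oxygen_threshold)
        m2_0 = pr.sigma_m2 / (pr.m_tam + pol0)
        m1_0 = (pr.sigma_m1 + pol0 * m2_0) / pr.m_tam
        p = pops(nk=pr.sigma_nk / pr.m_nk, t8=pr.sigma_t8 / pr.m_t8,
                 t4=pr.sigma_t4 / pr.m_t4, treg=pr.sigma_treg / pr.m_reg,
                 tam_m1=m1_0, tam_m2=m2_0)
        act = effector_activity(p, pr)
        assert np.allclose(act, pr.baseline_activity(), atol=1e-14)
        # and this state is stationary for the immune subsystem
        out = immune_rhs(p, host_ox(), pr.sigma_t8, pr.m_reg, np.zeros(N),
                         np.zeros(N), pr)
        for d in out:
            assert np.allclose(d, 0.0, atol=1e-12)


class TestPolarization:
    params = GrowthParams()

    def test_hypoxia_and_vegf_push_toward_m2(self):
        p = pops(tam_m1=0.1, tam_m2=0.1)
        flux = tam_polarization(np.zeros(N), np.full(N, 2.0), p, self.params)
        assert (flux < 0.0).all()

    def test_oxygen_pushes_toward_m1(self):
        p = pops(tam_m1=0.1, tam_m2=0.1)
        flux = tam_polarization(host_ox(), np.zeros(N), p, self.params)
        assert (flux > 0.0).all()

    def test_pure_polarization_conserves_tams(self):
        p = pops(tam_m1=0.07, tam_m2=0.21)
        params = GrowthParams(sigma_m1=0.0, sigma_m2=0.0, m_tam=0.0)
        out = immune_rhs(p, host_ox(), params.sigma_t8, params.m_reg,
                         np.zeros(N), np.full(N, 0.5), params)
        d_m1, d_m2 = out[4], out[5]
        assert np.allclose(d_m1 + d_m2, 0.0, atol=1e-12)


class TestVascular:
    params = GrowthParams()

    def factors(self, vegf=0.3, ang1=0.5, ang2=0.1):
        return AngiogenicFactors(np.full(N, vegf), np.full(N, ang1),
                                 np.full(N, ang2))

    def test_neutral_sono_factors_reproduce_baseline(self):
        p = pops(endo=0.4, cc=0.5)
        base = vascular_rhs(p, self.factors(), (1.0, 1.0), host_ox() / 2,
                            self.params)
        again = vascular_rhs(p, self.factors(), (1.0, 1.0), host_ox() / 2,
                             self.params)
        assert np.allclose(base[0], again[0])

    def test_no_vegf_and_ang2_dominance_stall_proliferation(self):
        p = pops(endo=0.4)
        d_endo = vascular_rhs(p, self.factors(vegf=0.0, ang1=1e-6, ang2=5.0),
                              (1.0, 0.0), host_ox(), self.params)[0]
        assert np.allclose(d_endo, 0.0, atol=1e-6)

    def test_proliferation_linear_in_sono_factor(self):
        p = pops(endo=0.4, cc=0.5)
        d1 = vascular_rhs(p, self.factors(), (1.0, 0.0), host_ox() / 2,
                          self.params)[0]
        d2 = vascular_rhs(p, self.factors(), (2.0, 0.0), host_ox() / 2,
                          self.params)[0]
        assert np.allclose(d2, 2.0 * d1, rtol=1e-12)

    def test_hypoxia_drives_vegf_and_ang2(self):
        p = pops(endo=0.4, cc=0.5)
        hypoxic = vascular_rhs(p, self.factors(vegf=0.0, ang2=0.0),
                               (1.0, 1.0), np.zeros(N), self.params)
        normoxic = vascular_rhs(p, self.factors(vegf=0.0, ang2=0.0),
                                (1.0, 1.0), host_ox(), self.params)
        assert (hypoxic[1] > normoxic[1]).all()   # VEGF production
        assert (hypoxic[3] > normoxic[3]).all()   # Ang2 production


class TestOxygen:
    grid = RadialGrid(64)
    params = GrowthParams()

    def test_no_cells_equilibrates_at_host_reference(self):
        c = solve_oxygen(self.grid, 3.0, np.full(64, 5.0),
                         CellPopulations.uniform(64, {}), self.params)
        assert np.allclose(c, HOST_OXYGEN, rtol=1e-10)

    def test_pure_sink_decays(self):
        p = CellPopulations.uniform(64, {"cc": 0.8})
        rhs = oxygen_rhs(self.grid, 3.0, np.full(64, 0.1), np.zeros(64), p,
                         self.params)
        assert (rhs[:-1] < 0.0).all()

    def test_single_node_algebraic_balance(self):
        """With negligible diffusion the supply/consumption balance
        reduces to c = c_host * S / (S + A) per node."""
        p = CellPopulations.uniform(16, {"cc": 0.6})
        grid = RadialGrid(16)
        params = GrowthParams(oxygen_diffusivity=1e-12)
        c = solve_oxygen(grid, 3.0, np.full(16, 2.0), p, params)
        supply = params.oxygen_wall_permeability * 2.0
        consume = params.oxygen_consumption * 0.6
        expected = HOST_OXYGEN * supply / (supply + consume)
        assert np.allclose(c[:-1], expected, rtol=1e-10)

    def test_quasi_static_solution_zeroes_the_dynamic_rhs(self):
        p = CellPopulations.uniform(64, {"cc": 0.5, "scc": 0.05})
        sv = np.linspace(1.0, 4.0, 64)
        c = solve_oxygen(self.grid, 3.0, sv, p, self.params)
        rhs = oxygen_rhs(self.grid, 3.0, c, sv, p, self.params)
        scale = self.params.oxygen_consumption * HOST_OXYGEN
        assert np.max(np.abs(rhs)) / scale < 1e-10


@pytest.mark.parametrize("c,expected", [
    (0.2, 0.0), (0.0, 100.0), (0.1, 50.0)])
def test_hypoxia_percent(c, expected):
    assert hypoxia_percent(c) == pytest.approx(expected)


def test_hypoxia_percent_clamps_above_reference():
    assert hypoxia_percent(0.25) == 0.0
    with pytest.raises(ValueError):
        hypoxia_percent(-0.01)
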