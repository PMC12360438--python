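"""Plasma kinetics, hindered pore transport, Starling exchange and the
three-state nanomedicine transport chain."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sonomech._radial import RadialGrid
from sonomech.drug_transport import (DrugFields, DrugSpecies, ICIParams,
                                     VesselWall, hindrance_coefficients,
                                     ici_pharmacodynamics,
                                     plasma_concentration, starling_flux,
                                     transport_rhs, wall_coefficients)


@pytest.mark.parametrize("t,expected", [
    (5.0, 1.0),                      # bolus peak at injection
    (5.0 + 24.0, np.exp(-1.0)),      # one decay constant later
    (4.99, 0.0),                     # pre-injection
])
def test_plasma_bolus(t, expected):
    assert plasma_concentration(t, 5.0, 24.0) == pytest.approx(expected)


def test_plasma_superposition_and_ceiling():
    t0 = [0.0, 1.0]
    val = plasma_concentration(1.0, t0, 24.0, ceiling=2.0)
    assert val == pytest.approx(np.exp(-1.0 / 24.0) + 1.0)
    assert plasma_concentration(1.0, [0.0, 0.5, 1.0], 1e6, ceiling=2.0) == 2.0
    with pytest.raises(ValueError):
        plasma_concentration(0.0, 0.0, 0.0)


class TestHindrance:
    def test_point_solute(self):
        h, sigma, phi = hindrance_coefficients(0.0)
        assert (h, sigma, phi) == pytest.approx((1.0, 0.0, 1.0))

    def test_excluded_solute(self):
        h, sigma, phi = hindrance_coefficients(1.0)
        assert (h, sigma, phi) == pytest.approx((0.0, 1.0, 0.0))

    def test_against_straight_line_oracle(self):
        # independent plain-arithmetic rendering of the same published
        # closure polynomials
        for lam in (0.1, 0.25, 0.5, 0.75, 0.9):
            phi = (1 - lam) * (1 - lam)
            h_oracle = phi * (1 - 2.104 * lam + 2.089 * lam * lam * lam
                              - 0.948 * lam**5)
            g = 1 - 2.0 / 3.0 * lam * lam - 0.163 * lam**3
            sigma_oracle = 1 - (1 - (1 - phi) ** 2) * g
            h, sigma, phi_out = hindrance_coefficients(lam)
            assert h == pytest.approx(h_oracle, abs=1e-12)
            assert sigma == pytest.approx(sigma_oracle, abs=1e-12)
            assert phi_out == pytest.approx(phi, abs=1e-12)

    def test_monotonicity_on_fine_grid(self):
        lams = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        vals = np.array([hindrance_coefficients(l) for l in lams])
        h, sigma = vals[:, 0], vals[:, 1]
        assert (np.diff(h) < 0.0).all()
        assert (np.diff(sigma) > 0.0).all()
        assert ((vals >= 0.0) & (vals <= 1.0)).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hindrance_coefficients(1.2)


def _species(name="probe", radius=10.0, **kw):
    return DrugSpecies(name=name, molecular_radius=radius, diffusivity=1.0,
                       **kw)


def _wall(pore=100.0):
    return VesselWall(pore_radius=pore, hydraulic_conductivity_wall=1e-3,
                      vascular_pressure=2000.0, base_pore_radius=100.0,
                      permeability_scale=0.3)


class TestWallCoefficients:
    def test_identity_at_baseline(self):
        sp = _species()
        base = wall_coefficients(100.0, [sp], _wall())
        again = wall_coefficients(100.0, [sp], base)
        assert again.permeability[sp.name] == base.permeability[sp.name]
        assert again.reflection[sp.name] == base.reflection[sp.name]
        assert again.effective_hydraulic_conductivity == pytest.approx(
            base.hydraulic_conductivity_wall)

    def test_poiseuille_lp_scaling(self):
        w = wall_coefficients(200.0, [_species()], _wall())
        assert w.effective_hydraulic_conductivity == pytest.approx(
            4.0 * w.hydraulic_conductivity_wall)

    def test_wide_pore_limit(self):
        sp = _species(radius=5.0)
        w = wall_coefficients(100.0 * sp.molecular_radius, [sp], _wall())
        assert w.reflection[sp.name] < 0.01

    def test_dilation_monotonicity(self):
        sp = _species(radius=50.0)
        pores = np.linspace(100.0, 1250.0, 24)
        perm = [wall_coefficients(r, [sp], _wall()).permeability[sp.name]
                for r in pores]
        refl = [wall_coefficients(r, [sp], _wall()).reflection[sp.name]
                for r in pores]
        assert (np.diff(perm) >= 0.0).all()
        assert (np.diff(refl) <= 0.0).all()

    def test_size_selectivity(self):
        small, big = _species("small", 5.0), _species("big", 50.0)
        w = wall_coefficients(100.0, [small, big], _wall())
        assert w.permeability["small"] >= w.permeability["big"]
        assert w.reflection["small"] <= w.reflection["big"]

    def test_sub_baseline_pore_clamped(self):
        w = wall_coefficients(10.0, [_species()], _wall())
        assert w.pore_radius == 100.0


@pytest.mark.parametrize("kw,expected", [
    (dict(p_er=1.0, sv=1.0, c_iv=0.3, c=0.3, l_p=1.0, p_v=500.0, p_i=500.0,
          sigma_f=0.2), 0.0),          # no gradients
    (dict(p_er=1.0, sv=1.0, c_iv=0.3, c=0.3, l_p=1.0, p_v=900.0, p_i=100.0,
          sigma_f=1.0), 0.0),          # fully reflected convection
    (dict(p_er=1.0, sv=2.0, c_iv=1.0, c=0.0, l_p=0.0, p_v=0.0, p_i=0.0,
          sigma_f=0.0), 2.0),          # diffusive term alone
])
def test_starling_flux_cases(kw, expected):
    assert starling_flux(**kw) == pytest.approx(expected)


def test_starling_convection_is_a_source_below_vascular_pressure():
    # p_i < P_V drives filtration into the tissue
    assert starling_flux(0.0, 1.0, 1.0, 0.0, 1e-3, 2000.0, 500.0, 0.5) > 0.0


# ---------------------------------------------------------------------------
# transport right-hand side
# ---------------------------------------------------------------------------

def _system(n=5, radius=2.0, sv=0.0):
    grid = RadialGrid(n)
    carrier = DrugSpecies(name="carrier", molecular_radius=50.0,
                          diffusivity=3e-4, release_rate=0.1,
                          internalization_rate=1.0, payload_count=3.0,
                          plasma_decay=24.0, injection_times=(0.0,),
                          wall_diffusivity=0.014)
    antibody = DrugSpecies(name="ab", molecular_radius=5.0, diffusivity=0.036,
                           degradation_rate=0.03, plasma_decay=72.0,
                           injection_times=(0.0,), wall_diffusivity=0.14)
    wall = wall_coefficients(100.0, [carrier, antibody], VesselWall(
        pore_radius=100.0, hydraulic_conductivity_wall=2.5e-5,
        vascular_pressure=2000.0, base_pore_radius=100.0,
        permeability_scale=0.3))
    kw = dict(grid=grid, radius=radius, nanocarrier=carrier, antibody=antibody,
              free_diffusivity=1.08, free_degradation=0.05, wall=wall,
              sv=np.full(n, sv), p_i=np.zeros(n), v_f=np.zeros(n),
              v_s=np.zeros(n), t=1.0)
    return grid, kw


def test_empty_system_is_a_fixed_point():
    grid, kw = _system()
    kw["t"] = -1.0  # before the injection: no plasma drug anywhere
    out = transport_rhs(fields=DrugFields.zeros(grid.n), **kw)
    assert np.allclose(out.stack(), 0.0)


def test_uniform_carrier_without_vessels_or_release_is_stationary():
    grid, kw = _system()
    kw["nanocarrier"] = DrugSpecies(
        name="carrier", molecular_radius=50.0, diffusivity=3e-4,
        release_rate=0.0, internalization_rate=0.0, plasma_decay=24.0,
        wall_diffusivity=0.014)
    kw["wall"] = wall_coefficients(
        100.0, [kw["nanocarrier"], kw["antibody"]], kw["wall"])
    fields = DrugFields.zeros(grid.n)
    fields.c_n[:] = 0.7
    out = transport_rhs(fields=fields, **kw)
    assert np.allclose(out.c_n, 0.0, atol=1e-14)


def test_rhs_matches_handwritten_finite_difference_oracle():
    """Loop-and-scalar re-derivation of the same finite-volume scheme."""
    grid, kw = _system(n=5, sv=1.5)
    rng = np.random.default_rng(3)
    fields = DrugFields(*rng.uniform(0.0, 1.0, size=(4, 5)))
    out = transport_rhs(fields=fields, **kw)

    carrier, antibody, wall = kw["nanocarrier"], kw["antibody"], kw["wall"]
    n, R = 5, kw["radius"]
    x = np.linspace(0.0, 1.0, n)
    dx = x[1] - x[0]
    dr = dx * R
    xf = np.array([0.0, *(0.5 * (x[:-1] + x[1:])), 1.0])
    vol = np.diff(xf**3) / 3.0

    def lap(c, d):
        out = np.zeros(n)
        for i in range(n):
            fr = d * (c[i + 1] - c[i]) / dr * xf[i + 1] ** 2 if i < n - 1 else 0.0
            fl = d * (c[i] - c[i - 1]) / dr * xf[i] ** 2 if i > 0 else 0.0
            out[i] = (fr - fl) / (vol[i] * R)
        return out

    c_iv = np.exp(-(kw["t"] - 0.0) / carrier.plasma_decay)
    c_iv_i = np.exp(-(kw["t"] - 0.0) / antibody.plasma_decay)
    sv = kw["sv"]
    q_n = (wall.permeability["carrier"] * sv * (c_iv - fields.c_n)
           + wall.effective_hydraulic_conductivity * sv
           * (wall.vascular_pressure - kw["p_i"])
           * (1 - wall.reflection["carrier"]) * c_iv)
    q_i = (wall.permeability["ab"] * sv * (c_iv_i - fields.c_f_i)
           + wall.effective_hydraulic_conductivity * sv
           * (wall.vascular_pressure - kw["p_i"])
           * (1 - wall.reflection["ab"]) * c_iv_i)

    exp_n = (lap(fields.c_n, carrier.diffusivity) + q_n
             - carrier.release_rate * fields.c_n)
    exp_f = (lap(fields.c_f, kw["free_diffusivity"])
             + carrier.payload_count * carrier.release_rate * fields.c_n
             - carrier.internalization_rate * fields.c_f)
    exp_int = (carrier.internalization_rate * fields.c_f
               - kw["free_degradation"] * fields.c_int)
    exp_fi = (lap(fields.c_f_i, antibody.diffusivity) + q_i
              - antibody.degradation_rate * fields.c_f_i)

    assert np.allclose(out.c_n, exp_n, atol=1e-10)
    assert np.allclose(out.c_f, exp_f, atol=1e-10)
    assert np.allclose(out.c_int, exp_int, atol=1e-10)
    assert np.allclose(out.c_f_i, exp_fi, atol=1e-10)


def test_closed_system_mass_balance_short():
    """With no vessels and zero-flux walls, alpha*c_n + c_f + c_int is
    lost only through degradation of the internalized pool."""
    grid, kw = _system(n=12, sv=0.0)
    rng = np.random.default_rng(5)
    y0 = np.concatenate([np.abs(rng.uniform(0.1, 1.0, size=4 * grid.n)),
                         [0.0]])  # last state: cumulative degraded mass
    vol = grid.cell_volumes()
    alpha = kw["nanocarrier"].payload_count
    k_deg = kw["free_degradation"]

    def rhs(t, y):
        f = DrugFields.unstack(y[:-1])
        d = transport_rhs(fields=f, **{**kw, "t": t})
        return np.concatenate([d.stack(), [k_deg * (vol @ f.c_int)]])

    sol = solve_ivp(rhs, (0.0, 6.0), y0, method="BDF", rtol=1e-11, atol=1e-14)
    assert sol.success

    def balance(y):
        f = DrugFields.unstack(y[:-1])
        return vol @ (alpha * f.c_n + f.c_f + f.c_int) + y[-1]

    b0, b1 = balance(y0), balance(sol.y[:, -1])
    assert abs(b1 - b0) / b0 < 1e-8


# ---------------------------------------------------------------------------


class TestICIPharmacodynamics:
    params = ICIParams(pd1_max_boost=2.0, pd1_half_conc=0.3,
                       ctla4_mortality_boost=1.5)

    def test_no_drug_no_effect(self):
        s, m = ici_pharmacodynamics(0.0, 3e-4, 0.02, self.params, False)
        assert s == pytest.approx(3e-4)
        assert m == pytest.approx(0.02)

    def test_saturation_limit(self):
        s, _ = ici_pharmacodynamics(1e9, 1.0, 0.02, self.params, False)
        assert s == pytest.approx(1.0 + self.params.pd1_max_boost, rel=1e-6)

    def test_half_saturation(self):
        s, _ = ici_pharmacodynamics(self.params.pd1_half_conc, 1.0, 0.02,
                                    self.params, False)
        assert s == pytest.approx(1.0 + self.params.pd1_max_boost / 2.0)

    def test_ctla4_window_raises_treg_mortality(self):
        _, m = ici_pharmacodynamics(0.0, 1.0, 0.02, self.params, True)
        assert m == pytest.approx(0.02 * 2.5)
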