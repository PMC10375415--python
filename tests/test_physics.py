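"""Stopping power, CSDA ranges, Rutherford cross-section and angle sampling,
and Highland multiple scattering, checked against independently coded
closed forms and brute-force numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from protonrv import physics as ph
from protonrv.materials import CONSTANTS, Material


# -- independent transcriptions used as oracles ---------------------------

def bethe_bloch_oracle(E, rho, Z, A, I_ev):
    """Separate transcription of the Bethe-Bloch stopping power (MeV/cm)."""
    me = 0.51099895
    mp = 938.27208816
    gamma = 1.0 + E / mp
    beta2 = 1.0 - gamma**-2
    I = I_ev * 1e-6
    return 0.307075 * rho * (Z / A) / beta2 * (math.log(2 * me * beta2 * gamma**2 / I) - beta2)


def highland_oracle(E, step_cm, X0_cm):
    mp = 938.27208816
    pc = math.sqrt(E * (E + 2 * mp))
    beta = pc / (E + mp)
    t = step_cm / X0_cm
    return 13.6 / (beta * pc) * math.sqrt(t) * (1 + 0.038 * math.log(t))


class TestStoppingPower:
    def test_monotone_decreasing_in_energy(self, water):
        E = np.linspace(10, 250, 49)
        S = ph.stopping_power(E, water)
        assert np.all(np.diff(S) < 0)
        assert ph.stopping_power(200.0, water) < ph.stopping_power(100.0, water)

    def test_density_linearity(self, water):
        doubled = water.with_density(2.0)
        assert ph.stopping_power(150.0, doubled) == pytest.approx(
            2.0 * ph.stopping_power(150.0, water), rel=1e-12
        )

    def test_matches_independent_transcription(self, water):
        got = ph.stopping_power(150.0, water)
        want = bethe_bloch_oracle(150.0, water.density, water.Z, water.A, water.I)
        assert got == pytest.approx(want, rel=1e-12)

    def test_water_reference_value(self, water):
        # tabulated electronic stopping power of water at 150 MeV is ~5.44 MeV/cm
        assert ph.stopping_power(150.0, water) == pytest.approx(5.44, rel=0.02)

    def test_rejects_nonpositive_energy(self, water):
        with pytest.raises(ValueError):
            ph.stopping_power(0.0, water)
        with pytest.raises(ValueError):
            ph.stopping_power(-5.0, water)


class TestCsdaRange:
    def test_monotone_in_energy(self, water):
        assert ph.csda_range(200.0, water) > ph.csda_range(100.0, water)
        assert ph.csda_range(2 * 80.0, water) > ph.csda_range(80.0, water)

    def test_density_halves_range(self, water):
        doubled = water.with_density(2.0)
        assert ph.csda_range(150.0, water) == pytest.approx(
            2.0 * ph.csda_range(150.0, doubled), rel=1e-9
        )

    def test_against_fine_trapezoid(self, water):
        E_cut = 1.0
        grid = np.linspace(E_cut, 200.0, 200_001)
        oracle = np.trapezoid(1.0 / ph.stopping_power(grid, water), grid)
        assert ph.csda_range(200.0, water) == pytest.approx(oracle, rel=0.01)

    def test_water_reference_value(self, water):
        # CSDA range of 200 MeV protons in water is ~26 cm
        assert ph.csda_range(200.0, water) == pytest.approx(26.0, rel=0.02)

    def test_supports_distinct_bragg_depths(self, water):
        assert ph.csda_range(180.0, water) > ph.csda_range(120.0, water)
        assert ph.csda_range(220.0, water) > ph.csda_range(120.0, water)


class TestRutherfordDcs:
    @pytest.mark.parametrize("E,Z,theta", [(100.0, 8.0, 0.5), (37.0, 13.0, 1.1), (220.0, 82.0, 2.2)])
    def test_energy_scaling(self, E, Z, theta):
        assert ph.rutherford_dcs(E, Z, theta) == pytest.approx(
            4.0 * ph.rutherford_dcs(2 * E, Z, theta), rel=1e-12
        )

    def test_angle_ratio_90_vs_30_degrees(self):
        r = ph.rutherford_dcs(150.0, 7.42, math.radians(30)) / ph.rutherford_dcs(
            150.0, 7.42, math.radians(90)
        )
        assert r == pytest.approx(16.0, rel=1e-12)

    @pytest.mark.parametrize("Z", [1.0, 7.42, 41.0])
    def test_charge_scaling(self, Z):
        assert ph.rutherford_dcs(150.0, 2 * Z, 0.7) == pytest.approx(
            4.0 * ph.rutherford_dcs(150.0, Z, 0.7), rel=1e-12
        )

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            ph.rutherford_dcs(100.0, 8.0, 0.0)

    def test_decreasing_on_first_quadrant(self):
        th = np.linspace(0.05, math.pi / 2, 100)
        vals = ph.rutherford_dcs(100.0, 8.0, th)
        assert np.all(np.diff(vals) < 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        E=st.floats(1.0, 250.0),
        Z=st.floats(1.0, 92.0),
        theta=st.floats(0.01, math.pi / 2),
    )
    def test_scaling_laws_hold_everywhere(self, E, Z, theta):
        base = ph.rutherford_dcs(E, Z, theta)
        assert ph.rutherford_dcs(2 * E, Z, theta) == pytest.approx(base / 4, rel=1e-9)
        assert ph.rutherford_dcs(E, 2 * Z, theta) == pytest.approx(4 * base, rel=1e-9)
        s4 = math.sin(theta) ** 4
        assert ph.rutherford_dcs(E, Z, theta) * s4 == pytest.approx(
            (Z * 1.43996 / (4 * E)) ** 2, rel=1e-9
        )


class TestScatterSampling:
    THETA_MIN = math.radians(2.0)

    def _analytic_cdf(self, grid, convention):
        lo = grid[0]
        if convention == "sin4theta":
            pdf = lambda t: math.sin(t) / math.sin(t) ** 4
        else:
            pdf = lambda t: math.sin(t) / math.sin(t / 2.0) ** 4
        vals = [0.0]
        for a, b in zip(grid[:-1], grid[1:]):
            vals.append(vals[-1] + integrate.quad(pdf, a, b, limit=100)[0])
        vals = np.array(vals)
        return vals / vals[-1]

    @pytest.mark.parametrize("convention", ["sin4theta", "sin4half"])
    def test_empirical_cdf_matches_quadrature(self, convention, rng):
        n = 100_000
        th = ph.sample_scatter_angles(n, self.THETA_MIN, rng, convention=convention)
        lo, hi = th.min(), th.max()
        assert lo >= self.THETA_MIN
        grid = np.linspace(self.THETA_MIN, {"sin4theta": math.pi - self.THETA_MIN,
                                            "sin4half": math.pi}[convention], 60)
        cdf = self._analytic_cdf(grid, convention)
        emp = np.searchsorted(np.sort(th), grid) / n
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_chi_square_goodness_of_fit(self, rng):
        n = 100_000
        th = ph.sample_scatter_angles(n, self.THETA_MIN, rng)
        edges = np.quantile(th, np.linspace(0, 1, 41))  # ~equal-count bins
        edges[0], edges[-1] = self.THETA_MIN, math.pi - self.THETA_MIN
        cdf = self._analytic_cdf(edges, "sin4theta")
        expected = np.diff(cdf) * n
        observed, _ = np.histogram(th, bins=edges)
        stat = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(stat, df=len(expected) - 1)
        assert p > 0.01

    def test_same_seed_identical_events(self, water):
        e1 = [ph.sample_hard_scatter(150.0, water, self.THETA_MIN, np.random.default_rng(7))
              for _ in range(3)]
        e2 = [ph.sample_hard_scatter(150.0, water, self.THETA_MIN, np.random.default_rng(7))
              for _ in range(3)]
        assert all(a == b for a, b in zip(e1, e2))

    def test_unnormalizable_theta_min_rejected(self, water, rng):
        with pytest.raises(ValueError):
            ph.sample_hard_scatter(150.0, water, 0.0, rng)

    def test_phi_uniform_range(self, water, rng):
        evs = [ph.sample_hard_scatter(100.0, water, self.THETA_MIN, rng) for _ in range(200)]
        phis = np.array([e.phi for e in evs])
        assert np.all((phis >= 0) & (phis < 2 * math.pi))


class TestHighland:
    def test_monotone_in_step(self, water):
        assert ph.highland_sigma(150.0, 2.0, water) > ph.highland_sigma(150.0, 1.0, water)

    def test_monotone_in_energy(self, water):
        assert ph.highland_sigma(300.0, 1.0, water) < ph.highland_sigma(150.0, 1.0, water)

    def test_matches_independent_transcription(self, water):
        got = ph.highland_sigma(200.0, 1.0, water)
        assert got == pytest.approx(highland_oracle(200.0, 1.0, water.radiation_length), rel=1e-9)

    def test_rejects_nonpositive_step(self, water):
        with pytest.raises(ValueError):
            ph.highland_sigma(150.0, 0.0, water)


class TestHardScatterRate:
    def test_calibration_inverts_path_integral(self, water):
        norm = ph.calibrate_hard_scatter_norm(0.005, 200.0, water)

        def de_integrand(e):
            return ph.hard_scatter_rate(e, norm, rho=water.density, Z=water.Z, A=water.A) / \
                ph.stopping_power(e, water)

        total, _ = integrate.quad(de_integrand, 1.0, 200.0, limit=200)
        assert total == pytest.approx(0.005, rel=1e-6)

    def test_energy_and_charge_scaling(self, water):
        r1 = ph.hard_scatter_rate(100.0, 1.0, rho=1.0, Z=10.0, A=20.0)
        assert ph.hard_scatter_rate(200.0, 1.0, rho=1.0, Z=10.0, A=20.0) == pytest.approx(r1 / 4)
        assert ph.hard_scatter_rate(100.0, 1.0, rho=1.0, Z=20.0, A=20.0) == pytest.approx(4 * r1)


class TestMaterialRegistry:
    def test_required_materials_present(self, registry):
        for name in ("water", "air", "hydroxyapatite", "glass", "Pb", "scintillator"):
            assert name in registry
        assert registry["water"].density == 1.0
        assert registry["hydroxyapatite"].density == 3.076
        assert registry["glass"].density == 1.8

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Material("x", -1.0, 7.0, 14.0, 75.0)
        with pytest.raises(ValueError):
            Material("x", 1.0, 7.0, 5.0, 75.0)  # A < Z
        with pytest.raises(ValueError):
            Material("x", 1.0, 0.5, 14.0, 75.0)
        with pytest.raises(ValueError):
            Material("x", 1.0, 7.0, 14.0, 0.0)

    def test_unknown_material_diagnostic(self, registry):
        with pytest.raises(KeyError, match="unknown material"):
            registry["bone"]

    def test_yaml_round_trip(self, registry, tmp_path):
        path = tmp_path / "materials.yaml"
        registry.to_yaml(path)
        back = type(registry).from_yaml(path)
        assert [m for m in back] == [m for m in registry]
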