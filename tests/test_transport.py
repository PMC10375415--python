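"""Monte Carlo transport: CSDA limit, determinism, energy bookkeeping,
Bragg-peak behaviour and current phenomenology."""

import numpy as np
import pytest

from protonrv.beam import BeamSpec, ProtonState, place_detectors_rect
from protonrv.phantom import build_rect_phantom, insert_air_layer, substitute_region
from protonrv.physics import csda_range
from protonrv.transport import (
    TransportConfig,
    depth_dose_profile,
    simulate,
    transport_proton,
)


def _csda_only():
    return TransportConfig(
        straggling=False, multiple_scattering=False, hard_scattering=False
    )


class TestSingleProton:
    def test_stops_at_csda_range(self, small_phantom, water, rng):
        cfg = _csda_only()
        s = ProtonState(np.array([0.0, 50.0, 50.0]), np.array([1.0, 0.0, 0.0]), 120.0)
        deposits, exit_state = transport_proton(s, small_phantom, cfg, rng)
        assert exit_state is None
        last_voxel = deposits[-1][0]
        depth_mm = (last_voxel // (small_phantom.shape[1] * small_phantom.shape[2]) + 0.5) * 5.0
        expect = csda_range(120.0, water) * 10.0
        assert depth_mm == pytest.approx(expect, abs=2 * 5.0)

    def test_deposits_sum_to_initial_energy(self, small_phantom, rng):
        s = ProtonState(np.array([0.0, 50.0, 50.0]), np.array([1.0, 0.0, 0.0]), 120.0)
        deposits, exit_state = transport_proton(s, small_phantom, _csda_only(), rng)
        assert exit_state is None
        assert sum(d for _, d in deposits) == pytest.approx(120.0, rel=1e-9)

    def test_same_seed_identical_trajectory(self, small_phantom):
        cfg = TransportConfig()
        s = ProtonState(np.array([0.0, 50.0, 50.0]), np.array([1.0, 0.0, 0.0]), 120.0)
        t1, _ = transport_proton(s, small_phantom, cfg, np.random.default_rng(5))
        t2, _ = transport_proton(s, small_phantom, cfg, np.random.default_rng(5))
        assert t1 == t2

    def test_non_unit_direction_rejected(self, small_phantom, rng):
        s = ProtonState(np.array([0.0, 50.0, 50.0]), np.array([2.0, 0.0, 0.0]), 120.0)
        with pytest.raises(ValueError):
            transport_proton(s, small_phantom, TransportConfig(), rng)

    def test_high_energy_proton_exits_downstream(self, small_phantom, rng):
        # 200 MeV range (~26 cm) far exceeds the 15 cm block
        s = ProtonState(np.array([0.0, 50.0, 50.0]), np.array([1.0, 0.0, 0.0]), 200.0)
        _, exit_state = transport_proton(s, small_phantom, _csda_only(), rng)
        assert exit_state is not None
        assert exit_state.position[0] >= small_phantom.extent_mm[0]
        assert 0.0 < exit_state.energy < 200.0


class TestSimulate:
    def test_energy_ledger_closes(self, small_phantom):
        det = place_detectors_rect(small_phantom, 12, ("+y", "-y"))
        b = BeamSpec(energy=120.0, n_protons=3000)
        res = simulate(small_phantom, b, det, TransportConfig(), np.random.default_rng(0))
        assert res.ledger["closure"] == pytest.approx(1.0, abs=0.01)
        assert res.n_absorbed + res.n_escaped >= b.n_protons

    def test_doubling_protons_doubles_dose(self, small_phantom):
        cfg = TransportConfig()
        r1 = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=2000), None, cfg,
                      np.random.default_rng(1))
        r2 = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=4000), None, cfg,
                      np.random.default_rng(2))
        assert r2.dose.total / r1.dose.total == pytest.approx(2.0, rel=0.02)

    def test_zero_detectors_valid(self, small_phantom):
        res = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=500), None,
                       TransportConfig(), np.random.default_rng(3))
        assert res.currents.values.shape == (0,)

    def test_bragg_peak_single_downstream_maximum(self, small_phantom):
        res = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=20000), None,
                       TransportConfig(), np.random.default_rng(4))
        prof = depth_dose_profile(res.dose)
        peak = int(np.argmax(prof))
        assert peak > small_phantom.shape[0] // 2  # downstream of the entrance
        # single global maximum: profile rises to the peak then collapses
        assert prof[peak] > 2.0 * prof[0]
        assert prof[peak + 1 :].max() < prof[peak]

    def test_peak_depth_monotone_in_energy(self, small_phantom):
        depths = []
        for E in (90.0, 105.0, 120.0):
            res = simulate(small_phantom, BeamSpec(energy=E, n_protons=10000), None,
                           TransportConfig(), np.random.default_rng(7))
            depths.append(int(np.argmax(depth_dose_profile(res.dose))))
        assert depths[0] < depths[1] < depths[2]

    def test_same_seed_identical_result(self, small_phantom):
        det = place_detectors_rect(small_phantom, 12, ("+y", "-y"))
        b = BeamSpec(energy=120.0, n_protons=2000)
        r1 = simulate(small_phantom, b, det, TransportConfig(), np.random.default_rng(9))
        r2 = simulate(small_phantom, b, det, TransportConfig(), np.random.default_rng(9))
        assert np.array_equal(r1.dose.grid, r2.dose.grid)
        assert np.array_equal(r1.currents.values, r2.currents.values)


class TestPhantomEffects:
    def test_air_layer_plateau_in_depth_profile(self):
        p = build_rect_phantom((15.0, 10.0, 10.0), 5.0)
        pa, rec = insert_air_layer(p, np.random.default_rng(21), thickness_range_cm=(3.0, 4.0))
        res = simulate(pa, BeamSpec(energy=120.0, n_protons=20000), None,
                       TransportConfig(), np.random.default_rng(22))
        prof = depth_dose_profile(res.dose)
        cx = pa.axis_centers(0)
        in_slab = (cx >= rec.x_start_mm) & (cx < rec.x_start_mm + rec.thickness_mm)
        assert in_slab.sum() >= 3
        # air deposits ~1/800 of water per unit length
        assert prof[in_slab].max() < 0.02 * prof[~in_slab].max()

    def test_pb_upstream_shifts_peak_upstream(self, small_phantom):
        box = ((10.0, 30.0), (0.0, 100.0), (0.0, 100.0))
        pb = substitute_region(small_phantom, box, "Pb")
        cfg = TransportConfig()
        r0 = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=10000), None, cfg,
                      np.random.default_rng(31))
        r1 = simulate(pb, BeamSpec(energy=120.0, n_protons=10000), None, cfg,
                      np.random.default_rng(31))
        assert np.argmax(depth_dose_profile(r1.dose)) < np.argmax(depth_dose_profile(r0.dose))

    def test_currents_come_from_upstream_of_peak(self, small_phantom):
        # the scattered-proton signal cuts off near the Bragg depth: detectors
        # far downstream of the peak see (almost) nothing
        det = place_detectors_rect(small_phantom, 15, ("+y", "-y"))
        res = simulate(small_phantom, BeamSpec(energy=100.0, n_protons=30000), det,
                       TransportConfig(), np.random.default_rng(41))
        peak_mm = csda_range(100.0, small_phantom.registry["water"]) * 10.0
        v = res.currents.values.reshape(2, 15).sum(axis=0)
        xs = (np.arange(15) + 0.5) * small_phantom.extent_mm[0] / 15
        upstream = v[xs < peak_mm].sum()
        far_down = v[xs > peak_mm + 20.0].sum()
        assert upstream > 0
        assert far_down < 0.05 * upstream


class TestDepthDoseProfile:
    def test_uniform_grid_constant_profile(self):
        from protonrv.transport import DoseVolume

        g = np.ones((6, 4, 4))
        prof = depth_dose_profile(DoseVolume(g, (1.0, 1.0, 1.0), (0, 0, 0)))
        assert np.allclose(prof, 16.0)

    def test_profile_conserves_total(self, small_phantom):
        res = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=2000), None,
                       TransportConfig(), np.random.default_rng(51))
        assert depth_dose_profile(res.dose).sum() == pytest.approx(res.dose.total)

    def test_transverse_axis_projection(self, rng):
        from protonrv.transport import DoseVolume

        g = rng.random((5, 6, 7))
        assert np.allclose(depth_dose_profile(DoseVolume(g, 1.0, (0, 0, 0)), axis=1),
                           g.sum(axis=(0, 2)))


class TestConfigValidation:
    def test_step_larger_than_half_voxel_rejected(self, small_phantom, rng):
        cfg = TransportConfig(step_mm=4.0)  # voxel is 5 mm
        with pytest.raises(ValueError):
            simulate(small_phantom, BeamSpec(energy=100.0, n_protons=10), None, cfg, rng)

    def test_splitting_off_reproduces_plain_sampling_support(self, small_phantom):
        cfg = TransportConfig(splitting=False)
        res = simulate(small_phantom, BeamSpec(energy=120.0, n_protons=3000), None, cfg,
                       np.random.default_rng(61))
        assert res.ledger["closure"] == pytest.approx(1.0, abs=1e-9)
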