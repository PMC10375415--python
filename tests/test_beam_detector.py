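"""Beam source sampling and detector-array placement rules."""

import numpy as np
import pytest

from protonrv.beam import (
    BeamSpec,
    CurrentReadout,
    place_detectors_cyl,
    place_detectors_rect,
    sample_initial_proton,
    sample_initial_protons,
    select_subset,
)
from protonrv.phantom import build_cylinder_phantom, build_rect_phantom


@pytest.fixture(scope="module")
def rect():
    return build_rect_phantom((30.0, 20.0, 20.0), 5.0)


@pytest.fixture(scope="module")
def cyl():
    p, _ = build_cylinder_phantom(20.0, 40.0, 10.0, np.random.default_rng(0))
    return p


class TestBeamSampling:
    def test_pencil_entry_within_radius(self, rect, rng):
        b = BeamSpec(energy=200.0, width_cm=1.0, n_protons=2000)
        pos, dirs, E = sample_initial_protons(b, rect, rng)
        center_y, center_z = 100.0, 100.0
        r = np.hypot(pos[:, 1] - center_y, pos[:, 2] - center_z)
        assert np.all(r <= 5.0 + 1e-9)
        assert np.all(dirs[:, 0] == 1.0)
        assert np.all(E == 200.0)

    def test_wobbler_zero_radius_degenerates_to_pencil(self, rect):
        b_p = BeamSpec(energy=200.0, mode="pencil", n_protons=500)
        b_w = BeamSpec(energy=200.0, mode="wobbler", wobble_radius_factor=0.0, n_protons=500)
        # wobbler consumes extra phase draws; compare the distributions
        pos_p, _, _ = sample_initial_protons(b_p, rect, np.random.default_rng(1), 5000)
        pos_w, _, _ = sample_initial_protons(b_w, rect, np.random.default_rng(1), 5000)
        r_p = np.hypot(pos_p[:, 1] - 100, pos_p[:, 2] - 100)
        r_w = np.hypot(pos_w[:, 1] - 100, pos_w[:, 2] - 100)
        assert abs(r_p.mean() - r_w.mean()) < 0.15
        assert r_w.max() <= 5.0 + 1e-9

    def test_pencil_mean_entry_near_shifted_center(self, rect):
        b = BeamSpec(energy=200.0, center_shift_cm=(2.0, 0.0), n_protons=10_000)
        pos, _, _ = sample_initial_protons(b, rect, np.random.default_rng(2))
        # uniform disc of radius 5 mm: sigma of the mean = 2.5 mm / sqrt(n)
        tol = 3 * 2.5 / np.sqrt(10_000)
        assert abs(pos[:, 1].mean() - 120.0) < tol
        assert abs(pos[:, 2].mean() - 100.0) < tol

    def test_single_proton_state(self, rect, rng):
        s = sample_initial_proton(BeamSpec(energy=150.0), rect, rng)
        assert s.energy == 150.0
        assert np.allclose(np.linalg.norm(s.direction), 1.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BeamSpec(energy=-1.0)
        with pytest.raises(ValueError):
            BeamSpec(energy=100.0, width_cm=0.0)
        with pytest.raises(ValueError):
            BeamSpec(energy=100.0, mode="scan")


class TestRectArrays:
    def test_two_sides_count(self, rect):
        assert len(place_detectors_rect(rect, 24, ("+y", "-y"))) == 48

    def test_four_sides_count(self, rect):
        assert len(place_detectors_rect(rect, 24, ("+y", "-y", "+z", "-z"))) == 96

    def test_standoff_exactly_10mm(self, rect):
        det = place_detectors_rect(rect, 24, ("+y", "-y"))
        ys = det.centers[:, 1]
        assert set(np.round(ys, 9)) == {-10.0, 210.0}

    def test_no_detector_inside_phantom(self, rect):
        det = place_detectors_rect(rect, 24, ("+y", "-y", "+z", "-z"))
        lo, hi = rect.origin, rect.origin + rect.extent_mm
        inside = np.all((det.centers > lo) & (det.centers < hi), axis=1)
        assert not inside.any()

    def test_empty_sides_rejected(self, rect):
        with pytest.raises(ValueError):
            place_detectors_rect(rect, 24, ())

    def test_mirror_permutation_swaps_sides(self, rect):
        det = place_detectors_rect(rect, 8, ("+y", "-y"))
        perm = det.mirror_permutation(1, rect.origin[1] + rect.extent_mm[1] / 2)
        ids = det.ids
        for i, j in enumerate(perm):
            assert ids[i][0] == ids[j][0]
            assert ids[i][1] != ids[j][1]


class TestCylArrays:
    def test_36_columns_before_exclusion(self, cyl):
        beam = BeamSpec(energy=150.0, width_cm=1.0)
        det = place_detectors_cyl(cyl, beam, exclusion_cm=0.0)
        cols = {d.id[0] for d in det.detectors}
        assert len(cols) == 36

    def test_rows_contiguous_120mm(self, cyl):
        beam = BeamSpec(energy=150.0, width_cm=1.0)
        det = place_detectors_cyl(cyl, beam, exclusion_cm=0.0)
        zs = sorted({d.center[2] for d in det.detectors})
        assert len(zs) == 12
        assert np.allclose(np.diff(zs), 10.0)  # gap-free 10 mm pitch
        assert zs[-1] - zs[0] == pytest.approx(110.0)

    def test_exclusion_matches_geometric_oracle(self, cyl):
        beam = BeamSpec(energy=150.0, width_cm=1.0, center_shift_cm=(0.0, 0.0))
        det = place_detectors_cyl(cyl, beam, exclusion_cm=2.0)
        # oracle: enumerate the full grid and measure center-to-beam-axis distance
        full = place_detectors_cyl(cyl, beam, exclusion_cm=0.0)
        beam_y = cyl.origin[1] + cyl.extent_mm[1] / 2
        beam_z = cyl.origin[2] + cyl.extent_mm[2] / 2
        expect_removed = {
            d.id
            for d in full.detectors
            if np.hypot(d.center[1] - beam_y, d.center[2] - beam_z) - 5.0 < 20.0
        }
        assert set(det.removed_ids) == expect_removed
        assert expect_removed  # the rule actually removes something
        # symmetric about the beam axis: column phi and -phi removed together
        removed_cols = {c for c, _ in det.removed_ids}
        assert removed_cols == {(36 - c) % 36 for c in removed_cols}

    def test_detectors_outside_cylinder(self, cyl):
        beam = BeamSpec(energy=150.0, width_cm=1.0)
        det = place_detectors_cyl(cyl, beam)
        cx = cyl.origin[0] + cyl.extent_mm[0] / 2
        cy = cyl.origin[1] + cyl.extent_mm[1] / 2
        r = np.hypot(det.centers[:, 0] - cx, det.centers[:, 1] - cy)
        assert np.all(r >= 200.0 + 10.0 - 1e-9)

    def test_bad_angular_step_rejected(self, cyl):
        with pytest.raises(ValueError):
            place_detectors_cyl(cyl, BeamSpec(energy=150.0), angular_step_deg=7.0)


class TestSubsetSelection:
    def test_identity(self, cyl):
        det = place_detectors_cyl(cyl, BeamSpec(energy=150.0, width_cm=1.0))
        sub = select_subset(det, None, None)
        assert sub.ids == det.ids

    def test_alternating_column_halving(self, cyl):
        det = place_detectors_cyl(cyl, BeamSpec(energy=150.0, width_cm=1.0), exclusion_cm=0.0)
        sub = select_subset(det, columns=range(0, 36, 2), rows=None)
        assert {c for c, _ in sub.ids} == set(range(0, 36, 2))
        assert len(sub) == 18 * 12

    def test_alternating_row_halving(self, cyl):
        det = place_detectors_cyl(cyl, BeamSpec(energy=150.0, width_cm=1.0), exclusion_cm=0.0)
        sub = select_subset(det, columns=None, rows=range(0, 12, 2))
        assert len(sub) == 36 * 6

    def test_unknown_id_rejected(self, cyl):
        det = place_detectors_cyl(cyl, BeamSpec(energy=150.0))
        with pytest.raises(ValueError):
            select_subset(det, columns=[99], rows=None)


class TestCurrentReadout:
    def test_length_and_nonnegativity_enforced(self):
        with pytest.raises(ValueError):
            CurrentReadout(ids=[(0, 0)], values=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            CurrentReadout(ids=[(0, 0)], values=np.array([-1.0]))

    def test_full_vector_embedding(self):
        r = CurrentReadout(ids=[(0, 0), (2, 1)], values=np.array([5.0, 7.0]))
        grid = r.to_full_vector(4, 2)
        assert grid[0, 0] == 5.0 and grid[2, 1] == 7.0
        assert grid.sum() == 12.0
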