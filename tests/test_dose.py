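"""Candidate-angle enumeration and the pencil-beam influence engine."""

import dataclasses

import numpy as np
import pytest

import lexiplan as lp
from lexiplan.dose import BeamGeometry, beam_direction, compute_dose

import oracles
from test_phantom import TINY


class TestCandidateAngles:
    def test_arc_counts_by_modular_enumeration(self):
        for lat in ("right", "left"):
            angles = lp.candidate_angles(lat, 5.0)
            start, end = (140, 40) if lat == "right" else (320, 220)
            assert len(angles) == ((end - start) % 360) // 5 + 1 == 53
            assert angles[0] == start and angles[-1] == end

    def test_left_set_mirrors_right_set(self):
        right = set(lp.candidate_angles("right", 5.0).tolist())
        left = set(lp.candidate_angles("left", 5.0).tolist())
        assert {(360.0 - a) % 360.0 for a in right} == left

    def test_right_arc_traverses_patient_right_side(self):
        assert 270.0 in set(lp.candidate_angles("right", 5.0).tolist())
        assert 90.0 in set(lp.candidate_angles("left", 5.0).tolist())

    def test_degenerate_spacing_keeps_only_endpoints(self):
        assert lp.candidate_angles("right", 260.0).tolist() == [140.0, 40.0]

    def test_non_dividing_spacing_rejected(self):
        with pytest.raises(ValueError, match="does not divide"):
            lp.candidate_angles("right", 7.0)

    def test_unknown_laterality_rejected(self):
        with pytest.raises(ValueError, match="laterality"):
            lp.candidate_angles("central")


@pytest.fixture(scope="module")
def tiny_phantom():
    return lp.generate_phantom(TINY, seed=6)


class TestInfluence:
    def test_central_axis_attenuation_closed_form(self):
        """Homogeneous body: dose ratio between 200 mm depth and the
        surface equals exp(-mu*200) = exp(-1) at mu = 0.005/mm."""
        cfg = dataclasses.replace(
            TINY,
            grid_shape=(61, 61),
            spacing_mm=(5.0, 5.0),
            body_semiaxes_mm=(130.0, 130.0),
            tumor_offset_mm=(0.0, 0.0),
            tumor_radius_mm=10.0,
            lung_semiaxes_mm=(1.0, 1.0),
            lung_offset_mm=(100.0, 100.0),
            jitter_mm=0.0,
        )
        ph = lp.generate_phantom(cfg, seed=0)
        geom = BeamGeometry(
            beamlet_width_mm=200.0,  # broad field: flat profile on axis
            penumbra_sigma_mm=1.0,
            mu_per_mm=0.005,
            step_mm=0.25,
            field_margin_mm=0.0,
        )
        inf = lp.compute_influence(ph, [0.0], geom)
        dose = compute_dose(inf, np.ones(inf.n_beamlets))
        grid = lp.dose_grid(inf, dose)
        col = 30
        rows = np.flatnonzero(ph.masks["body"][:, col])
        surface_row = rows[0]
        depth_row = surface_row + 40  # 200 mm at 5 mm spacing
        ratio = grid[depth_row, col] / grid[surface_row, col]
        # surface voxel center sits half a voxel deep; compare at offset depth
        expected = np.exp(-0.005 * 200.0)
        assert ratio == pytest.approx(expected, rel=2e-2)

    def test_opposed_beams_give_symmetric_dose(self):
        cfg = dataclasses.replace(
            TINY, tumor_offset_mm=(0.0, 0.0), jitter_mm=0.0,
            lung_offset_mm=(38.0, 0.0), heart_center_mm=(0.0, 0.0),
            esophagus_center_mm=(-2.0, -21.0),
        )
        ph = lp.generate_phantom(cfg, seed=0)
        # symmetric density: drop asymmetric organs from the density map
        ph.masks["lungs"][:] = False
        geom = BeamGeometry(step_mm=0.5)
        inf = lp.compute_influence(ph, [90.0, 270.0], geom)
        n_half = np.sum(inf.beamlet_beam == 0)
        fl = np.zeros(inf.n_beamlets)
        fl[:n_half] = 1.0
        left = lp.dose_grid(inf, compute_dose(inf, fl))
        fl2 = np.zeros(inf.n_beamlets)
        fl2[n_half:] = 1.0
        right = lp.dose_grid(inf, compute_dose(inf, fl2))
        np.testing.assert_allclose(left, right[:, ::-1], atol=1e-9)

    def test_matrix_matches_brute_force_line_integrals(self, tiny_phantom):
        geom = BeamGeometry(beamlet_width_mm=12.0, step_mm=2.0)
        angles = [0.0, 110.0, 245.0]
        inf = lp.compute_influence(tiny_phantom, angles, geom)
        dense = inf.matrix.toarray()
        rng = np.random.default_rng(0)
        # spot-check a random sample of (voxel, beamlet) entries
        rows = rng.integers(0, inf.n_voxels, 60)
        cols = rng.integers(0, inf.n_beamlets, 60)
        ny, nx = tiny_phantom.grid_shape
        for r, c in zip(rows, cols):
            flat = inf.voxel_indices[r]
            voxel_rc = (flat // nx, flat % nx)
            beam = inf.beamlet_beam[c]
            center = _beamlet_center(tiny_phantom, inf, geom, c)
            expected = oracles.brute_influence_entry(
                tiny_phantom, angles[beam], geom, voxel_rc, center
            )
            assert dense[r, c] == pytest.approx(expected, abs=1e-12)

    def test_depth_dose_monotone_in_homogeneous_body(self, tiny_phantom):
        ph = tiny_phantom
        dense_masks = dict(ph.masks)
        dense_masks["lungs"] = np.zeros_like(ph.masks["lungs"])
        ph_h = dataclasses.replace(ph, masks=dense_masks)
        geom = BeamGeometry(step_mm=0.5)
        inf = lp.compute_influence(ph_h, [0.0], geom)
        grid = lp.dose_grid(inf, compute_dose(inf, np.ones(inf.n_beamlets)))
        for col in range(grid.shape[1]):
            profile = grid[:, col][ph_h.masks["body"][:, col]]
            if len(profile) > 1:
                assert (np.diff(profile) <= 1e-12).all()

    def test_duplicate_angles_rejected(self, tiny_phantom):
        with pytest.raises(ValueError, match="distinct"):
            lp.compute_influence(tiny_phantom, [0.0, 360.0])


def _beamlet_center(phantom, influence, geom, col):
    """Recompute the lateral center of one beamlet from the grid layout."""
    beam = influence.beamlet_beam[col]
    _, lateral = beam_direction(influence.angles_deg[beam])
    xx, yy = phantom.coordinates()
    lat_ptv = np.c_[xx[phantom.masks["PTV"]], yy[phantom.masks["PTV"]]] @ lateral
    lo = lat_ptv.min() - geom.field_margin_mm
    hi = lat_ptv.max() + geom.field_margin_mm
    n_b = np.sum(influence.beamlet_beam == beam)
    first = np.flatnonzero(influence.beamlet_beam == beam)[0]
    mid = 0.5 * (lo + hi)
    return mid + (col - first - (n_b - 1) / 2) * geom.beamlet_width_mm


class TestComputeDose:
    def test_zero_fluence_zero_dose(self, tiny_phantom):
        inf = lp.compute_influence(tiny_phantom, [30.0])
        assert not compute_dose(inf, np.zeros(inf.n_beamlets)).any()

    def test_unit_fluence_returns_column(self, tiny_phantom):
        inf = lp.compute_influence(tiny_phantom, [30.0])
        fl = np.zeros(inf.n_beamlets)
        fl[2] = 1.0
        np.testing.assert_allclose(
            compute_dose(inf, fl), inf.matrix[:, 2].toarray().ravel()
        )

    def test_linearity_identity(self, tiny_phantom):
        inf = lp.compute_influence(tiny_phantom, [30.0, 200.0])
        rng = np.random.default_rng(1)
        x = rng.random(inf.n_beamlets)
        y = rng.random(inf.n_beamlets)
        a, b = 0.7, 2.3
        lhs = compute_dose(inf, a * x + b * y)
        rhs = a * compute_dose(inf, x) + b * compute_dose(inf, y)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-13)

    def test_negative_fluence_rejected(self, tiny_phantom):
        inf = lp.compute_influence(tiny_phantom, [30.0])
        with pytest.raises(ValueError, match="nonnegative"):
            compute_dose(inf, np.full(inf.n_beamlets, -1.0))

    def test_length_mismatch_rejected(self, tiny_phantom):
        inf = lp.compute_influence(tiny_phantom, [30.0])
        with pytest.raises(ValueError, match="beamlets"):
            compute_dose(inf, np.ones(inf.n_beamlets + 3))


def test_influence_hdf5_round_trip(tmp_path, tiny_phantom):
    from lexiplan.dose import load_influence, save_influence

    inf = lp.compute_influence(tiny_phantom, [15.0, 300.0])
    path = tmp_path / "influence.h5"
    save_influence(path, inf)
    back = load_influence(path)
    np.testing.assert_allclose(back.matrix.toarray(), inf.matrix.toarray())
    np.testing.assert_array_equal(back.voxel_indices, inf.voxel_indices)
    np.testing.assert_array_equal(back.beamlet_beam, inf.beamlet_beam)
    assert back.geometry == inf.geometry
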