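"""Solver physics: closed-form oracles, conservation, symmetry, invariance."""

import numpy as np
import pytest

from ttdose import (
    ConductivityVolume,
    FieldSolution,
    HeadGeometry,
    SolverError,
    assign_conductivities,
    default_pathology,
    field_intensity,
    insert_pathology,
    build_head_phantom,
    make_array,
    solve_fields,
    solve_masked,
)
from ttdose.solver import assemble_system


def _slab_cv(shape=(16, 16, 24), sigma=1.0, spacing=(2.0, 2.0, 2.0)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    return ConductivityVolume(np.full(shape, sigma), aff)


def _plate_masks(shape):
    src = np.zeros(shape, dtype=bool)
    snk = np.zeros(shape, dtype=bool)
    src[:, :, 0] = True
    snk[:, :, -1] = True
    return src, snk


class TestSlabOracle:
    def test_uniform_field_matches_ohms_law(self):
        """Homogeneous slab with full-face terminals: |E| = I / (sigma A)."""
        shape, h, sigma, I = (16, 16, 24), 2.0, 1.0, 0.9
        cv = _slab_cv(shape, sigma, (h, h, h))
        sol = solve_masked(cv, *_plate_masks(shape), current_A=I)
        area_m2 = shape[0] * shape[1] * (h * 1e-3) ** 2
        expected = I / (sigma * area_m2)
        interior = np.zeros(shape, dtype=bool)
        interior[:, :, 1:-1] = True
        assert np.allclose(sol.norm_E[interior], expected, rtol=0.01)

    def test_anisotropic_voxels_propagate_to_face_areas(self):
        """Same slab with 1 x 2 x 2 mm voxels still reproduces Ohm's law."""
        shape = (20, 10, 24)
        cv = _slab_cv(shape, 0.5, (1.0, 2.0, 2.0))
        sol = solve_masked(cv, *_plate_masks(shape), current_A=0.9)
        area_m2 = (shape[0] * 1.0e-3) * (shape[1] * 2.0e-3)
        expected = 0.9 / (0.5 * area_m2)
        interior = np.zeros(shape, dtype=bool)
        interior[:, :, 1:-1] = True
        assert np.allclose(sol.norm_E[interior], expected, rtol=0.01)

    def test_linear_potential_ramp(self):
        cv = _slab_cv((8, 8, 12), 1.0)
        sol = solve_masked(cv, *_plate_masks((8, 8, 12)), current_A=0.9)
        # phi depends on z only and is affine in z
        prof = sol.phi.mean(axis=(0, 1))
        assert np.allclose(sol.phi, prof[None, None, :], atol=1e-6 * abs(prof).max())
        assert np.allclose(np.diff(prof, 2), 0.0, atol=1e-8 * abs(prof).max())


class TestAssembly:
    def test_matrix_symmetric_and_conservative(self):
        rng = np.random.default_rng(7)
        sigma = rng.uniform(0.1, 2.0, size=(6, 6, 6))
        src, snk = _plate_masks((6, 6, 6))
        system = assemble_system(sigma, np.array([2.0, 2.0, 2.0]), [(src, 0.5), (snk, -0.5)])
        A = system.A
        asym = abs(A - A.T)
        assert (asym.max() if asym.nnz else 0.0) == 0.0
        # interior rows (no Dirichlet neighbour) sum to zero
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        interior = np.asarray(abs(system.b) == 0.0)
        assert np.allclose(rowsum[interior], 0.0, atol=1e-12 * A.diagonal().max())

    def test_disconnected_terminals_rejected(self):
        sigma = np.ones((6, 6, 7))
        sigma[:, :, 3] = 0.0  # insulating wall splits the domain
        src, snk = _plate_masks((6, 6, 7))
        with pytest.raises(SolverError, match="disconnected"):
            assemble_system(sigma, np.ones(3) * 2.0, [(src, 0.5), (snk, -0.5)])


class TestConservationAndSymmetry:
    def test_terminal_current_balance(self, sol_holes_60):
        assert sol_holes_60.diagnostics["current_balance_rel"] <= 1e-6

    def test_injected_current_is_realized(self, sol_holes_60):
        assert sol_holes_60.I_injected_A == 0.9

    def test_current_scaling_is_exactly_linear(self, cv_holes, pair60, sol_holes_60):
        sol2 = solve_fields(cv_holes, pair60, current_A=1.8)
        assert np.allclose(sol2.phi, 2.0 * sol_holes_60.phi, rtol=1e-6, atol=1e-9)
        assert np.allclose(sol2.norm_E, 2.0 * sol_holes_60.norm_E, rtol=1e-6, atol=1e-9)

    def test_polarity_swap_negates_phi_leaves_intensity(self, cv_holes, pair60, sol_holes_60):
        src, snk = pair60
        swapped = (src.with_polarity("sink"), snk.with_polarity("source"))
        sol2 = solve_fields(cv_holes, swapped)
        ref = abs(sol_holes_60.phi).max()
        assert np.allclose(sol2.phi, -sol_holes_60.phi, atol=1e-6 * ref)
        assert np.allclose(sol2.norm_E, sol_holes_60.norm_E, atol=1e-5 * sol_holes_60.norm_E.max())

    def test_nonpositive_current_rejected(self, cv_holes, pair60):
        with pytest.raises(ValueError, match="current"):
            solve_fields(cv_holes, pair60, current_A=0.0)


class TestFieldIntensity:
    def test_euclidean_norm(self):
        E = np.zeros((2, 2, 2, 3))
        E[..., 0], E[..., 1] = 3.0, 4.0
        sol = FieldSolution(
            phi=np.zeros((2, 2, 2)),
            E=E,
            norm_E=np.linalg.norm(E, axis=-1),
            affine=np.eye(4),
            domain=np.ones((2, 2, 2), dtype=bool),
            I_injected_A=0.9,
        )
        mask = np.ones((2, 2, 2), dtype=bool)
        assert np.all(field_intensity(sol, mask) == 5.0)

    def test_empty_mask_is_empty_not_error(self, sol_holes_60):
        vals = field_intensity(sol_holes_60, np.zeros(sol_holes_60.shape, dtype=bool))
        assert vals.size == 0

    def test_lattice_mismatch_rejected(self, sol_holes_60):
        with pytest.raises(ValueError, match="lattice"):
            field_intensity(sol_holes_60, np.ones((2, 2, 2), dtype=bool))


class TestProblemInvariance:
    def test_rotating_whole_problem_preserves_intensity(self):
        """Rotate phantom + arrays 90 deg about z: tumor median |E| within 2%."""
        meds = []
        for axes, azim in (((85.0, 105.0, 95.0), 60.0), ((105.0, 85.0, 95.0), -30.0)):
            geom = HeadGeometry(semi_axes_mm=axes)
            path = default_pathology(geom, azimuth_deg=azim)
            vol = insert_pathology(build_head_phantom(geom, 3.0), path)
            cv = assign_conductivities(vol)
            surf = geom.scalp_surface()
            pair = (
                make_array(surf.point_at(azim, 50.0), 0.0, surf, "source"),
                make_array(surf.point_at(azim + 180.0, 50.0), 0.0, surf, "sink"),
            )
            sol = solve_fields(cv, pair)
            meds.append(float(np.median(sol.norm_E[vol.labels == 8])))
        assert abs(meds[0] - meds[1]) / meds[1] < 0.02

    def test_refined_grid_self_oracle_two_shell_sphere(self):
        """Concentric two-shell spherical conductor with point-like polar
        caps: core median |E| agrees within 5% after one grid refinement."""
        r_core, r_outer = 45.0, 60.0
        meds = {}
        for h in (3.0, 1.5):
            n = 2 * int(np.ceil((r_outer + 2 * h) / h)) + 1
            c = (n - 1) / 2.0
            x = (np.arange(n) - c) * h
            r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2)
            sigma = np.zeros((n, n, n))
            sigma[r <= r_outer] = 0.08  # resistive shell
            sigma[r <= r_core] = 0.4  # conductive core
            aff = np.eye(4)
            aff[:3, :3] = np.diag([h, h, h])
            aff[:3, 3] = -c * h
            cv = ConductivityVolume(sigma, aff)
            # point-like caps: surface voxels within 12 mm of the two poles
            z = x[None, None, :]
            axis_dist = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2)
            surface = (sigma > 0) & (r > r_outer - 1.5 * h)
            src = surface & (z > 0) & (axis_dist < 12.0)
            snk = surface & (z < 0) & (axis_dist < 12.0)
            sol = solve_masked(cv, src, snk, current_A=0.9)
            meds[h] = float(np.median(sol.norm_E[r <= r_core]))
        assert abs(meds[3.0] - meds[1.5]) / meds[1.5] < 0.05

    def test_reciprocity_source_sink_exchange(self, cv_holes, pair60, sol_holes_60):
        src, snk = pair60
        sol2 = solve_fields(cv_holes, (snk.with_polarity("source"), src.with_polarity("sink")))
        assert np.allclose(sol2.norm_E, sol_holes_60.norm_E, atol=1e-5 * sol_holes_60.norm_E.max())
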