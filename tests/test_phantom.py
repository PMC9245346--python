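"""Phantom construction: nested shells, pathology carving, burr-hole surgery."""

import numpy as np
import pytest
from scipy import ndimage

from ttdose import (
    HeadGeometry,
    PathologySpec,
    QuincunxSpec,
    apply_sr_surgery,
    build_head_phantom,
    default_pathology,
    insert_pathology,
    place_quincunx,
)
from ttdose.volume import (
    BURR_HOLE,
    CSF,
    FUNNEL,
    GM,
    RESECTION_CAVITY,
    RESIDUAL_TUMOR,
    SCALP,
    SKULL,
    WM,
)


class TestBuildHeadPhantom:
    def test_all_shells_present_and_resolved(self):
        vol = build_head_phantom(HeadGeometry(), 2.0)
        present = set(np.unique(vol.labels).tolist())
        assert {0, SCALP, SKULL, CSF, GM, WM} <= present

    def test_spherical_wm_volume_matches_analytic(self):
        # Spherical head 85/78/71/68/63 mm: WM volume vs (4/3) pi 63^3.
        geom = HeadGeometry(
            semi_axes_mm=(85.0, 85.0, 85.0),
            scalp_thickness_mm=7.0,
            skull_thickness_mm=7.0,
            csf_thickness_mm=3.0,
            gm_thickness_mm=5.0,
        )
        vol = build_head_phantom(geom, 2.0)
        wm_mm3 = vol.count(WM) * vol.voxel_volume_mm3
        analytic = 4.0 / 3.0 * np.pi * 63.0**3
        assert abs(wm_mm3 - analytic) / analytic < 0.05

    def test_deterministic(self):
        a = build_head_phantom(HeadGeometry(), 3.0)
        b = build_head_phantom(HeadGeometry(), 3.0)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.affine, b.affine)

    def test_rejects_voxel_coarser_than_thinnest_shell(self):
        geom = HeadGeometry(csf_thickness_mm=1.5)
        with pytest.raises(ValueError, match="too coarse"):
            build_head_phantom(geom, 2.0)

    @pytest.mark.parametrize("voxel", [0.5, 5.0])
    def test_rejects_voxel_outside_supported_range(self, voxel):
        with pytest.raises(ValueError, match="voxel size"):
            build_head_phantom(HeadGeometry(), voxel)

    def test_mesh_independence_of_shell_volumes(self):
        # Halving the voxel size changes each labeled solid's volume < 5%.
        coarse = build_head_phantom(HeadGeometry(), 3.0)
        fine = build_head_phantom(HeadGeometry(), 1.5)
        for lab in (SCALP, SKULL, CSF, GM, WM):
            vc = coarse.count(lab) * coarse.voxel_volume_mm3
            vf = fine.count(lab) * fine.voxel_volume_mm3
            assert abs(vc - vf) / vf < 0.05, lab

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            HeadGeometry(scalp_thickness_mm=-1.0)
        with pytest.raises(ValueError):
            HeadGeometry(semi_axes_mm=(15.0, 105.0, 95.0))  # shells exceed semi-axis


class TestInsertPathology:
    def test_cavity_volume_matches_analytic(self, geom, pathology):
        vol = insert_pathology(build_head_phantom(geom, 2.0), pathology)
        cav_mm3 = vol.count(RESECTION_CAVITY) * vol.voxel_volume_mm3
        analytic = 4.0 / 3.0 * np.pi * 12.5**3
        assert abs(cav_mm3 - analytic) / analytic < 0.10

    def test_zero_diameter_funnel_rejected(self, pathology):
        with pytest.raises(ValueError, match="funnel"):
            PathologySpec(
                pathology.cavity_center_mm,
                pathology.tumor_center_mm,
                pathology.funnel_axis,
                funnel_diameter_mm=0.0,
            )

    def test_locality_outside_solids(self, geom, pathology):
        base = build_head_phantom(geom, 3.0)
        out = insert_pathology(base, pathology)
        changed = out.labels != base.labels
        assert set(np.unique(out.labels[changed])) <= {RESECTION_CAVITY, FUNNEL, RESIDUAL_TUMOR}
        # everything not in the three new solids is untouched
        untouched = ~out.mask(RESECTION_CAVITY, FUNNEL, RESIDUAL_TUMOR)
        assert np.array_equal(out.labels[untouched], base.labels[untouched])

    def test_funnel_connects_cavity_to_skull(self, geom, pathology):
        vol = insert_pathology(build_head_phantom(geom, 2.0), pathology)
        # cavity+funnel form one connected component reaching the skull
        blob = vol.mask(RESECTION_CAVITY, FUNNEL)
        lab, n = ndimage.label(blob)
        assert n == 1
        dil = ndimage.binary_dilation(blob)
        assert np.any(vol.labels[dil & ~blob] == SKULL)

    def test_tumor_outside_brain_rejected(self, geom):
        bad = PathologySpec(
            cavity_center_mm=(0.0, 0.0, 0.0),
            tumor_center_mm=(0.0, 0.0, -90.0),  # protrudes through skull
            funnel_axis=(0.0, 0.0, 1.0),
        )
        with pytest.raises(ValueError, match="protrudes"):
            insert_pathology(build_head_phantom(geom, 3.0), bad)

    def test_tumor_must_be_deeper_than_cavity(self, pathology):
        with pytest.raises(ValueError, match="deeper"):
            PathologySpec(
                pathology.cavity_center_mm,
                pathology.cavity_center_mm + 30.0 * pathology.axis_unit,
                pathology.funnel_axis,
            )


class TestSrSurgery:
    def test_five_connected_holes_piercing_skull(self, phantom_holes):
        vol, quincunx = phantom_holes
        holes = vol.mask(BURR_HOLE)
        _, n = ndimage.label(holes, structure=np.ones((3, 3, 3)))
        assert n == 5
        # each hole axis ray crosses no skull voxel (full-thickness pierce is
        # validated inside apply_sr_surgery; re-check here independently)
        for c in quincunx.hole_centers():
            nvec = quincunx.surface.normal(c)
            for s in np.arange(0.0, 30.0, 1.0):
                ijk = np.round(vol.world_to_voxel(c - s * nvec)[0]).astype(int)
                assert vol.labels[tuple(ijk)] != SKULL

    def test_hole_cross_sectional_area(self, phantom_holes):
        vol, quincunx = phantom_holes
        # total burr-hole volume / local skull thickness ~ 5 * pi * 7.5^2
        hole_mm3 = vol.count(BURR_HOLE) * vol.voxel_volume_mm3
        geom = vol.meta["geom"]
        area_cm2 = hole_mm3 / geom.skull_thickness_mm / 100.0
        assert abs(area_cm2 - 8.84) / 8.84 < 0.15  # voxelization tolerance

    def test_only_skull_voxels_replaced(self, geom, pathology, phantom_control, phantom_holes):
        vol_h, _ = phantom_holes
        vol_c = phantom_control
        for lab in (SCALP, CSF, GM, WM, RESECTION_CAVITY, FUNNEL, RESIDUAL_TUMOR):
            assert vol_h.count(lab) == vol_c.count(lab), lab
        assert vol_h.count(SKULL) + vol_h.count(BURR_HOLE) == vol_c.count(SKULL)

    def test_off_skull_template_rejected(self, geom, pathology):
        base = insert_pathology(build_head_phantom(geom, 3.0), pathology)
        surf = geom.skull_outer_surface()
        bad = QuincunxSpec(tuple(surf.point_at(0.0, 85.0)), surf)  # near the vertex edge
        # template near the top: corner walks may leave the skull patch of the
        # bounding grid or fail the pierce check; accept either rejection or a
        # valid 5-hole result
        try:
            out = apply_sr_surgery(base, bad)
        except ValueError:
            return
        _, n = ndimage.label(out.mask(BURR_HOLE), structure=np.ones((3, 3, 3)))
        assert n == 5

    def test_overlapping_holes_rejected(self, geom):
        surf = geom.skull_outer_surface()
        with pytest.raises(ValueError, match="overlap"):
            QuincunxSpec(tuple(surf.point_at(60.0, 50.0)), surf, hole_diameter_mm=40.0)


class TestPlaceQuincunx:
    def test_over_tumor_is_radial_projection(self, geom, pathology):
        q = place_quincunx("over_tumor", geom, pathology)
        centroid = 0.5 * (
            np.asarray(pathology.cavity_center_mm) + np.asarray(pathology.tumor_center_mm)
        )
        proj = geom.skull_outer_surface().project(centroid)
        assert np.linalg.norm(np.asarray(q.center_mm) - proj) < 1e-6

    @pytest.mark.parametrize("variant", ["sup3", "post3"])
    def test_30mm_surface_displacement(self, geom, pathology, variant):
        q0 = place_quincunx("over_tumor", geom, pathology)
        q = place_quincunx(variant, geom, pathology)
        surf = geom.skull_outer_surface()
        d = surf.surface_distance(np.asarray(q0.center_mm), np.asarray(q.center_mm))
        assert abs(d - 30.0) < 2.0

    def test_sup3_moves_superior_post3_posterior(self, geom, pathology):
        q0 = place_quincunx("over_tumor", geom, pathology)
        assert place_quincunx("sup3", geom, pathology).center_mm[2] > q0.center_mm[2]
        assert place_quincunx("post3", geom, pathology).center_mm[1] < q0.center_mm[1]

    def test_far_is_distant(self, geom, pathology):
        q0 = place_quincunx("over_tumor", geom, pathology)
        qf = place_quincunx("far", geom, pathology)
        surf = geom.skull_outer_surface()
        assert surf.surface_distance(np.asarray(q0.center_mm), np.asarray(qf.center_mm)) >= 80.0

    def test_none_is_control(self, geom, pathology):
        assert place_quincunx("none", geom, pathology) is None

    def test_unknown_variant_rejected(self, geom, pathology):
        with pytest.raises(ValueError, match="unknown"):
            place_quincunx("sideways", geom, pathology)
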