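"""Synthetic layered head phantom with tumor pathology and skull burr holes.

The phantom is a nest of axis-aligned ellipsoids (scalp, skull, CSF, gray
matter, white matter from the outside in) into which a spherical resection
cavity, a cylindrical surgical funnel track, a spherical residual tumor, and
a five-hole burr-hole quincunx can be carved.  It stands in for an
MRI-derived head model: geometry-generic placement rules can be reproduced
on it without any imaging data.

All solids are defined analytically in world mm (RAS, head centre at the
affine-defined origin) and rasterised by voxel-centre inclusion, so label
volumes are deterministic functions of the geometry and voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import EllipsoidSurface
from .volume import (
    BACKGROUND,
    BRAIN_LABELS,
    BURR_HOLE,
    CSF,
    FUNNEL,
    GM,
    LABEL_NAMES,
    RESECTION_CAVITY,
    RESIDUAL_TUMOR,
    SCALP,
    SKULL,
    WM,
    LabelVolume,
)

SR_VARIANTS = ("over_tumor", "sup3", "post3", "sup3post3", "far", "none")


@dataclass(frozen=True)
class HeadGeometry:
    """Nested-ellipsoid head: outer scalp semi-axes and shell thicknesses (mm).

    Defaults approximate an adult head: 170 x 210 x 190 mm outer extent with
    a 6 mm scalp, 7 mm skull, 3 mm subarachnoid CSF and 4 mm cortical gray
    matter shell; the remainder is white matter.
    """

    semi_axes_mm: tuple[float, float, float] = (85.0, 105.0, 95.0)
    scalp_thickness_mm: float = 6.0
    skull_thickness_mm: float = 7.0
    csf_thickness_mm: float = 3.0
    gm_thickness_mm: float = 4.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        th = self.shell_thicknesses
        if min(th) <= 0:
            raise ValueError("all shell thicknesses must be positive")
        if sum(th) >= min(self.semi_axes_mm):
            raise ValueError("shell thicknesses exceed the smallest semi-axis")

    @property
    def shell_thicknesses(self) -> tuple[float, float, float, float]:
        return (
            self.scalp_thickness_mm,
            self.skull_thickness_mm,
            self.csf_thickness_mm,
            self.gm_thickness_mm,
        )

    def _shrunk(self, depth: float) -> EllipsoidSurface:
        axes = tuple(a - depth for a in self.semi_axes_mm)
        return EllipsoidSurface(axes, self.center_mm)

    def scalp_surface(self) -> EllipsoidSurface:
        return self._shrunk(0.0)

    def skull_outer_surface(self) -> EllipsoidSurface:
        return self._shrunk(self.scalp_thickness_mm)

    def skull_inner_surface(self) -> EllipsoidSurface:
        return self._shrunk(self.scalp_thickness_mm + self.skull_thickness_mm)

    def brain_surface(self) -> EllipsoidSurface:
        """Outer gray-matter surface (inner CSF boundary)."""
        return self._shrunk(sum(self.shell_thicknesses[:3]))

    def wm_surface(self) -> EllipsoidSurface:
        return self._shrunk(sum(self.shell_thicknesses))


def build_head_phantom(geom: HeadGeometry, voxel_size_mm: float) -> LabelVolume:
    """Rasterise the layered head onto a regular grid.

    The grid is centred on the head with one voxel of background padding on
    every side.  Raises if the voxel size lies outside [1, 4] mm or exceeds
    the thinnest shell (which would erase that compartment entirely).
    """
    if not (1.0 <= voxel_size_mm <= 4.0):
        raise ValueError(f"voxel size {voxel_size_mm} mm outside the supported [1, 4] mm range")
    thinnest = min(geom.shell_thicknesses)
    if voxel_size_mm > thinnest:
        raise ValueError(
            f"voxel size {voxel_size_mm} mm too coarse to resolve the thinnest "
            f"shell ({thinnest} mm across)"
        )
    h = float(voxel_size_mm)
    half = np.asarray(geom.semi_axes_mm) + 2.0 * h
    n = (np.ceil(2.0 * half / h).astype(int) // 2) * 2 + 1  # odd: centre voxel on centre
    affine = np.eye(4)
    affine[:3, :3] = np.diag([h, h, h])
    affine[:3, 3] = np.asarray(geom.center_mm) - h * (n - 1) / 2.0

    labels = np.full(tuple(n), BACKGROUND, dtype=np.int16)
    vol = LabelVolume(labels, affine, dict(LABEL_NAMES), meta={"geom": geom, "voxel_size_mm": h})
    xs, ys, zs = vol.voxel_centers_world()
    depths = np.concatenate([[0.0], np.cumsum(geom.shell_thicknesses)])
    shells = [SCALP, SKULL, CSF, GM, WM]
    cx, cy, cz = geom.center_mm
    for depth, lab in zip(depths, shells):
        a, b, c = (np.asarray(geom.semi_axes_mm) - depth)
        q = (
            ((xs - cx) / a)[:, None, None] ** 2
            + ((ys - cy) / b)[None, :, None] ** 2
            + ((zs - cz) / c)[None, None, :] ** 2
        )
        labels[q <= 1.0] = lab
    return vol


# --------------------------------------------------------------------------
# Pathology

@dataclass(frozen=True)
class PathologySpec:
    """Resection cavity + funnel track + residual tumor, in world mm.

    The cavity and tumor are spheres inside the brain; the funnel is a
    cylinder from the cavity centre along ``funnel_axis`` up to the inner
    skull table, mimicking the surgical entry corridor.  The tumor sits
    strictly deeper than the cavity along the funnel axis.
    """

    cavity_center_mm: tuple[float, float, float]
    tumor_center_mm: tuple[float, float, float]
    funnel_axis: tuple[float, float, float]
    cavity_diameter_mm: float = 25.0
    tumor_diameter_mm: float = 25.0
    funnel_diameter_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.cavity_diameter_mm <= 0 or self.tumor_diameter_mm <= 0:
            raise ValueError("cavity and tumor diameters must be positive")
        if self.funnel_diameter_mm <= 0:
            raise ValueError("funnel diameter must be positive (it must connect cavity to skull)")
        ax = np.asarray(self.funnel_axis, dtype=float)
        if np.linalg.norm(ax) < 1e-9:
            raise ValueError("funnel axis must be a non-zero vector")
        rel = np.asarray(self.tumor_center_mm) - np.asarray(self.cavity_center_mm)
        if float(rel @ ax) >= 0.0:
            raise ValueError("tumor must lie deeper than the cavity along the funnel axis")

    @property
    def axis_unit(self) -> np.ndarray:
        ax = np.asarray(self.funnel_axis, dtype=float)
        return ax / np.linalg.norm(ax)


def default_pathology(
    geom: HeadGeometry,
    azimuth_deg: float = 60.0,
    ring_z_mm: float = 50.0,
    margin_mm: float = 3.0,
) -> PathologySpec:
    """Default lesion: a 25 mm cavity + tangent 25 mm tumor on the radial ray
    through the scalp point at (azimuth, ring height).

    The defaults put the lesion's radial skull projection at the 60-degree
    position of the circumferential array ring, so the over-tumor burr-hole
    quincunx and the 60-degree layout overlap (the clinically optimal case).
    """
    scalp = geom.scalp_surface()
    p = scalp.point_at(azimuth_deg, ring_z_mm)
    u = (p - np.asarray(geom.center_mm)) / np.linalg.norm(p - np.asarray(geom.center_mm))
    brain = geom.brain_surface()
    axes = np.asarray(brain.semi_axes)
    t_exit = 1.0 / np.sqrt(np.sum((u / axes) ** 2))
    r_cav = 25.0 / 2.0
    cav = np.asarray(geom.center_mm) + (t_exit - r_cav - margin_mm) * u
    tum = cav - 25.0 * u
    return PathologySpec(tuple(cav), tuple(tum), tuple(u))


def _cylinder_mask(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    base: np.ndarray,
    axis: np.ndarray,
    radius: float,
    s_min: float,
    s_max: float,
) -> np.ndarray:
    """Voxel-centre mask of a finite cylinder around base + s*axis."""
    dx = (xs - base[0])[:, None, None]
    dy = (ys - base[1])[None, :, None]
    dz = (zs - base[2])[None, None, :]
    s = dx * axis[0] + dy * axis[1] + dz * axis[2]
    r2 = (dx - s * axis[0]) ** 2 + (dy - s * axis[1]) ** 2 + (dz - s * axis[2]) ** 2
    return (r2 <= radius**2) & (s >= s_min) & (s <= s_max)


def _sphere_mask(xs, ys, zs, center, radius) -> np.ndarray:
    return (
        ((xs - center[0]) ** 2)[:, None, None]
        + ((ys - center[1]) ** 2)[None, :, None]
        + ((zs - center[2]) ** 2)[None, None, :]
    ) <= radius**2


def insert_pathology(vol: LabelVolume, spec: PathologySpec) -> LabelVolume:
    """Carve cavity, funnel and residual tumor into a copy of the volume.

    Only voxels inside the three analytic solids change; the cavity and
    tumor must lie entirely inside brain parenchyma and must not overlap.
    """
    out = vol.copy()
    xs, ys, zs = out.voxel_centers_world()
    cav_c = np.asarray(spec.cavity_center_mm, dtype=float)
    tum_c = np.asarray(spec.tumor_center_mm, dtype=float)
    u = spec.axis_unit

    cav = _sphere_mask(xs, ys, zs, cav_c, spec.cavity_diameter_mm / 2.0)
    tum = _sphere_mask(xs, ys, zs, tum_c, spec.tumor_diameter_mm / 2.0)
    if np.any(cav & tum):
        raise ValueError("resection cavity and residual tumor overlap")
    brain = out.mask(*BRAIN_LABELS)
    for name, m in (("cavity", cav), ("tumor", tum)):
        if not np.all(brain[m]):
            raise ValueError(f"{name} sphere protrudes outside the brain parenchyma")

    # Funnel: from the cavity centre along the axis to the inner skull table.
    geom: HeadGeometry | None = out.meta.get("geom")
    if geom is not None:
        inner_skull = np.asarray(geom.skull_inner_surface().semi_axes)
        rel = cav_c - np.asarray(geom.center_mm)
        # Ray rel + s*u exits the inner-skull ellipsoid at the positive root.
        A = float(np.sum((u / inner_skull) ** 2))
        B = 2.0 * float(np.sum(rel * u / inner_skull**2))
        C = float(np.sum((rel / inner_skull) ** 2)) - 1.0
        disc = B * B - 4 * A * C
        if disc <= 0:
            raise ValueError("funnel axis misses the skull")
        s_skull = (-B + np.sqrt(disc)) / (2 * A)
    else:
        # User-supplied volume: extend until the ray leaves non-skull tissue.
        s_skull = float(np.max(vol.voxel_size_mm)) * max(vol.shape)
    h = float(np.max(out.voxel_size_mm))
    fun = _cylinder_mask(xs, ys, zs, cav_c, u, spec.funnel_diameter_mm / 2.0, 0.0, s_skull + h / 2)
    fun &= out.mask(GM, WM, CSF) & ~cav & ~tum

    lab = out.labels
    lab[fun] = FUNNEL
    lab[cav] = RESECTION_CAVITY
    lab[tum] = RESIDUAL_TUMOR
    return out


# --------------------------------------------------------------------------
# Skull-remodeling surgery (burr-hole quincunx)

@dataclass(frozen=True)
class QuincunxSpec:
    """Five-hole burr-hole template on the outer skull surface.

    One central hole plus four holes at the corners of a ``span_mm`` square
    centred on it; hole axes follow the local skull-surface normal.
    """

    center_mm: tuple[float, float, float]
    surface: EllipsoidSurface
    hole_diameter_mm: float = 15.0
    span_mm: float = 45.0
    orientation_deg: float = 0.0
    variant: str = "custom"

    def __post_init__(self) -> None:
        if self.hole_diameter_mm <= 0 or self.span_mm <= 0:
            raise ValueError("hole diameter and span must be positive")
        if self.hole_diameter_mm > self.span_mm / np.sqrt(2.0):
            raise ValueError("holes overlap: diameter too large for the span")

    def hole_centers(self) -> list[np.ndarray]:
        """Central hole + 4 corner holes, by geodesic walks on the surface."""
        surf = self.surface
        c = surf.project(np.asarray(self.center_mm, dtype=float))
        e1 = surf.azimuthal_tangent(c)
        n = surf.normal(c)
        th = np.deg2rad(self.orientation_deg)
        e1r = surf.tangent(c, np.cos(th) * e1 + np.sin(th) * np.cross(n, e1))
        half = self.span_mm / 2.0
        centers = [c]
        for s1 in (-half, half):
            p1, v1 = surf.walk(c, e1r, s1)
            n1 = surf.normal(p1)
            e2 = np.cross(n1, v1 if s1 > 0 else -v1)
            for s2 in (-half, half):
                p2, _ = surf.walk(p1, e2, s2)
                centers.append(p2)
        return centers

    def axis(self) -> np.ndarray:
        """Outward unit normal at the template centre (the quincunx axis)."""
        return self.surface.normal(self.surface.project(np.asarray(self.center_mm)))


def place_quincunx(
    variant: str,
    geom: HeadGeometry,
    pathology: PathologySpec,
    far_azimuth_deg: float = 150.0,
    far_ring_z_mm: float = 30.0,
) -> QuincunxSpec | None:
    """Position the quincunx per the studied placement variants.

    ``over_tumor`` centres the template at the skull point radially above the
    cavity/tumor centroid; ``sup3``/``post3``/``sup3post3`` displace it 30 mm
    along the skull surface superiorly and/or posteriorly; ``far`` places it
    in the ipsilateral occipito-parietal region (>= 80 mm surface distance);
    ``none`` is the no-hole control and returns None.
    """
    if variant not in SR_VARIANTS:
        raise ValueError(f"unknown SR variant {variant!r}; expected one of {SR_VARIANTS}")
    if variant == "none":
        return None
    surf = geom.skull_outer_surface()
    centroid = 0.5 * (
        np.asarray(pathology.cavity_center_mm) + np.asarray(pathology.tumor_center_mm)
    )
    c0 = surf.project(centroid)
    if variant == "over_tumor":
        c = c0
    elif variant == "sup3":
        c, _ = surf.walk(c0, surf.superior_tangent(c0), 30.0)
    elif variant == "post3":
        c, _ = surf.walk(c0, surf.posterior_tangent(c0), 30.0)
    elif variant == "sup3post3":
        p, _ = surf.walk(c0, surf.superior_tangent(c0), 30.0)
        c, _ = surf.walk(p, surf.posterior_tangent(p), 30.0)
    else:  # far
        c = surf.point_at(far_azimuth_deg, far_ring_z_mm)
    return QuincunxSpec(tuple(c), surf, variant=variant)


def apply_sr_surgery(vol: LabelVolume, spec: QuincunxSpec) -> LabelVolume:
    """Drill the five burr holes: skull voxels inside each hole cylinder are
    relabelled ``burr_hole``; no other label is ever modified.

    Raises if any hole fails to pierce the full skull thickness (e.g. the
    template extends off the skull patch).
    """
    out = vol.copy()
    xs, ys, zs = out.voxel_centers_world()
    lab = out.labels
    h = float(np.max(out.voxel_size_mm))
    r = spec.hole_diameter_mm / 2.0
    centers = spec.hole_centers()
    for i, c in enumerate(centers):
        n = spec.surface.normal(c)
        # Window along the axis: the skull sits within a few cm inboard of the
        # outer skull surface; the cap excludes the far side of the head.
        m = _cylinder_mask(xs, ys, zs, c, n, r, -40.0, 2.0 * h)
        m &= lab == SKULL
        if not np.any(m):
            raise ValueError(f"burr hole {i} has no skull contact (off the skull patch?)")
        lab[m] = BURR_HOLE
        # The hole must fully pierce the skull: a ray along the axis through
        # the hole centre may no longer cross any skull voxel.
        for s in np.arange(0.0, 40.0, h / 2.0):
            p = c - s * n
            ijk = np.round(out.world_to_voxel(p)[0]).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= np.asarray(out.shape)):
                continue
            if lab[tuple(ijk)] == SKULL:
                raise ValueError(f"burr hole {i} does not pierce the full skull thickness")
    return out


def make_sr_phantom(
    geom: HeadGeometry | None = None,
    voxel_size_mm: float = 2.0,
    sr_variant: str = "over_tumor",
    pathology: PathologySpec | None = None,
) -> tuple[LabelVolume, PathologySpec, QuincunxSpec | None]:
    """Convenience: head + pathology + (optionally) burr holes in one call."""
    geom = geom or HeadGeometry()
    pathology = pathology or default_pathology(geom)
    vol = insert_pathology(build_head_phantom(geom, voxel_size_mm), pathology)
    q = place_quincunx(sr_variant, geom, pathology)
    if q is not None:
        vol = apply_sr_surgery(vol, q)
    return vol, pathology, q
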