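"""Transducer-array geometry on the scalp surface.

An array is a rigid 3x3 grid of 20 mm ceramic discs (1 mm high) with
centre-to-centre pitch 45 mm along the long axis and 22 mm along the short
axis, laid out on the scalp by geodesic walks so the pitch is preserved as
surface distance.  Two opposed arrays form a driven pair (source/sink)
carrying 0.9 A baseline-to-peak.

Three layout families parameterise clinically relevant placements:

* ``circumferential`` — the pair rotates in 15-degree steps around the
  craniocaudal axis on the ring 50 mm above the central horizontal plane;
  azimuth 0 is anterior-posterior, and at 60 degrees the ipsilateral array
  overlaps the over-tumor burr-hole template.
* ``normal_rotation`` — starting from the 60-degree pair, the ipsilateral
  array spins about the surface normal at its (fixed) centre while the
  contralateral array never moves.
* ``vertex_translation`` — starting 30 mm inferior to the 60-degree pair,
  both arrays slide up their meridians toward the vertex, progressively
  shunting current through the scalp between them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import HeadGeometry
from .surface import EllipsoidSurface

LONG_PITCH_MM = 45.0
SHORT_PITCH_MM = 22.0
DISC_DIAMETER_MM = 20.0
DISC_HEIGHT_MM = 1.0

CIRCUMFERENTIAL_RING_Z_MM = 50.0
OPTIMAL_ANGLE_DEG = 60.0
VERTEX_START_INFERIOR_MM = 30.0

CIRCUMFERENTIAL_ANGLES = tuple(range(0, 166, 15))
NORMAL_ROTATION_ANGLES = tuple(range(0, 166, 15))
VERTEX_TRAVELS_MM = tuple(range(20, 151, 10))


@dataclass(frozen=True)
class TransducerArray:
    """One 3x3 disc array: centres and outward normals in world mm."""

    disc_centers: np.ndarray  # (9, 3)
    disc_normals: np.ndarray  # (9, 3)
    polarity: str  # "source" | "sink"
    center_mm: np.ndarray  # array centre on the surface
    disc_diameter_mm: float = DISC_DIAMETER_MM
    disc_height_mm: float = DISC_HEIGHT_MM

    def __post_init__(self) -> None:
        if self.polarity not in ("source", "sink"):
            raise ValueError("polarity must be 'source' or 'sink'")
        if self.disc_centers.shape != (9, 3) or self.disc_normals.shape != (9, 3):
            raise ValueError("an array has exactly 9 discs")

    def with_polarity(self, polarity: str) -> "TransducerArray":
        return replace(self, polarity=polarity)

    def to_dict(self) -> dict:
        return {
            "polarity": self.polarity,
            "center_mm": self.center_mm.tolist(),
            "disc_diameter_mm": self.disc_diameter_mm,
            "disc_height_mm": self.disc_height_mm,
            "disc_centers_mm": self.disc_centers.tolist(),
            "disc_normals": self.disc_normals.tolist(),
        }


def make_array(
    surface_point: np.ndarray,
    in_plane_angle_deg: float,
    surface: EllipsoidSurface,
    polarity: str = "source",
    long_axis_hint: np.ndarray | None = None,
) -> TransducerArray:
    """Lay a 3x3 array out on the surface around ``surface_point``.

    The grid is built by geodesic walks from the centre: first along the long
    axis (45 mm pitch), then along the locally perpendicular short axis
    (22 mm pitch), so centre-to-centre surface distances match the nominal
    pitch.  ``in_plane_angle_deg`` rotates the grid about the surface normal;
    the zero direction is the azimuthal (horizontal ring) tangent unless a
    ``long_axis_hint`` is given.
    """
    c = surface.project(np.asarray(surface_point, dtype=float))
    n = surface.normal(c)
    base = (
        surface.tangent(c, long_axis_hint)
        if long_axis_hint is not None
        else surface.azimuthal_tangent(c)
    )
    th = np.deg2rad(in_plane_angle_deg)
    e1 = surface.tangent(c, np.cos(th) * base + np.sin(th) * np.cross(n, base))
    centers: list[np.ndarray] = []
    for i in (-1, 0, 1):
        if i == 0:
            p_i, v_i = c, e1
        else:
            p_i, v_raw = surface.walk(c, e1, i * LONG_PITCH_MM)
            v_i = v_raw
        n_i = surface.normal(p_i)
        e2 = np.cross(n_i, v_i)
        e2 /= np.linalg.norm(e2)
        for j in (-1, 0, 1):
            if j == 0:
                centers.append(p_i)
            else:
                p_ij, _ = surface.walk(p_i, e2, j * SHORT_PITCH_MM)
                centers.append(p_ij)
    centers_arr = np.asarray(centers)
    normals = np.asarray([surface.normal(p) for p in centers])
    return TransducerArray(centers_arr, normals, polarity, c)


def _validate_grid_angle(angle_deg: float) -> None:
    if angle_deg not in range(0, 166, 15):
        raise ValueError(
            f"angle {angle_deg} not on the 15-degree grid [0, 165] "
            "(the pair has 180-degree symmetry)"
        )


def layout_circumferential(
    angle_deg: float, geom: HeadGeometry | None = None
) -> tuple[TransducerArray, TransducerArray]:
    """Opposed pair on the ring 50 mm above the central horizontal plane."""
    _validate_grid_angle(angle_deg)
    geom = geom or HeadGeometry()
    surf = geom.scalp_surface()
    z = CIRCUMFERENTIAL_RING_Z_MM
    ipsi = make_array(surf.point_at(angle_deg, z), 0.0, surf, "source")
    contra = make_array(surf.point_at(angle_deg + 180.0, z), 0.0, surf, "sink")
    return ipsi, contra


def layout_normal_rotation(
    angle_deg: float, geom: HeadGeometry | None = None
) -> tuple[TransducerArray, TransducerArray]:
    """Spin the ipsilateral (60-degree) array about its surface normal.

    Angle 0 reproduces ``layout_circumferential(60)``; the contralateral
    array is identical across all angles.
    """
    _validate_grid_angle(angle_deg)
    geom = geom or HeadGeometry()
    surf = geom.scalp_surface()
    z = CIRCUMFERENTIAL_RING_Z_MM
    ipsi = make_array(surf.point_at(OPTIMAL_ANGLE_DEG, z), angle_deg, surf, "source")
    contra = make_array(surf.point_at(OPTIMAL_ANGLE_DEG + 180.0, z), 0.0, surf, "sink")
    return ipsi, contra


def layout_vertex_translation(
    travel_mm: float, geom: HeadGeometry | None = None
) -> tuple[TransducerArray, TransducerArray]:
    """Slide both arrays up their meridians toward the vertex.

    The start (travel would be 0) sits 30 mm inferior to the 60-degree
    circumferential pair; the supported grid is 20-150 mm in 10 mm steps.  At
    large travel the two arrays meet at the vertex and their footprints
    overlap, the maximally shunted configuration.
    """
    if not (20.0 <= travel_mm <= 150.0):
        raise ValueError("vertex travel must lie in [20, 150] mm (grid starts at 20 mm)")
    geom = geom or HeadGeometry()
    surf = geom.scalp_surface()
    z = CIRCUMFERENTIAL_RING_Z_MM
    arrays = []
    vertex = np.asarray(geom.center_mm) + np.array([0.0, 0.0, geom.semi_axes_mm[2]])
    for az, pol in ((OPTIMAL_ANGLE_DEG, "source"), (OPTIMAL_ANGLE_DEG + 180.0, "sink")):
        p0 = surf.point_at(az, z)
        start, _ = surf.walk(p0, -surf.superior_tangent(p0), VERTEX_START_INFERIOR_MM)
        # Travel saturates at the vertex: moving "toward the craniocaudal
        # axis" cannot overshoot it, so at large travel the two arrays meet
        # there and their footprints abut (the maximally shunted case).  The
        # stop is quantized to the family's 10 mm step so every saturated
        # travel maps to the identical geometry.
        to_vertex = surf.surface_distance(start, vertex)
        stop = np.floor(to_vertex / 10.0) * 10.0
        center, v_up = surf.walk(start, surf.superior_tangent(start), min(travel_mm, stop))
        n = surf.normal(center)
        long_axis = np.cross(n, v_up)  # azimuth-like direction transported through the vertex
        arrays.append(make_array(center, 0.0, surf, pol, long_axis_hint=long_axis))
    return arrays[0], arrays[1]


def layout_pair(
    family: str, parameter: float, geom: HeadGeometry | None = None
) -> tuple[TransducerArray, TransducerArray]:
    """Dispatch on the layout family name."""
    if family == "circumferential":
        return layout_circumferential(parameter, geom)
    if family == "normal_rotation":
        return layout_normal_rotation(parameter, geom)
    if family == "vertex_translation":
        return layout_vertex_translation(parameter, geom)
    raise ValueError(f"unknown layout family {family!r}")


def family_grid(family: str) -> tuple[float, ...]:
    return {
        "circumferential": CIRCUMFERENTIAL_ANGLES,
        "normal_rotation": NORMAL_ROTATION_ANGLES,
        "vertex_translation": VERTEX_TRAVELS_MM,
    }[family]
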