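"""Analytic ellipsoid surface used for scalp/skull placement geometry.

The phantom's scalp is an axis-aligned ellipsoid centred at the head centre.
Transducer arrays and burr-hole templates are laid out on this surface:
points are generated by short geodesic walks (tangent step + reprojection),
which preserves arc-length pitch to well under a millimetre at head
curvature.

Conventions: world RAS in mm.  Azimuth is measured from the +y (anterior)
axis, increasing toward +x (subject's right), so azimuth 0 deg is the
anterior pole of a horizontal ring and 90 deg is the right side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class EllipsoidSurface:
    """Surface of the ellipsoid (x/a)^2 + (y/b)^2 + (z/c)^2 = 1, shifted to center."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def _axes(self) -> np.ndarray:
        return np.asarray(self.semi_axes, dtype=float)

    @property
    def _c(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def implicit(self, p: np.ndarray) -> float:
        q = (np.asarray(p, dtype=float) - self._c) / self._axes
        return float(np.dot(q, q) - 1.0)

    def contains(self, p: np.ndarray) -> bool:
        return self.implicit(p) <= 0.0

    def project(self, p: np.ndarray) -> np.ndarray:
        """Radially (from the center) rescale p onto the surface."""
        v = np.asarray(p, dtype=float) - self._c
        q = v / self._axes
        r = float(np.linalg.norm(q))
        if r == 0.0:
            raise ValueError("cannot project the center point onto the surface")
        return self._c + v / r

    def normal(self, p: np.ndarray) -> np.ndarray:
        """Outward unit normal at a (near-)surface point."""
        v = np.asarray(p, dtype=float) - self._c
        g = 2.0 * v / self._axes**2
        n = np.linalg.norm(g)
        if n == 0.0:
            raise ValueError("normal undefined at the center")
        return g / n

    def point_at(self, azimuth_deg: float, z_mm: float) -> np.ndarray:
        """Surface point at a given azimuth on the horizontal ring z = z_mm."""
        a, b, c = self._axes
        if abs(z_mm) >= c:
            raise ValueError(f"ring height {z_mm} mm outside the ellipsoid (|z| < {c})")
        th = np.deg2rad(azimuth_deg)
        ux, uy = np.sin(th), np.cos(th)
        t = np.sqrt((1.0 - (z_mm / c) ** 2) / ((ux / a) ** 2 + (uy / b) ** 2))
        return self._c + np.array([t * ux, t * uy, z_mm])

    def tangent(self, p: np.ndarray, direction: np.ndarray) -> np.ndarray:
        """Unit tangent at p: direction with its normal component removed."""
        n = self.normal(p)
        d = np.asarray(direction, dtype=float)
        t = d - np.dot(d, n) * n
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            raise ValueError("direction is (anti)parallel to the surface normal")
        return t / nt

    def walk(
        self,
        p: np.ndarray,
        direction: np.ndarray,
        distance_mm: float,
        step_mm: float = 0.25,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Walk a geodesic-approximating path of given arc length.

        Steps in the tangent plane and reprojects; the step direction is
        parallel-transported (reprojected to each new tangent plane), so the
        walk passes smoothly through points where the initial direction field
        would be singular (e.g. the vertex for a 'superior' walk).

        Returns (end point, end direction).
        """
        p = self.project(np.asarray(p, dtype=float))
        v = self.tangent(p, direction)
        remaining = float(distance_mm)
        sign = 1.0
        if remaining < 0:
            sign, remaining = -1.0, -remaining
        while remaining > 1e-9:
            h = min(step_mm, remaining)
            p = self.project(p + sign * h * v)
            n = self.normal(p)
            v = v - np.dot(v, n) * n
            nv = np.linalg.norm(v)
            if nv < 1e-12:
                raise RuntimeError("geodesic walk lost its direction")
            v = v / nv
            remaining -= h
        return p, v

    def surface_distance(self, p: np.ndarray, q: np.ndarray, n_seg: int = 256) -> float:
        """Arc length of the projected chord path between two surface points.

        For points within a hemisphere of each other this approximates the
        geodesic to a fraction of a millimetre, which is all the placement
        logic needs.
        """
        p = self.project(p)
        q = self.project(q)
        ts = np.linspace(0.0, 1.0, n_seg + 1)[:, None]
        pts = p[None, :] * (1 - ts) + q[None, :] * ts
        v = (pts - self._c) / self._axes
        r = np.linalg.norm(v, axis=1, keepdims=True)
        pts = self._c + (pts - self._c) / r
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def superior_tangent(self, p: np.ndarray) -> np.ndarray:
        """Unit tangent pointing toward the vertex (undefined at the vertex)."""
        return self.tangent(p, _Z)

    def posterior_tangent(self, p: np.ndarray) -> np.ndarray:
        return self.tangent(p, np.array([0.0, -1.0, 0.0]))

    def azimuthal_tangent(self, p: np.ndarray) -> np.ndarray:
        """Unit tangent along the horizontal ring through p (toward +azimuth)."""
        v = np.asarray(p, dtype=float) - self._c
        d = np.array([v[1], -v[0], 0.0])
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise ValueError("azimuthal direction undefined on the polar axis")
        return self.tangent(p, d / nd)
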