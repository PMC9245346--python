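"""Voxel containers shared by all stages of the pipeline.

Everything lives on a regular rectilinear lattice in world RAS millimetre
coordinates.  Voxel indices are 0-based and internal; public APIs speak
world mm.  The affine maps voxel index -> world mm (homogeneous 4x4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Canonical tissue label ids.  The phantom builder emits the first six;
# pathology insertion and virtual skull-remodeling surgery add the rest.
BACKGROUND = 0
SCALP = 1
SKULL = 2
CSF = 3
GM = 4
WM = 5
RESECTION_CAVITY = 6
FUNNEL = 7
RESIDUAL_TUMOR = 8
BURR_HOLE = 9

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    SCALP: "scalp",
    SKULL: "skull",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
    RESECTION_CAVITY: "resection_cavity",
    FUNNEL: "funnel",
    RESIDUAL_TUMOR: "residual_tumor",
    BURR_HOLE: "burr_hole",
}

#: Brain parenchyma labels (used for region masks and placement checks).
BRAIN_LABELS = (GM, WM)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    return affine


@dataclass
class LabelVolume:
    """3-D integer tissue-label grid with world affine (RAS, mm)."""

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_names")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers as three broadcastable axes.

        Valid for axis-aligned affines (all phantoms are); returns 1-D arrays
        xs, ys, zs so masks can be built without materialising an (nx,ny,nz,3)
        array.
        """
        R = self.affine[:3, :3]
        if not np.allclose(R, np.diag(np.diag(R))):
            raise ValueError("voxel_centers_world requires an axis-aligned affine")
        d = np.diag(R)
        t = self.affine[:3, 3]
        nx, ny, nz = self.labels.shape
        xs = t[0] + d[0] * np.arange(nx)
        ys = t[1] + d[1] * np.arange(ny)
        zs = t[2] + d[2] * np.arange(nz)
        return xs, ys, zs

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def mask(self, *labels_: int) -> np.ndarray:
        return np.isin(self.labels, labels_)

    def copy(self) -> "LabelVolume":
        return replace(
            self,
            labels=self.labels.copy(),
            affine=self.affine.copy(),
            label_names=dict(self.label_names),
            meta=dict(self.meta),
        )


@dataclass
class ConductivityVolume:
    """Per-voxel isotropic conductivity (S/m) on a LabelVolume lattice.

    Background voxels carry sigma == 0 and are excluded from the solve domain.
    """

    sigma: np.ndarray
    affine: np.ndarray
    source: LabelVolume | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 3:
            raise ValueError("sigma must be a 3-D array")
        self.affine = _check_affine(self.affine)
        if np.any(self.sigma < 0) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("conductivities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy(self) -> "ConductivityVolume":
        return ConductivityVolume(self.sigma.copy(), self.affine.copy(), self.source)
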