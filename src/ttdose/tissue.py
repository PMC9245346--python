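"""Tissue label -> isotropic conductivity mapping.

Literature values at the TTFields operating frequency (~200 kHz), treated as
purely ohmic: skin 0.25 S/m, merged skull bone 0.010 S/m (spongy 0.025 /
compact 0.008 when modelled as two layers), CSF 1.654 S/m, gray matter
0.276 S/m, white matter 0.126 S/m, residual tumor 0.24 S/m, necrotic/fluid
resection cavity 1.0 S/m.  The surgical funnel track and the burr holes are
assumed CSF-filled (1.654 S/m) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BACKGROUND, ConductivityVolume, LabelVolume

DEFAULT_CONDUCTIVITIES_S_PER_M: dict[str, float] = {
    "scalp": 0.25,
    "skull": 0.010,  # merged spongy + compact bone
    "csf": 1.654,
    "gm": 0.276,
    "wm": 0.126,
    "resection_cavity": 1.0,
    "funnel": 1.654,
    "residual_tumor": 0.24,
    "burr_hole": 1.654,
}

#: Two-layer skull alternative (outer compact / inner spongy), exposed for
#: users who rasterise the skull as separate compartments.
SPONGY_BONE_S_PER_M = 0.025
COMPACT_BONE_S_PER_M = 0.008


@dataclass(frozen=True)
class TissueTable:
    """Map tissue name -> conductivity sigma (S/m); all values positive."""

    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES_S_PER_M)
    )

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"conductivity for {name!r} must be positive, got {v}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_value(self, name: str, value: float) -> "TissueTable":
        if value <= 0:
            raise ValueError("conductivity must be positive")
        vals = dict(self.values)
        vals[name] = float(value)
        return TissueTable(vals)


def assign_conductivities(
    vol: LabelVolume, table: TissueTable | None = None
) -> ConductivityVolume:
    """Voxelwise lookup of conductivity by tissue label.

    Background stays at sigma == 0 (non-conducting, excluded from the solve
    domain).  Raises if a non-background label present in the volume has no
    table entry.
    """
    table = table or TissueTable()
    present = np.unique(vol.labels)
    lut = np.zeros(int(present.max()) + 1, dtype=float)
    for lab in present.tolist():
        if lab == BACKGROUND:
            continue
        name = vol.label_names.get(lab)
        if name is None or name not in table.values:
            raise KeyError(
                f"label {lab} ({name or 'unnamed'}) has no conductivity table entry"
            )
        lut[lab] = table[name]
    sigma = lut[vol.labels]
    return ConductivityVolume(sigma, vol.affine.copy(), source=vol)


def override_conductivity(
    cv: ConductivityVolume, label: int | str, value: float
) -> ConductivityVolume:
    """Return a new volume with one tissue's conductivity replaced.

    ``label`` may be a label id or a tissue name (resolved through the source
    label volume).  Only voxels of that label change; overriding background
    is rejected (it is not part of the conductive domain).
    """
    if value <= 0 or not np.isfinite(value):
        raise ValueError(f"override conductivity must be positive, got {value}")
    if cv.source is None:
        raise ValueError("override requires a ConductivityVolume with a source LabelVolume")
    if isinstance(label, str):
        ids = [k for k, v in cv.source.label_names.items() if v == label]
        if not ids:
            raise KeyError(f"unknown tissue name {label!r}")
        label_id = ids[0]
    else:
        label_id = int(label)
    if label_id == BACKGROUND:
        raise ValueError("background is not part of the conductive domain")
    out = cv.copy()
    out.sigma[cv.source.labels == label_id] = float(value)
    return out
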