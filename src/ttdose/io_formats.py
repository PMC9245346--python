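"""File formats and configuration plumbing.

Label and field volumes travel as NIfTI-1 (optionally .nii.gz) with a JSON
sidecar mapping label ids to tissue names; run configuration is YAML/JSON
with defaults equal to the study parameters (0.9 A drive, 20 mm / 1 mm
discs at 45 x 22 mm pitch, 15 mm holes on a 45 mm quincunx, burr-hole
conductivity uncertainty uniform on [0.465, 1.654] S/m).  Every output
manifest embeds a hash of the canonicalised configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .tissue import DEFAULT_CONDUCTIVITIES_S_PER_M
from .uq import UNIFORM_HI_S_PER_M, UNIFORM_LO_S_PER_M
from .volume import LABEL_NAMES, ConductivityVolume, LabelVolume


def write_volume(
    vol: LabelVolume | ConductivityVolume | np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> Path:
    """Write a label, conductivity or field grid as NIfTI-1.

    Label volumes also get a ``<stem>.labels.json`` sidecar with the label
    table.  Integer data round-trips bit-exactly; floats are stored as
    float64.
    """
    path = Path(path)
    if isinstance(vol, LabelVolume):
        img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
        nib.save(img, str(path))
        sidecar = _sidecar_path(path)
        sidecar.write_text(
            json.dumps({str(k): v for k, v in vol.label_names.items()}, indent=2)
        )
        return path
    if isinstance(vol, ConductivityVolume):
        data, aff = vol.sigma, vol.affine
    else:
        if affine is None:
            raise ValueError("writing a bare array requires an affine")
        data, aff = np.asarray(vol), affine
    nib.save(nib.Nifti1Image(data.astype(np.float64), aff), str(path))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".labels.json")
    return path.with_suffix(".labels.json")


def read_label_volume(path: str | Path, labels_path: str | Path | None = None) -> LabelVolume:
    """Read a NIfTI label volume plus its label-table sidecar.

    Rejects non-integer data and volumes carrying a label id with no name in
    the sidecar (or in the built-in table when no sidecar exists).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path} does not contain integer label data")
    data = np.round(data).astype(np.int16)
    sidecar = Path(labels_path) if labels_path else _sidecar_path(path)
    if sidecar.exists():
        names = {int(k): str(v) for k, v in json.loads(sidecar.read_text()).items()}
    else:
        names = dict(LABEL_NAMES)
    present = set(np.unique(data).tolist())
    unknown = present - set(names)
    if unknown:
        raise ValueError(
            f"{path} contains label ids {sorted(unknown)} with no entry in the label "
            f"table (expected a sidecar at {sidecar})"
        )
    return LabelVolume(data, np.asarray(img.affine, dtype=float), names)


def read_field_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(Path(path)))
    return np.asanyarray(img.dataobj).astype(float), np.asarray(img.affine, dtype=float)


# --------------------------------------------------------------------------
# Run configuration

@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable run description; defaults are the study parameters."""

    voxel_size_mm: float = 2.0
    sr_variant: str = "over_tumor"
    layout_family: str = "circumferential"
    layout_parameter: float = 60.0
    current_A: float = 0.9
    disc_diameter_mm: float = 20.0
    disc_height_mm: float = 1.0
    array_pitch_mm: tuple[float, float] = (45.0, 22.0)
    hole_diameter_mm: float = 15.0
    quincunx_span_mm: float = 45.0
    cap_sigma_S_per_m: float = 500.0
    solver_rtol: float = 1e-8
    peritumoral_margin_mm: float = 10.0
    conductivities_S_per_m: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES_S_PER_M)
    )
    uq_interval_S_per_m: tuple[float, float] = (UNIFORM_LO_S_PER_M, UNIFORM_HI_S_PER_M)
    uq_draws: int = 64
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_CONFIG_FIELDS = set(RunConfig.__dataclass_fields__)


def load_config(path: str | Path | None = None, strict: bool = True, **overrides) -> RunConfig:
    """Load YAML/JSON config, filling defaults from the study parameters.

    Unknown keys are rejected in strict mode (default) or dropped with a
    warning otherwise; invalid values (negative current, bad variant) raise.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
    raw.update(overrides)
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        if strict:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        import warnings

        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        raw = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    for tup_key in ("array_pitch_mm", "uq_interval_S_per_m"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    cfg = RunConfig(**raw)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: RunConfig) -> None:
    problems = []
    if cfg.current_A <= 0:
        problems.append("current_A must be positive")
    if cfg.voxel_size_mm <= 0:
        problems.append("voxel_size_mm must be positive")
    if cfg.disc_diameter_mm <= 0 or cfg.disc_height_mm <= 0:
        problems.append("disc geometry must be positive")
    if cfg.hole_diameter_mm <= 0 or cfg.quincunx_span_mm <= 0:
        problems.append("burr-hole geometry must be positive")
    lo, hi = cfg.uq_interval_S_per_m
    if not (0 < lo <= hi):
        problems.append("uq interval must satisfy 0 < lo <= hi")
    if cfg.uq_draws < 2:
        problems.append("uq_draws must be >= 2")
    if any(v <= 0 for v in cfg.conductivities_S_per_m.values()):
        problems.append("all conductivities must be positive")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))


def config_hash(config: dict | RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a configuration."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(blob).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
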