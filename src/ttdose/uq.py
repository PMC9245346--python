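"""Monte-Carlo uncertainty quantification over the burr-hole conductivity.

The burr-hole filling (scar tissue, fluid, regrown bone) has an uncertain
conductivity assumed to lie somewhere between skin and CSF; it is modelled
as uniform on [0.465, 1.654] S/m.  All other tissue conductivities are held
fixed.  For each seeded draw the forward problem is re-solved and the
voxelwise mean and (n-1)-denominator standard deviation of the field
intensity are accumulated.

A single uncertain scalar makes plain Monte Carlo adequate; the draws reuse
the previous solution as the CG warm start, so a UQ run costs far less than
n independent solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .electrodes import TransducerArray
from .solver import FieldSolution, solve_fields
from .tissue import override_conductivity
from .volume import ConductivityVolume

UNIFORM_LO_S_PER_M = 0.465
UNIFORM_HI_S_PER_M = 1.654


@dataclass(frozen=True)
class UQSpec:
    """Uniform conductivity uncertainty on one tissue label."""

    target_label: str = "burr_hole"
    sigma_lo_S_per_m: float = UNIFORM_LO_S_PER_M
    sigma_hi_S_per_m: float = UNIFORM_HI_S_PER_M
    n_draws: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_lo_S_per_m <= self.sigma_hi_S_per_m):
            raise ValueError("need 0 < sigma_lo <= sigma_hi")
        if self.n_draws < 2:
            raise ValueError("at least 2 draws are required for a standard deviation")


@dataclass
class UQResult:
    """Voxelwise and per-region moments of |E| over the conductivity draws."""

    mean_E: np.ndarray  # V/m
    sd_E: np.ndarray  # V/m, (n-1) denominator
    draws_S_per_m: np.ndarray
    n_draws: int
    seed: int
    region_summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def relative_sd(self, mask: np.ndarray, floor_V_per_m: float = 1.0) -> np.ndarray:
        """Voxelwise SD/mean on a mask, excluding near-zero-mean voxels."""
        m = mask & (self.mean_E >= floor_V_per_m)
        return self.sd_E[m] / self.mean_E[m]


def run_uq(
    cv: ConductivityVolume,
    pair: tuple[TransducerArray, TransducerArray],
    spec: UQSpec,
    regions: dict[str, np.ndarray] | None = None,
    current_A: float = 0.9,
    solve_fn: Callable[..., FieldSolution] | None = None,
) -> UQResult:
    """Seeded Monte Carlo over the target tissue's conductivity.

    ``solve_fn(cv, pair, current_A, x0=...)`` may be injected for testing;
    the default is the package solver with warm starts between draws.
    Deterministic for a fixed seed.  Any solver failure aborts carrying the
    draw index.
    """
    if cv.source is None:
        raise ValueError("UQ requires a ConductivityVolume with a source LabelVolume")
    names = set(cv.source.label_names.values())
    if spec.target_label not in names:
        raise ValueError(f"target label {spec.target_label!r} unknown to the volume")
    target_ids = [
        k for k, v in cv.source.label_names.items() if v == spec.target_label
    ]
    if not any(np.any(cv.source.labels == t) for t in target_ids):
        raise ValueError(f"volume contains no {spec.target_label!r} voxels")

    rng = np.random.default_rng(spec.seed)
    draws = rng.uniform(spec.sigma_lo_S_per_m, spec.sigma_hi_S_per_m, spec.n_draws)
    solve = solve_fn or solve_fields

    s = None
    s2 = None
    x0 = None
    for i, sigma in enumerate(draws):
        cvi = override_conductivity(cv, spec.target_label, float(sigma))
        try:
            if solve_fn is None:
                sol = solve(cvi, pair, current_A, x0=x0)
                x0 = sol.diagnostics.get("unknown_vector")
            else:
                sol = solve(cvi, pair, current_A)
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(f"solver failed at draw {i} (sigma={sigma:.4f} S/m)") from exc
        e = sol.norm_E
        if s is None:
            s = np.zeros_like(e)
            s2 = np.zeros_like(e)
        s += e
        s2 += e * e

    n = spec.n_draws
    mean = s / n
    var = np.maximum(s2 - n * mean * mean, 0.0) / (n - 1)
    sd = np.sqrt(var)
    result = UQResult(mean, sd, draws, n, spec.seed)
    if regions:
        for name, mask in regions.items():
            mm = float(np.mean(mean[mask])) if np.any(mask) else float("nan")
            ms = float(np.mean(sd[mask])) if np.any(mask) else float("nan")
            rel = result.relative_sd(mask)
            result.region_summary[name] = {
                "mean_V_per_m": mm,
                "sd_V_per_m": ms,
                "median_relative_sd_pct": float(100.0 * np.median(rel)) if rel.size else float("nan"),
            }
    return result
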