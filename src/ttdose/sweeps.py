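"""Experiment orchestration: SR-surgery variants x array-layout grids.

A plan solves every (variant, layout) cell at a fixed resolution, always
against a matched control (identical array geometry, no burr holes), and
collects per-region medians, peaks and enhancements into one tidy table.
Cells are pure functions of the configuration, so results are
order-independent and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .dosimetry import derive_regions, enhancement, region_stats
from .electrodes import family_grid, layout_pair
from .phantom import (
    SR_VARIANTS,
    HeadGeometry,
    PathologySpec,
    apply_sr_surgery,
    build_head_phantom,
    default_pathology,
    insert_pathology,
    place_quincunx,
)
from .solver import solve_fields
from .tissue import TissueTable, assign_conductivities

TABLE_COLUMNS = [
    "sr_variant",
    "family",
    "parameter",
    "region",
    "median_V_per_m",
    "peak_V_per_m",
    "delta_median_V_per_m",
    "pct_enhancement",
]


@dataclass(frozen=True)
class ExperimentPlan:
    """One sweep: which SR variants, which layout family/grid, what lattice."""

    sr_variants: tuple[str, ...] = ("over_tumor", "none")
    family: str = "circumferential"
    parameters: tuple[float, ...] | None = None  # None -> the family's full grid
    voxel_size_mm: float = 3.0
    current_A: float = 0.9
    peritumoral_margin_mm: float = 10.0
    rtol: float = 1e-8
    seed: int = 0  # forwarded to UQ sub-runs; the sweep itself is deterministic

    def __post_init__(self) -> None:
        bad = set(self.sr_variants) - set(SR_VARIANTS)
        if bad:
            raise ValueError(f"unknown SR variants: {sorted(bad)}")

    def grid(self) -> tuple[float, ...]:
        return self.parameters if self.parameters is not None else family_grid(self.family)

    def needs_control(self) -> bool:
        return any(v != "none" for v in self.sr_variants)


@dataclass
class SweepResult:
    table: pd.DataFrame
    manifest: dict
    controls: dict[float, object] = dc_field(default_factory=dict)  # parameter -> FieldSolution


def run_plan(
    plan: ExperimentPlan,
    geom: HeadGeometry | None = None,
    pathology: PathologySpec | None = None,
    table: TissueTable | None = None,
    out_dir: str | Path | None = None,
    keep_controls: bool = False,
) -> SweepResult:
    """Execute the plan: phantom -> conductivities -> layouts -> solves ->
    dose table, with every enhancement computed against the matched control.

    A failed solve marks its cell in the manifest and the sweep continues.
    """
    geom = geom or HeadGeometry()
    pathology = pathology or default_pathology(geom)
    base = insert_pathology(build_head_phantom(geom, plan.voxel_size_mm), pathology)
    regions = derive_regions(base, plan.peritumoral_margin_mm)

    variants = list(plan.sr_variants)
    if plan.needs_control() and "none" not in variants:
        variants.append("none")  # enhancement always needs the matched control

    volumes = {}
    for v in variants:
        q = place_quincunx(v, geom, pathology)
        volumes[v] = base if q is None else apply_sr_surgery(base, q)

    grid = plan.grid()
    rows: list[dict] = []
    failed: list[dict] = []
    controls: dict[float, object] = {}

    cv_none = assign_conductivities(volumes.get("none", base), table)
    for p in grid:
        pair = layout_pair(plan.family, p, geom)
        try:
            sol = solve_fields(cv_none, pair, plan.current_A, rtol=plan.rtol)
        except Exception as exc:
            failed.append({"sr_variant": "none", "parameter": p, "error": str(exc)})
            continue
        sol.diagnostics["layout_key"] = (plan.family, p)
        controls[p] = sol
        if "none" in plan.sr_variants:
            rep = region_stats(sol, regions)
            for name, rd in rep.regions.items():
                rows.append(
                    {
                        "sr_variant": "none",
                        "family": plan.family,
                        "parameter": p,
                        "region": name,
                        "median_V_per_m": rd.median_V_per_m,
                        "peak_V_per_m": rd.peak_V_per_m,
                        "delta_median_V_per_m": 0.0,
                        "pct_enhancement": 0.0,
                    }
                )

    for v in variants:
        if v == "none":
            continue
        cv = assign_conductivities(volumes[v], table)
        for p in grid:
            if p not in controls:
                failed.append({"sr_variant": v, "parameter": p, "error": "control solve failed"})
                continue
            pair = layout_pair(plan.family, p, geom)
            try:
                sol = solve_fields(cv, pair, plan.current_A, rtol=plan.rtol)
            except Exception as exc:
                failed.append({"sr_variant": v, "parameter": p, "error": str(exc)})
                continue
            sol.diagnostics["layout_key"] = (plan.family, p)
            rep = region_stats(sol, regions)
            enh = enhancement(sol, controls[p], regions)
            for name, rd in rep.regions.items():
                re_ = enh.regions[name]
                rows.append(
                    {
                        "sr_variant": v,
                        "family": plan.family,
                        "parameter": p,
                        "region": name,
                        "median_V_per_m": rd.median_V_per_m,
                        "peak_V_per_m": rd.peak_V_per_m,
                        "delta_median_V_per_m": re_.delta_median_V_per_m,
                        "pct_enhancement": re_.pct_of_control,
                    }
                )

    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    config = {
        "plan": {
            "sr_variants": list(plan.sr_variants),
            "family": plan.family,
            "parameters": [float(x) for x in grid],
            "voxel_size_mm": plan.voxel_size_mm,
            "current_A": plan.current_A,
            "peritumoral_margin_mm": plan.peritumoral_margin_mm,
            "rtol": plan.rtol,
            "seed": plan.seed,
        },
        "geometry": {
            "semi_axes_mm": list(geom.semi_axes_mm),
            "shell_thicknesses_mm": list(geom.shell_thicknesses),
        },
    }
    manifest = {
        "config": config,
        "config_hash": io_formats.config_hash(config),
        "n_cells": len(variants) * len(grid),
        "failed_cells": failed,
    }
    result = SweepResult(df, manifest, controls if keep_controls else {})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


# --------------------------------------------------------------------------
# Rule-of-thumb report

RULES = (
    "localization",
    "overlap_benefit",
    "far_hole_futility",
    "shunting_monotonicity",
    "normal_rotation_tolerance",
    "uq_smallness",
)


def _rule(status: str, detail: str) -> dict:
    return {"status": status, "detail": detail}


def summarize_rules(table: pd.DataFrame, extras: dict | None = None) -> dict:
    """Map the placement rules of thumb to quantitative pass/fail predicates
    over a sweep table.

    Rules needing voxelwise maps (localization) or UQ runs are evaluated from
    ``extras`` when provided (keys ``localization_ratio``,
    ``uq_median_relative_sd_pct``) and reported unevaluable otherwise.
    """
    extras = extras or {}
    report: dict[str, dict] = {}
    if table is None or len(table) == 0:
        for r in RULES:
            report[r] = _rule("unevaluable", "empty sweep table")
        report["all_evaluable"] = False
        return report

    def sel(**kw):
        m = pd.Series(True, index=table.index)
        for k, v in kw.items():
            m &= table[k] == v
        return table[m]

    # 1. Localization: enhancement concentrates under the holes (>= 5x).
    ratio = extras.get("localization_ratio")
    if ratio is None:
        report["localization"] = _rule("unevaluable", "needs voxelwise enhancement maps")
    else:
        ok = ratio >= 5.0
        report["localization"] = _rule(
            "pass" if ok else "fail",
            f"mean dE under holes / elsewhere = {ratio:.1f} (require >= 5)",
        )

    # 2. Overlap benefit: over-tumor holes at the 60-degree layout raise the
    # tumor median strictly above control, and the best circumferential angle
    # for tumor enhancement lies in 45-105 degrees.
    cell = sel(sr_variant="over_tumor", family="circumferential", parameter=60.0,
               region="residual_tumor")
    if len(cell) == 0:
        report["overlap_benefit"] = _rule("unevaluable", "over_tumor @ 60 deg not in table")
    else:
        d = float(cell["delta_median_V_per_m"].iloc[0])
        tumor = sel(sr_variant="over_tumor", family="circumferential", region="residual_tumor")
        best = float(tumor.loc[tumor["pct_enhancement"].idxmax(), "parameter"])
        ok = d > 0 and 45.0 <= best <= 105.0
        report["overlap_benefit"] = _rule(
            "pass" if ok else "fail",
            f"tumor delta at 60 deg = {d:.1f} V/m; best angle = {best:.0f} deg",
        )

    # 3. Far-hole futility: distant holes never enhance the tumor by >= 10%.
    far = sel(sr_variant="far", region="residual_tumor")
    if len(far) == 0:
        report["far_hole_futility"] = _rule("unevaluable", "far variant not in table")
    else:
        worst = float(far["pct_enhancement"].max())
        report["far_hole_futility"] = _rule(
            "pass" if worst < 10.0 else "fail",
            f"max tumor enhancement with far holes = {worst:.1f}% (require < 10%)",
        )

    # 4. Shunting: brain medians fall monotonically with vertex travel and
    # collapse (< 5% of the start) when the arrays meet.
    vt = table[table["family"] == "vertex_translation"]
    if len(vt) == 0:
        report["shunting_monotonicity"] = _rule("unevaluable", "vertex family not in table")
    else:
        variant = "none" if "none" in set(vt["sr_variant"]) else vt["sr_variant"].iloc[0]
        ok = True
        details = []
        for region in ("wm", "gm"):
            sub = vt[(vt["sr_variant"] == variant) & (vt["region"] == region)]
            sub = sub.sort_values("parameter")
            med = sub["median_V_per_m"].to_numpy()
            mono = bool(np.all(np.diff(med) <= 1e-9 + 0.0 * med[:-1]))
            collapse = med[-1] < 0.05 * med[0]
            ok &= mono and collapse
            details.append(f"{region}: last/first = {med[-1] / med[0]:.3f}, monotone={mono}")
        report["shunting_monotonicity"] = _rule("pass" if ok else "fail", "; ".join(details))

    # 5. Normal-rotation tolerance: without holes, spinning the ipsilateral
    # array changes no region median by >= 5%.
    nr = sel(sr_variant="none", family="normal_rotation")
    if len(nr) == 0:
        report["normal_rotation_tolerance"] = _rule(
            "unevaluable", "control normal-rotation rows not in table"
        )
    else:
        worst = 0.0
        for region, sub in nr.groupby("region"):
            med = sub["median_V_per_m"].to_numpy()
            worst = max(worst, float((med.max() - med.min()) / med.min()))
        report["normal_rotation_tolerance"] = _rule(
            "pass" if worst < 0.05 else "fail",
            f"max relative median spread across angles = {100 * worst:.2f}% (require < 5%)",
        )

    # 6. UQ smallness: burr-hole conductivity uncertainty moves the field by
    # < 10% (relative SD) in the region of interest.
    uq = extras.get("uq_median_relative_sd_pct")
    if uq is None:
        report["uq_smallness"] = _rule("unevaluable", "needs a UQ run")
    else:
        report["uq_smallness"] = _rule(
            "pass" if uq <= 10.0 else "fail",
            f"median relative SD under the holes = {uq:.1f}% (require <= 10%)",
        )

    report["all_evaluable"] = all(
        report[r]["status"] != "unevaluable" for r in RULES
    )
    return report
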