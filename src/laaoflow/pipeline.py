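"""Study orchestration: configuration, scenario runs, comparative report.

A :class:`ScenarioConfig` fully describes one case (anatomy + device +
position + fluid + waveform + solver + ROI).  :func:`run_scenario` executes
the stages anatomy -> implant -> hemo -> transport -> markers and returns a
report row; :func:`run_study` runs a configuration set (by default the
eight occluded scenarios plus the pre-occlusion model) and assembles the
summary table; :func:`compare` emits signed pairwise differences.

Resolution tiers scale the study down from the reference protocol (10
warm-up + 6 evaluation cycles on a fine grid) to a desk-scale regime; the
``test`` tier uses 2 + 2 cycles at 1.75 mm spacing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import anatomy as anat
from . import implant as imp
from . import markers as mk
from . import transport as tp
from .anatomy import AnatomyParams, build_anatomy, build_roi, discretize
from .hemo import (MM, AfWaveform, FlowSolver, FluidProperties, SolverSettings,
                   _plane_flux, reynolds_check, wall_shear, waveform_inflow)


@dataclass(frozen=True)
class Tier:
    spacing: float
    warmup_cycles: int
    eval_cycles: int
    dt: float = 0.005
    save_stride: int = 2


TIERS = {
    "test": Tier(spacing=2.0, warmup_cycles=2, eval_cycles=2),
    "standard": Tier(spacing=1.25, warmup_cycles=10, eval_cycles=6),
    "fine": Tier(spacing=1.0, warmup_cycles=10, eval_cycles=6, save_stride=1),
}


@dataclass
class ScenarioConfig:
    """Declarative description of one simulated case."""

    scenario_id: str
    anatomy_params: AnatomyParams = field(default_factory=AnatomyParams)
    device: imp.DeviceSpec | None = None
    placement_kwargs: dict | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)
    waveform: AfWaveform = field(default_factory=AfWaveform)
    solver: SolverSettings = field(default_factory=SolverSettings)
    grid_spacing: float = 2.0
    roi_diameter: float = 40.0
    accommodation_band: float = 4.0

    def __post_init__(self):
        if self.device is not None and self.placement_kwargs is None:
            raise ValueError("a device requires a placement")

    def with_tier(self, tier: str | Tier) -> "ScenarioConfig":
        t = TIERS[tier] if isinstance(tier, str) else tier
        cfg = dataclasses.replace(self)
        cfg.grid_spacing = t.spacing
        cfg.solver = dataclasses.replace(
            self.solver, dt=t.dt, warmup_cycles=t.warmup_cycles,
            eval_cycles=t.eval_cycles, save_stride=t.save_stride)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.device is not None:
            d["device"] = asdict(self.device)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        ap = d.get("anatomy_params")
        if isinstance(ap, dict):
            ap = dict(ap)
            ap["pv_tubes"] = tuple(anat.Tube(**t) if isinstance(t, dict) else t
                                   for t in ap.get("pv_tubes", ()))
            mv = ap.get("mv_tube")
            if isinstance(mv, dict):
                ap["mv_tube"] = anat.Tube(**mv)
            d["anatomy_params"] = AnatomyParams(**ap)
        if isinstance(d.get("device"), dict):
            d["device"] = imp.DeviceSpec(**d["device"])
        for key, typ in (("fluid", FluidProperties), ("waveform", AfWaveform),
                         ("solver", SolverSettings)):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        s = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(s.encode()).hexdigest()[:16]


def scenario_suite(tier: str | Tier | None = None, **overrides):
    """The built-in suite of nine scenario configurations."""
    configs = imp.scenario_suite(**overrides)
    if tier is not None:
        configs = [c.with_tier(tier) for c in configs]
    return configs


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    row: dict
    times: np.ndarray | None = None
    phi_roi: np.ndarray | None = None
    phi_domain: np.ndarray | None = None
    wall: mk.WallMetricMap | None = None
    position: imp.PositionMetrics | None = None
    max_reynolds: float = 0.0
    mass_residual_max: float = 0.0
    cycle_drift: float | None = None
    warnings: list = field(default_factory=list)
    error: str | None = None
    elapsed: float = 0.0


def run_scenario(config: ScenarioConfig, keep_fields: bool = False) -> ScenarioResult:
    """Execute one scenario end to end and assemble its report row."""
    t_start = time.perf_counter()
    notes = []
    anatomy = build_anatomy(config.anatomy_params)
    grid = discretize(anatomy, config.grid_spacing)

    placement = None
    position = None
    exclusion = None
    if config.device is not None:
        placement = imp.make_placement(anatomy, **config.placement_kwargs)
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            dep = imp.deploy(config.device, placement, grid,
                             accommodation_band=config.accommodation_band)
        notes.extend(str(w.message) for w in wrec)
        position = imp.measure_position(placement, config.device, anatomy,
                                        compression=dep.compression_rate)
        exclusion = (placement.anchor, placement.axis, config.device.distal_extent)

    roi = build_roi(grid, exclusion=exclusion, diameter=config.roi_diameter)
    sim = _simulate(config, anatomy, grid, roi, placement)
    notes.extend(sim["notes"])

    washout = {
        "halftime": tp.washout_halftime(sim["times"], sim["phi_roi"]),
        "phi_final": float(sim["phi_roi"][-1]),
    }
    if washout["halftime"][1]:
        notes.append("washout half-time censored within the evaluation window")

    row = mk.build_report_row(
        config.scenario_id, flow_stats=sim["flow_stats"], washout=washout,
        wall=sim["wall"], position=position, laa_influx=sim["laa_influx"])
    return ScenarioResult(
        config=config, row=row, times=sim["times"], phi_roi=sim["phi_roi"],
        phi_domain=sim["phi_domain"], wall=sim["wall"], position=position,
        max_reynolds=sim["max_re"], mass_residual_max=sim["mass_residual_max"],
        cycle_drift=sim["cycle_drift"], warnings=notes,
        elapsed=time.perf_counter() - t_start)


def _roi_face_subset(grid, roi, exclusion):
    table = grid.wall_face_table()
    c = table["centroid"]
    sel = np.linalg.norm(c - roi.center, axis=1) <= roi.radius
    if exclusion is not None and grid.anatomy is not None:
        anchor, axis, distal_s = exclusion
        s = (c - np.asarray(anchor)) @ np.asarray(axis)
        sel &= ~((s > distal_s) & grid.anatomy.in_laa(c))
    return table, sel


def _simulate(config, anatomy, grid, roi, placement):
    """Warm-up + evaluation cycles with on-the-fly marker recording."""
    wf = config.waveform
    settings = config.solver
    solver = FlowSolver(grid, props=config.fluid, settings=settings,
                        inflow=waveform_inflow(anatomy, wf))
    state = solver.initial_state()
    solver.apply_inlet(state, 0.0)

    steps_per_cycle = int(round(wf.cycle_period / settings.dt))
    n_warm = settings.warmup_cycles * steps_per_cycle
    n_eval = settings.eval_cycles * steps_per_cycle

    notes = []
    mass_max = 0.0
    for _ in range(n_warm):
        solver.step(state)
        mass_max = max(mass_max, solver.last_mass_residual)

    # gate for flux entering the occluded appendage compartment: the plane one
    # cell behind the device's distal closure surface (pre-occlusion: one cell
    # behind the ostium plane)
    pts = grid.cell_centers().reshape(-1, 3)
    if placement is not None:
        z = (pts - placement.anchor) @ placement.axis
        gate_s = config.device.distal_extent + grid.spacing
    else:
        z, _ = anatomy.laa_coords(pts)
        gate_s = grid.spacing
    z = z.reshape(grid.shape)
    laa_region = anatomy.in_laa(pts).reshape(grid.shape)

    exclusion_faces = None
    if placement is not None:
        exclusion_faces = (placement.anchor, placement.axis,
                           config.device.distal_extent)
    table, face_sel = _roi_face_subset(grid, roi, exclusion_faces)
    sub = {k: v[face_sel] for k, v in table.items()}

    tracer = tp.init_tracer(grid, 1.0, t=state.t)
    roi_mask = roi.mask
    fluid_all = grid.fluid_mask | (grid.cell_class == anat.SEALED)
    h_m = grid.spacing * MM
    roi_volume_m3 = float(roi_mask.sum()) * h_m ** 3

    times, phi_roi, phi_dom = [], [], []
    speeds, vorts = [], []
    taus = []
    influx = 0.0
    max_re = 0.0
    cycle_speed_means = []
    this_cycle = []

    def record():
        times.append(state.t)
        phi_roi.append(tp.residual_fraction(tracer.c, roi_mask))
        phi_dom.append(tp.residual_fraction(tracer.c, fluid_all))
        uc = solver.cell_velocity(state)
        speed = np.linalg.norm(uc, axis=-1)
        speeds.append(float(speed[roi_mask].mean()))
        w = mk.vorticity(uc, h_m, mask=grid.fluid_mask)
        vorts.append(float(np.linalg.norm(w, axis=-1)[roi_mask].mean()))
        taus.append(wall_shear(state, grid, config.fluid, table=sub))

    record()
    for i in range(n_eval):
        solver.step(state)
        mass_max = max(mass_max, solver.last_mass_residual)
        tracer = tp.advect(tracer, state, grid, settings.dt)
        _, qpos = _plane_flux(state, grid, z, gate_s, region=laa_region)
        influx += qpos * settings.dt
        this_cycle.append(float(solver.max_speed(state)))
        if (i + 1) % settings.save_stride == 0 or i == n_eval - 1:
            record()
        if (i + 1) % steps_per_cycle == 0:
            cycle_speed_means.append(float(np.mean(this_cycle)))
            this_cycle = []
    re = reynolds_check(state, grid, config.fluid)
    max_re = re["max"]

    drift = None
    if len(cycle_speed_means) >= 2 and cycle_speed_means[-1] > 0:
        drift = abs(cycle_speed_means[-1] - cycle_speed_means[-2]) \
            / cycle_speed_means[-1]
        if drift > 0.05:
            notes.append(f"cycle-to-cycle drift {drift:.3f} after warm-up")

    times = np.asarray(times)
    taus = np.asarray(taus)
    # integration period: the last stored cycle
    m_last = times >= times[-1] - wf.cycle_period - 1e-9
    wall = mk.wall_metrics(taus[m_last], times[m_last], sub["centroid"],
                           sub["area"], sub["is_device"])
    flow_stats = mk.roi_flow_stats(times, speeds, vorts, roi_volume_m3,
                                   wf.cycle_period)
    return {
        "times": times - times[0], "phi_roi": np.asarray(phi_roi),
        "phi_domain": np.asarray(phi_dom), "wall": wall,
        "flow_stats": flow_stats, "laa_influx": influx * 1e6,  # mL
        "max_re": max_re, "mass_residual_max": mass_max,
        "cycle_drift": drift, "notes": notes,
    }


def run_study(configs=None, tier: str | Tier | None = "test", outdir=None):
    """Run a configuration set and assemble the comparative report.

    Returns ``(report, results)``.  A failing scenario yields a null row and
    is recorded in its result's ``error``; the others continue.
    """
    if configs is None:
        configs = scenario_suite(tier=tier)
    elif tier is not None:
        configs = [c.with_tier(tier) for c in configs]
    results = {}
    rows = []
    for cfg in configs:
        try:
            res = run_scenario(cfg)
        except Exception as exc:  # noqa: BLE001 - isolate per-scenario failures
            res = ScenarioResult(config=cfg, row=mk.build_report_row(cfg.scenario_id),
                                 error=f"{type(exc).__name__}: {exc}")
        results[cfg.scenario_id] = res
        rows.append(res.row)
    report = mk.build_report(rows)
    if outdir is not None:
        _write_outputs(report, results, outdir)
    return report, results


def _write_outputs(report, results, outdir):
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv", index=False)
    report.to_json(out / "report.json", orient="records", indent=2)
    manifest = {
        "scenarios": {
            sid: {
                "config_hash": r.config.config_hash(),
                "elapsed_s": round(r.elapsed, 2),
                "error": r.error,
                "warnings": r.warnings,
                "max_reynolds": r.max_reynolds,
                "mass_residual_max": r.mass_residual_max,
            }
            for sid, r in results.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


#: pairwise contrasts mirroring the study's qualitative findings
COMPARISON_PAIRS = [
    ("np_ds", "np_os"), ("np_tl", "np_os"), ("np_cl", "np_os"),
    ("sp_ds", "sp_os"), ("lp_ds", "lp_os"),
    ("sp_os", "np_os"), ("lp_os", "np_os"),
]

COMPARISON_MARKERS = ["phi_final", "avg_wss", "avg_ecap", "avg_velocity",
                      "washout_half_time", "frac_area_high_ecap"]


def compare(report: pd.DataFrame, pairs=None, markers=None) -> pd.DataFrame:
    """Signed differences a - b per marker with direction labels."""
    if len(report) < 2:
        raise ValueError("need at least two scenarios to compare")
    pairs = pairs or COMPARISON_PAIRS
    markers = markers or COMPARISON_MARKERS
    idx = report.set_index("scenario")
    out = []
    for a, b in pairs:
        if a not in idx.index or b not in idx.index:
            continue
        for mcol in markers:
            va, vb = idx.at[a, mcol], idx.at[b, mcol]
            if va is None or vb is None or pd.isna(va) or pd.isna(vb):
                continue
            diff = float(va) - float(vb)
            out.append({
                "pair": f"{a}-{b}", "marker": mcol, "a": a, "b": b,
                "value_a": float(va), "value_b": float(vb), "diff": diff,
                "direction": "higher" if diff > 0 else ("lower" if diff < 0 else "equal"),
            })
    return pd.DataFrame(out)
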