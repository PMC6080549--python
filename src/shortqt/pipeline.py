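"""Experiment recipes, configuration and result serialization.

This is the programmatic surface that the numbered analysis scripts (and
any batch runner) call: a validated :class:`RunConfig` selects one of the
shipped recipes — ``figure2`` (single-cell APD/I_Ks/restitution),
``sinus-cable`` (transmural cable CV/wavelength/EAT-EDT), ``reentry-sheet``
(S1–S2 induction, sustainment, rotor and DF analysis) and ``pump``
(calibrated lumped circulation, WT vs mutant) — runs it end-to-end and
writes CSV/JSON results with a provenance record.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .geometry import GeometrySpec, make_sheet, make_transmural_cable
from .ionic import cell_params
from .protocols import (Trace, dynamic_restitution, iks_summary, measure_apd,
                        pace_to_steady_state)
from .pump import calibrate_wt_pump, run_heartbeat, transmural_force
from .reentry import classify_sustainment, df_map, rotation_rate
from .tissue import (StimulusSchedule, _edge_stim, activation_maps,
                     calibrate_conductivity, compute_wavelength,
                     conditioned_tissue_state, measure_cv, s1s2_cross_field,
                     simulate_monodomain)

__all__ = ["RunConfig", "run_experiment", "write_results", "read_results"]

CELL_TYPES = ("endo", "M", "epi")
CONDITIONS = ("wt", "s140g")


class RunConfig(BaseModel):
    """Validated experiment configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    experiment: Literal["figure2", "sinus-cable", "reentry-sheet", "pump"]
    name: str = ""
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    # figure2
    bcl_ms: float = 1000.0
    n_beats: int = 100
    restitution_cell_types: tuple[str, ...] = ("endo",)

    # cable / sheet geometry
    cable_length_cm: float = 2.0
    cable_dx_cm: float = 0.02
    sheet_size_cm: float = 6.4
    sheet_dx_cm: float = 0.05
    target_cv: dict[str, float] = {"wt": 67.4, "s140g": 64.7}
    sinus_bcl_ms: float = 600.0

    # re-entry
    reentry_cv: float = 65.0
    reentry_duration_ms: float = 4200.0
    low_cv: float = 20.0
    include_low_cv_wt: bool = False

    # pump
    pump_cycles: int = 20
    target_sv_ml: float = 58.6
    target_ef_pct: float = 54.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _figure2(cfg: RunConfig) -> dict[str, Any]:
    rows = []
    for ct in CELL_TYPES:
        for cond in cfg.conditions:
            tr = pace_to_steady_state(cell_params(ct, cond), cfg.bcl_ms,
                                      n_beats=cfg.n_beats)
            dur, mean = iks_summary(tr)
            rows.append({"cell_type": ct, "condition": cond,
                         "apd90_ms": measure_apd(tr),
                         "iks_duration_ms": dur,
                         "iks_mean_pA_pF": mean,
                         "alternans": tr.alternans})
    out: dict[str, Any] = {"apd": pd.DataFrame(rows)}
    rcurves = []
    for ct in cfg.restitution_cell_types:
        for cond in cfg.conditions:
            c = dynamic_restitution(cell_params(ct, cond))
            pts = c.points.assign(cell_type=ct, condition=cond)
            rcurves.append(pts)
            out.setdefault("restitution_summary", []).append({
                "cell_type": ct, "condition": cond,
                "max_slope": c.max_slope,
                "alternans_onset_bcl_ms": c.alternans_onset_bcl})
    if rcurves:
        out["restitution"] = pd.concat(rcurves, ignore_index=True)
        out["restitution_summary"] = pd.DataFrame(out["restitution_summary"])
    return out


def _sinus_cable(cfg: RunConfig) -> dict[str, Any]:
    spec = GeometrySpec(shape="cable", length_cm=cfg.cable_length_cm,
                        dx=cfg.cable_dx_cm)
    cable = make_transmural_cable(spec)
    rows = []
    for cond in cfg.conditions:
        g = calibrate_conductivity(cable, cfg.target_cv[cond], cond)
        state = conditioned_tissue_state(g, cond, cfg.sinus_bcl_ms)
        times = np.arange(3) * cfg.sinus_bcl_ms + 5.0
        stim = StimulusSchedule((_edge_stim(g),) * 3, times)
        mid = g.nx // 2
        tr = simulate_monodomain(
            g, cond, stim, 3 * cfg.sinus_bcl_ms, state=state, record_dt=2.0,
            probe_nodes=np.array([mid]), probe_dt=0.2,
            map_start=float(times[-1]))
        cv = measure_cv(tr, g)
        pv = tr.probe_V[:, 0]
        ptr = Trace(tr.probe_t, pv, np.zeros_like(pv), np.zeros_like(pv),
                    times)
        apd = measure_apd(ptr)
        maps = activation_maps(tr, window=(float(times[-1]),
                                           3 * cfg.sinus_bcl_ms))
        rows.append({"condition": cond, "rho_x_kohm_cm": g.rho_x,
                     "cv_cm_s": cv, "apd90_mid_ms": apd,
                     "wavelength_cm": compute_wavelength(cv, apd),
                     "qrs_proxy_ms": maps.qrs_proxy,
                     "qt_proxy_ms": maps.qt_proxy})
    return {"cable": pd.DataFrame(rows)}


def _reentry_sheet(cfg: RunConfig) -> dict[str, Any]:
    spec = GeometrySpec(shape="sheet", length_cm=cfg.sheet_size_cm,
                        width_cm=cfg.sheet_size_cm, dx=cfg.sheet_dx_cm)
    sheet = make_sheet(spec)
    rows = []
    for cond in cfg.conditions:
        g = calibrate_conductivity(sheet, cfg.reentry_cv, cond)
        tr = s1s2_cross_field(g, cond, duration=cfg.reentry_duration_ms)
        sus = classify_sustainment(tr)
        row = {"condition": cond, "cv_cm_s": cfg.reentry_cv,
               "s2_time_ms": tr.s2_time,
               "sustained": sus.sustained,
               "termination_ms": sus.termination_time_ms}
        if sus.sustained:
            dfm = df_map(tr)
            row.update({
                "rotation_hz": rotation_rate(tr.probe_V[:, 0], tr.probe_t),
                "df_mean_hz": dfm.mean, "df_min_hz": dfm.min,
                "df_max_hz": dfm.max, "df_bandwidth_hz": dfm.bandwidth})
        rows.append(row)
    if cfg.include_low_cv_wt:
        g20 = calibrate_conductivity(sheet, cfg.low_cv, "wt")
        tr20 = s1s2_cross_field(g20, "wt", duration=cfg.reentry_duration_ms)
        sus = classify_sustainment(tr20)
        row = {"condition": "wt", "cv_cm_s": cfg.low_cv,
               "s2_time_ms": tr20.s2_time, "sustained": sus.sustained,
               "termination_ms": sus.termination_time_ms}
        if sus.sustained:
            dfm = df_map(tr20)
            row.update({
                "rotation_hz": rotation_rate(tr20.probe_V[:, 0], tr20.probe_t),
                "df_mean_hz": dfm.mean, "df_min_hz": dfm.min,
                "df_max_hz": dfm.max, "df_bandwidth_hz": dfm.bandwidth})
        rows.append(row)
    return {"reentry": pd.DataFrame(rows)}


def _pump(cfg: RunConfig) -> dict[str, Any]:
    par, f_wt = calibrate_wt_pump(cfg.target_sv_ml, cfg.target_ef_pct,
                                  bcl=cfg.sinus_bcl_ms)
    ref = float(f_wt["force"].max())
    rows, loops = [], []
    for cond in cfg.conditions:
        force = f_wt if cond == "wt" else transmural_force(
            cond, bcl=cfg.sinus_bcl_ms)
        res = run_heartbeat(cond, n_cycles=cfg.pump_cycles,
                            bcl=cfg.sinus_bcl_ms, par=par,
                            reference_peak=ref, force=force)
        rows.append({"condition": cond,
                     "stroke_volume_ml": res.stroke_volume,
                     "ejection_fraction_pct": res.ejection_fraction,
                     "edv_ml": res.end_diastolic_volume,
                     "esv_ml": res.end_systolic_volume,
                     "stroke_work_mmHg_ml": res.stroke_work,
                     "atp_rate_per_s": res.atp_rate,
                     "efficiency_mmHg_ml_per_atp": res.efficiency})
        # thin the written loop to 2 ms resolution
        loops.append(res.loop.iloc[::4].assign(condition=cond))
    return {"pump": pd.DataFrame(rows),
            "pv_loops": pd.concat(loops, ignore_index=True)}


_RECIPES = {"figure2": _figure2, "sinus-cable": _sinus_cable,
            "reentry-sheet": _reentry_sheet, "pump": _pump}


def run_experiment(config: RunConfig | dict) -> dict[str, Any]:
    """Execute a recipe end-to-end; returns (and optionally writes) the
    result bundle — a dict of DataFrames plus a provenance record."""
    if isinstance(config, dict):
        try:
            config = RunConfig(**config)
        except ValidationError:
            raise
    np.random.seed(config.seed % (2 ** 31))
    t0 = time.time()
    bundle = _RECIPES[config.experiment](config)
    digest = hashlib.sha256(
        config.model_dump_json().encode()).hexdigest()[:16]
    bundle["provenance"] = {
        "experiment": config.experiment, "name": config.name,
        "config_sha256": digest, "package_version": __version__,
        "seed": config.seed, "runtime_s": round(time.time() - t0, 2),
        "config": json.loads(config.model_dump_json()),
    }
    if config.out_dir:
        write_results(bundle, config.out_dir)
    return bundle


def write_results(bundle: dict[str, Any], path: str | Path) -> None:
    """Write a bundle: DataFrames as CSV, everything else into JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(path / f"{key}.csv", index=False)
        else:
            meta[key] = val
    with open(path / "results.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)


def read_results(path: str | Path) -> dict[str, Any]:
    """Inverse of :func:`write_results` (CSV column schemas preserved)."""
    path = Path(path)
    bundle: dict[str, Any] = {}
    for csv in sorted(path.glob("*.csv")):
        bundle[csv.stem] = pd.read_csv(csv)
    meta = path / "results.json"
    if meta.exists():
        with open(meta) as fh:
            bundle.update(json.load(fh))
    return bundle
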