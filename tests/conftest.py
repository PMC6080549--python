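"""Shared fixtures.  The expensive simulations (paced cells, restitution
curves, calibrated cables, sheet re-entry episodes, pump runs) are
session-scoped so every test reuses one computation."""

from __future__ import annotations

import numpy as np
import pytest

from shortqt.geometry import GeometrySpec, make_sheet, make_transmural_cable
from shortqt.ionic import cell_params
from shortqt.protocols import (Trace, dynamic_restitution, measure_apd,
                               pace_to_steady_state)
from shortqt.pump import calibrate_wt_pump, run_heartbeat, transmural_force
from shortqt.tissue import (StimulusSchedule, _edge_stim, activation_maps,
                            calibrate_conductivity, compute_wavelength,
                            conditioned_tissue_state, measure_cv,
                            s1s2_cross_field, simulate_monodomain)

CELL_TYPES = ("endo", "M", "epi")
CONDITIONS = ("wt", "s140g")


@pytest.fixture(scope="session")
def paced_traces():
    """Steady-state BCL-1000 traces for every cell type and condition."""
    return {(ct, cond): pace_to_steady_state(cell_params(ct, cond), 1000.0)
            for ct in CELL_TYPES for cond in CONDITIONS}


@pytest.fixture(scope="session")
def apd_table(paced_traces):
    return {key: measure_apd(tr) for key, tr in paced_traces.items()}


@pytest.fixture(scope="session")
def restitution_curves():
    """Dynamic restitution of the endocardial cell, both conditions."""
    return {cond: dynamic_restitution(cell_params("endo", cond))
            for cond in CONDITIONS}


@pytest.fixture(scope="session")
def cable_runs():
    """Calibrated transmural cables paced at BCL 600, with metrics."""
    spec = GeometrySpec(shape="cable", length_cm=2.0, dx=0.02)
    cable = make_transmural_cable(spec)
    out = {}
    for cond, target in (("wt", 67.4), ("s140g", 64.7)):
        g = calibrate_conductivity(cable, target, cond)
        state = conditioned_tissue_state(g, cond, 600.0)
        times = np.arange(3) * 600.0 + 5.0
        stim = StimulusSchedule((_edge_stim(g),) * 3, times)
        tr = simulate_monodomain(
            g, cond, stim, 1800.0, state=state, record_dt=2.0,
            probe_nodes=np.array([g.nx // 2]), probe_dt=0.2,
            map_start=float(times[-1]))
        cv = measure_cv(tr, g)
        pv = tr.probe_V[:, 0]
        apd = measure_apd(Trace(tr.probe_t, pv, np.zeros_like(pv),
                                np.zeros_like(pv), times))
        out[cond] = {
            "grid": g, "trace": tr, "cv": cv, "apd": apd,
            "wavelength": compute_wavelength(cv, apd),
            "maps": activation_maps(tr, window=(float(times[-1]), 1800.0)),
        }
    return out


@pytest.fixture(scope="session")
def reentry_sheet_grid():
    spec = GeometrySpec(shape="sheet", length_cm=6.4, width_cm=6.4, dx=0.05)
    return make_sheet(spec)


@pytest.fixture(scope="session")
def mutant_episode(reentry_sheet_grid):
    """Sustained S140G S1–S2 episode at 65 cm/s (4.2 s horizon)."""
    g = calibrate_conductivity(reentry_sheet_grid, 65.0, "s140g")
    return s1s2_cross_field(g, "s140g", duration=4200.0)


@pytest.fixture(scope="session")
def wt_episode(reentry_sheet_grid):
    """Wild-type S1–S2 episode at the same conduction velocity."""
    g = calibrate_conductivity(reentry_sheet_grid, 65.0, "wt")
    return s1s2_cross_field(g, "wt", duration=4200.0)


@pytest.fixture(scope="session")
def pump_runs():
    """Calibrated circulation: WT reference beat and mutant beat."""
    par, f_wt = calibrate_wt_pump()
    ref = float(f_wt["force"].max())
    wt = run_heartbeat("wt", par=par, force=f_wt)
    mut = run_heartbeat("s140g", par=par, reference_peak=ref,
                        force=transmural_force("s140g"))
    return {"par": par, "wt": wt, "s140g": mut, "force_wt": f_wt}
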