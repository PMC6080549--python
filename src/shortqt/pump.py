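"""Lumped electromechanical pump: passive material law, Ca-driven
activation, time-varying-compliance ventricles in a closed Windkessel
circulation, with pressure–volume-loop metrics.

Ventricular pressure follows the time-varying compliance law

    P = (V − V_rest(y_v)) / C(y_v),
    C(y_v)      = y_v (C_act − C_pass) + C_pass,
    V_rest(y_v) = (1 − y_v) V_rest,d + y_v V_rest,s,

where the activation y_v(t) ∈ [0, 1] is the myofilament active force
peak-normalized to a wild-type reference beat.  The circulation closes
through eight compartments (LV, systemic artery/vein, RA, RV, pulmonary
artery/vein, LA) connected by resistances with diode valves (mitral,
aortic, tricuspid, pulmonary).  The exponential transversely isotropic
strain-energy law of the myocardium is provided as an evaluatable
material function (it is not fed back into the lumped pump).

The circulation parameters are not inherited from any particular dataset:
C_act/C_pass of the left ventricle are calibrated once so the wild-type
sinus beat reproduces the reference stroke volume and ejection fraction;
the mutant run then changes only the cellular inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ionic import cell_params
from .myofilament import MyofilamentParams, atp_rate, run_myofilament
from .protocols import pace_to_steady_state

__all__ = [
    "MaterialParams", "passive_strain_energy", "green_strain",
    "VentriclePumpParams", "CirculationParams", "CirculationState",
    "activation_from_calcium", "ventricular_pressure", "circulation_step",
    "run_heartbeat", "calibrate_wt_pump", "transmural_force",
    "HeartbeatResult",
]

#: transmural weights used when lumping the three cell types (endo, M, epi)
LAYER_WEIGHTS = (0.45, 0.25, 0.30)


# --------------------------------------------------------------------------
# passive material law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParams:
    """Exponential strain-energy constants (kPa / dimensionless)."""

    C: float = 2.0
    b1: float = 8.0
    b2: float = 2.0
    b3: float = 4.0


def passive_strain_energy(E: dict[str, float] | np.ndarray,
                          mat: MaterialParams = MaterialParams()) -> float:
    """W = (C/2)(e^Q − 1) with
    Q = b1·E_ff² + b2·(E_rr² + E_cc² + 2E_rc²) + 2b3·(E_fr² + E_fc²).
    """
    if isinstance(E, np.ndarray):
        Eff, Err, Ecc = E[0, 0], E[1, 1], E[2, 2]
        Efr, Efc, Erc = E[0, 1], E[0, 2], E[1, 2]
    else:
        Eff = E.get("Eff", 0.0)
        Err = E.get("Err", 0.0)
        Ecc = E.get("Ecc", 0.0)
        Erc = E.get("Erc", 0.0)
        Efr = E.get("Efr", 0.0)
        Efc = E.get("Efc", 0.0)
    Q = (mat.b1 * Eff ** 2 + mat.b2 * (Err ** 2 + Ecc ** 2 + 2 * Erc ** 2)
         + 2 * mat.b3 * (Efr ** 2 + Efc ** 2))
    if not np.isfinite(Q):
        raise ValueError("strain components must be finite")
    if Q > 50.0:
        raise OverflowError("strain energy exponent Q > 50")
    return mat.C / 2.0 * (np.exp(Q) - 1.0)


def green_strain(F: np.ndarray) -> np.ndarray:
    """Green–Lagrange strain E = ½(FᵀF − I) in fiber coordinates."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("deformation gradient must be 3x3")
    if abs(np.linalg.det(F)) < 1e-12:
        raise ValueError("deformation gradient is singular")
    return 0.5 * (F.T @ F - np.eye(3))


# --------------------------------------------------------------------------
# activation from the cellular calcium transient
# --------------------------------------------------------------------------

def transmural_force(condition: str, bcl: float = 600.0,
                     n_beats: int = 30,
                     myo: MyofilamentParams = MyofilamentParams()
                     ) -> pd.DataFrame:
    """Layer-weighted myofilament force/ATP trace for one sinus beat.

    Each cell type is paced to steady state at ``bcl``; its Ca transient
    drives the cross-bridge model; traces are combined with the
    transmural layer weights.
    """
    out = None
    for w, ct in zip(LAYER_WEIGHTS, ("endo", "M", "epi")):
        tr = pace_to_steady_state(cell_params(ct, condition), bcl,
                                  n_beats=n_beats, record_beats=1)
        df = run_myofilament(tr.t, tr.Cai, params=myo, bcl_ms=bcl)
        if out is None:
            out = pd.DataFrame({"t_ms": df["t_ms"],
                                "force": w * df["force"],
                                "atp_flux": w * df["atp_flux"]})
        else:
            out["force"] += w * df["force"].to_numpy()
            out["atp_flux"] += w * df["atp_flux"].to_numpy()
    return out


def activation_from_calcium(force: pd.DataFrame,
                            reference_peak: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Ventricular activation y_v(t) from a force trace.

    Peak-normalizes to ``reference_peak`` (the wild-type beat's maximum
    force) and clips to [0, 1]; returns (t_ms, y_v, reference_peak).
    """
    f = force["force"].to_numpy()
    if reference_peak is None:
        reference_peak = float(f.max())
    if reference_peak <= 0:
        return force["t_ms"].to_numpy(), np.zeros_like(f), 0.0
    yv = np.clip(f / reference_peak, 0.0, 1.0)
    return force["t_ms"].to_numpy(), yv, float(reference_peak)


# --------------------------------------------------------------------------
# ventricles and circulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VentriclePumpParams:
    """Time-varying compliance ventricle (one side)."""

    c_active: float    # compliance at full activation (mL/mmHg, stiff)
    c_passive: float   # compliance at rest (mL/mmHg)
    v_rest_d: float    # zero-pressure volume, diastole (mL)
    v_rest_s: float    # zero-pressure volume, systole (mL)

    def __post_init__(self):
        if not 0 < self.c_active < self.c_passive:
            raise ValueError("need 0 < C_act < C_pass (activation stiffens)")


def ventricular_pressure(V: float, y_v: float,
                         params: VentriclePumpParams) -> float:
    """P = (V − V_rest(y_v)) / C(y_v) in mmHg."""
    y = min(max(y_v, 0.0), 1.0)
    c = y * (params.c_active - params.c_passive) + params.c_passive
    v_rest = (1.0 - y) * params.v_rest_d + y * params.v_rest_s
    return (V - v_rest) / c


@dataclass(frozen=True)
class CirculationParams:
    """Closed-loop lumped circulation (resistances mmHg·ms/mL,
    compliances mL/mmHg, unstressed volumes mL)."""

    r_mi: float = 5.0        # mitral valve
    r_ao: float = 5.0        # aortic valve
    r_sa: float = 1000.0     # systemic arteries -> veins
    r_sv: float = 20.0       # systemic veins -> RA
    r_ra: float = 5.0        # RA -> RV path resistance (tricuspid)
    r_pu: float = 5.0        # pulmonary valve
    r_pa: float = 80.0       # pulmonary artery -> veins
    r_pv: float = 10.0       # pulmonary veins -> LA
    c_sa: float = 1.6
    c_sv: float = 30.0
    c_pa: float = 4.5
    c_pv: float = 10.0
    c_la: float = 10.0
    c_ra: float = 12.0
    v0_sa: float = 450.0
    v0_sv: float = 2800.0
    v0_pa: float = 80.0
    v0_pv: float = 300.0
    v0_la: float = 20.0
    v0_ra: float = 20.0
    lv: VentriclePumpParams = VentriclePumpParams(0.4, 12.0, 10.0, 15.0)
    rv: VentriclePumpParams = VentriclePumpParams(1.2, 25.0, 20.0, 25.0)


COMPARTMENTS = ("LV", "SA", "SV", "RA", "RV", "PA", "PV", "LA")


@dataclass
class CirculationState:
    """Compartment volumes (mL); pressures are derived."""

    volumes: dict[str, float] = field(default_factory=lambda: {
        "LV": 120.0, "SA": 600.0, "SV": 3000.0, "RA": 60.0,
        "RV": 130.0, "PA": 150.0, "PV": 400.0, "LA": 60.0})

    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))

    def pressures(self, par: CirculationParams, y_lv: float, y_rv: float
                  ) -> dict[str, float]:
        v = self.volumes
        return {
            "LV": ventricular_pressure(v["LV"], y_lv, par.lv),
            "RV": ventricular_pressure(v["RV"], y_rv, par.rv),
            "SA": (v["SA"] - par.v0_sa) / par.c_sa,
            "SV": (v["SV"] - par.v0_sv) / par.c_sv,
            "PA": (v["PA"] - par.v0_pa) / par.c_pa,
            "PV": (v["PV"] - par.v0_pv) / par.c_pv,
            "LA": (v["LA"] - par.v0_la) / par.c_la,
            "RA": (v["RA"] - par.v0_ra) / par.c_ra,
        }


def circulation_step(state: CirculationState, par: CirculationParams,
                     y_lv: float, y_rv: float, dt: float
                     ) -> tuple[CirculationState, dict[str, float]]:
    """Advance the closed loop one ``dt`` (ms); returns (state, flows).

    Flows are pressure differences over resistances; the four valves are
    ideal diodes (no backward conduction).  Total blood volume is
    conserved identically because every flow leaves one compartment and
    enters another.
    """
    if dt > 1.0:
        raise ValueError("circulation step limited to dt <= 1 ms")
    p = state.pressures(par, y_lv, y_rv)
    q = {
        "MI": max(0.0, (p["LA"] - p["LV"]) / par.r_mi),
        "AO": max(0.0, (p["LV"] - p["SA"]) / par.r_ao),
        "SA": (p["SA"] - p["SV"]) / par.r_sa,
        "SV": (p["SV"] - p["RA"]) / par.r_sv,
        "TR": max(0.0, (p["RA"] - p["RV"]) / par.r_ra),
        "PU": max(0.0, (p["RV"] - p["PA"]) / par.r_pu),
        "PA": (p["PA"] - p["PV"]) / par.r_pa,
        "PV": (p["PV"] - p["LA"]) / par.r_pv,
    }
    v = dict(state.volumes)
    v["LV"] += dt * (q["MI"] - q["AO"])
    v["SA"] += dt * (q["AO"] - q["SA"])
    v["SV"] += dt * (q["SA"] - q["SV"])
    v["RA"] += dt * (q["SV"] - q["TR"])
    v["RV"] += dt * (q["TR"] - q["PU"])
    v["PA"] += dt * (q["PU"] - q["PA"])
    v["PV"] += dt * (q["PA"] - q["PV"])
    v["LA"] += dt * (q["PV"] - q["MI"])
    for name, vol in v.items():
        if vol <= 0:
            raise ValueError(f"compartment {name} volume became nonpositive")
    return CirculationState(v), q


@dataclass
class HeartbeatResult:
    """Steady-state PV loop and pump metrics for one condition."""

    loop: pd.DataFrame            # t_ms, V_mL, P_mmHg (last cycle)
    stroke_volume: float          # mL
    ejection_fraction: float      # %
    end_diastolic_volume: float   # mL
    end_systolic_volume: float    # mL
    stroke_work: float            # mmHg·mL (loop area)
    atp_rate: float               # 1/s
    atp_per_beat: float           # dimensionless cycles per BCL
    efficiency: float             # stroke work / ATP per beat


def _loop_area(v: np.ndarray, p: np.ndarray) -> float:
    """Signed shoelace area of the PV loop (positive = counterclockwise)."""
    return float(0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def _simulate_cycles(par: CirculationParams, t_yv: np.ndarray,
                     yv: np.ndarray, bcl: float, n_cycles: int,
                     dt: float = 0.5, state: CirculationState | None = None
                     ) -> tuple[pd.DataFrame, CirculationState]:
    state = state or CirculationState()
    nt = int(round(bcl / dt))
    rows = None
    for cyc in range(n_cycles):
        if cyc == n_cycles - 1:
            rows = np.empty((nt, 3))
        for k in range(nt):
            t = k * dt
            y = float(np.interp(t, t_yv, yv))
            if rows is not None:
                p = state.pressures(par, y, y)
                rows[k] = (t, state.volumes["LV"], p["LV"])
            state, _ = circulation_step(state, par, y, y, dt)
    return pd.DataFrame(rows, columns=["t_ms", "V_mL", "P_mmHg"]), state


def run_heartbeat(condition: str, n_cycles: int = 20, bcl: float = 600.0,
                  par: CirculationParams | None = None,
                  reference_peak: float | None = None,
                  force: pd.DataFrame | None = None) -> HeartbeatResult:
    """Steady-state sinus beat of the closed loop under one condition.

    ``reference_peak`` must be the wild-type beat's peak force when
    simulating the mutant so that both conditions share one activation
    scale.  Raises if the stroke volume has not settled to <1 % per cycle.
    """
    par = par or CirculationParams()
    if force is None:
        force = transmural_force(condition, bcl=bcl)
    t_yv, yv, _ = activation_from_calcium(force, reference_peak)

    loop_prev, state = _simulate_cycles(par, t_yv, yv, bcl, max(2, n_cycles - 1))
    loop, _ = _simulate_cycles(par, t_yv, yv, bcl, 1, state=state)
    sv_prev = loop_prev["V_mL"].max() - loop_prev["V_mL"].min()
    v = loop["V_mL"].to_numpy()
    p = loop["P_mmHg"].to_numpy()
    edv, esv = float(v.max()), float(v.min())
    sv = edv - esv
    if sv > 1.0 and abs(sv - sv_prev) > 0.01 * max(sv, 1e-9):
        raise RuntimeError("pump did not reach cyclic steady state")
    rate = atp_rate(force, bcl_ms=bcl)
    atp_beat = rate * bcl / 1000.0
    work = abs(_loop_area(v, p))
    return HeartbeatResult(
        loop=loop, stroke_volume=sv,
        ejection_fraction=100.0 * sv / edv if edv > 0 else 0.0,
        end_diastolic_volume=edv, end_systolic_volume=esv,
        stroke_work=work, atp_rate=rate, atp_per_beat=atp_beat,
        efficiency=work / atp_beat if atp_beat > 0 else np.nan)


def calibrate_wt_pump(target_sv: float = 58.6, target_ef: float = 54.2,
                      bcl: float = 600.0, max_iter: int = 25,
                      force: pd.DataFrame | None = None
                      ) -> tuple[CirculationParams, pd.DataFrame]:
    """One-time adjustment of LV compliances to the WT reference point.

    Fixed-point iteration: the passive compliance controls end-diastolic
    volume, the active compliance the end-systolic volume.  Returns the
    calibrated parameters and the WT force trace (whose peak is the
    activation reference for mutant runs).
    """
    par = CirculationParams()
    if force is None:
        force = transmural_force("wt", bcl=bcl)
    edv_t = target_sv / (target_ef / 100.0)
    esv_t = edv_t - target_sv
    for _ in range(max_iter):
        res = run_heartbeat("wt", par=par, bcl=bcl, force=force)
        err_edv = res.end_diastolic_volume / edv_t
        err_esv = ((res.end_systolic_volume - par.lv.v_rest_s)
                   / max(esv_t - par.lv.v_rest_s, 1e-6))
        if abs(err_edv - 1) < 0.005 and abs(err_esv - 1) < 0.01:
            break
        lv = par.lv
        lv = replace(lv,
                     c_passive=float(np.clip(lv.c_passive / err_edv ** 1.0,
                                             1.0, 60.0)),
                     c_active=float(np.clip(lv.c_active * err_esv ** -1.0,
                                            0.05, 5.0)))
        par = replace(par, lv=lv)
    return par, force
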