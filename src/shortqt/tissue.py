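"""Monodomain reaction–diffusion simulation on cables and sheets.

Operator splitting per step: the ionic reaction (Rush–Larsen gates,
explicit ion balances) followed by second-order central-difference
diffusion with no-flux boundaries.  Provides conduction-velocity
calibration by bisection on the axial resistivity, activation/
repolarization maps (EAT/EDT at −30/−75 mV), wavelength, and the S1–S2
cross-field re-entry induction protocol with an optional low-CV induction
/ checkpoint / restart sequence for sustained re-entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import _kernels as kern
from .geometry import TissueGrid
from .ionic import CELL_TYPE_INDEX, CellParams, cell_params, resting_state
from .protocols import Trace, _run_paced, measure_apd

__all__ = [
    "FieldTrace", "ActivationMaps", "StimulusSchedule", "simulate_monodomain",
    "calibrate_conductivity", "measure_cv", "compute_wavelength",
    "activation_maps", "s1s2_cross_field", "sustained_reentry_protocol",
    "layer_params", "conditioned_tissue_state",
]

EAT_THRESHOLD = -30.0   # mV, upward crossing = electrical activation time
EDT_THRESHOLD = -75.0   # mV, downward crossing = electrical deactivation

STIM_AMPLITUDE = -52.0  # pA/pF
STIM_DURATION = 2.0     # ms (tissue; a little wide for robust capture)
DT_TISSUE = 0.02        # ms


@dataclass(frozen=True)
class StimulusSchedule:
    """A set of stimuli: node lists with onset times (shared amp/dur)."""

    node_lists: tuple[np.ndarray, ...]
    times: np.ndarray                  # ms, one onset per node list
    amplitude: float = STIM_AMPLITUDE
    duration: float = STIM_DURATION

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        offsets = np.zeros(len(self.node_lists) + 1, dtype=np.int64)
        for i, nl in enumerate(self.node_lists):
            offsets[i + 1] = offsets[i] + nl.size
        nodes = (np.concatenate(self.node_lists) if self.node_lists
                 else np.empty(0, dtype=np.int64))
        return offsets, nodes.astype(np.int64)


@dataclass
class FieldTrace:
    """Space–time recording of V_m from a tissue run."""

    grid: TissueGrid
    t: np.ndarray                 # ms, field sample times
    V: np.ndarray                 # (n_t, n_nodes) float32
    probe_t: np.ndarray           # ms
    probe_V: np.ndarray           # (n_t_probe, n_probes)
    probe_nodes: np.ndarray
    stim: StimulusSchedule
    eat: np.ndarray               # online maps from the solver (ms, NaN=absent)
    edt: np.ndarray
    map_start: float
    s2_time: float = -1.0         # ms; −1 when no S2 was fired
    term_time: float = -1.0       # ms; −1 when activity reached the horizon
    final_state: np.ndarray | None = None   # (n_nodes, 19) end state

    def __post_init__(self):
        if not np.all(np.isfinite(self.V)):
            raise ValueError("field trace contains non-finite samples")


@dataclass
class ActivationMaps:
    """Per-node EAT/EDT with the derived scalar summaries."""

    eat: np.ndarray   # ms, NaN where never activated
    edt: np.ndarray   # ms, NaN where never repolarized

    def __post_init__(self):
        both = np.isfinite(self.eat) & np.isfinite(self.edt)
        if np.any(self.edt[both] <= self.eat[both]):
            raise ValueError("EDT must follow EAT at every activated node")

    @property
    def eat_min(self) -> float:
        return float(np.nanmin(self.eat))

    @property
    def eat_max(self) -> float:
        return float(np.nanmax(self.eat))

    @property
    def edt_max(self) -> float:
        return float(np.nanmax(self.edt))

    @property
    def qrs_proxy(self) -> float:
        """Activation spread, max EAT − min EAT (QRS-width analogue)."""
        return self.eat_max - self.eat_min

    @property
    def qt_proxy(self) -> float:
        """Max EDT − min EAT (QT-interval analogue)."""
        return self.edt_max - self.eat_min


def layer_params(condition: str = "wt") -> dict[str, CellParams]:
    """Endo/M/epi parameter sets for one condition."""
    return {ct: cell_params(ct, condition) for ct in ("endo", "M", "epi")}


def conditioned_tissue_state(grid: TissueGrid, condition: str, bcl: float,
                             n_beats: int = 20) -> np.ndarray:
    """Per-node initial states from single-cell pacing at ``bcl``.

    Each cell type is conditioned in isolation and its end state copied to
    every node of that type — a cheap surrogate for pacing the whole
    tissue to steady state.
    """
    S = np.empty((grid.n_nodes, kern.N_STATE))
    for ct, idx in CELL_TYPE_INDEX.items():
        mask = grid.cell_type_idx == idx
        if not np.any(mask):
            continue
        _, ys = _run_paced(cell_params(ct, condition), bcl, n_beats)
        S[mask] = ys
    return S


def _node_arrays(grid: TissueGrid, condition: str):
    stype = grid.cell_type_idx.astype(np.int8)
    gks = np.empty(grid.n_nodes)
    gto = np.empty(grid.n_nodes)
    for ct, idx in CELL_TYPE_INDEX.items():
        p = cell_params(ct, condition)
        m = stype == idx
        gks[m] = p.g_ks
        gto[m] = p.g_to
    phi = 0.1 if condition == "s140g" else 0.0
    return stype, gks, gto, phi


def simulate_monodomain(grid: TissueGrid, condition: str,
                        stim: StimulusSchedule, duration: float,
                        state: np.ndarray | None = None,
                        record_dt: float = 10.0,
                        probe_nodes: np.ndarray | None = None,
                        probe_dt: float = 1.0,
                        map_start: float = 0.0,
                        dt: float = DT_TISSUE,
                        s2_quadrant: np.ndarray | None = None,
                        s2_watch: np.ndarray | None = None,
                        s2_earliest: float = 0.0,
                        term_check_after: float | None = None,
                        ) -> FieldTrace:
    """Run the monodomain model; see :class:`FieldTrace` for outputs.

    When ``s2_quadrant`` is given, a premature cross-field stimulus is
    fired once every node in ``s2_watch`` has repolarized below −75 mV
    (the wave-tail timing rule), no earlier than ``s2_earliest``.
    """
    dx2 = grid.dx * grid.dx
    Dx, Dy = grid.diffusivity()
    cx = Dx * dt / dx2
    cy = (Dy * dt / dx2) if grid.ny > 1 else 0.0
    if cx + cy > 0.45:
        raise ValueError("explicit diffusion step unstable for this dx/dt")

    stype, gks, gto, phi = _node_arrays(grid, condition)
    if state is None:
        state = np.tile(resting_state().y, (grid.n_nodes, 1))
    S = np.ascontiguousarray(state, dtype=np.float64)

    lut, lutk = kern.build_tables(dt)
    offsets, nodes = stim.flat()
    nrec = int(np.floor(duration / record_dt)) + 1
    vrec = np.empty((nrec, grid.n_nodes), dtype=np.float32)
    if probe_nodes is None:
        probe_nodes = np.array([grid.n_nodes // 2], dtype=np.int64)
    nprec = int(np.floor(duration / probe_dt)) + 1
    probe_rec = np.empty((nprec, probe_nodes.size))
    eat = np.full(grid.n_nodes, -1.0)
    edt = np.full(grid.n_nodes, -1.0)

    s2_enabled = s2_quadrant is not None
    if term_check_after is None:
        # plain paced runs must not stop during diastole; only re-entry
        # episodes (S2 fired, or an explicit opt-in) terminate early
        term_check_after = 0.0 if s2_enabled else float(duration) + 1.0

    jrec, jprobe, s2_time, term_time = kern.run_tissue(
        S, stype, gks, gto, phi, -75.3, grid.nx, grid.ny, cx, cy, dt,
        float(duration), offsets, nodes,
        stim.times.astype(np.float64), stim.duration, stim.amplitude,
        max(1, int(round(record_dt / dt))), vrec,
        probe_nodes.astype(np.int64), max(1, int(round(probe_dt / dt))),
        probe_rec, eat, edt, float(map_start),
        s2_enabled,
        (s2_watch if s2_watch is not None else np.empty(0)).astype(np.int64),
        (s2_quadrant if s2_quadrant is not None else np.empty(0)).astype(np.int64),
        float(s2_earliest), STIM_DURATION, STIM_AMPLITUDE,
        float(term_check_after), lut, lutk)

    eat[eat < -0.5] = np.nan
    edt[edt < -0.5] = np.nan
    tr = FieldTrace(
        grid=grid,
        t=np.arange(jrec) * record_dt,
        V=vrec[:jrec],
        probe_t=np.arange(jprobe) * probe_dt,
        probe_V=probe_rec[:jprobe],
        probe_nodes=probe_nodes,
        stim=stim, eat=eat, edt=edt, map_start=map_start,
        s2_time=s2_time, term_time=term_time, final_state=S)
    return tr


def _crossing_times(t, V, threshold, direction, first=True):
    """Per-node linear-interpolated threshold crossing of a (n_t, n) field."""
    above = V >= threshold
    n = V.shape[1]
    out = np.full(n, np.nan)
    if direction == "up":
        hits = (~above[:-1]) & above[1:]
    else:
        hits = above[:-1] & (~above[1:])
    for i in range(n):
        idx = np.nonzero(hits[:, i])[0]
        if idx.size == 0:
            continue
        k = idx[0] if first else idx[-1]
        v0, v1 = float(V[k, i]), float(V[k + 1, i])
        out[i] = t[k] + (t[k + 1] - t[k]) * (threshold - v0) / (v1 - v0)
    return out


def activation_maps(trace: FieldTrace, window: tuple[float, float] | None = None
                    ) -> ActivationMaps:
    """EAT/EDT maps from the recorded field samples.

    EAT is the first upward −30 mV crossing in the window, EDT the last
    downward −75 mV crossing; nodes that never cross are NaN (absent).
    """
    t, V = trace.t, trace.V
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, V = t[sel], V[sel]
    if t.size < 2:
        raise ValueError("trace too short for activation mapping")
    eat = _crossing_times(t, V, EAT_THRESHOLD, "up", first=True)
    edt = _crossing_times(t, V, EDT_THRESHOLD, "down", first=False)
    return ActivationMaps(eat=eat, edt=edt)


def measure_cv(trace: FieldTrace, grid: TissueGrid | None = None,
               maps: ActivationMaps | None = None) -> float:
    """Planar conduction velocity (cm/s) along x from the EAT map.

    Distance between the 25 % and 75 % cable positions divided by their
    activation-time difference; for sheets the first row is used.
    """
    grid = grid or trace.grid
    if maps is None:
        eat = trace.eat if np.any(np.isfinite(trace.eat)) else None
        if eat is None:
            eat = activation_maps(trace).eat
    else:
        eat = maps.eat
    row = eat[:grid.nx]
    i1, i2 = int(round(0.25 * (grid.nx - 1))), int(round(0.75 * (grid.nx - 1)))
    t1, t2 = row[i1], row[i2]
    if not (np.isfinite(t1) and np.isfinite(t2)) or t2 == t1:
        raise ValueError("wave did not traverse the 25%/75% positions")
    return abs((i2 - i1) * grid.dx / (t2 - t1)) * 1000.0


def compute_wavelength(cv_cm_s: float, apd_ms: float) -> float:
    """Conduction wavelength CV·APD in cm."""
    if cv_cm_s < 0 or apd_ms < 0:
        raise ValueError("inputs must be nonnegative")
    return cv_cm_s * apd_ms / 1000.0


def _edge_stim(grid: TissueGrid, n_cols: int | None = None) -> np.ndarray:
    if n_cols is None:
        # strip width ≥ a space constant so capture survives high diffusivity
        n_cols = max(2, int(np.ceil(0.15 / grid.dx)))
    cols = np.arange(min(n_cols, grid.nx))
    rows = np.arange(grid.ny)
    return (rows[:, None] * grid.nx + cols[None, :]).ravel()


def calibrate_conductivity(grid: TissueGrid, target_cv: float,
                           condition: str = "wt", tol: float = 0.02,
                           max_iter: int = 30) -> TissueGrid:
    """Bisection on axial resistivity until the planar CV matches.

    CV ∝ √(1/ρ), so the bracket is seeded from the current measurement
    and refined until ``|CV − target| ≤ tol·target``.
    """
    if not 10.0 <= target_cv <= 120.0:
        raise ValueError("target CV outside the supported 10–120 cm/s")

    def cv_of(rho: float) -> float:
        g = grid.with_rho(rho)
        # short planar run on a single-row cable of the same composition
        cable = TissueGrid(g.nx, 1, g.dx, g.cell_type_idx[:g.nx], rho, rho,
                           surface_to_volume=g.surface_to_volume,
                           cm_area=g.cm_area)
        stim = StimulusSchedule((_edge_stim(cable),), np.array([5.0]))
        # long enough for the slow end of the bracket (~15% of target CV)
        dur = 5.0 + cable.nx * cable.dx / (0.15 * target_cv) * 1000.0
        tr = simulate_monodomain(cable, condition, stim, dur, record_dt=1e9)
        return measure_cv(tr, cable)

    rho = grid.rho_x
    cv = cv_of(rho)
    # seed from CV ∝ 1/sqrt(rho)
    rho_guess = rho * (cv / target_cv) ** 2
    lo, hi = rho_guess / 4.0, rho_guess * 4.0
    cv_lo, cv_hi = cv_of(lo), cv_of(hi)   # lo rho → fast, hi rho → slow
    if not (cv_hi <= target_cv <= cv_lo):
        raise ValueError("failed to bracket the target conduction velocity")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        cv_mid = cv_of(mid)
        if abs(cv_mid - target_cv) <= tol * target_cv:
            return grid.with_rho(mid)
        if cv_mid > target_cv:
            lo = mid
        else:
            hi = mid
    raise ValueError("conduction-velocity calibration did not converge")


def s1s2_cross_field(grid: TissueGrid, condition: str,
                     s1_bcl: float = 600.0, n_s1: int = 3,
                     duration: float = 4200.0,
                     state: np.ndarray | None = None,
                     record_dt: float = 10.0,
                     probe_nodes: np.ndarray | None = None) -> FieldTrace:
    """S1–S2 re-entry induction on a 2D sheet.

    Three planar S1 stimuli from the left edge at 600 ms intervals; the
    premature S2 depolarizes the lower-left quadrant at the moment the
    repolarization tail of the third wave clears the sheet midline.
    """
    if grid.ny == 1:
        raise ValueError("cross-field S2 needs a 2D grid")
    if state is None:
        state = conditioned_tissue_state(grid, condition, s1_bcl)
    s1_nodes = _edge_stim(grid)
    stim = StimulusSchedule((s1_nodes,) * n_s1,
                            np.arange(n_s1) * s1_bcl + 5.0)
    mid = grid.nx // 2
    xs = np.arange(grid.n_nodes) % grid.nx
    ys = np.arange(grid.n_nodes) // grid.nx
    watch = np.nonzero(xs <= mid)[0]
    quad = np.nonzero((xs <= mid) & (ys <= grid.ny // 2))[0]
    if probe_nodes is None:
        # one probe per layer plus the sheet centre
        probe_nodes = np.array(
            [grid.ny // 8 * grid.nx + 3 * grid.nx // 4,
             grid.ny // 2 * grid.nx + 3 * grid.nx // 4,
             (grid.ny - grid.ny // 8) * grid.nx + 3 * grid.nx // 4,
             grid.ny // 2 * grid.nx + grid.nx // 2], dtype=np.int64)
    return simulate_monodomain(
        grid, condition, stim, duration, state=state, record_dt=record_dt,
        probe_nodes=probe_nodes, map_start=0.0,
        s2_quadrant=quad, s2_watch=watch,
        s2_earliest=(n_s1 - 1) * s1_bcl + 60.0)


def sustained_reentry_protocol(grid: TissueGrid, condition: str,
                               induction_cv: float = 20.0,
                               restart_cv: float = 70.0,
                               induction_duration: float = 2600.0,
                               restart_duration: float = 4200.0,
                               **kw) -> FieldTrace:
    """Induce re-entry at very low CV, checkpoint, restart at normal CV.

    The S1–S2 episode is run on a grid calibrated to ``induction_cv``;
    the full cellular state at the end of the episode is then used as the
    initial condition of a second run at ``restart_cv``.
    """
    g_slow = calibrate_conductivity(grid, induction_cv, condition)
    tr1 = s1s2_cross_field(g_slow, condition,
                           duration=induction_duration, **kw)
    if tr1.term_time >= 0:
        raise ValueError("induction at low CV terminated; no re-entry to "
                         "transfer")
    g_fast = calibrate_conductivity(grid, restart_cv, condition)
    stim = StimulusSchedule((np.empty(0, dtype=np.int64),),
                            np.array([-1e9]))
    tr2 = simulate_monodomain(
        g_fast, condition, stim, restart_duration,
        state=tr1.final_state, record_dt=10.0,
        probe_nodes=tr1.probe_nodes, term_check_after=0.0)
    tr2.s2_time = 0.0
    return tr2
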