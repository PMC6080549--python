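"""Synthetic tissue geometry and analytic test fixtures.

A full image-based 3D ventricular mesh is beyond desk scale; it is
replaced by a
transmurally layered 1D cable (endo → M → epi blocks) and a 2D sheet with
a 1.5 longitudinal:transverse conduction-velocity anisotropy.  This module
also generates closed-form fixture signals (traveling waves, sinusoid
fields, triangular action potentials) whose ground truth is known exactly,
so every downstream metric has an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometrySpec", "TissueGrid", "make_transmural_cable",
           "make_sheet", "make_fixture_field"]

#: default transmural layer fractions endo:M:epi
DEFAULT_LAYERS = (0.45, 0.25, 0.30)

#: default surface-to-volume ratio (1/cm) and membrane capacitance (µF/cm²)
SURFACE_TO_VOLUME = 2000.0
CM_AREA = 1.0

#: default axial resistivity (kΩ·cm); gives D = 1/(ρSC) ≈ 1.54e-3 cm²/ms
RHO_DEFAULT = 0.3247


@dataclass(frozen=True)
class GeometrySpec:
    """Declarative description of a synthetic grid (deterministic)."""

    shape: str = "cable"                      # cable | sheet
    length_cm: float = 2.0                    # x extent
    width_cm: float = 0.0                     # y extent (sheets)
    dx: float = 0.02                          # node spacing (cm)
    layer_fractions: tuple[float, float, float] = DEFAULT_LAYERS
    anisotropy_ratio: float = 1.5             # CV_long / CV_trans
    rho_x: float = RHO_DEFAULT                # kΩ·cm
    uniform_cell_type: str | None = "epi"     # sheets: None = layered along y
    seed: int = 0                             # reserved for jitter; none by default

    def __post_init__(self):
        if self.shape not in ("cable", "sheet"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        n = self.length_cm / self.dx
        if abs(n - round(n)) > 1e-6:
            raise ValueError("dx must divide the length")


@dataclass
class TissueGrid:
    """Layered 1D/2D lattice with per-node cell type and conductivity."""

    nx: int
    ny: int
    dx: float                        # cm
    cell_type_idx: np.ndarray        # int8 per node (0 endo, 1 M, 2 epi)
    rho_x: float                     # kΩ·cm
    rho_y: float                     # kΩ·cm (unused for cables)
    anisotropy_ratio: float = 1.0
    surface_to_volume: float = SURFACE_TO_VOLUME   # 1/cm
    cm_area: float = CM_AREA                       # µF/cm²
    boundary: str = "no-flux"

    def __post_init__(self):
        if self.rho_x <= 0 or self.rho_y <= 0:
            raise ValueError("resistivity must be positive")
        if self.cell_type_idx.size != self.nx * self.ny:
            raise ValueError("cell-type labels must cover every node")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def dimensionality(self) -> int:
        return 1 if self.ny == 1 else 2

    def diffusivity(self) -> tuple[float, float]:
        """(D_x, D_y) in cm²/ms, D = 1/(ρ S C_m)."""
        dfac = self.surface_to_volume * self.cm_area
        return 1.0 / (self.rho_x * dfac), 1.0 / (self.rho_y * dfac)

    def with_rho(self, rho_x: float) -> "TissueGrid":
        """Same grid with rescaled resistivity (anisotropy preserved)."""
        return TissueGrid(self.nx, self.ny, self.dx,
                          self.cell_type_idx, rho_x,
                          rho_x * (self.rho_y / self.rho_x),
                          self.anisotropy_ratio, self.surface_to_volume,
                          self.cm_area, self.boundary)

    def x_of(self, node: int) -> float:
        return (node % self.nx) * self.dx


def _layer_labels(n: int, fractions) -> np.ndarray:
    counts = np.floor(np.asarray(fractions) * n).astype(int)
    while counts.sum() < n:  # distribute rounding remainder endo-first
        counts[int(np.argmax(np.asarray(fractions) * n - counts))] += 1
    labels = np.concatenate([np.full(c, i, dtype=np.int8)
                             for i, c in enumerate(counts)])
    return labels


def make_transmural_cable(spec: GeometrySpec) -> TissueGrid:
    """1D endo→M→epi cable with contiguous layer blocks."""
    if spec.shape != "cable":
        raise ValueError("spec.shape must be 'cable'")
    nx = int(round(spec.length_cm / spec.dx))
    labels = _layer_labels(nx, spec.layer_fractions)
    return TissueGrid(nx, 1, spec.dx, labels, spec.rho_x, spec.rho_x)


def make_sheet(spec: GeometrySpec) -> TissueGrid:
    """2D sheet, anisotropic along x; uniform cell type by default
    (an epicardial patch), optionally layered transmurally along y.

    CV scales as √(1/ρ), so a CV anisotropy ratio r requires
    ρ_y = ρ_x · r².
    """
    if spec.shape != "sheet":
        raise ValueError("spec.shape must be 'sheet'")
    nx = int(round(spec.length_cm / spec.dx))
    ny = int(round((spec.width_cm or spec.length_cm) / spec.dx))
    if spec.uniform_cell_type is not None:
        from .ionic import CELL_TYPE_INDEX
        labels = np.full(nx * ny,
                         CELL_TYPE_INDEX[spec.uniform_cell_type],
                         dtype=np.int8)
    else:
        col = _layer_labels(ny, spec.layer_fractions)
        labels = np.repeat(col, nx)   # row-major: y-blocks of layers
    rho_y = spec.rho_x * spec.anisotropy_ratio ** 2
    return TissueGrid(nx, ny, spec.dx, labels, spec.rho_x, rho_y,
                      anisotropy_ratio=spec.anisotropy_ratio)


def make_fixture_field(kind: str, **params):
    """Closed-form fixtures with attached ground truth.

    kinds:
      ``analytic_wave``  — V(x,t) = f(x − c·t) on a cable; truth: CV.
      ``sinusoid``       — uniform sinusoidal V(t); truth: frequency.
      ``triangular_ap``  — one triangular AP; truth: APD at any fraction.

    Returns ``(t, V, truth)`` where V is (n_t, n_nodes) for fields and
    (n_t,) for the single-cell fixture, and ``truth`` is a dict.
    """
    if kind == "analytic_wave":
        c = params.get("cv_cm_s", 50.0)          # cm/s
        length = params.get("length_cm", 5.0)
        dx = params.get("dx", 0.02)
        dt = params.get("dt_ms", 1.0)
        dur = params.get("duration_ms", None)
        x = np.arange(0.0, length + dx / 2, dx)
        if dur is None:
            dur = (length / c) * 1000.0 + 200.0
        t = np.arange(0.0, dur, dt)
        cms = c / 1000.0                          # cm/ms
        # smooth upstroke profile: rest −85 → plateau +20 over 1 mm
        xi = x[None, :] - cms * t[:, None]
        V = -85.0 + 105.0 / (1.0 + np.exp(xi / 0.02))
        return t, V, {"cv_cm_s": c, "x": x}
    if kind == "sinusoid":
        fhz = params.get("freq_hz", 3.0)
        fs = params.get("fs_hz", 100.0)
        dur = params.get("duration_s", 4.0)
        n_nodes = params.get("n_nodes", 1)
        t = np.arange(0.0, dur, 1.0 / fs) * 1000.0   # ms
        V = -60.0 + 30.0 * np.sin(2 * np.pi * fhz * t / 1000.0)
        if n_nodes > 1:
            V = np.tile(V[:, None], (1, n_nodes))
        return t, V, {"freq_hz": fhz}
    if kind == "triangular_ap":
        rest = params.get("rest_mv", -85.0)
        peak = params.get("peak_mv", 40.0)
        repol_ms = params.get("repol_ms", 300.0)
        dt = params.get("dt_ms", 0.5)
        pre = params.get("pre_ms", 20.0)
        post = params.get("post_ms", 80.0)
        t = np.arange(0.0, pre + repol_ms + post, dt)
        V = np.full_like(t, rest)
        up = t >= pre
        V[up] = peak - (peak - rest) * np.clip((t[up] - pre) / repol_ms, 0, 1)
        frac = params.get("repol_fraction", 0.9)
        truth_apd = frac * repol_ms
        return t, V, {"apd": truth_apd, "upstroke_ms": pre}
    raise ValueError(f"unknown fixture kind {kind!r}")
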