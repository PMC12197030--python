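"""Quasi-static frequency-domain field solver for layered skin.

Solves ∇·(κ∇V) = 0 on a 2-D cross-section of layered tissue, where
κ = σ + iωε₀εᵣ is the complex effective conductivity of each layer, with
Dirichlet potentials on the electrode footprints and insulating (zero
normal current) boundaries elsewhere.  From the complex potential the
solver derives

    E      = −∇V                    (electric field)
    J_real = σ·E                    (conduction current density)
    D      = ε₀·εᵣ·E                (electric displacement)
    J_imag = iω·D                   (displacement current density)
    |J|    = |(σ + iωε₀εᵣ)·E|       (total current-density magnitude)

Discretisation is a cell-centred finite-volume scheme on a uniform
rectangular grid with harmonic averaging of κ across cell faces, which
treats layer interfaces exactly in the 1-D (plate-electrode) limit.
Electrode Dirichlet conditions enter through half-cell face conductances,
so the net complex current through each electrode is a natural by-product
and charge conservation can be checked to solver accuracy.

Two electrode configurations are supported: the device-like pair of
surface strips (driven + and grounded REF), and full-width plate
electrodes top and bottom, which has a closed-form series-resistance
solution used as the solver oracle.

The bundled layer table (thicknesses, σ, εᵣ at 1 Hz / 100 Hz / 1 kHz) is a
synthetic set of plausible literature-scale values — real reproduction work
should override it from configuration with measured dielectric data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)

__all__ = [
    "EPS0",
    "LayerSpec",
    "FieldGrid",
    "FieldSolution",
    "FieldReport",
    "default_layers",
    "build_layer_grid",
    "solve_potential",
    "current_density",
    "summarize_field",
    "A_PER_M2_TO_MA_PER_CM2",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
A_PER_M2_TO_MA_PER_CM2 = 0.1


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: thickness plus σ / εᵣ tables keyed by frequency (Hz).

    Scalar σ/εᵣ apply at all frequencies; dict tables are interpolated
    linearly in log-frequency between configured points and clamped outside.
    """

    name: str
    thickness: float
    sigma: float | dict[float, float]
    eps_r: float | dict[float, float] = 1.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name}: thickness must be > 0")
        for label, table in (("sigma", self.sigma), ("eps_r", self.eps_r)):
            vals = table.values() if isinstance(table, dict) else [table]
            for v in vals:
                if v <= 0 or (label == "eps_r" and v < 1.0):
                    raise ValueError(f"layer {self.name}: invalid {label} value {v}")

    def _lookup(self, table, f: float) -> float:
        if not isinstance(table, dict):
            return float(table)
        freqs = np.array(sorted(table))
        vals = np.array([table[k] for k in sorted(table)])
        if f <= freqs[0]:
            return float(vals[0])
        if f >= freqs[-1]:
            return float(vals[-1])
        return float(np.interp(np.log10(f), np.log10(freqs), vals))

    def sigma_at(self, f: float) -> float:
        return self._lookup(self.sigma, f)

    def eps_r_at(self, f: float) -> float:
        return self._lookup(self.eps_r, f)

    def kappa_at(self, f: float) -> complex:
        return self.sigma_at(f) + 1j * 2.0 * np.pi * f * EPS0 * self.eps_r_at(f)


def default_layers() -> list[LayerSpec]:
    """Synthetic default four-layer stack (plausible magnitudes, not measured data)."""
    return [
        LayerSpec("stratum_corneum", 20e-6,
                  sigma={1.0: 1e-4, 100.0: 2e-4, 1000.0: 5e-4},
                  eps_r={1.0: 1e4, 100.0: 1.2e3, 1000.0: 8e2}),
        LayerSpec("epidermis", 80e-6,
                  sigma={1.0: 0.01, 100.0: 0.02, 1000.0: 0.03},
                  eps_r={1.0: 1e5, 100.0: 3e4, 1000.0: 1e4}),
        LayerSpec("dermis", 1.5e-3,
                  sigma={1.0: 0.20, 100.0: 0.22, 1000.0: 0.25},
                  eps_r={1.0: 1e6, 100.0: 1e5, 1000.0: 5e4}),
        LayerSpec("subcutis", 3.0e-3,
                  sigma={1.0: 0.05, 100.0: 0.05, 1000.0: 0.06},
                  eps_r={1.0: 5e5, 100.0: 5e4, 1000.0: 2e4}),
    ]


@dataclass
class FieldGrid:
    """Discretised cross-section: complex κ per cell plus electrode masks."""

    dx: float
    dz: float
    kappa: np.ndarray            # (nz, nx) complex, row 0 at the surface
    plus_mask: np.ndarray        # (nx,) bool, driven electrode on the top surface
    ref_mask: np.ndarray         # (nx,) bool, reference electrode
    omega: float
    bottom_ref: bool = False     # plate mode: REF covers the bottom surface
    layer_edges: list[tuple[str, int]] = field(default_factory=list)  # (name, first row)

    def __post_init__(self) -> None:
        if np.any(self.kappa.real <= 0):
            raise ValueError("kappa real part must be > 0 everywhere")
        if not self.bottom_ref and np.any(self.plus_mask & self.ref_mask):
            raise ValueError("electrode masks must be disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.kappa.shape


@dataclass
class FieldSolution:
    """Complex potential and derived current-density maps on the grid."""

    potential: np.ndarray                      # (nz, nx) complex V
    e_field: np.ndarray | None = None          # (2, nz, nx): (Ez, Ex) complex V/m
    j_real: np.ndarray | None = None           # (2, nz, nx) conduction A/m²
    d_field: np.ndarray | None = None          # (2, nz, nx) displacement C/m²
    j_imag: np.ndarray | None = None           # (2, nz, nx) displacement current A/m²
    j_total_mag: np.ndarray | None = None      # (nz, nx) real, A/m²
    i_plus: complex = 0.0                      # net complex current in through (+), A/m depth
    i_ref: complex = 0.0                       # net complex current in through REF


@dataclass
class FieldReport:
    peak_mA_per_cm2: float
    depth_profile_mA_per_cm2: np.ndarray
    depths_m: np.ndarray
    dermis_fraction: float
    current_balance_error: float
    f_hz: float

    def to_dict(self) -> dict:
        return {
            "peak_mA_per_cm2": self.peak_mA_per_cm2,
            "dermis_fraction": self.dermis_fraction,
            "current_balance_error": self.current_balance_error,
            "f_hz": self.f_hz,
        }


# --------------------------------------------------------------------------
# grid construction
# --------------------------------------------------------------------------


def build_layer_grid(
    layers: list[LayerSpec],
    width: float = 64e-3,
    dx: float = 0.5e-3,
    dz: float = 10e-6,
    f: float = 20.0,
    electrode_width: float = 8e-3,
    electrode_gap: float = 12e-3,
    plate_electrodes: bool = False,
) -> FieldGrid:
    """Assign per-cell κ from the layer stack and mark the electrode footprints.

    Surface mode (default): two ``electrode_width``-wide strips separated by
    ``electrode_gap``, centred on the top surface; ``width`` must be at
    least 4× the summed electrode widths.  Plate mode: the whole top surface
    is driven and the whole bottom surface grounded (the closed-form oracle
    configuration).
    """
    for layer in layers:
        if layer.thickness < 2.0 * dz:
            raise ValueError(
                f"resolution too coarse: layer {layer.name!r} ({layer.thickness:g} m) "
                f"needs dz <= {layer.thickness / 2:g} m"
            )
    nx = int(round(width / dx))
    nz_per = [int(round(layer.thickness / dz)) for layer in layers]
    nz = sum(nz_per)
    kappa = np.empty((nz, nx), dtype=complex)
    edges: list[tuple[str, int]] = []
    row = 0
    for layer, n in zip(layers, nz_per):
        edges.append((layer.name, row))
        kappa[row : row + n, :] = layer.kappa_at(f)
        row += n

    xc = (np.arange(nx) + 0.5) * dx
    if plate_electrodes:
        plus = np.ones(nx, dtype=bool)
        ref = np.ones(nx, dtype=bool)
        bottom = True
    else:
        if width < 4.0 * 2.0 * electrode_width:
            raise ValueError("width must be >= 4x the summed electrode widths")
        span = 2.0 * electrode_width + electrode_gap
        x0 = (width - span) / 2.0
        plus = (xc >= x0) & (xc < x0 + electrode_width)
        ref = (xc >= x0 + electrode_width + electrode_gap) & (xc < x0 + span)
        bottom = False
        if not plus.any() or not ref.any():
            raise ValueError("electrode masks are empty; refine dx or widen electrodes")
    return FieldGrid(dx=dx, dz=dz, kappa=kappa, plus_mask=plus, ref_mask=ref,
                     omega=2.0 * np.pi * f, bottom_ref=bottom, layer_edges=edges)


# --------------------------------------------------------------------------
# potential solve
# --------------------------------------------------------------------------


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def solve_potential(grid: FieldGrid, v_drive: float = 1.65) -> FieldSolution:
    """Solve ∇·(κ∇V)=0 with electrode Dirichlet and insulating side/bottom walls."""
    if not grid.plus_mask.any() or not grid.ref_mask.any():
        raise ValueError("both electrode masks must be non-empty")
    nz, nx = grid.shape
    k = grid.kappa
    dx, dz = grid.dx, grid.dz
    n = nz * nx
    idx = np.arange(n).reshape(nz, nx)

    # face conductances per unit depth (2-D): horizontal faces couple rows,
    # vertical faces couple columns; harmonic mean handles layer interfaces.
    g_v = _harmonic(k[:-1, :], k[1:, :]) * dx / dz      # (nz-1, nx)
    g_h = _harmonic(k[:, :-1], k[:, 1:]) * dz / dx      # (nz, nx-1)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n, dtype=complex)
    rhs = np.zeros(n, dtype=complex)

    def couple(a: np.ndarray, b: np.ndarray, g: np.ndarray) -> None:
        a, b, g = a.ravel(), b.ravel(), g.ravel()
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-g, -g])
        np.add.at(diag, a, g)
        np.add.at(diag, b, g)

    couple(idx[:-1, :], idx[1:, :], g_v)
    couple(idx[:, :-1], idx[:, 1:], g_h)

    # electrode faces: half-cell conductance to the Dirichlet surface value
    g_top = k[0, :] * dx / (dz / 2.0)
    top_ids = idx[0, :]
    for mask, v_bc in ((grid.plus_mask, v_drive), (grid.ref_mask if not grid.bottom_ref else np.zeros(nx, bool), 0.0)):
        sel = top_ids[mask]
        diag[sel] += g_top[mask]
        rhs[sel] += g_top[mask] * v_bc
    if grid.bottom_ref:
        g_bot = k[-1, :] * dx / (dz / 2.0)
        sel = idx[-1, :]
        diag[sel] += g_bot
        # rhs += 0

    a_mat = sparse.csr_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n)]), np.concatenate(cols + [np.arange(n)]))),
        shape=(n, n),
    )
    v = spsolve(a_mat, rhs)
    res = np.linalg.norm(a_mat @ v - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and res / scale > 1e-8:
        raise RuntimeError(f"solver residual {res / scale:.2e} exceeds 1e-8 relative tolerance")
    vmap = v.reshape(nz, nx)

    # net complex current through each electrode (positive = into the tissue)
    i_plus = complex(np.sum(g_top[grid.plus_mask] * (v_drive - vmap[0, grid.plus_mask])))
    if grid.bottom_ref:
        g_bot = k[-1, :] * dx / (dz / 2.0)
        i_ref = complex(np.sum(g_bot * (0.0 - vmap[-1, :])))
    else:
        i_ref = complex(np.sum(g_top[grid.ref_mask] * (0.0 - vmap[0, grid.ref_mask])))
    return FieldSolution(potential=vmap, i_plus=i_plus, i_ref=i_ref)


# --------------------------------------------------------------------------
# derived fields
# --------------------------------------------------------------------------


def current_density(sol: FieldSolution, grid: FieldGrid) -> FieldSolution:
    """Fill E, J_real, D, J_imag and |J| from the solved potential."""
    if sol.potential is None:
        raise ValueError("potential must be solved first")
    v = sol.potential
    gz, gx = np.gradient(v, grid.dz, grid.dx)
    e = -np.stack([gz, gx])                       # (2, nz, nx) complex
    sigma = grid.kappa.real
    w_eps = grid.kappa.imag                       # ω·ε0·εr per cell
    sol.e_field = e
    sol.j_real = sigma * e
    with np.errstate(invalid="ignore", divide="ignore"):
        eps_abs = np.where(grid.omega > 0, w_eps / grid.omega, 0.0)
    sol.d_field = eps_abs * e
    sol.j_imag = 1j * grid.omega * sol.d_field
    j_total = grid.kappa * e
    sol.j_total_mag = np.sqrt(np.abs(j_total[0]) ** 2 + np.abs(j_total[1]) ** 2)
    return sol


def _interface_row(grid: FieldGrid, below_layer: str) -> int | None:
    for name, row in grid.layer_edges:
        if name == below_layer:
            return row
    return None


def summarize_field(sol: FieldSolution, grid: FieldGrid) -> FieldReport:
    """Peak |J|, laterally averaged depth profile, dermis-crossing fraction, balance."""
    if sol.j_total_mag is None:
        raise ValueError("current densities must be computed first")
    nz, nx = grid.shape
    peak = float(sol.j_total_mag.max()) * A_PER_M2_TO_MA_PER_CM2
    profile = sol.j_total_mag.mean(axis=1) * A_PER_M2_TO_MA_PER_CM2
    depths = (np.arange(nz) + 0.5) * grid.dz

    balance = abs(sol.i_plus + sol.i_ref) / max(abs(sol.i_plus), 1e-300)

    dermis_fraction = 0.0
    row = _interface_row(grid, "dermis")
    if row is not None and row > 0 and abs(sol.i_plus) > 0:
        g_face = _harmonic(grid.kappa[row - 1, :], grid.kappa[row, :]) * grid.dx / grid.dz
        flux_down = g_face * (sol.potential[row - 1, :] - sol.potential[row, :])
        # current that flows downward across the epidermis-dermis interface
        # under the driven electrode, as a fraction of the injected current
        i_cross = np.sum(flux_down[flux_down.real > 0])
        dermis_fraction = float(abs(i_cross) / abs(sol.i_plus))
    return FieldReport(
        peak_mA_per_cm2=peak,
        depth_profile_mA_per_cm2=profile,
        depths_m=depths,
        dermis_fraction=dermis_fraction,
        current_balance_error=float(balance),
        f_hz=grid.omega / (2.0 * np.pi),
    )
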