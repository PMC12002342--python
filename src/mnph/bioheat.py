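"""Transient Pennes bioheat solver on the nested-cylinder tumor/skin model.

Physics
-------
Heat transfer in perfused tissue follows the Pennes equation

    rho C_p dT/dt = div(k grad T) + rho_b C_b omega_b (T_b - T) + Q_met + Q_nano

with a distributed blood heat sink proportional to the perfusion rate
omega_b, a metabolic source Q_met, and the nanoparticle power Q_nano
deposited uniformly in the tumor.  The geometry is two coaxial cylinders of
equal height — tumor (r <= 5 mm by default) nested in normal skin
(r <= 15 mm) — so the full 3-D problem reduces exactly to the axisymmetric
(r, z) plane.

Discretization
--------------
Node-centered finite volumes on a uniform (r, z) grid.  Face conductances use
the harmonic mean of the nodal conductivities, which keeps the heat flux
continuous across the tumor-skin material jump.  The symmetry axis r = 0
carries a half-cell with zero flux; the outer lateral surface r = R_skin is
convective, n.(-k grad T) = h (T - T_ext); top and bottom faces are insulated
(each face is configurable).  Time integration is fully implicit backward
Euler by default (unconditionally stable; its steady state is the exact
discrete steady state), with Crank-Nicolson available.  The constant system
matrix is LU-factorized once per run.

Temperatures are kelvin internally; Celsius only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import splu

from .constants import T_BODY

__all__ = [
    "TissueMaterial",
    "BloodProperties",
    "TissueModel",
    "SimulationGrid",
    "TemperatureHistory",
    "PennesBioheatModel",
    "perfusion_source",
    "steady_state_estimate",
    "simulate",
    "default_probe_points",
    "extract_probes",
]


@dataclass(frozen=True)
class TissueMaterial:
    """Per-domain thermal and perfusion properties (SI)."""

    rho: float  # density (kg/m^3)
    C_p: float  # heat capacity (J/kg/K)
    k: float  # thermal conductivity (W/m/K)
    omega_b: float  # blood perfusion rate (1/s)
    Q_met: float  # metabolic heat (W/m^3)

    def __post_init__(self):
        if self.rho <= 0 or self.C_p <= 0 or self.k <= 0:
            raise ValueError("rho, C_p and k must be strictly positive")
        if self.omega_b < 0 or self.Q_met < 0:
            raise ValueError("omega_b and Q_met cannot be negative")


@dataclass(frozen=True)
class BloodProperties:
    rho_b: float = 1050.0  # kg/m^3
    C_b: float = 3617.0  # J/kg/K
    T_b: float = T_BODY  # arterial temperature (K)

    def __post_init__(self):
        if self.rho_b <= 0 or self.C_b <= 0 or self.T_b <= 0:
            raise ValueError("blood properties must be strictly positive")


@dataclass(frozen=True)
class TissueModel:
    """Nested-cylinder scenario: geometry, materials and thermal forcing."""

    tumor_radius: float  # m
    skin_radius: float  # m
    height: float  # m
    tumor: TissueMaterial
    skin: TissueMaterial
    blood: BloodProperties
    Q_nano: float  # volumetric nanoparticle power in the tumor (W/m^3)
    h: float = 3.6  # skin-surface heat transfer coefficient (W/m^2/K)
    T_ext: float = T_BODY  # external temperature (K)
    T_0: float = T_BODY  # initial temperature (K)
    # which boundary faces exchange heat convectively (others insulated)
    convective_faces: tuple[str, ...] = ("lateral",)

    def __post_init__(self):
        if not 0 < self.tumor_radius < self.skin_radius:
            raise ValueError("need 0 < tumor radius < skin radius")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.h < 0 or self.Q_nano < 0:
            raise ValueError("h and Q_nano cannot be negative")
        bad = set(self.convective_faces) - {"lateral", "top", "bottom"}
        if bad:
            raise ValueError(f"unknown boundary faces: {sorted(bad)}")


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform discretization of the (r, z) plane and of time."""

    dr: float = 0.5e-3  # m
    dz: float = 0.5e-3  # m
    dt: float = 1.0  # s
    duration: float = 3600.0  # s
    output_interval: float = 60.0  # field storage cadence (s)
    theta: float = 1.0  # 1.0 backward Euler, 0.5 Crank-Nicolson

    def __post_init__(self):
        for name in ("dr", "dz", "dt", "duration", "output_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1] for stability")


@dataclass
class TemperatureHistory:
    """Stored temperature fields plus per-step probe traces.

    ``fields`` has shape (n_stored, n_r, n_z) on the node grid (r, z); all
    temperatures in kelvin.
    """

    r: np.ndarray  # radial node coordinates (m)
    z: np.ndarray  # axial node coordinates (m)
    times: np.ndarray  # stored-field times (s)
    fields: np.ndarray  # (nt, nr, nz) kelvin
    probe_times: np.ndarray  # per-step times (s)
    probe_values: np.ndarray  # (nsteps+1, nprobes) kelvin
    probe_points: np.ndarray  # (nprobes, 2) (r, z) in m
    probe_names: tuple[str, ...]
    tumor_mask: np.ndarray = dataclass_field(default=None)  # (nr, nz) bool

    def interpolator(self, index: int = -1) -> RegularGridInterpolator:
        """Bilinear interpolator of the stored field at one output time."""
        return RegularGridInterpolator(
            (self.r, self.z), self.fields[index], method="linear", bounds_error=True
        )

    def peak(self, index: int = -1) -> float:
        """Domain-maximum temperature (K) of a stored field."""
        return float(self.fields[index].max())

    def radial_profile(self, index: int = -1, z_pos: float | None = None):
        """Temperature along the radial line at height ``z_pos`` (default mid)."""
        if z_pos is None:
            z_pos = 0.5 * (self.z[0] + self.z[-1])
        interp = self.interpolator(index)
        pts = np.column_stack([self.r, np.full_like(self.r, z_pos)])
        return self.r.copy(), interp(pts)


def perfusion_source(T, material: TissueMaterial, blood: BloodProperties):
    """Blood heat sink/source density rho_b C_b omega_b (T_b - T) in W/m^3.

    Positive (heating) when the tissue is colder than arterial blood.
    """
    return blood.rho_b * blood.C_b * material.omega_b * (blood.T_b - np.asarray(T))


def steady_state_estimate(model: TissueModel) -> float:
    """Conduction-free local balance T_b + (Q_nano + Q_met)/(rho_b C_b omega_b).

    Upper bound on the simulated peak: conduction can only carry heat away
    from the hottest point.
    """
    if model.tumor.omega_b <= 0:
        raise ValueError("steady-state estimate requires nonzero perfusion")
    denom = model.blood.rho_b * model.blood.C_b * model.tumor.omega_b
    return model.blood.T_b + (model.Q_nano + model.tumor.Q_met) / denom


class PennesBioheatModel:
    """Discretized axisymmetric bioheat problem with a prepared sparse solver.

    Construction assembles the finite-volume operators (``build_domain``);
    :meth:`step` advances one time step, :meth:`solve` runs the configured
    duration and records probes and field snapshots.
    """

    def __init__(self, model: TissueModel, grid: SimulationGrid):
        self.model = model
        self.grid = grid
        self._build_domain()
        self._assemble()

    # -- domain construction -------------------------------------------------
    def _build_domain(self):
        m, g = self.model, self.grid
        n_r = int(round(m.skin_radius / g.dr)) + 1
        n_z = int(round(m.height / g.dz)) + 1
        if not math.isclose((n_r - 1) * g.dr, m.skin_radius, rel_tol=1e-9):
            raise ValueError("dr must divide the skin radius evenly")
        if not math.isclose((n_z - 1) * g.dz, m.height, rel_tol=1e-9):
            raise ValueError("dz must divide the height evenly")
        if m.tumor_radius / g.dr < 4:
            raise ValueError(
                "grid too coarse: fewer than 4 cells span the tumor radius"
            )
        self.n_r, self.n_z = n_r, n_z
        self.r = np.arange(n_r) * g.dr
        self.z = np.arange(n_z) * g.dz
        # node is tumor when its radius is inside the tumor cylinder
        self.tumor_mask_r = self.r <= m.tumor_radius + 1e-12
        self.tumor_mask = np.repeat(
            self.tumor_mask_r[:, None], n_z, axis=1
        )  # (n_r, n_z)

        # per-node material coefficient arrays
        def per_node(attr):
            vals = np.where(
                self.tumor_mask_r,
                getattr(m.tumor, attr),
                getattr(m.skin, attr),
            )
            return np.repeat(vals[:, None], n_z, axis=1)

        self.k_node = per_node("k")
        self.rhoC_node = per_node("rho") * per_node("C_p")
        self.omega_node = per_node("omega_b")
        self.Qmet_node = per_node("Q_met")
        self.Qnano_node = np.where(self.tumor_mask, m.Q_nano, 0.0)

        # control volumes: radial annulus area x axial width (full 2*pi)
        rm = np.maximum(self.r - g.dr / 2, 0.0)
        rp = np.minimum(self.r + g.dr / 2, m.skin_radius)
        self.annulus = math.pi * (rp**2 - rm**2)  # (n_r,)
        wz = np.full(n_z, g.dz)
        wz[0] = wz[-1] = g.dz / 2
        self.wz = wz
        self.volume = self.annulus[:, None] * wz[None, :]  # (n_r, n_z)

    def cell_volumes(self) -> np.ndarray:
        return self.volume

    # -- operator assembly ---------------------------------------------------
    def _assemble(self):
        m, g = self.model, self.grid
        n_r, n_z, n = self.n_r, self.n_z, self.n_r * self.n_z
        idx = np.arange(n).reshape(n_r, n_z)

        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        def harmonic(k1, k2):
            return 2.0 * k1 * k2 / (k1 + k2)

        # radial faces between (i, j) and (i+1, j)
        for i in range(n_r - 1):
            r_face = self.r[i] + g.dr / 2
            k_face = harmonic(self.k_node[i, 0], self.k_node[i + 1, 0])
            for j in range(n_z):
                G = 2.0 * math.pi * r_face * self.wz[j] * k_face / g.dr
                a, b = idx[i, j], idx[i + 1, j]
                add(a, a, G), add(a, b, -G)
                add(b, b, G), add(b, a, -G)
        # axial faces between (i, j) and (i, j+1)
        for j in range(n_z - 1):
            for i in range(n_r):
                k_face = self.k_node[i, 0]  # uniform in z within a column
                G = self.annulus[i] * k_face / g.dz
                a, b = idx[i, j], idx[i, j + 1]
                add(a, a, G), add(a, b, -G)
                add(b, b, G), add(b, a, -G)

        L = sp.csr_matrix(
            (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
        )

        # perfusion sink (diagonal) and constant sources
        P = (
            m.blood.rho_b * m.blood.C_b * self.omega_node * self.volume
        ).ravel()  # W/K per node
        rhs = ((self.Qmet_node + self.Qnano_node) * self.volume).ravel()
        rhs = rhs + P * m.blood.T_b

        # convective faces
        hA = np.zeros(n)
        if m.h > 0:
            if "lateral" in m.convective_faces:
                area = 2.0 * math.pi * m.skin_radius * self.wz  # per z node
                hA[idx[-1, :]] += m.h * area
            if "bottom" in m.convective_faces:
                hA[idx[:, 0]] += m.h * self.annulus
            if "top" in m.convective_faces:
                hA[idx[:, -1]] += m.h * self.annulus
        rhs = rhs + hA * m.T_ext

        self._L = L + sp.diags(P + hA)
        self._rhs_const = rhs
        self._capacity = (self.rhoC_node * self.volume).ravel()  # J/K per node
        C_dt = sp.diags(self._capacity / g.dt)
        theta = g.theta
        self._lhs = (C_dt + theta * self._L).tocsc()
        self._rhs_mat = (C_dt - (1.0 - theta) * self._L).tocsr()
        self._lu = splu(self._lhs)

    # -- stepping ------------------------------------------------------------
    def step(self, T: np.ndarray) -> np.ndarray:
        """Advance the flattened temperature state by one time step."""
        rhs = self._rhs_mat.dot(T) + self._rhs_const
        T_new = self._lu.solve(rhs)
        if not np.all(np.isfinite(T_new)):
            raise RuntimeError(
                "linear solver produced non-finite temperatures "
                f"(|rhs| max {np.abs(rhs).max():.3e})"
            )
        return T_new

    def energy_residual(self, T_old: np.ndarray, T_new: np.ndarray) -> float:
        """Discrete energy-balance defect of one step, relative to the source term.

        (stored energy rate) - (sources - diffusive/convective losses) summed
        over the domain; identically zero for the implicit scheme up to
        roundoff and linear-solver tolerance.
        """
        g = self.grid
        stored = np.sum(self._capacity * (T_new - T_old)) / g.dt
        T_theta = g.theta * T_new + (1.0 - g.theta) * T_old
        net_in = np.sum(self._rhs_const - self._L.dot(T_theta))
        scale = max(np.abs(self._rhs_const).sum(), 1.0)
        return abs(stored - net_in) / scale

    # -- full run ------------------------------------------------------------
    def solve(
        self, probe_points: np.ndarray | None = None, probe_names=None
    ) -> TemperatureHistory:
        m, g = self.model, self.grid
        n_steps = int(round(g.duration / g.dt))
        store_every = max(1, int(round(g.output_interval / g.dt)))

        if probe_points is None:
            probe_points = default_probe_points(m)
            probe_names = tuple(f"P{i + 1}" for i in range(len(probe_points)))
        probe_points = np.asarray(probe_points, dtype=float)
        if probe_names is None:
            probe_names = tuple(f"P{i + 1}" for i in range(len(probe_points)))
        w_idx, w_val = self._probe_weights(probe_points)

        T = np.full(self.n_r * self.n_z, m.T_0)
        fields = [T.reshape(self.n_r, self.n_z).copy()]
        times = [0.0]
        probe_vals = [(w_val * T[w_idx]).sum(axis=1)]
        probe_times = [0.0]

        for step_i in range(1, n_steps + 1):
            T = self.step(T)
            t = step_i * g.dt
            probe_vals.append((w_val * T[w_idx]).sum(axis=1))
            probe_times.append(t)
            if step_i % store_every == 0 or step_i == n_steps:
                fields.append(T.reshape(self.n_r, self.n_z).copy())
                times.append(t)

        return TemperatureHistory(
            r=self.r.copy(),
            z=self.z.copy(),
            times=np.asarray(times),
            fields=np.asarray(fields),
            probe_times=np.asarray(probe_times),
            probe_values=np.asarray(probe_vals),
            probe_points=probe_points,
            probe_names=tuple(probe_names),
            tumor_mask=self.tumor_mask.copy(),
        )

    def _probe_weights(self, points: np.ndarray):
        """Bilinear interpolation stencils (node indices and weights) per probe."""
        g = self.grid
        idx = np.arange(self.n_r * self.n_z).reshape(self.n_r, self.n_z)
        w_idx = np.empty((len(points), 4), dtype=int)
        w_val = np.empty((len(points), 4))
        for p, (r, z) in enumerate(points):
            if not (self.r[0] - 1e-12 <= r <= self.r[-1] + 1e-12) or not (
                self.z[0] - 1e-12 <= z <= self.z[-1] + 1e-12
            ):
                raise ValueError(f"probe point ({r}, {z}) outside the domain")
            fi = min(max(r / g.dr, 0.0), self.n_r - 1)
            fj = min(max(z / g.dz, 0.0), self.n_z - 1)
            i0, j0 = min(int(fi), self.n_r - 2), min(int(fj), self.n_z - 2)
            xi, zj = fi - i0, fj - j0
            w_idx[p] = [idx[i0, j0], idx[i0 + 1, j0], idx[i0, j0 + 1], idx[i0 + 1, j0 + 1]]
            w_val[p] = [
                (1 - xi) * (1 - zj),
                xi * (1 - zj),
                (1 - xi) * zj,
                xi * zj,
            ]
        return w_idx, w_val


def default_probe_points(model: TissueModel, n: int = 6) -> np.ndarray:
    """P1..Pn equally spaced along the mid-height radial line, center to edge."""
    r = np.linspace(0.0, model.skin_radius, n)
    z = np.full(n, model.height / 2.0)
    return np.column_stack([r, z])


def simulate(
    model: TissueModel, grid: SimulationGrid, probe_points=None, probe_names=None
) -> TemperatureHistory:
    """Run the transient solve for the configured duration (functional surface)."""
    return PennesBioheatModel(model, grid).solve(probe_points, probe_names)


def extract_probes(history: TemperatureHistory, points, names=None):
    """Interpolate the stored fields of a finished run at arbitrary points.

    Returns a pandas DataFrame (time plus one column per point, in kelvin).
    """
    import pandas as pd

    points = np.asarray(points, dtype=float)
    if names is None:
        names = [f"P{i + 1}" for i in range(len(points))]
    cols = {name: [] for name in names}
    for i in range(len(history.times)):
        interp = history.interpolator(i)
        vals = interp(points)
        for name, v in zip(names, vals):
            cols[name].append(float(v))
    out = pd.DataFrame({"time_s": history.times, **cols})
    return out
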