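"""Spatial simulator of one spherical synthetic cell.

A surfactant-stabilized aqueous microdroplet (the "cell", radius r_cell)
confines the fuel-driven reaction cycle.  Dilute species live on a vertical
stack of layers (1-D discretization of the sphere); coacervate droplets
carry full 3-D positions and move by Stokes sedimentation (v ∝ R², downward)
plus Stokes–Einstein Brownian motion (D_drop ∝ 1/R).  Droplets exchange
material with the layer their center occupies via the size-control growth
law, fuse on contact, dissolve below R_min, and nucleate where the local
activated concentration exceeds c_sat.

The combination of threshold nucleation, size-dependent sedimentation and
super-linear efflux produces the emergent relaxation oscillation: droplets
nucleate near the top, grow, sediment, fuse into a large bottom droplet
that expels material, which is reactivated and accumulates at the top until
the next nucleation wave.

Units: mM, µm, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem_cycle import KineticParams, aqueous_fuel
from .size_control import (
    FOUR_THIRDS_PI,
    DropletFieldParams,
    MaterialBalanceError,
    radii_to_volumes,
    volumes_to_radii,
)

__all__ = [
    "CellParams",
    "DropletState",
    "SimOutput",
    "CellSimulator",
    "sedimentation_velocity",
    "coalesce",
    "run_cell",
]


@dataclass(frozen=True)
class CellParams:
    """Geometry, transport and chemistry of one synthetic cell.

    ``sed_coeff`` is the Stokes prefactor 2Δρg/(9η) scaled so that the
    settling speed is sed_coeff·R² (µm·s⁻¹ for R in µm); ``kT_drag`` sets
    the droplet diffusivity D_drop = kT_drag/R.  Neither is measured in the
    source system; defaults make µm droplets settle across a ~25 µm cell in
    tens of seconds while sub-optimal nuclei stay suspended by Brownian
    motion (see docs/methods.md).
    """

    r_cell: float = 25.0
    n_layers: int = 12
    D_A: float = 50.0
    D_P: float = 50.0
    sed_coeff: float = 1.0
    kT_drag: float = 0.02
    fusion_enabled: bool = True
    motion_enabled: bool = True
    c_total: float = 10.0
    field: DropletFieldParams = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field is None:
            object.__setattr__(
                self,
                "field",
                DropletFieldParams(nucleation_rate_coeff=1.0e-4, nucleation_exponent=3.0),
            )
        if self.r_cell <= 0:
            raise ValueError("r_cell must be > 0")
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.D_A < 0 or self.D_P < 0:
            raise ValueError("diffusivities must be >= 0")
        if self.sed_coeff < 0 or self.kT_drag < 0:
            raise ValueError("sed_coeff and kT_drag must be >= 0")

    def with_(self, **kwargs) -> "CellParams":
        return replace(self, **kwargs)

    @property
    def chem(self) -> KineticParams:
        return self.field.chem

    @property
    def layer_edges(self) -> np.ndarray:
        return np.linspace(-self.r_cell, self.r_cell, self.n_layers + 1)

    @property
    def layer_volumes(self) -> np.ndarray:
        """Volumes (µm³) of the horizontal slabs of the sphere."""
        z = self.layer_edges
        r = self.r_cell
        # ∫ π (r² − z²) dz between consecutive edges
        prim = math.pi * (r ** 2 * z - z ** 3 / 3.0)
        return np.diff(prim)

    @property
    def interface_areas(self) -> np.ndarray:
        """Horizontal cross-section areas (µm²) at interior layer edges."""
        z = self.layer_edges[1:-1]
        return math.pi * (self.r_cell ** 2 - z ** 2)

    def stable_dt(self) -> float:
        """Largest time step passing the explicit-scheme stability check."""
        dz = 2.0 * self.r_cell / self.n_layers
        limits = [60.0]
        D = max(self.D_A, self.D_P)
        if D > 0:
            limits.append(0.1 * dz * dz / D)
        if self.chem.k_deact > 0:
            limits.append(0.1 / self.chem.k_deact)
        f_eq = aqueous_fuel(self.chem.c_fuel_oil, self.chem)
        if self.chem.k_act * f_eq > 0:
            limits.append(0.1 / (self.chem.k_act * f_eq))
        return min(limits)


@dataclass
class DropletState:
    """One droplet: stable id, center position (µm, z up, origin at cell
    center) and radius (µm)."""

    id: int
    x: float
    y: float
    z: float
    R: float

    @property
    def volume(self) -> float:
        return FOUR_THIRDS_PI * self.R ** 3


def sedimentation_velocity(R: float, params: CellParams) -> float:
    """Downward Stokes settling speed sed_coeff·R² (µm·s⁻¹, magnitude)."""
    if np.any(np.asarray(R) < 0):
        raise ValueError("R must be >= 0")
    return params.sed_coeff * np.asarray(R) ** 2


def coalesce(a: DropletState, b: DropletState, r_cell: float | None = None) -> DropletState:
    """Fuse two overlapping droplets, conserving volume exactly.

    The product radius is (R_a³+R_b³)^(1/3), the center the volume-weighted
    centroid (shifted minimally back inside the cell when r_cell is given),
    and the id the smaller of the two — the older track continues.
    """
    dist = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
    if dist >= a.R + b.R:
        raise ValueError(f"droplets do not overlap (distance {dist:.3f} >= {a.R + b.R:.3f})")
    Va, Vb = a.volume, b.volume
    R = (a.R ** 3 + b.R ** 3) ** (1.0 / 3.0)
    c = np.array([
        (Va * a.x + Vb * b.x) / (Va + Vb),
        (Va * a.y + Vb * b.y) / (Va + Vb),
        (Va * a.z + Vb * b.z) / (Va + Vb),
    ])
    if r_cell is not None:
        norm = np.linalg.norm(c)
        if norm + R > r_cell:
            c *= max(r_cell - R, 0.0) / max(norm, 1e-12)
    return DropletState(id=min(a.id, b.id), x=c[0], y=c[1], z=c[2], R=R)


@dataclass
class SimOutput:
    """Trajectory table, event log and per-layer concentration history."""

    trajectory: pd.DataFrame  # t, id, x, y, z, R
    events: pd.DataFrame      # t, kind, ids
    layers: pd.DataFrame      # t, layer, c_P, c_A, c_F
    params: CellParams

    def droplet_counts(self) -> pd.Series:
        return self.trajectory.groupby("t")["id"].count()


class CellSimulator:
    """Stateful explicit-time-step simulator of one synthetic cell.

    A fixed seed plus fixed parameters gives a bit-identical event
    sequence.  ``dt`` must pass the stability check; by default it is
    chosen automatically.
    """

    def __init__(self, params: CellParams, dt: float | None = None):
        self.params = params
        limit = params.stable_dt()
        if dt is None:
            dt = limit
        elif dt > limit * 1.0000001:
            raise ValueError(
                f"dt={dt:g}s too large for stability; use dt <= {limit:.4g}s"
            )
        self.dt = dt
        self.rng = np.random.default_rng(params.seed)
        self.t = 0.0
        n = params.n_layers
        self.c_P = np.full(n, float(params.c_total))
        self.c_A = np.zeros(n)
        self.c_W = np.zeros(n)
        self.f_eq = aqueous_fuel(params.chem.c_fuel_oil, params.chem)
        self.ids = np.empty(0, dtype=int)
        self.pos = np.empty((0, 3))
        self.R = np.empty(0)
        self._next_id = 0
        self.events: list[tuple[float, str, str]] = []
        self._V_l = params.layer_volumes
        self._A_if = params.interface_areas
        self._dz = 2.0 * params.r_cell / params.n_layers
        self._inventory0 = self.total_peptide()

    # -- bookkeeping ---------------------------------------------------

    def total_peptide(self) -> float:
        """Peptide inventory (mM·µm³): dilute layers + droplet-bound."""
        dilute = float(((self.c_P + self.c_A) * self._V_l).sum())
        bound = self.params.chem.c_den * radii_to_volumes(self.R).sum()
        return dilute + bound

    def droplet_layers(self) -> np.ndarray:
        idx = np.floor((self.pos[:, 2] + self.params.r_cell) / self._dz).astype(int)
        return np.clip(idx, 0, self.params.n_layers - 1)

    def add_droplet(self, x: float, y: float, z: float, R: float) -> int:
        i = self._next_id
        self._next_id += 1
        self.ids = np.append(self.ids, i)
        self.pos = np.vstack([self.pos, [x, y, z]])
        self.R = np.append(self.R, R)
        return i

    def _remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        self.ids, self.pos, self.R = self.ids[keep], self.pos[keep], self.R[keep]

    # -- one explicit step ---------------------------------------------

    def step(self) -> None:
        p = self.params
        chem = p.chem
        fld = p.field
        dt = self.dt

        # (1) layer chemistry (fuel clamped to partition equilibrium)
        act = chem.k_act * self.c_P * self.f_eq * dt
        np.minimum(act, self.c_P, out=act)
        deact = chem.k_deact * self.c_A * dt
        self.c_A += act - deact
        self.c_P += deact - act
        self.c_W += act + chem.k_fuel_loss * self.f_eq * dt

        # (2) vertical diffusion of dilute species (conservative explicit)
        for c, D in ((self.c_P, p.D_P), (self.c_A, p.D_A)):
            if D > 0 and p.n_layers > 1:
                flux = D * self._A_if * np.diff(c) / self._dz * dt  # mM·µm³ upward-positive
                c[:-1] += flux / self._V_l[:-1]
                c[1:] -= flux / self._V_l[1:]

        # (3) droplet ↔ layer material exchange
        if self.R.size:
            lay = self.droplet_layers()
            V_old = radii_to_volumes(self.R)
            drive = fld.growth_drive(self.c_A[lay].clip(min=0.0))
            infl = 4.0 * math.pi * self.R ** 2 * fld.k_up * drive * dt
            # cap uptake at the material available in each layer
            demand = np.zeros(p.n_layers)
            np.add.at(demand, lay, infl)
            avail = np.maximum(self.c_A, 0.0) * self._V_l
            scale = np.ones(p.n_layers)
            over = demand > avail
            scale[over] = np.where(demand[over] > 0, avail[over] / demand[over], 0.0)
            infl *= scale[lay]
            effl = chem.k_deact * chem.c_den * V_old * dt
            V_new = np.maximum(V_old + (infl - effl) / chem.c_den, 0.0)
            np.add.at(self.c_A, lay, -infl / self._V_l[lay])
            np.add.at(self.c_P, lay, effl / self._V_l[lay])
            self.R = volumes_to_radii(V_new)
            # dissolution below R_min returns material to the layer
            small = self.R < fld.R_min
            if small.any():
                np.add.at(self.c_A, lay[small],
                          chem.c_den * V_new[small] / self._V_l[lay[small]])
                for i in self.ids[small]:
                    self.events.append((self.t, "dissolve", str(int(i))))
                self._remove(small)

        # (4) motion: sedimentation + Brownian, reflective spherical wall
        if p.motion_enabled and self.R.size:
            v = sedimentation_velocity(self.R, p)
            self.pos[:, 2] -= v * dt
            if p.kT_drag > 0:
                sigma = np.sqrt(2.0 * (p.kT_drag / self.R) * dt)
                self.pos += self.rng.normal(size=self.pos.shape) * sigma[:, None]
            # wall contact: project inside, then roll towards the bottom
            norm = np.linalg.norm(self.pos, axis=1)
            max_norm = np.maximum(p.r_cell - self.R, 0.0)
            outside = norm > max_norm
            if outside.any():
                u = self.pos[outside] / np.maximum(norm[outside], 1e-12)[:, None]
                # tangential component of gravity drives rolling
                g_t = -np.eye(3)[2] - (-u[:, 2])[:, None] * u
                roll = v[outside, None] * g_t * dt
                self.pos[outside] = u * max_norm[outside][:, None] + roll
                norm2 = np.linalg.norm(self.pos[outside], axis=1)
                self.pos[outside] *= (
                    np.minimum(norm2, max_norm[outside]) / np.maximum(norm2, 1e-12)
                )[:, None]

        # (5) pairwise fusion where enabled (ascending-id tie-break)
        if p.fusion_enabled and self.R.size > 1:
            self._fuse_overlaps()

        # (6) layer-local nucleation above c_sat
        if fld.nucleation_rate_coeff > 0:
            excess = np.maximum(self.c_A - chem.c_sat, 0.0)
            x = excess / chem.c_sat
            lam = (fld.nucleation_rate_coeff * excess
                   * x ** (fld.nucleation_exponent - 1.0) * self._V_l * dt)
            counts = self.rng.poisson(lam)
            if counts.any():
                V_nuc = FOUR_THIRDS_PI * fld.R_nuc ** 3
                edges = p.layer_edges
                for l in np.nonzero(counts)[0]:
                    cost = chem.c_den * V_nuc / self._V_l[l]
                    for _ in range(int(counts[l])):
                        if self.c_A[l] < cost:
                            break
                        pt = self._sample_point_in_layer(l, fld.R_nuc, edges)
                        if pt is None:
                            break
                        self.c_A[l] -= cost
                        i = self.add_droplet(*pt, fld.R_nuc)
                        self.events.append((self.t, "nucleate", str(i)))

        self.t += dt

    def _fuse_overlaps(self) -> None:
        # iterate until no overlapping pair remains
        while self.R.size > 1:
            d = np.linalg.norm(self.pos[:, None, :] - self.pos[None, :, :], axis=2)
            touch = d < (self.R[:, None] + self.R[None, :])
            np.fill_diagonal(touch, False)
            ii, jj = np.nonzero(touch)
            if ii.size == 0:
                return
            pairs = [(min(self.ids[i], self.ids[j]), i, j) for i, j in zip(ii, jj) if i < j]
            pairs.sort()
            _, i, j = pairs[0]
            a = DropletState(int(self.ids[i]), *self.pos[i], self.R[i])
            b = DropletState(int(self.ids[j]), *self.pos[j], self.R[j])
            merged = coalesce(a, b, r_cell=self.params.r_cell)
            self.events.append((self.t, "fuse", f"{a.id}+{b.id}"))
            keep = np.ones(self.R.size, dtype=bool)
            keep[[i, j]] = False
            self.ids = np.append(self.ids[keep], merged.id)
            self.pos = np.vstack([self.pos[keep], [merged.x, merged.y, merged.z]])
            self.R = np.append(self.R[keep], merged.R)

    def _sample_point_in_layer(self, l: int, R_nuc: float, edges: np.ndarray):
        r_in = self.params.r_cell - R_nuc
        lo, hi = max(edges[l], -r_in), min(edges[l + 1], r_in)
        if hi <= lo:
            return None
        for _ in range(20):
            z = self.rng.uniform(lo, hi)
            s_max = math.sqrt(max(r_in * r_in - z * z, 0.0))
            s = math.sqrt(self.rng.uniform(0.0, 1.0)) * s_max
            phi = self.rng.uniform(0.0, 2.0 * math.pi)
            return (s * math.cos(phi), s * math.sin(phi), z)
        return None  # pragma: no cover

    # -- runs ----------------------------------------------------------

    def check_balance(self, tol: float = 1e-6) -> float:
        drift = abs(self.total_peptide() - self._inventory0) / self._inventory0
        if drift > tol:
            raise MaterialBalanceError(
                f"peptide inventory drift {drift:.3e} exceeds {tol:.1e} at t={self.t:.1f}s"
            )
        return drift

    def snapshot_rows(self) -> list[tuple]:
        return [
            (self.t, int(i), x, y, z, r)
            for i, (x, y, z), r in zip(self.ids, self.pos, self.R)
        ]

    def run(self, t_end: float, out_dt: float = 2.0, balance_tol: float = 1e-6) -> SimOutput:
        # snap the step to divide the output interval so samples are uniform
        m = max(1, math.ceil(out_dt / self.dt - 1e-12))
        self.dt = out_dt / m
        n_blocks = max(1, math.ceil(t_end / out_dt - 1e-12))
        traj: list[tuple] = []
        layer_rows: list[tuple] = []

        def record(t_nominal: float) -> None:
            self.t = t_nominal  # suppress float drift in recorded times
            traj.extend(self.snapshot_rows())
            for l in range(self.params.n_layers):
                layer_rows.append((t_nominal, l, self.c_P[l], self.c_A[l], self.f_eq))

        record(0.0)
        for b in range(n_blocks):
            for _ in range(m):
                self.step()
            record((b + 1) * out_dt)
            if b % 10 == 9:
                self.check_balance(balance_tol)
        self.check_balance(balance_tol)
        trajectory = pd.DataFrame(traj, columns=["t", "id", "x", "y", "z", "R"])
        events = pd.DataFrame(self.events, columns=["t", "kind", "ids"])
        layers = pd.DataFrame(layer_rows, columns=["t", "layer", "c_P", "c_A", "c_F"])
        return SimOutput(trajectory=trajectory, events=events, layers=layers,
                         params=self.params)


def run_cell(params: CellParams, t_end: float, out_dt: float = 2.0,
             dt: float | None = None) -> SimOutput:
    """Run one synthetic cell from a droplet-free, all-precursor start.

    Deterministic for a fixed ``params.seed``.
    """
    return CellSimulator(params, dt=dt).run(t_end, out_dt=out_dt)
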