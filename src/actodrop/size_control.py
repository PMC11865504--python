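"""Droplet size control: area-proportional influx, volume-proportional efflux.

Droplet material is activated in the dilute phase, so a droplet takes up
activated material through its surface (influx ∝ 4πR²).  Deactivation
happens inside the dense phase, so material leaves in proportion to the
droplet volume (efflux ∝ (4/3)πR³).  The two laws balance at a single
stable radius

    R* = 3·k_up·c_A / (k_deact·c_den),

below which droplets grow and above which they shrink — the opposite of
Ostwald ripening.  This module implements the single-droplet growth law,
the optimal radius, and mean-field evolution of a whole emulsion sharing
one dilute pool (nucleation, dissolution, perturbation, parameter sweeps),
plus a passive Gibbs–Thomson ripening mode as the thermodynamic control.

Units: mM, µm, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

from .chem_cycle import KineticParams, aqueous_fuel, steady_state

FOUR_THIRDS_PI = 4.0 * math.pi / 3.0

__all__ = [
    "DropletFieldParams",
    "Emulsion",
    "MaterialBalanceError",
    "droplet_radius_rate",
    "influx",
    "efflux",
    "optimal_radius",
    "integrate_radius",
    "evolve_emulsion",
    "perturb_emulsion",
    "sweep",
    "extinction_k_deact",
    "fit_relaxation",
    "radii_to_volumes",
    "volumes_to_radii",
]


class MaterialBalanceError(RuntimeError):
    """Raised when the peptide inventory drifts beyond tolerance."""


def radii_to_volumes(radii: np.ndarray) -> np.ndarray:
    return FOUR_THIRDS_PI * np.asarray(radii, dtype=float) ** 3


def volumes_to_radii(volumes: np.ndarray) -> np.ndarray:
    return (np.asarray(volumes, dtype=float) / FOUR_THIRDS_PI) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DropletFieldParams:
    """Growth-law and nucleation parameters for a droplet population.

    ``k_up`` converts dilute activated-peptide concentration into an uptake
    velocity at the droplet surface; its default is calibrated so that at a
    pool pinned to c_sat the optimal radius is 0.75 µm (see docs/methods.md).

    Modes: ``active`` (full cycle), ``gel`` (identical mean-field physics;
    fusion is impossible, which only matters in the spatial simulator) and
    ``passive`` (reactions off, Gibbs–Thomson ripening with capillary
    length ``gibbs_thomson_length``).
    """

    chem: KineticParams = field(default_factory=KineticParams)
    k_up: float = 38.5
    R_nuc: float = 0.2
    R_min: float = 0.1
    nucleation_rate_coeff: float = 1.0e-3
    nucleation_exponent: float = 1.0
    gibbs_thomson_length: float = 0.0
    mode: str = "active"
    supersaturation_influx: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("active", "gel", "passive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.R_min < self.R_nuc:
            raise ValueError("R_min must be < R_nuc")
        if self.nucleation_exponent < 1:
            raise ValueError("nucleation_exponent must be >= 1")
        for name in ("k_up", "nucleation_rate_coeff", "gibbs_thomson_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode == "passive" and self.gibbs_thomson_length <= 0:
            raise ValueError("passive mode requires gibbs_thomson_length > 0")

    def with_(self, **kwargs) -> "DropletFieldParams":
        return replace(self, **kwargs)

    def nucleation_rate(self, excess: float) -> float:
        """Nucleation events per unit volume and time at a supersaturation
        ``excess`` = c_A − c_sat (> 0).  The exponent steepens the
        supersaturation dependence (classical nucleation is strongly
        non-linear); at the default exponent 1 the rate is simply
        coeff·excess."""
        x = excess / self.chem.c_sat
        return self.nucleation_rate_coeff * excess * x ** (self.nucleation_exponent - 1.0)

    def growth_drive(self, c_A: float) -> float:
        """Concentration driving the influx (c_A, or c_A − c_sat if the
        supersaturation-driven variant is switched on)."""
        if self.supersaturation_influx:
            return max(c_A - self.chem.c_sat, 0.0)
        return c_A


@dataclass
class Emulsion:
    """Droplet radii plus the shared dilute pool of one well-mixed system.

    ``c_A_pool`` is the dilute activated-peptide concentration, ``c_P_pool``
    the precursor.  ``volume`` is the system volume (µm³).
    """

    radii: np.ndarray
    c_A_pool: float
    c_P_pool: float
    volume: float
    c_W_pool: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.volume <= 0:
            raise ValueError("system volume must be > 0")
        if self.c_A_pool < 0 or self.c_P_pool < 0:
            raise ValueError("pool concentrations must be >= 0")

    @property
    def n_droplets(self) -> int:
        return int(self.radii.size)

    @property
    def droplet_volumes(self) -> np.ndarray:
        return radii_to_volumes(self.radii)

    @property
    def total_droplet_volume(self) -> float:
        return float(self.droplet_volumes.sum())

    def total_material(self, c_den: float) -> float:
        """Conserved peptide inventory in mM-equivalent of system volume."""
        return self.c_P_pool + self.c_A_pool + c_den * self.total_droplet_volume / self.volume

    def copy(self) -> "Emulsion":
        return Emulsion(self.radii.copy(), self.c_A_pool, self.c_P_pool,
                        self.volume, self.c_W_pool, self.t)


def droplet_radius_rate(R: float, c_A_local: float, params: DropletFieldParams) -> float:
    """dR/dt (µm·s⁻¹) of one droplet in a dilute field c_A_local.

    (influx − efflux) / (4πR²·c_den) with influx = 4πR²·k_up·c_A and
    efflux = k_deact·c_den·(4/3)πR³; positive below R*, negative above.
    """
    if np.any(np.asarray(R) < 0):
        raise ValueError("R must be >= 0")
    chem = params.chem
    return params.k_up * params.growth_drive(c_A_local) / chem.c_den - (chem.k_deact / 3.0) * R


def influx(R: float, c_A_local: float, params: DropletFieldParams) -> float:
    """Activated-material uptake rate through the surface (mM·µm³·s⁻¹)."""
    return 4.0 * math.pi * R ** 2 * params.k_up * params.growth_drive(c_A_local)


def efflux(R: float, params: DropletFieldParams) -> float:
    """Deactivated-material release rate from the volume (mM·µm³·s⁻¹)."""
    return params.chem.k_deact * params.chem.c_den * FOUR_THIRDS_PI * R ** 3


def optimal_radius(c_A: float, params: DropletFieldParams) -> float:
    """The stable radius R* = 3·k_up·c_A/(k_deact·c_den) (µm).

    Raises if k_deact = 0 (passive limit: no optimal radius exists).
    """
    if c_A < 0:
        raise ValueError("c_A must be >= 0")
    if params.chem.k_deact == 0:
        raise ValueError("no optimal radius (passive): k_deact = 0")
    return 3.0 * params.k_up * params.growth_drive(c_A) / (params.chem.k_deact * params.chem.c_den)


def integrate_radius(
    R0: float, c_A: float, params: DropletFieldParams, t_end: float, n_out: int = 200
) -> pd.DataFrame:
    """Integrate the single-droplet growth law at fixed ambient c_A."""
    sol = solve_ivp(
        lambda t, y: [droplet_radius_rate(max(y[0], 0.0), c_A, params)],
        (0.0, t_end), [R0], t_eval=np.linspace(0.0, t_end, n_out),
        rtol=1e-11, atol=1e-13,
    )
    return pd.DataFrame({"t": sol.t, "R": sol.y[0]})


def _stable_dt(params: DropletFieldParams) -> float:
    chem = params.chem
    scales = [60.0]
    if chem.k_deact > 0:
        scales.append(0.05 / chem.k_deact)
    if chem.k_act > 0 and chem.c_fuel_oil > 0:
        scales.append(0.05 / (chem.k_act * aqueous_fuel(chem.c_fuel_oil, chem) + 1e-30))
    return min(min(scales), 1.0)


def evolve_emulsion(
    em: Emulsion,
    params: DropletFieldParams,
    t_end: float,
    seed: int | np.random.Generator | None = 0,
    dt: float | None = None,
    n_out: int = 100,
    balance_tol: float = 1e-6,
) -> list[Emulsion]:
    """Mean-field evolution of an emulsion against its shared dilute pool.

    Active/gel mode: the pool obeys the reaction cycle; droplets exchange
    material by the area/volume flux laws; nucleation is a Poisson process
    with rate ∝ max(0, c_A − c_sat)·volume inserting droplets at R_nuc;
    droplets crossing R_min dissolve back into the pool.  Passive mode:
    reactions off, radii evolve by Gibbs–Thomson exchange with local
    saturation c_sat·(1 + ℓ_c/R).

    Material bookkeeping is exact per step (fluxes are converted to volume
    changes and pool increments from the same numbers), so the peptide
    inventory is conserved to floating-point rounding; drift beyond
    ``balance_tol`` aborts.  Identical seed ⇒ identical event sequence.

    Returns snapshots at ``n_out`` evenly spaced times (including t=0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chem = params.chem
    if dt is None:
        dt = _stable_dt(params)
    state = em.copy()
    inventory0 = state.total_material(chem.c_den)
    t_out = np.linspace(0.0, t_end, n_out)
    snapshots: list[Emulsion] = []
    next_out = 0
    f_eq = aqueous_fuel(chem.c_fuel_oil, chem)
    t = 0.0
    t0 = state.t

    while True:
        while next_out < n_out and t >= t_out[next_out] - 1e-9:
            snap = state.copy()
            snap.t = t0 + t_out[next_out]
            snapshots.append(snap)
            next_out += 1
        if next_out >= n_out:
            break
        step = min(dt, t_out[next_out] - t)
        if params.mode == "passive":
            _passive_step(state, params, step)
        else:
            _active_step(state, params, step, rng, f_eq)
        t += step
        drift = abs(state.total_material(chem.c_den) - inventory0) / max(inventory0, 1e-30)
        if drift > balance_tol:
            raise MaterialBalanceError(
                f"peptide inventory drift {drift:.3e} exceeds {balance_tol:.1e} at t={t:.1f}s"
            )
    return snapshots


def _active_step(state: Emulsion, params: DropletFieldParams, dt: float,
                 rng: np.random.Generator, f_eq: float) -> None:
    """One step of the pool+population dynamics.

    The pool ODE c_A' = S − k_deact·c_A − β·drive(c_A) is linear (β is the
    summed uptake conductance Σ4πR²k_up / V_sys), and often stiff relative
    to the radius dynamics, so c_A is advanced with the exact exponential
    solution over the step and droplet uptake is computed from the
    time-integrated pool concentration — material bookkeeping then closes
    identically whatever dt is.
    """
    chem = params.chem
    V_sys = state.volume
    c_A, c_P = state.c_A_pool, state.c_P_pool
    c_F = f_eq  # instantaneous fuel exchange; finite exchange handled upstream

    S = min(chem.k_act * c_P * c_F, c_P / dt if dt > 0 else np.inf)  # activation source
    R = state.radii
    beta = 4.0 * math.pi * params.k_up * float((R ** 2).sum()) / V_sys if R.size else 0.0
    lam = chem.k_deact + beta
    S_eff = S + beta * chem.c_sat if params.supersaturation_influx else S
    if lam > 0:
        c_ss = S_eff / lam
        decay = math.exp(-lam * dt)
        integral = c_ss * dt + (c_A - c_ss) * (1.0 - decay) / lam  # ∫c_A dt
    else:
        integral = c_A * dt + 0.5 * S_eff * dt * dt
    drive_integral = (
        max(integral - chem.c_sat * dt, 0.0) if params.supersaturation_influx else integral
    )

    uptake_total = 0.0
    if R.size:
        V_old = radii_to_volumes(R)
        upt = 4.0 * math.pi * R ** 2 * params.k_up * drive_integral
        effl = chem.k_deact * chem.c_den * V_old * dt
        uptake_total = float(upt.sum())
        c_P += effl.sum() / V_sys
        V_new = np.maximum(V_old + (upt - effl) / chem.c_den, 0.0)
        R_new = volumes_to_radii(V_new)
        # dissolution: droplets shrinking through R_min return to the pool
        dissolve = R_new < params.R_min
        if dissolve.any():
            c_A += chem.c_den * V_new[dissolve].sum() / V_sys
            R_new = R_new[~dissolve]
        state.radii = R_new

    c_A += S * dt - chem.k_deact * integral - uptake_total / V_sys
    c_P += -S * dt + chem.k_deact * integral
    state.c_W_pool += S * dt + chem.k_fuel_loss * c_F * dt

    # nucleation while supersaturated
    excess = c_A - chem.c_sat
    if excess > 0 and params.nucleation_rate_coeff > 0:
        lam = params.nucleation_rate(excess) * V_sys * dt
        k = int(rng.poisson(lam))
        if k:
            V_nuc = FOUR_THIRDS_PI * params.R_nuc ** 3
            cost = chem.c_den * V_nuc / V_sys
            k = min(k, int(max(c_A, 0.0) // cost))
            if k:
                state.radii = np.concatenate([state.radii, np.full(k, params.R_nuc)])
                c_A -= k * cost

    state.c_A_pool = max(c_A, 0.0)
    state.c_P_pool = max(c_P, 0.0)
    state.t += dt


def _passive_step(state: Emulsion, params: DropletFieldParams, dt: float) -> None:
    """Gibbs–Thomson ripening: exchange with radius-dependent saturation."""
    chem = params.chem
    R = state.radii
    if not R.size:
        state.t += dt
        return
    c_sat_R = chem.c_sat * (1.0 + params.gibbs_thomson_length / np.maximum(R, 1e-9))
    dR = params.k_up * (state.c_A_pool - c_sat_R) / chem.c_den * dt
    V_old = radii_to_volumes(R)
    R_new = np.maximum(R + dR, 0.0)
    V_new = radii_to_volumes(R_new)
    state.c_A_pool -= chem.c_den * (V_new.sum() - V_old.sum()) / state.volume
    dissolve = R_new < params.R_min
    if dissolve.any():
        state.c_A_pool += chem.c_den * V_new[dissolve].sum() / state.volume
        R_new = R_new[~dissolve]
    state.radii = R_new
    state.t += dt


def perturb_emulsion(em: Emulsion, spread: float,
                     seed: int | np.random.Generator | None = 0) -> Emulsion:
    """Randomly rescale droplet volumes, conserving the total exactly.

    Volumes are multiplied by log-normal factors with shape ``spread`` and
    renormalized so the total droplet volume (hence the pool) is unchanged.
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    out = em.copy()
    if spread == 0 or em.n_droplets == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = em.droplet_volumes
    factors = rng.lognormal(mean=0.0, sigma=spread, size=V.size)
    V_new = V * factors
    V_new *= V.sum() / V_new.sum()
    out.radii = volumes_to_radii(V_new)
    return out


def run_to_steady(
    params: DropletFieldParams,
    c_total: float,
    volume: float,
    t_end: float = 4000.0,
    seed: int = 0,
    dt: float | None = None,
    settle_frac: float = 0.2,
    settle_tol: float = 0.05,
) -> tuple[Emulsion, bool]:
    """Evolve a fresh supersaturated system to steady state.

    Starts from all material as precursor, no droplets.  Convergence is
    judged on the relative change of total droplet volume over the final
    ``settle_frac`` of the run.
    """
    em0 = Emulsion(radii=np.empty(0), c_A_pool=0.0, c_P_pool=c_total, volume=volume)
    hist = evolve_emulsion(em0, params, t_end, seed=seed, dt=dt, n_out=200)
    tail = hist[int(len(hist) * (1.0 - settle_frac)):]
    v = np.array([h.total_droplet_volume for h in tail])
    if v[-1] <= 0:
        converged = bool(np.all(v <= 0) or v[0] > 0)  # extinct (or just emptied)
    else:
        converged = bool(abs(v[-1] - v[0]) / max(v[-1], 1e-30) < settle_tol)
    return hist[-1], converged


def sweep(
    name: str,
    values,
    params: DropletFieldParams,
    c_total: float = 14.0,
    volume: float = 1.0e5,
    t_end: float = 4000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state response to a parameter sweep.

    ``name`` is one of ``fuel`` (aqueous fuel concentration, mM),
    ``peptide`` (total peptide, mM), ``k_deact`` (s⁻¹) or ``cell_radius``
    (system radius, µm).  Each row reports the optimal radius at the final
    pool concentration, the measured mean radius, the droplet number
    density and the total droplet volume, plus a convergence flag.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or np.any(np.diff(values) < 0):
        raise ValueError("sweep values must be positive and sorted ascending")
    rows = []
    for i, v in enumerate(values):
        p, ct, vol = params, c_total, volume
        if name == "fuel":
            p = params.with_(chem=params.chem.with_(c_fuel_oil=v / params.chem.K_p))
        elif name == "peptide":
            ct = v
        elif name == "k_deact":
            p = params.with_(chem=params.chem.with_(k_deact=v))
        elif name == "cell_radius":
            vol = FOUR_THIRDS_PI * v ** 3
        else:
            raise ValueError(f"unknown sweep parameter {name!r}")
        final, converged = run_to_steady(p, ct, vol, t_end=t_end, seed=seed + i)
        n = final.n_droplets
        rows.append({
            "value": v,
            "R_star": optimal_radius(final.c_A_pool, p) if n else np.nan,
            "mean_radius": float(final.radii.mean()) if n else np.nan,
            "number_density": n / vol,
            "total_droplet_volume": final.total_droplet_volume,
            "converged": converged,
        })
    return pd.DataFrame(rows)


def extinction_k_deact(params: DropletFieldParams, c_total: float = 14.0) -> float:
    """Deactivation rate above which no droplets can exist (s⁻¹).

    Droplets require the droplet-free steady activated concentration to
    exceed c_sat; the threshold is the root of c_A_ss(k_deact) = c_sat,
    found by bracketed root solving on the kinetic steady state.
    """
    chem = params.chem

    def gap(k: float) -> float:
        ss = steady_state(chem.with_(k_deact=k), c_total_peptide=c_total)
        return ss.state.c_A - chem.c_sat

    k_lo, k_hi = 1e-6, 1.0
    while gap(k_hi) > 0 and k_hi < 1e6:
        k_hi *= 10.0
    if gap(k_lo) < 0:
        raise ValueError("no droplets even at vanishing k_deact under these conditions")
    return float(brentq(gap, k_lo, k_hi, xtol=1e-12, rtol=1e-12))


@dataclass(frozen=True)
class RelaxationFit:
    """Least-squares recovery of growth-law constants from an R(t) trace."""

    k_deact: float
    k_up_over_c_den: float
    R_star: float


def fit_relaxation(t: np.ndarray, R: np.ndarray, c_A: float) -> RelaxationFit:
    """Fit R(t) = R* + (R0 − R*)·exp(−k_deact·t/3) to a noisy relaxation.

    The growth law is linear in R, so a relaxation at fixed ambient c_A is
    a single exponential; recovers k_deact and k_up/c_den = R*·k_deact/(3·c_A).
    """
    t = np.asarray(t, dtype=float)
    R = np.asarray(R, dtype=float)

    def model(t, R_star, R0, b):
        return R_star + (R0 - R_star) * np.exp(-b * t)

    p0 = (R[-1], R[0], max(1.0 / (t[-1] - t[0] + 1e-12), 1e-3))
    popt, _ = curve_fit(model, t, R, p0=p0, maxfev=20000)
    R_star, _, b = popt
    k_deact = 3.0 * b
    return RelaxationFit(k_deact=k_deact, k_up_over_c_den=R_star * k_deact / (3.0 * c_A),
                         R_star=R_star)
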