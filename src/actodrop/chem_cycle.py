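"""Fuel-driven chemical reaction cycle of an active-droplet emulsion.

A hydrophobic carbodiimide fuel sits in an oil reservoir and partitions into
the aqueous phase, where it activates a precursor peptide into its cyclic
anhydride.  The activated peptide hydrolyses back spontaneously, releasing
waste (the urea).  Above a critical activated-peptide concentration
(``c_sat``) complex-coacervate droplets can nucleate; the cycle then keeps
precursor, activated peptide, fuel and waste in a non-equilibrium steady
state at the expense of fuel.

Species (all dilute-phase concentrations, mM):

* ``c_P`` precursor peptide
* ``c_A`` activated (anhydride) peptide
* ``c_F`` aqueous fuel
* ``c_W`` waste (urea + hydrolysed fuel)

Units package-wide: mM, µm, s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

LN2 = math.log(2.0)

__all__ = [
    "KineticParams",
    "ChemState",
    "SteadyStateError",
    "aqueous_fuel",
    "reaction_rhs",
    "integrate",
    "steady_state",
    "halflife_to_rate",
    "rate_to_halflife",
]


class SteadyStateError(RuntimeError):
    """Raised when the fixed-point search fails; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual={residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and partitioning parameters of the fuel cycle.

    Defaults are calibrated placeholders: the experimental system's full
    rate table is not publicly tabulated, so each value here is anchored to
    a reported observable (see docs/methods.md) and can be overridden
    verbatim from a config file.

    Parameters
    ----------
    k_act : float
        Second-order activation rate constant (mM⁻¹·s⁻¹).
    k_deact : float
        First-order deactivation (hydrolysis) rate constant (s⁻¹).
        Default ln2/60: activated-peptide half-life of about a minute.
    k_fuel_loss : float
        First-order direct fuel hydrolysis rate (s⁻¹).
    k_exchange : float
        Oil↔water fuel exchange rate (s⁻¹).  ``inf`` (the default) means
        instantaneous partition equilibrium: the aqueous fuel is clamped to
        ``aqueous_fuel(c_fuel_oil)``.
    K_p : float
        Oil→water fuel partition coefficient (dimensionless, 0 < K_p ≤ 1).
    c_fuel_oil : float
        Fuel concentration in the oil reservoir (mM).
    c_sat : float
        Coacervation-critical (saturation) concentration of activated
        peptide (mM); droplets can only nucleate above it.
    c_den : float
        Activated-material concentration inside the dense droplet phase (mM).
    fuel_solubility : float
        Aqueous solubility cap on the fuel (mM).
    """

    k_act: float = 1.25e-4
    k_deact: float = LN2 / 60.0
    k_fuel_loss: float = 1.0e-4
    k_exchange: float = math.inf
    K_p: float = 0.013
    c_fuel_oil: float = 250.0
    c_sat: float = 0.0375
    c_den: float = 500.0
    fuel_solubility: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k_act", "k_deact", "k_fuel_loss", "k_exchange"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.K_p <= 1.0):
            raise ValueError("K_p must be in (0, 1]")
        if self.c_sat <= 0:
            raise ValueError("c_sat must be > 0")
        if self.c_den <= self.c_sat:
            raise ValueError("c_den must exceed c_sat")
        if self.c_fuel_oil < 0 or self.fuel_solubility < 0:
            raise ValueError("concentrations must be >= 0")

    def with_(self, **kwargs) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def instantaneous_exchange(self) -> bool:
        return math.isinf(self.k_exchange)


@dataclass
class ChemState:
    """Dilute-phase concentrations (mM) of the cycle at time ``t`` (s)."""

    c_P: float
    c_A: float = 0.0
    c_F: float = 0.0
    c_W: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_P", "c_A", "c_F", "c_W"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_peptide(self) -> float:
        """Conserved peptide inventory c_P + c_A (droplet-free system)."""
        return self.c_P + self.c_A


def aqueous_fuel(c_fuel_oil: float, params: KineticParams) -> float:
    """Steady aqueous fuel concentration set by the oil reservoir (mM).

    In the fast-exchange limit this is the partition equilibrium
    ``K_p · c_fuel_oil``, capped at the aqueous solubility.
    """
    if c_fuel_oil < 0:
        raise ValueError("c_fuel_oil must be >= 0")
    return min(params.K_p * c_fuel_oil, params.fuel_solubility)


def reaction_rhs(state: ChemState, params: KineticParams) -> tuple[float, float, float, float]:
    """Time derivatives (dc_P, dc_A, dc_F, dc_W) in mM·s⁻¹.

    Activation: P + F → A (+ waste); deactivation: A → P; direct fuel
    hydrolysis F → waste; fuel exchange relaxes c_F towards the partition
    equilibrium.  With instantaneous exchange the fuel derivative is zero
    (c_F is clamped by the caller).
    """
    act = params.k_act * state.c_P * state.c_F
    deact = params.k_deact * state.c_A
    loss = params.k_fuel_loss * state.c_F
    dA = act - deact
    dP = -act + deact
    dW = act + loss
    if params.instantaneous_exchange:
        dF = 0.0
    else:
        dF = params.k_exchange * (aqueous_fuel(params.c_fuel_oil, params) - state.c_F) - act - loss
    return (dP, dA, dF, dW)


def integrate(
    state0: ChemState,
    params: KineticParams,
    t_end: float,
    n_out: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the cycle ODEs; returns a table (t, c_P, c_A, c_F, c_W).

    With instantaneous exchange the aqueous fuel is held at the partition
    equilibrium throughout.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    clamp = params.instantaneous_exchange
    f_eq = aqueous_fuel(params.c_fuel_oil, params)

    def rhs(t, y):
        c_F = f_eq if clamp else y[2]
        s = ChemState.__new__(ChemState)  # skip validation in the hot loop
        s.c_P, s.c_A, s.c_F, s.c_W, s.t = max(y[0], 0.0), max(y[1], 0.0), max(c_F, 0.0), y[3], t
        return reaction_rhs(s, params)

    y0 = [state0.c_P, state0.c_A, f_eq if clamp else state0.c_F, state0.c_W]
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - integrator failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    out = pd.DataFrame(
        {"t": sol.t, "c_P": sol.y[0], "c_A": sol.y[1], "c_F": sol.y[2], "c_W": sol.y[3]}
    )
    if clamp:
        out["c_F"] = f_eq
    return out


@dataclass(frozen=True)
class CycleSteadyState:
    """Fixed point of the cycle with the oil reservoir held constant."""

    state: ChemState
    droplets_possible: bool
    residual: float = 0.0


def steady_state(params: KineticParams, c_total_peptide: float = 10.0) -> CycleSteadyState:
    """Steady state of the dilute cycle for a conserved peptide inventory.

    At the fixed point ``c_A = k_act·c_P·c_F / k_deact``.  The waste pool
    grows linearly in time at steady state and is reported as 0.
    ``droplets_possible`` flags whether the steady activated concentration
    exceeds the coacervation-critical concentration ``c_sat``.
    """
    if params.k_deact <= 0:
        raise ValueError("steady state requires k_deact > 0")
    if c_total_peptide < 0:
        raise ValueError("c_total_peptide must be >= 0")
    f_eq = aqueous_fuel(params.c_fuel_oil, params)

    def c_A_of(c_F: float) -> float:
        # With c_P + c_A = c_tot and k_act·c_P·c_F = k_deact·c_A:
        return params.k_act * c_total_peptide * c_F / (params.k_deact + params.k_act * c_F)

    if params.instantaneous_exchange or f_eq == 0.0:
        c_F = f_eq
    else:
        def balance(c_F: float) -> float:
            c_A = c_A_of(c_F)
            c_P = c_total_peptide - c_A
            return (
                params.k_exchange * (f_eq - c_F)
                - params.k_act * c_P * c_F
                - params.k_fuel_loss * c_F
            )

        try:
            c_F = brentq(balance, 0.0, f_eq, xtol=1e-14, rtol=1e-12)
        except ValueError as exc:
            raise SteadyStateError("fuel balance has no root in [0, K_p·c_oil]",
                                   residual=balance(f_eq)) from exc
        res = abs(balance(c_F))
        if res > 1e-8:
            raise SteadyStateError("fuel balance root did not converge", residual=res)

    c_A = c_A_of(c_F)
    st = ChemState(c_P=c_total_peptide - c_A, c_A=c_A, c_F=c_F, c_W=0.0)
    return CycleSteadyState(state=st, droplets_possible=c_A > params.c_sat)


def halflife_to_rate(t_half: float) -> float:
    """First-order rate constant (s⁻¹) from a half-life (s): ln2 / t½."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    return LN2 / t_half


def rate_to_halflife(k: float) -> float:
    """Half-life (s) from a first-order rate constant (s⁻¹): ln2 / k."""
    if k <= 0:
        raise ValueError("rate must be > 0")
    return LN2 / k
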