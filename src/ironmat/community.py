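"""Steady-state autotroph-heterotroph community mass balance.

The oxic zone of the mat (depth 0.07 cm, unit area, volume V) is treated as a
homogeneous, steadily accreting control volume that moves upward with the mat
surface.  Two populations live in it: an Fe(II)-oxidizing autotroph (biomass
density X_A, specific growth rate mu_A) and an aerobic heterotroph (X_H,
mu_H) that consumes autotroph biomass released by lysis.  The governing
balances:

* heterotroph:  dX_H/dt * V = mu_H X_H V - F X_H        (=> F/V = mu_H at
  steady state; this single dilution applies to both populations since they
  share the accreting-mat frame)
* autotroph:    dX_A/dt * V = mu_A X_A V
                - (mu_H Y_A/BH + M_H Y_A/EH) X_H V - F X_A
* oxygen:       j_O2 * area = (mu_A Y_O2/BA + M_A Y_O2/EA) X_A V
                + (mu_H Y_O2/BH + M_H Y_O2/EH) X_H V

Given the oxygen flux j_O2, the biomass ratio r = X_A/X_H and the total
biomass X_Tot, the two steady-state equations are linear in (mu_A, mu_H) and
are solved in closed form.  Derived outputs follow the published rate
definitions: total community growth rate R_Xtot, net community growth rate
R_Xnet (total minus autotroph consumed), and the Fe(II) oxidation rate R_Fe.

Internal units: g, mol, cm, h.  ``nmol_cm2_h`` helpers convert the customary
field units at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import CellParameters, Limitation

__all__ = [
    "SystemGeometry",
    "CommunityState",
    "CommunityRates",
    "solve_steady_state",
    "solve_at_mu_A",
    "sweep_biomass",
    "min_carrying_capacity",
    "max_carrying_capacity",
    "oxygen_partition",
    "autotroph_turnover",
    "exchange_variant_parameters",
    "NMOL_PER_CM2_H",
]

#: multiply nmol cm^-2 h^-1 by this to get mol cm^-2 h^-1
NMOL_PER_CM2_H = 1e-9

FEASIBLE = "feasible"


@dataclass(frozen=True)
class SystemGeometry:
    """Oxic-zone control volume (defaults: 0.07 cm depth over 1 cm^2)."""

    depth: float = 0.07  # cm
    area: float = 1.0    # cm^2

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.area <= 0:
            raise ValueError("depth and area must be positive")

    @property
    def V(self) -> float:
        return self.depth * self.area


@dataclass(frozen=True)
class CommunityState:
    X_A: float            # g cm^-3
    X_H: float            # g cm^-3
    mu_A: float           # 1/h
    mu_H: float           # 1/h
    j_O2: float           # mol cm^-2 h^-1
    limitation: Limitation
    status: str = FEASIBLE

    @property
    def X_Tot(self) -> float:
        return self.X_A + self.X_H

    @property
    def r(self) -> float:
        return self.X_A / self.X_H if self.X_H > 0 else math.inf

    @property
    def dilution(self) -> float:
        """F/V; equals mu_H at steady state (mu_A when no heterotroph)."""
        return self.mu_H if self.X_H > 0 else self.mu_A


@dataclass(frozen=True)
class CommunityRates:
    R_Xtot_g: float       # g biomass produced cm^-2 h^-1
    R_Xnet_g: float       # g cm^-2 h^-1 (production minus autotroph consumed)
    R_Xtot: float         # mol C cm^-2 h^-1
    R_Xnet: float         # mol C cm^-2 h^-1
    R_Fe: float           # mol Fe cm^-2 h^-1
    o2_autotroph_share: float
    turnover: float


def _o2_factors(p: CellParameters, limitation: Limitation, mu_A: float, mu_H: float):
    """Per-gram volumetric O2 consumption rates of each population."""
    _, Y_O2_BH, _, Y_O2_EH = p.het(limitation)
    qa = mu_A * p.Y_O2_BA + p.M_A * p.Y_O2_EA
    qh = mu_H * Y_O2_BH + p.M_H * Y_O2_EH
    return qa, qh


def solve_steady_state(
    p: CellParameters,
    g: SystemGeometry,
    j_O2: float,
    r: float,
    X_Tot: float,
    limitation: Limitation = "carbon_limited",
) -> tuple[CommunityState, CommunityRates]:
    """Closed-form steady state at a given oxygen flux, biomass ratio and
    total biomass.

    Infeasible configurations (negative mu_H, or mu_A above the kinetic cap
    mu_max) are returned with a diagnostic ``status`` rather than raised, so
    sweeps can chart the feasibility boundary.  ``r = inf`` gives the
    autotroph-only limit, ``r = 0`` the (carbon-unsupported) heterotroph-only
    limit.
    """
    if j_O2 < 0 or X_Tot <= 0 or r < 0:
        raise ValueError("j_O2 >= 0, X_Tot > 0 and r >= 0 required")
    Y_A_BH, Y_O2_BH, Y_A_EH, Y_O2_EH = p.het(limitation)
    q_area = j_O2 * g.area / g.V  # mol O2 cm^-3 h^-1 available

    if math.isinf(r):
        X_A, X_H = X_Tot, 0.0
        mu_A = (q_area / X_A - p.M_A * p.Y_O2_EA) / p.Y_O2_BA
        mu_H = 0.0
    elif r == 0:
        X_A, X_H = 0.0, X_Tot
        mu_H = (q_area / X_H - p.M_H * Y_O2_EH) / Y_O2_BH
        mu_A = 0.0
    else:
        X_A = X_Tot * r / (1.0 + r)
        X_H = X_Tot / (1.0 + r)
        # mu_A = mu_H * (1 + Y_A_BH/r) + M_H*Y_A_EH/r   (autotroph balance)
        a = 1.0 + Y_A_BH / r
        b = p.M_H * Y_A_EH / r
        denom = (a * p.Y_O2_BA) * X_A + Y_O2_BH * X_H
        numer = q_area - (b * p.Y_O2_BA + p.M_A * p.Y_O2_EA) * X_A - p.M_H * Y_O2_EH * X_H
        mu_H = numer / denom
        mu_A = mu_H * a + b

    status = FEASIBLE
    if mu_H < 0 or mu_A < 0:
        status = "infeasible_negative_growth"
    elif mu_A > p.mu_max * (1 + 1e-12):
        status = "infeasible_mu_A_exceeds_max"
    state = CommunityState(X_A, X_H, mu_A, mu_H, j_O2, limitation, status)
    return state, community_rates(state, p, g)


def solve_at_mu_A(
    p: CellParameters,
    g: SystemGeometry,
    j_O2: float,
    r: float,
    mu_A: float | None = None,
    limitation: Limitation = "carbon_limited",
) -> tuple[CommunityState, CommunityRates]:
    """Steady state with the autotroph pinned at a given specific growth rate
    (default mu_max); the total biomass adjusts to absorb the oxygen flux.

    This is the configuration at the minimum-biomass boundary, where the
    community is limited by the autotroph's kinetic capability rather than by
    oxygen dilution over standing biomass.
    """
    mu_A = p.mu_max if mu_A is None else mu_A
    if not 0 <= mu_A <= p.mu_max:
        raise ValueError("mu_A must lie in [0, mu_max]")
    Y_A_BH, Y_O2_BH, Y_A_EH, Y_O2_EH = p.het(limitation)
    q_area = j_O2 * g.area / g.V
    if math.isinf(r):
        mu_H = 0.0
        X_H = 0.0
        X_A = q_area / (mu_A * p.Y_O2_BA + p.M_A * p.Y_O2_EA)
    else:
        mu_H = (mu_A - p.M_H * Y_A_EH / r) / (1.0 + Y_A_BH / r)
        qa, qh = _o2_factors(p, limitation, mu_A, mu_H)
        X_H = q_area / (qa * r + qh)
        X_A = r * X_H
    status = FEASIBLE if mu_H >= 0 else "infeasible_negative_growth"
    state = CommunityState(X_A, X_H, mu_A, mu_H, j_O2, limitation, status)
    return state, community_rates(state, p, g)


def community_rates(
    state: CommunityState, p: CellParameters, g: SystemGeometry
) -> CommunityRates:
    Y_A_BH, Y_O2_BH, Y_A_EH, Y_O2_EH = p.het(state.limitation)
    V, area = g.V, g.area
    consumed = (state.mu_H * Y_A_BH + p.M_H * Y_A_EH) * state.X_H  # g cm^-3 h^-1
    R_Xtot_g = (state.mu_A * state.X_A + state.mu_H * state.X_H) * V / area
    R_Xnet_g = R_Xtot_g - consumed * V / area
    R_Xtot = (state.mu_A * state.X_A * p.c_A + state.mu_H * state.X_H * p.c_H) * V / area
    R_Xnet = R_Xtot - consumed * p.c_A * V / area
    R_Fe = (state.mu_A * p.Y_Fe_BA + p.M_A * p.Y_Fe_EA) * state.X_A * V / area
    qa, qh = _o2_factors(p, state.limitation, state.mu_A, state.mu_H)
    o2_a = qa * state.X_A
    o2_h = qh * state.X_H
    share = o2_a / (o2_a + o2_h) if (o2_a + o2_h) > 0 else float("nan")
    prod = state.mu_A * state.X_A
    turnover = consumed / prod if prod > 0 else float("nan")
    return CommunityRates(R_Xtot_g, R_Xnet_g, R_Xtot, R_Xnet, R_Fe, share, turnover)


def oxygen_partition(state: CommunityState, p: CellParameters, g: SystemGeometry) -> float:
    """Fraction of total community O2 consumption used by the autotroph."""
    if state.status != FEASIBLE:
        raise ValueError(f"state is not feasible: {state.status}")
    return community_rates(state, p, g).o2_autotroph_share


def autotroph_turnover(state: CommunityState, p: CellParameters) -> float:
    """Fraction of autotroph biomass production consumed by the heterotroph."""
    if state.mu_A * state.X_A <= 0:
        raise ValueError("turnover undefined: no autotroph production")
    Y_A_BH, _, Y_A_EH, _ = p.het(state.limitation)
    consumed = (state.mu_H * Y_A_BH + p.M_H * Y_A_EH) * state.X_H
    return consumed / (state.mu_A * state.X_A)


# ---------------------------------------------------------------------------
# sweeps and carrying capacities
# ---------------------------------------------------------------------------

def sweep_biomass(
    p: CellParameters,
    g: SystemGeometry,
    j_O2_list,
    r_list,
    X_Tot_grid,
    limitation: Limitation = "carbon_limited",
) -> pd.DataFrame:
    """Steady-state solutions over the product grid, one row per combination."""
    rows = []
    for j in j_O2_list:
        for r in r_list:
            for X in X_Tot_grid:
                state, rates = solve_steady_state(p, g, j, r, X, limitation)
                rows.append(
                    {
                        "j_O2_nmol_cm2_h": j / NMOL_PER_CM2_H,
                        "r": r,
                        "X_tot_mg_cm3": X * 1e3,
                        "mu_A": state.mu_A,
                        "mu_H": state.mu_H,
                        "R_Xtot_umol_cm2_h": rates.R_Xtot * 1e6,
                        "R_Xnet_umol_cm2_h": rates.R_Xnet * 1e6,
                        "R_Fe_umol_cm2_h": rates.R_Fe * 1e6,
                        "o2_share_autotroph": rates.o2_autotroph_share,
                        "turnover": rates.turnover,
                        "status": state.status,
                    }
                )
    return pd.DataFrame(rows)


def _r_grid(r_range, n: int = 5):
    lo, hi = r_range
    if math.isinf(lo) and math.isinf(hi):
        return [math.inf]
    return list(np.linspace(lo, hi, n))


def _bisect_X(predicate, lo: float, hi: float, rtol: float) -> float:
    """Bisect on X_Tot for the boundary of a monotone predicate; returns the
    predicate-true endpoint of the final bracket (within rtol of the
    boundary)."""
    p_lo, p_hi = predicate(lo), predicate(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"no predicate sign change in bracket [{lo}, {hi}] "
            f"(predicate is {p_lo} at both ends)"
        )
    while (hi - lo) > rtol * hi:
        mid = math.sqrt(lo * hi)  # geometric: bracket spans orders of magnitude
        if predicate(mid) == p_hi:
            hi = mid
        else:
            lo = mid
    return hi if p_hi else lo


def min_carrying_capacity(
    p: CellParameters,
    g: SystemGeometry,
    j_O2: float,
    r_range=(0.3, 0.5),
    mu_cap: float | None = None,
    limitation: Limitation = "carbon_limited",
    rtol: float = 1e-6,
) -> float:
    """Smallest sustainable total biomass (g cm^-3): the least X_Tot at which
    the steady-state autotroph growth rate stays at or below ``mu_cap``
    (default mu_max) across the whole abundance window.

    Below this concentration the community would demand an autotroph specific
    growth rate beyond its measured kinetic capability.
    """
    mu_cap = p.mu_max if mu_cap is None else mu_cap
    if mu_cap <= 0:
        raise ValueError("mu_cap must be positive")
    rs = _r_grid(r_range)

    def ok(X: float) -> bool:
        return all(
            solve_steady_state(p, g, j_O2, r, X, limitation)[0].mu_A <= mu_cap
            for r in rs
        )

    return _bisect_X(ok, 1e-9, 0.1, rtol)


def max_carrying_capacity(
    p: CellParameters,
    g: SystemGeometry,
    j_O2: float,
    r_range=(0.3, 0.5),
    limitation: Limitation = "carbon_limited",
    rtol: float = 1e-6,
) -> float:
    """Largest sustainable total biomass (g cm^-3): the greatest X_Tot at
    which some abundance ratio in the window still yields mu_H >= 0
    (equivalently a non-negative net community growth rate).

    Above this concentration, maintenance consumption of autotroph biomass
    exceeds what the oxygen flux can regenerate.
    """
    rs = _r_grid(r_range)

    def ok(X: float) -> bool:
        return any(
            solve_steady_state(p, g, j_O2, r, X, limitation)[0].mu_H >= 0
            for r in rs
        )

    return _bisect_X(ok, 1e-9, 0.1, rtol)


# ---------------------------------------------------------------------------
# metabolite-exchange (secretion) variant
# ---------------------------------------------------------------------------

def exchange_variant_parameters(
    p: CellParameters, credit_fraction: float = 0.04
) -> CellParameters:
    """Parameter set for the metabolite-exchange carbon-transfer mechanism.

    Under the lysis mechanism the autotroph pays the full polymerization ATP
    cost for biomass that the heterotroph then depolymerizes.  If the
    autotroph instead secretes monomers, that ATP (a ``credit_fraction`` of
    GAM_A per gram of autotroph-derived food) is never spent, which lowers
    the effective autotroph requirement of the heterotroph.  The credit is
    applied as a multiplicative reduction s = credit_fraction * GAM_A * Y_A_EH
    of both the growth- and maintenance-associated autotroph requirements;
    ``credit_fraction = 0`` is the identity.
    """
    if credit_fraction < 0:
        raise ValueError("credit_fraction must be non-negative")
    out = {}
    for var in ("carbon", "oxygen"):
        y_eh = getattr(p, f"Y_A_EH_{var}")
        s = credit_fraction * p.GAM_A * y_eh
        if s >= 1:
            raise ValueError("credit too large: effective yields would be negative")
        out[f"Y_A_BH_{var}"] = getattr(p, f"Y_A_BH_{var}") * (1 - s)
        out[f"Y_A_EH_{var}"] = y_eh * (1 - s)
    return replace(p, **out)
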