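"""Community-level linear programming over EFM-derived transformation
reactions (electron-donor scenario analysis).

Cell-scale elementary-mode optima are condensed into five overall
transformation reactions, each expressed per gram of biomass formed via the
Pirt rate law:

* R1 — Fe(II)-oxidizing autotroph growth
* R2 — sulfide-oxidizing autotroph growth
* R3 — net autotroph export (production not consumed by the heterotroph)
* R4 — heterotroph growth on autotroph biomass
* R5 — heterotroph growth on exogenous landscape carbon (same macromolecular
  composition as autotroph biomass; its production costs no oxygen inside
  the mat)

A scenario wraps these into an LP: autotroph mass balance, an oxygen budget
bounded by the flux into the mat, kinetic rate caps (mu_max times the
standing pool), autotroph:heterotroph abundance bounds, and a constraint on
the fraction of biomass carbon of autotrophic origin (stable-isotope
window).  Scenario A admits R1/R3/R4 only, B adds landscape carbon (R5),
C additionally lets the autotroph pool split its activity (and its
maintenance energy) between Fe(II) and sulfide oxidation.

Solving for the minimum and maximum Fe(II)-oxidation rate over a grid of
oxygen fluxes traces the feasible (j_O2, R_Fe) envelope of each scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .community import SystemGeometry
from .params import CellParameters, Limitation

__all__ = [
    "TransformationReaction",
    "ScenarioSpec",
    "ScenarioLP",
    "ScenarioSolution",
    "build_transformations",
    "build_scenario_lp",
    "solve_scenario",
    "envelope_sweep",
    "compare_to_measurements",
]

# internal LP scale: masses in ug, moles in umol (numerically equal yields;
# keeps the LP well-conditioned for HiGHS tolerances)
_SCALE = 1e6

_VARS = ["v1", "v2", "v3", "v4", "v5", "X_A", "X_H_AC", "X_H_LC", "m_Fe", "m_S"]


@dataclass(frozen=True)
class TransformationReaction:
    """One overall community transformation.

    ``growth_coeffs`` are resource amounts per gram of biomass formed
    (mol/g, or g/g for biomass-on-biomass); ``maintenance_coeffs`` are per
    gram of standing biomass per hour.  ``combined(mu)`` folds maintenance
    into a per-gram-formed coefficient at specific growth rate ``mu`` (the
    Pirt law): coeff = growth + maintenance/mu.
    """

    id: str
    population: str  # autotroph | heterotroph | none
    growth_coeffs: dict[str, float]
    maintenance_coeffs: dict[str, float] = field(default_factory=dict)

    def combined(self, mu: float) -> dict[str, float]:
        if mu <= 0:
            raise ValueError("mu must be positive to fold maintenance per gram")
        out = dict(self.growth_coeffs)
        for k, v in self.maintenance_coeffs.items():
            out[k] = out.get(k, 0.0) + v / mu
        return out


def build_transformations(
    p: CellParameters, mu: float | None = None, limitation: Limitation = "carbon_limited"
) -> list[TransformationReaction]:
    """The five transformation reactions R1-R5 from a cell parameter set.

    ``mu`` is only validated against the kinetic cap; the coefficients keep
    the growth/maintenance split so the LP can apply maintenance to standing
    pools rather than to rates.
    """
    mu = p.mu_max if mu is None else mu
    if not 0 <= mu <= p.mu_max:
        raise ValueError("mu must lie in [0, mu_max]")
    Y_A_BH, Y_O2_BH, Y_A_EH, Y_O2_EH = p.het(limitation)
    return [
        TransformationReaction(
            "R1_Fe_autotroph", "autotroph",
            {"o2": p.Y_O2_BA, "fe2": p.Y_Fe_BA, "dic": p.c_A},
            {"o2": p.M_A * p.Y_O2_EA, "fe2": p.M_A * p.Y_Fe_EA},
        ),
        TransformationReaction(
            "R2_S_autotroph", "autotroph",
            {"o2": p.Y_O2_BA_sulfide, "sulfide": p.Y_S_BA, "dic": p.c_A},
            {"o2": p.M_A * p.Y_O2_EA_sulfide, "sulfide": p.M_A * p.Y_S_EA},
        ),
        TransformationReaction(
            "R3_autotroph_export", "none",
            {"autotroph_biomass": 1.0},
        ),
        TransformationReaction(
            "R4_autotroph_consuming_het", "heterotroph",
            {"autotroph_biomass": Y_A_BH, "o2": Y_O2_BH},
            {"autotroph_biomass": p.M_H * Y_A_EH, "o2": p.M_H * Y_O2_EH},
        ),
        TransformationReaction(
            "R5_landscape_het", "heterotroph",
            {"landscape_carbon": Y_A_BH, "o2": Y_O2_BH},
            {"landscape_carbon": p.M_H * Y_A_EH, "o2": p.M_H * Y_O2_EH},
        ),
    ]


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one electron-donor scenario LP."""

    scenario: str                      # "A" | "B" | "C"
    X_Tot: float                       # g cm^-3
    j_O2: float                        # mol cm^-2 h^-1
    r_bounds: tuple[float, float] = (0.3, 0.5)
    f_DIC_bounds: tuple[float, float] = (0.42, 0.99)
    mu_max: float = 0.1
    objective: str = "max_total_growth"  # or "max_net_growth"
    limitation: Limitation = "carbon_limited"
    steady_state_closure: bool = False   # v3 = r * v4; needs degenerate r_bounds
    oxygen_equality: bool = False        # bind the O2 balance (j is consumed)

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise ValueError("scenario must be A, B or C")
        if self.objective not in ("max_total_growth", "max_net_growth"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.steady_state_closure and self.r_bounds[0] != self.r_bounds[1]:
            raise ValueError("steady-state closure requires a fixed abundance ratio")

    @property
    def active_transformations(self) -> set[str]:
        base = {"R1_Fe_autotroph", "R3_autotroph_export", "R4_autotroph_consuming_het"}
        if self.scenario in ("B", "C"):
            base.add("R5_landscape_het")
        if self.scenario == "C":
            base.add("R2_S_autotroph")
        return base


@dataclass
class ScenarioLP:
    """Assembled LP; variables (ug or umol cm^-2 h^-1 rates, ug cm^-3 pools):
    v1..v5 transformation rates, X_A/X_H_AC/X_H_LC pools, m_Fe/m_S the
    autotroph maintenance-ATP split between the two donors."""

    spec: ScenarioSpec
    geometry: SystemGeometry
    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    bounds: list[tuple[float, float | None]]
    oxygen_row: int          # index into A_ub/b_ub of the oxygen budget
    r_fe: np.ndarray         # R_Fe = r_fe @ x  (umol cm^-2 h^-1)
    total_growth: np.ndarray
    net_growth: np.ndarray

    @property
    def variables(self) -> list[str]:
        return list(_VARS)


def build_scenario_lp(
    spec: ScenarioSpec,
    transforms: list[TransformationReaction],
    p: CellParameters,
    g: SystemGeometry | None = None,
) -> ScenarioLP:
    """Assemble the scenario LP from the transformation reactions."""
    g = g or SystemGeometry()
    t = {tr.id: tr for tr in transforms}
    missing = spec.active_transformations - set(t)
    if missing:
        raise ValueError(f"missing transformations: {sorted(missing)}")
    d = g.depth
    n = len(_VARS)
    iv = {name: i for i, name in enumerate(_VARS)}
    X_tot = spec.X_Tot * _SCALE          # ug cm^-3
    j = spec.j_O2 * _SCALE               # umol cm^-2 h^-1

    r1, r4 = t["R1_Fe_autotroph"], t["R4_autotroph_consuming_het"]
    r2 = t.get("R2_S_autotroph")
    r5 = t.get("R5_landscape_het")

    A_eq_rows, b_eq = [], []

    def row(entries: dict[str, float]) -> np.ndarray:
        v = np.zeros(n)
        for name, coef in entries.items():
            v[iv[name]] = coef
        return v

    # pools sum to the prescribed total biomass
    A_eq_rows.append(row({"X_A": 1, "X_H_AC": 1, "X_H_LC": 1}))
    b_eq.append(X_tot)
    # autotroph biomass balance: production = consumption + export
    A_eq_rows.append(
        row({
            "v1": 1, "v2": 1, "v3": -1,
            "v4": -r4.growth_coeffs["autotroph_biomass"],
            "X_H_AC": -r4.maintenance_coeffs["autotroph_biomass"] * d,
        })
    )
    b_eq.append(0.0)
    # autotroph maintenance ATP split between the two electron donors
    A_eq_rows.append(row({"m_Fe": 1, "m_S": 1, "X_A": -p.M_A * d}))
    b_eq.append(0.0)
    if spec.steady_state_closure:
        r_fix = spec.r_bounds[0]
        A_eq_rows.append(row({"v3": 1, "v4": -r_fix}))
        b_eq.append(0.0)

    A_ub_rows, b_ub = [], []
    # oxygen budget
    o2 = {
        "v1": r1.growth_coeffs["o2"],
        "v4": r4.growth_coeffs["o2"],
        "m_Fe": p.Y_O2_EA,
        "X_H_AC": r4.maintenance_coeffs["o2"] * d,
    }
    if r2 is not None:
        o2["v2"] = r2.growth_coeffs["o2"]
        o2["m_S"] = p.Y_O2_EA_sulfide
    if r5 is not None:
        o2["v5"] = r5.growth_coeffs["o2"]
        o2["X_H_LC"] = r5.maintenance_coeffs["o2"] * d
    oxygen_row = len(A_ub_rows)
    A_ub_rows.append(row(o2))
    b_ub.append(j)
    if spec.oxygen_equality:
        # the flux into the mat is fully consumed (measured-uptake reading)
        A_eq_rows.append(row(o2))
        b_eq.append(j)
    # kinetic caps: production rate <= mu_max * standing pool * depth
    A_ub_rows.append(row({"v1": 1, "v2": 1, "X_A": -spec.mu_max * d}))
    b_ub.append(0.0)
    A_ub_rows.append(row({"v4": 1, "X_H_AC": -spec.mu_max * d}))
    b_ub.append(0.0)
    A_ub_rows.append(row({"v5": 1, "X_H_LC": -spec.mu_max * d}))
    b_ub.append(0.0)
    # abundance bounds r_lo <= X_A / X_H <= r_hi
    r_lo, r_hi = spec.r_bounds
    A_ub_rows.append(row({"X_A": 1, "X_H_AC": -r_hi, "X_H_LC": -r_hi}))
    b_ub.append(0.0)
    A_ub_rows.append(row({"X_A": -1, "X_H_AC": r_lo, "X_H_LC": r_lo}))
    b_ub.append(0.0)
    # autotrophy-derived fraction of biomass carbon (pool encoding); only
    # meaningful once the landscape-carbon route exists (scenarios B and C —
    # in A the fraction is 1 by construction)
    if spec.scenario in ("B", "C"):
        f_lo, f_hi = spec.f_DIC_bounds
        A_ub_rows.append(row({"X_A": -1, "X_H_AC": -1}))
        b_ub.append(-f_lo * X_tot)
        A_ub_rows.append(row({"X_A": 1, "X_H_AC": 1}))
        b_ub.append(f_hi * X_tot)

    bounds: list[tuple[float, float | None]] = [(0.0, None)] * n
    inactive = {"A": ["v2", "v5", "X_H_LC", "m_S"], "B": ["v2", "m_S"], "C": []}
    for name in inactive[spec.scenario]:
        bounds[iv[name]] = (0.0, 0.0)

    total = row({"v1": 1, "v2": 1, "v4": 1, "v5": 1})
    net = total - row({
        "v4": r4.growth_coeffs["autotroph_biomass"],
        "X_H_AC": r4.maintenance_coeffs["autotroph_biomass"] * d,
    })
    r_fe = row({"v1": r1.growth_coeffs["fe2"], "m_Fe": p.Y_Fe_EA})
    c = -(total if spec.objective == "max_total_growth" else net)
    return ScenarioLP(
        spec, g, c,
        np.vstack(A_eq_rows), np.array(b_eq),
        np.vstack(A_ub_rows), np.array(b_ub),
        bounds, oxygen_row, r_fe, total, net,
    )


@dataclass(frozen=True)
class ScenarioSolution:
    status: str                 # optimal | infeasible | unbounded | error
    objective_value: float      # g cm^-2 h^-1 (growth objectives)
    rates: dict[str, float]     # g (or mol) cm^-2 h^-1, unscaled
    pools: dict[str, float]     # g cm^-3
    R_Fe: float                 # mol cm^-2 h^-1
    total_growth: float         # g cm^-2 h^-1
    net_growth: float           # g cm^-2 h^-1
    duals: dict[str, float] | None = None


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_scenario(lp: ScenarioLP, objective: np.ndarray | None = None) -> ScenarioSolution:
    """Solve the LP (HiGHS, deterministic); ``objective`` overrides the
    spec's growth objective with an arbitrary linear functional (minimized)."""
    c = objective if objective is not None else lp.c
    res = linprog(
        c, A_ub=lp.A_ub, b_ub=lp.b_ub, A_eq=lp.A_eq, b_eq=lp.b_eq,
        bounds=lp.bounds, method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        nan = float("nan")
        return ScenarioSolution(status, nan, {}, {}, nan, nan, nan)
    x = res.x
    rates = {v: x[i] / _SCALE for i, v in enumerate(_VARS) if v.startswith("v")}
    pools = {v: x[i] / _SCALE for i, v in enumerate(_VARS) if v.startswith(("X_", "m_"))}
    duals = None
    if res.ineqlin is not None:
        duals = {f"ub{i}": m for i, m in enumerate(res.ineqlin.marginals)}
    return ScenarioSolution(
        status,
        float(-res.fun / _SCALE) if objective is None else float(res.fun / _SCALE),
        rates, pools,
        float(lp.r_fe @ x / _SCALE),
        float(lp.total_growth @ x / _SCALE),
        float(lp.net_growth @ x / _SCALE),
        duals,
    )


def envelope_sweep(
    spec: ScenarioSpec,
    transforms: list[TransformationReaction],
    p: CellParameters,
    j_grid,
    g: SystemGeometry | None = None,
) -> pd.DataFrame:
    """Feasible (j_O2, R_Fe) envelope: min and max Fe(II)-oxidation rate at
    each oxygen flux, in both per-area and per-volume normalizations.

    The grid value is interpreted as the measured oxygen uptake of the mat,
    i.e. the oxygen balance is enforced as an equality at each grid point;
    otherwise the lower boundary would degenerate to the maintenance floor
    regardless of flux."""
    g = g or SystemGeometry()
    rows = []
    for j in j_grid:
        lp = build_scenario_lp(
            replace(spec, j_O2=j, oxygen_equality=True), transforms, p, g
        )
        lo = solve_scenario(lp, objective=lp.r_fe)
        hi = solve_scenario(lp, objective=-lp.r_fe)
        feasible = lo.status == "optimal" and hi.status == "optimal"
        obj = solve_scenario(lp)
        rows.append(
            {
                "scenario": spec.scenario,
                "j_O2_nmol_cm2_h": j * 1e9,
                "j_O2_umol_cm3_h": j * 1e6 / g.depth,
                "RFe_min_umol_cm2_h": lo.R_Fe * 1e6 if feasible else float("nan"),
                "RFe_max_umol_cm2_h": hi.R_Fe * 1e6 if feasible else float("nan"),
                "RFe_min_umol_cm3_h": lo.R_Fe * 1e6 / g.depth if feasible else float("nan"),
                "RFe_max_umol_cm3_h": hi.R_Fe * 1e6 / g.depth if feasible else float("nan"),
                "objective_g_cm2_h": obj.objective_value,
                "status": "feasible" if feasible else lo.status,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["depth_cm"] = g.depth
    return df


def compare_to_measurements(
    envelope: pd.DataFrame,
    measured,
    margin: float = 0.0,
) -> pd.DataFrame:
    """Containment report of measured (j_O2, R_Fe) points against an envelope.

    ``measured`` rows need ``site``, ``j_O2``, ``R_Fe`` and ``units``
    ("umol_cm3_h" or "nmol_cm2_h"); per-volume values are converted with the
    envelope's oxic depth.  The envelope is treated as a closed region;
    ``margin`` widens it by a relative tolerance (measurement-uncertainty
    band).  Reports inside/outside with the signed relative margin to the
    nearest boundary.
    """
    depth = envelope.attrs.get("depth_cm")
    feas = envelope[envelope["status"] == "feasible"]
    if feas.empty:
        raise ValueError("envelope has no feasible rows")
    jcol = feas["j_O2_nmol_cm2_h"].to_numpy()
    order = np.argsort(jcol)
    js = jcol[order]
    lo = feas["RFe_min_umol_cm2_h"].to_numpy()[order]
    hi = feas["RFe_max_umol_cm2_h"].to_numpy()[order]
    rows = []
    records = measured.to_dict("records") if isinstance(measured, pd.DataFrame) else measured
    for m in records:
        units = m["units"]
        if units == "umol_cm3_h":
            if depth is None:
                raise ValueError("per-volume measurement but envelope lacks depth")
            j_nmol = m["j_O2"] * depth * 1e3   # umol cm^-3 -> nmol cm^-2
            rfe_umol = m["R_Fe"] * depth       # umol cm^-3 -> umol cm^-2
        elif units == "nmol_cm2_h":
            j_nmol = m["j_O2"]
            rfe_umol = m["R_Fe"] * 1e-3
        elif units == "umol_cm2_h":
            j_nmol = m["j_O2"] * 1e3
            rfe_umol = m["R_Fe"]
        else:
            raise ValueError(f"unknown units {units!r}")
        in_j = js.min() - 1e-12 <= j_nmol <= js.max() + 1e-12
        if in_j:
            lo_i = float(np.interp(j_nmol, js, lo))
            hi_i = float(np.interp(j_nmol, js, hi))
            band_lo = lo_i * (1 - margin) - abs(rfe_umol) * margin
            band_hi = hi_i * (1 + margin) + abs(rfe_umol) * margin
            inside = band_lo - 1e-12 <= rfe_umol <= band_hi + 1e-12
            scale = max(abs(hi_i), abs(rfe_umol), 1e-30)
            rel_margin = min(rfe_umol - lo_i, hi_i - rfe_umol) / scale
        else:
            inside, rel_margin = False, float("-inf")
        rows.append(
            {
                "site": m.get("site", ""),
                "j_O2_nmol_cm2_h": j_nmol,
                "R_Fe_umol_cm2_h": rfe_umol,
                "inside": bool(inside),
                "rel_margin": rel_margin,
            }
        )
    return pd.DataFrame(rows)
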