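"""Synthetic inputs: toy stoichiometric networks with known elementary-mode
structure, perturbed parameter sets, and simulated field measurements.

Everything the pipeline consumes can be generated here without downloads.
Toy networks stand in for the genome-scale models: the ``autotroph_fixture``
couples a 4:1 Fe(II):O2 pseudo-electron-transport chain to a biomass
reaction so that its elementary-mode yields land at the published per-Cmole
scale (about 38 mol O2 and 152 mol Fe per Cmole biomass), and the
``heterotroph_fixture`` consumes a biomass-monomer pool at the published
carbon and oxygen costs.  Simulated field datasets mimic the measured
quantities (oxygen microelectrode flux, Fe(III)-oxide deposition rate,
autotroph:heterotroph read-fraction abundance, isotope-derived DIC fraction)
as truncated-positive normal draws around model-implied values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .community import CommunityState, SystemGeometry, community_rates
from .efm import enumerate_efms
from .network import Metabolite, MetabolicNetwork, Reaction
from .params import CellParameters
from .scenarios import ScenarioSpec, build_transformations, compare_to_measurements, envelope_sweep

__all__ = [
    "ToyNetworkSpec",
    "SyntheticFieldDataset",
    "make_toy_network",
    "perturb_parameters",
    "simulate_field_measurements",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ToyNetworkSpec:
    kind: str = "chain"      # chain | diamond | parallel_k | autotroph_fixture
    #                          | heterotroph_fixture | random
    size: int = 3            # reaction count (random) or path count (parallel_k)
    seed: int = 0

    @property
    def known_efm_count(self) -> int | None:
        """Ground-truth elementary-mode count for the analytic kinds."""
        return {"chain": 1, "diamond": 2, "parallel_k": self.size}.get(self.kind)


def _chain() -> MetabolicNetwork:
    mets = [
        Metabolite("Aext", is_external=True, carbon_atoms=1),
        Metabolite("A", carbon_atoms=1),
        Metabolite("B", carbon_atoms=1),
        Metabolite("Bext", is_external=True, carbon_atoms=1),
    ]
    rxns = [
        Reaction("R1", {"Aext": -1, "A": 1}, is_exchange=True),
        Reaction("R2", {"A": -1, "B": 1}),
        Reaction("R3", {"B": -1, "Bext": 1}, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, biomass_reaction_id="R2")


def _diamond() -> MetabolicNetwork:
    mets = [
        Metabolite("Aext", is_external=True),
        Metabolite("A"),
        Metabolite("B1"),
        Metabolite("B2"),
        Metabolite("C"),
        Metabolite("Cext", is_external=True),
    ]
    rxns = [
        Reaction("Rin", {"Aext": -1, "A": 1}, is_exchange=True),
        Reaction("Rup", {"A": -1, "B1": 1}),
        Reaction("Rdown", {"A": -1, "B2": 1}),
        Reaction("Rup2", {"B1": -1, "C": 1}),
        Reaction("Rdown2", {"B2": -1, "C": 1}),
        Reaction("Rout", {"C": -1, "Cext": 1}, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, biomass_reaction_id="Rout")


def _parallel(k: int) -> MetabolicNetwork:
    mets = [Metabolite("Aext", is_external=True), Metabolite("A"), Metabolite("B"),
            Metabolite("Bext", is_external=True)]
    rxns = [Reaction("Rin", {"Aext": -1, "A": 1}, is_exchange=True)]
    for i in range(k):
        rxns.append(Reaction(f"P{i + 1}", {"A": -1, "B": 1}))
    rxns.append(Reaction("Rout", {"B": -1, "Bext": 1}, is_exchange=True))
    return MetabolicNetwork(mets, rxns, biomass_reaction_id="Rout")


def _autotroph_fixture() -> MetabolicNetwork:
    """Minimal Fe(II)-oxidizing autotroph at the published yield scale.

    The electron-transport pseudo-reaction oxidizes 4 Fe(II) per O2 into one
    unit of cellular energy E; the biomass reaction fixes one CO2 per Cmole
    of biomass at a cost of 38 E.  The single biomass-producing mode then
    requires 38 mol O2 and 152 mol Fe(II) per Cmole, the carbon-limited
    optimum implied by the published per-gram yields (1.63 / 0.0430).
    """
    mets = [
        Metabolite("Fe2_ext", is_external=True, carbon_atoms=0),
        Metabolite("Fe3_ext", is_external=True, carbon_atoms=0),
        Metabolite("O2_ext", is_external=True, carbon_atoms=0),
        Metabolite("CO2_ext", is_external=True, carbon_atoms=1),
        Metabolite("Fe2", carbon_atoms=0),
        Metabolite("O2", carbon_atoms=0),
        Metabolite("CO2", carbon_atoms=1),
        Metabolite("E", carbon_atoms=0),
        Metabolite("BIO", carbon_atoms=1),
        Metabolite("BIO_ext", is_external=True, carbon_atoms=1),
    ]
    rxns = [
        Reaction("EX_fe2", {"Fe2_ext": -1, "Fe2": 1}, is_exchange=True),
        Reaction("EX_o2", {"O2_ext": -1, "O2": 1}, is_exchange=True),
        Reaction("EX_co2", {"CO2_ext": -1, "CO2": 1}, is_exchange=True),
        Reaction("ETC", {"Fe2": -4, "O2": -1, "E": 1, "Fe3_ext": 4}, is_exchange=True),
        Reaction("BIOMASS", {"E": -38, "CO2": -1, "BIO": 1}),
        Reaction("EX_bio", {"BIO": -1, "BIO_ext": 1}, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, biomass_reaction_id="BIOMASS")


def _heterotroph_fixture() -> MetabolicNetwork:
    """Minimal heterotroph consuming autotroph-biomass monomers.

    2.4 Cmol of monomer carbon and 1.3 mol O2 yield one Cmole of heterotroph
    biomass plus 1.4 CO2 (carbon-balanced), matching the published
    carbon-limited per-Cmole requirements.
    """
    mets = [
        Metabolite("MONO_ext", is_external=True, carbon_atoms=1),
        Metabolite("MONO", carbon_atoms=1),
        Metabolite("O2_ext", is_external=True, carbon_atoms=0),
        Metabolite("O2", carbon_atoms=0),
        Metabolite("CO2_ext", is_external=True, carbon_atoms=1),
        Metabolite("BIOH", carbon_atoms=1),
        Metabolite("BIOH_ext", is_external=True, carbon_atoms=1),
    ]
    rxns = [
        Reaction("EX_mono", {"MONO_ext": -1, "MONO": 1}, is_exchange=True),
        Reaction("EX_o2", {"O2_ext": -1, "O2": 1}, is_exchange=True),
        Reaction(
            "BIOMASS_H",
            {"MONO": Fraction(-12, 5), "O2": Fraction(-13, 10),
             "BIOH": 1, "CO2_ext": Fraction(7, 5)},
            is_exchange=True,
        ),
        Reaction("EX_bioh", {"BIOH": -1, "BIOH_ext": 1}, is_exchange=True),
    ]
    return MetabolicNetwork(mets, rxns, biomass_reaction_id="BIOMASS_H")


def _random_network(size: int, seed: int) -> MetabolicNetwork:
    """Random sparse network, resampled until it holds a biomass-producing
    mode (so yield operations are always exercisable)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        n_int = max(2, size // 2)
        mets = [Metabolite("Sext", is_external=True), Metabolite("Pext", is_external=True)]
        mets += [Metabolite(f"M{i}") for i in range(n_int)]
        internal = [m.id for m in mets if not m.is_external]
        rxns = [Reaction("Rin", {"Sext": -1, internal[0]: 1}, is_exchange=True)]
        for i in range(size - 2):
            a, b = rng.choice(n_int, size=2, replace=False)
            coeff = int(rng.integers(1, 3))
            rxns.append(Reaction(f"R{i}", {f"M{a}": -coeff, f"M{b}": coeff}))
        rxns.append(
            Reaction("Rbio", {internal[-1]: -1, "Pext": 1}, is_exchange=True)
        )
        try:
            net = MetabolicNetwork(mets, rxns, biomass_reaction_id="Rbio")
        except Exception:
            continue
        modes = enumerate_efms(net)
        if any(m.flux.get("Rbio", 0) > 0 for m in modes):
            return net
    raise RuntimeError("could not sample a productive random network")


def make_toy_network(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Generate a toy network with documented ground-truth mode structure."""
    if spec.kind == "chain":
        return _chain()
    if spec.kind == "diamond":
        return _diamond()
    if spec.kind == "parallel_k":
        if spec.size < 1:
            raise ValueError("parallel_k needs size >= 1")
        return _parallel(spec.size)
    if spec.kind == "autotroph_fixture":
        return _autotroph_fixture()
    if spec.kind == "heterotroph_fixture":
        return _heterotroph_fixture()
    if spec.kind == "random":
        if not 4 <= spec.size <= 14:
            raise ValueError("random networks support sizes 4-14")
        return _random_network(spec.size, spec.seed)
    raise ValueError(f"unknown toy kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# parameter perturbation
# ---------------------------------------------------------------------------

_YIELD_FIELDS = [
    "Y_Fe_BA", "Y_O2_BA", "Y_Fe_EA", "Y_O2_EA",
    "Y_S_BA", "Y_O2_BA_sulfide", "Y_S_EA", "Y_O2_EA_sulfide",
    "Y_O2_BH_carbon", "Y_O2_BH_oxygen", "Y_O2_EH_carbon", "Y_O2_EH_oxygen",
]
# perturbed jointly (one factor for both variants) to preserve the
# carbon-limited <= oxygen-limited ordering
_JOINT_FIELDS = [("Y_A_BH_carbon", "Y_A_BH_oxygen"), ("Y_A_EH_carbon", "Y_A_EH_oxygen")]


def perturb_parameters(
    p: CellParameters, cv: float, n: int, seed: int, hold_carbon_contents: bool = True
) -> list[CellParameters]:
    """``n`` multiplicative log-normal perturbations of every yield.

    The log-normal is parameterized so each yield's mean equals its nominal
    value with coefficient of variation ``cv``.  Carbon contents (and mu_max,
    maintenance) are held fixed by default.  Reproducible by seed.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if cv == 0:
            out.append(replace(p))
            continue
        sigma = math.sqrt(math.log(1 + cv * cv))
        mu_ln = -0.5 * sigma * sigma  # unit-mean log-normal
        updates = {
            f: getattr(p, f) * rng.lognormal(mu_ln, sigma) for f in _YIELD_FIELDS
        }
        for fa, fb in _JOINT_FIELDS:
            factor = rng.lognormal(mu_ln, sigma)
            updates[fa] = getattr(p, fa) * factor
            updates[fb] = getattr(p, fb) * factor
        if not hold_carbon_contents:
            for f in ("c_A", "c_H"):
                updates[f] = getattr(p, f) * rng.lognormal(mu_ln, sigma)
        out.append(replace(p, **updates))
    return out


# ---------------------------------------------------------------------------
# simulated field measurements
# ---------------------------------------------------------------------------

DEFAULT_NOISE = {"j_O2": 0.1, "R_Fe": 0.1, "abundance": 0.1, "dic_fraction": 0.1}


@dataclass(frozen=True)
class SyntheticFieldDataset:
    true_state: CommunityState
    observations: pd.DataFrame   # replicate, j_O2_nmol_cm2_h, R_Fe_umol_cm2_h,
    #                              abundance_ratio, dic_fraction
    noise_model: dict[str, float]
    seed: int
    n_truncated: int = 0


def _truncated_positive_normal(rng, mean: float, cv: float, n: int):
    """Positive draws; returns (draws, truncation count)."""
    if cv == 0:
        return np.full(n, mean), 0
    draws = rng.normal(mean, cv * mean, size=n)
    bad = draws <= 0
    tries = 0
    while bad.any() and tries < 100:
        draws[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
        bad = draws <= 0
        tries += 1
    return np.abs(draws), int(bad.sum())


def simulate_field_measurements(
    true_state: CommunityState,
    p: CellParameters,
    g: SystemGeometry,
    noise: dict[str, float] | None = None,
    n: int = 100,
    seed: int = 0,
    dic_fraction: float | None = None,
) -> SyntheticFieldDataset:
    """Replicate (j_O2, R_Fe, abundance, DIC-fraction) observations around the
    model-implied values of a feasible community state.

    R_Fe is implied through the community Fe-oxidation balance; the DIC
    fraction defaults to the autotrophy-derived biomass share implied by the
    state's pools (autotroph plus autotroph-consuming heterotroph = 1 here,
    so the site lower bound is used instead when supplied via
    ``p.f_DIC_min``).
    """
    if true_state.status != "feasible":
        raise ValueError(f"true state is not feasible: {true_state.status}")
    noise = {**DEFAULT_NOISE, **(noise or {})}
    rates = community_rates(true_state, p, g)
    rng = np.random.default_rng(seed)
    truths = {
        "j_O2": true_state.j_O2 / 1e-9,          # nmol cm^-2 h^-1
        "R_Fe": rates.R_Fe * 1e6,                # umol cm^-2 h^-1
        "abundance": true_state.r,
        "dic_fraction": dic_fraction if dic_fraction is not None else 0.99,
    }
    cols, n_trunc = {}, 0
    for key, mean in truths.items():
        draws, bad = _truncated_positive_normal(rng, mean, noise[key], n)
        n_trunc += bad
        cols[key] = draws
    obs = pd.DataFrame(
        {
            "replicate": np.arange(n),
            "j_O2_nmol_cm2_h": cols["j_O2"],
            "R_Fe_umol_cm2_h": cols["R_Fe"],
            "abundance_ratio": cols["abundance"],
            "dic_fraction": np.clip(cols["dic_fraction"], 0.0, 1.0),
        }
    )
    return SyntheticFieldDataset(true_state, obs, noise, seed, n_trunc)


def recovery_experiment(
    dataset: SyntheticFieldDataset,
    scenario: ScenarioSpec,
    p: CellParameters,
    g: SystemGeometry | None = None,
    n_grid: int = 13,
    margin_sigmas: float = 2.5,
) -> dict:
    """Check that noisy observations fall inside the generating scenario's
    feasible envelope.

    The envelope is computed at the generating parameters over a flux grid
    spanning the observations; each replicate is tested with a
    measurement-uncertainty band of ``margin_sigmas`` times the noise CV per
    quantity (zero noise means exact containment is required).  Returns the
    containment frequency and the flux window used.
    """
    g = g or SystemGeometry()
    obs = dataset.observations
    j_lo = obs["j_O2_nmol_cm2_h"].min() * 0.8
    j_hi = obs["j_O2_nmol_cm2_h"].max() * 1.2
    grid = np.linspace(j_lo, j_hi, n_grid) * 1e-9
    transforms = build_transformations(p, limitation=scenario.limitation)
    env = envelope_sweep(scenario, transforms, p, grid, g)
    cv = max(dataset.noise_model.get("j_O2", 0.0), dataset.noise_model.get("R_Fe", 0.0))
    margin = margin_sigmas * cv
    measured = [
        {
            "site": "synthetic",
            "j_O2": row.j_O2_nmol_cm2_h,
            "R_Fe": row.R_Fe_umol_cm2_h * 1e3,  # umol -> nmol cm^-2 h^-1
            "units": "nmol_cm2_h",
        }
        for row in obs.itertuples()
    ]
    report = compare_to_measurements(env, measured, margin=margin)
    frac = float(report["inside"].mean())
    return {
        "containment_frequency": frac,
        "n": len(report),
        "margin": margin,
        "j_window_nmol_cm2_h": (float(j_lo), float(j_hi)),
        "report": report,
    }
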