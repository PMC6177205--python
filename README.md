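# ironmat

Multiscale metabolic analysis of autotroph–heterotroph interactions in
high-temperature, acidic Fe(III)-oxide microbial mats.

Hot-spring Fe(III)-oxide mats (Yellowstone-type acid-sulfate-chloride
springs, 65–75 °C, pH ~3) host a remarkably simple community: an
Fe(II)-oxidizing chemolithoautotroph (a *Metallosphaera*-like crenarchaeon)
fixes CO₂ with energy from the reaction 4 Fe²⁺ + O₂ + 4 H⁺ → 4 Fe³⁺ + 2 H₂O,
and an aerobic heterotroph (a *Geoarchaeum*-like archaeon) lives on the
organic carbon the autotroph produces. Both compete for the oxygen diffusing
into the thin oxic zone of the mat. `ironmat` is a library for asking, from
stoichiometry and a handful of measured parameters, what such a community
can and cannot do: how much oxygen a Cmole of biomass costs, how the two
populations partition the oxygen flux, how much standing biomass the flux
can sustain, and which electron-donor repertoires are consistent with field
measurements.

## What is inside

* **`ironmat.network`** — stoichiometric networks (exact rational
  coefficients, boundary-flagged external metabolites), a plain TSV dialect,
  SBML Level 2/3 import, structural validation (carbon balance, dead ends,
  blocked reactions) and EFM-preserving network compression.
* **`ironmat.efm`** — elementary flux mode (EFM) enumeration by the tableau
  double-description algorithm over `fractions.Fraction` (so `S·v = 0` holds
  exactly and support minimality is never a rounding artifact), a
  brute-force extreme-ray oracle for independent verification, Boolean
  gene-regulatory-rule pruning, and per-Cmole yield extraction with
  carbon-/oxygen-limited optima.
* **`ironmat.params`** — the published yield, maintenance and geometry
  parameter registry; the Pirt rate law q = μ·Y\_B + M·Y\_E; per-gram ↔
  per-Cmole conversions; trophic-chain oxygen aggregation; genome-derived
  biomass macromolecular composition.
* **`ironmat.community`** — the closed-form steady-state community balance
  (autotroph, heterotroph, oxygen) in the accreting-mat frame, growth rates,
  total/net community production, Fe(II)-oxidation rate, oxygen partition,
  autotroph turnover, minimum/maximum carrying capacity, and the
  metabolite-exchange (secretion) parameter variant.
* **`ironmat.scenarios`** — the hybrid step: EFM-derived overall
  transformation reactions R1–R5 wrapped into a community linear program;
  feasible (oxygen flux, Fe-oxidation) envelopes for electron-donor
  scenarios A (Fe only), B (+ landscape carbon) and C (+ sulfide); and
  containment tests of measured points.
* **`ironmat.synth`** — toy networks with known EFM structure (including
  fixtures built to the published yield scale), log-normal parameter
  perturbation, simulated field measurements and envelope-recovery
  experiments. No downloads are needed anywhere.

## The model in brief

With X_A, X_H the biomass densities (g cm⁻³) in the oxic volume V, growth
rates μ_A, μ_H (h⁻¹), and the Pirt yields of the parameter registry, steady
state in the frame that moves with the accreting mat surface requires

    μ_A X_A = (μ_H Y_A/BH + M_H Y_A/EH) X_H + μ_H X_A
    j_O2 · area = [(μ_A Y_O2/BA + M_A Y_O2/EA) X_A
                  + (μ_H Y_O2/BH + M_H Y_O2/EH) X_H] · V

(the heterotroph balance fixes the dilution F/V = μ_H). Given the oxygen
flux j_O2, the biomass ratio r = X_A/X_H and total biomass X_Tot, the system
is linear in (μ_A, μ_H) and solved in closed form; everything else (R_Xtot,
R_Xnet, R_Fe, oxygen shares, turnover, carrying capacities) follows.

## Worked example

```
$ python examples/community_steady_state.py
autotroph-only community at mu_max: X = 0.037 mg cm^-3
r = 0.3: mu_H = 0.0109 h^-1, autotroph O2 share = 98.7 %, turnover = 89.1 %
r = 0.4: mu_H = 0.0142 h^-1, autotroph O2 share = 98.7 %, turnover = 85.8 %
r = 0.5: mu_H = 0.0173 h^-1, autotroph O2 share = 98.8 %, turnover = 82.7 %
carrying capacity window: 0.16 - 2.75 mg cm^-3
```

Reading: at the observed oxygen flux (420 nmol O₂ cm⁻² h⁻¹) an
autotroph-only mat growing at its measured maximum rate (0.1 h⁻¹) can hold
only ~0.04 mg cm⁻³ of biomass. Across the observed abundance window
(autotroph:heterotroph mass ratio 0.3–0.5) the autotroph consumes ≥ 98 % of
the oxygen, yet the heterotroph turns over more than 80 % of what the
autotroph produces; the community's sustainable total biomass is bracketed
between ~0.2 and ~2–3 mg cm⁻³.

The other examples cover the cell scale (`examples/efm_yields.py`: 38 mol O₂
and 152 mol Fe(II) per Cmole of autotroph biomass on Fe(II)), the ecosystem
scale (`examples/scenario_envelopes.py`: scenario envelopes vs field
measurements) and the synthetic-data round trip
(`examples/synthetic_recovery.py`).

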