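# Methods

This note records the models implemented in `ironmat`, their assumptions,
the tunable parameters, the numerical choices, and what the synthetic-data
exercises do and do not demonstrate.

## Elementary flux mode layer

A metabolic network is a list of reactions with exact rational
stoichiometry; metabolites flagged external are outside the steady-state
constraint (boundary convention; explicit exchange fluxes are normalized to
this convention on import). An elementary flux mode (EFM) is a flux vector
with `S·v = 0` over internal metabolites, non-negative flux through
irreversible reactions, and minimal support. The enumerator is the
classical tableau double-description algorithm: reversible reactions are
split into forward/backward halves, one metabolite constraint is processed
at a time, opposite-sign row pairs are combined under the combinatorial
adjacency test, pure forward+backward two-cycles are dropped at the end,
and a final global support filter removes any residual non-elementary rows.

All arithmetic uses `fractions.Fraction`. This is deliberate: support
minimality — the defining property of an EFM — is a rank condition, and
rank decisions made in floating point silently merge or split modes. The
exact kernel/rank routines live in `ironmat._rational` (plain Gaussian
elimination; matrices here have tens of rows at most) and are cross-checked
against sympy in the test suite.

Two independent routes exist to the same answer: `enumerate_efms` (tableau)
and `brute_force_extreme_rays`, which tests every support subset J for
`rank(S[:,J]) = |J| − 1` with a one-dimensional strictly-positive kernel.
The suite asserts set equality of the two on every generated network with
up to 12 reactions. The enumeration budget (default 5×10⁶ intermediate
rays) turns combinatorial blow-up into an explicit error with a progress
report, never silent truncation.

Gene-regulatory rules are Boolean expressions (AND/OR/NOT, parentheses)
over reaction-activity literals, applied post-enumeration: a mode survives
iff its support, read as an activity pattern, satisfies every rule.
Pruning is a subset operation and idempotent.

Yields divide each exchange flux by the biomass flux (scale-invariant by
construction) and convert to per-Cmole units; carbon-, donor- or
oxygen-limited optima minimize the respective requirement with
deterministic tie-breaking (other resource, then mode id).

Network compression removes blocked reactions (LP flux-variability test)
and lumps unbranched irreversible chains; the mapping returned with the
compressed network expands any compressed flux vector back to the original
reactions, and lumping is EFM-preserving (checked against enumeration).

## Parameter registry and unit system

The registry (`table1_defaults`) carries the published growth-associated
yields for the Fe(II)- and sulfide-oxidizing autotroph and for the
carbon-/oxygen-limited heterotroph acclimations, the maintenance energies,
the kinetic cap μ_max = 0.1 h⁻¹, the carbon contents (0.0430 / 0.0438
Cmol g⁻¹), the site-specific minimum DIC-derived biomass-carbon fraction
(0.42 Beowulf, 0.67 OSP) and the oxic-zone geometry (0.07 cm over 1 cm²).
Internal units are g, mol, cm, h; nmol/µmol appear only at I/O boundaries.

Interpretation choices that matter:

* The growth-associated yields Y\_\*/B\* are taken as inclusive of
  growth-associated maintenance (GAM); GAM values are carried as metadata
  only, never re-added — re-adding them would double-count and break the
  reproduction of the autotroph-only biomass bound. An alternative GAM set
  (171/149 mmol ATP g⁻¹, from the model-calibration description) is
  selectable via `gam_source="methods"`.
* Biomass concentrations are mg cm⁻³ throughout; a µg-scale unit printed in
  the source table is inconsistent with its own text and treated as a typo.
* Two bookkeepings exist for the autotroph-per-heterotroph carbon cost: the
  published per-Cmole figures (2.4 carbon-limited / 3.8 oxygen-limited) and
  the value derived from the per-gram yield and carbon contents
  (2.29 × 0.0430/0.0438 ≈ 2.25). They differ by ~6 % and the energy-carbon
  bookkeeping behind the published figure is not fully specified; both are
  exposed (`trophic_yields(..., basis=)`) and the aggregate trophic oxygen
  cost (≈ 93 mol O₂ per Cmole heterotroph) uses the published basis.

The Pirt law q = μ·Y_B + M·Y_E is the single rate model: growth-associated
consumption proportional to μ plus a constant non-growth maintenance draw.

## Community steady state

Assumptions: the oxic zone is homogeneous (no depth-resolved
reaction–diffusion), the system is at steady state on the days-to-weeks
scale, both populations share one dilution rate in the frame moving with
the accreting mat surface (the heterotroph balance then forces
F/V = μ_H — the only closure consistent with both population balances),
and the heterotroph's carbon source is autotroph biomass released by lysis.
The two balance equations are linear in (μ_A, μ_H) at fixed flux, biomass
ratio and total biomass, and are solved in closed form; infeasibility
(μ_H < 0, μ_A > μ_max) is a reported status so sweeps can chart the
feasibility boundary. `solve_at_mu_A` pins the autotroph at a given rate
(default μ_max) and lets total biomass absorb the flux instead — the
configuration at the minimum-biomass boundary.

Carrying capacities are geometric bisections on X_Tot (bracket 10⁻⁶–10²
mg cm⁻³, relative tolerance 10⁻⁶, deterministic): the minimum capacity is
the least biomass at which μ_A stays within its kinetic cap across the
whole abundance window; the maximum is the greatest biomass at which some
ratio in the window still has μ_H ≥ 0 (equivalently non-negative net
community growth). Closed-form boundary solutions are used as oracles in
the tests. With the default registry at 420 nmol O₂ cm⁻² h⁻¹ the window
computes to ≈ 0.16 – 2.75 mg cm⁻³ (the published window is quoted as
~0.2 – ~2.0; the upper end is sensitive to which abundance ratio attains
the boundary and is reported here as computed).

The metabolite-exchange variant models carbon transfer by secretion of
monomers instead of lysis of polymerized biomass: the polymerization ATP
the autotroph never spends is credited to the heterotroph's effective
autotroph requirements, as a multiplicative reduction
s = credit · GAM_A · Y_A/EH applied to Y_A/BH and Y_A/EH. The credit
fraction (default 0.04, ≈ 5.5 mmol ATP g⁻¹) is configuration: the
comparison of the two transfer mechanisms reports near-indistinguishable
capacities, which implies a small effective credit, and the sensitivity is
a one-argument sweep. Zero credit is the identity; the credit monotonically
raises the maximum capacity.

## Scenario linear programs

Cell-scale optima are condensed into five transformation reactions
(Fe-autotroph, S-autotroph, autotroph export, autotroph-consuming
heterotroph, landscape-carbon heterotroph), each split into per-gram-formed
growth coefficients and per-gram-standing maintenance coefficients.
Landscape carbon shares the autotroph's macromolecular composition and its
production costs no oxygen inside the mat. The LP variables are the five
rates, three biomass pools (autotroph, autotroph-consuming and
landscape-consuming heterotroph) and a split of the autotroph's maintenance
ATP between the two donors; constraints are the pool total, the autotroph
mass balance (with export as a free non-negative slack), the oxygen budget,
kinetic caps (rate ≤ μ_max · pool · depth), abundance-ratio bounds and — in
scenarios B/C — the DIC-origin window encoded on pools (autotrophy-derived
pools as a fraction of total). Scenario A admits Fe only; B adds landscape
carbon; C adds sulfide, with one autotroph pool shared between the two
donors so Fe and S oxidation trade off under the same kinetic cap.

Numerical choices: the LP is scaled internally to µg/µmol so HiGHS default
tolerances are comfortably below the constraint magnitudes; solutions are
deterministic (single HiGHS vertex, reproducible run-to-run). With the
steady-state closure (export = r · heterotroph rate, fixed ratio) the
scenario-A optimum equals the closed-form balance to machine precision —
the cross-module consistency check in the suite.

Envelopes minimize and maximize the Fe(II)-oxidation rate over a grid of
oxygen fluxes. The sweep binds the oxygen balance as an equality: the grid
value represents the measured oxygen uptake of the mat, which is consumed
by definition. Under a plain inequality the lower envelope boundary would
collapse to a flux-independent maintenance floor. Envelope rows are emitted
in per-area and per-volume (÷ depth) normalizations, because field oxygen
uptake and Fe-deposition rates are reported per volume while the flux is
per area; the depth behind the published conversion is not stated, and
this package uses the oxic depth (0.07 cm) consistently.

Containment of a measured point is a closed-region test against the
envelope interpolated at the measured flux, with an optional relative
margin per quantity for measurement uncertainty.

## Synthetic data

Toy networks: analytic kinds with known mode counts (chain 1, diamond 2,
k parallel paths k), an autotroph fixture whose single biomass mode lands
at the published scale (4 Fe(II) : 1 O₂ electron transport, 38 energy units
per Cmole fixed → 38 mol O₂ and 152 mol Fe per Cmole), a heterotroph
fixture at the published 2.4 Cmol + 1.3 mol O₂ per Cmole, and random sparse
networks rejected-and-resampled until they carry a biomass-producing mode.
All generated networks pass structural validation.

Parameter perturbation draws unit-mean log-normal factors per yield at a
configurable coefficient of variation (CV); the two heterotroph acclimation
variants are perturbed jointly so their ordering is preserved in every
draw; carbon contents are held fixed by default.

Field-measurement simulation draws truncated-positive normal replicates of
(oxygen flux, Fe-oxidation rate, abundance ratio, DIC fraction) around
model-implied values of a feasible state, with default CV 0.1 per quantity
(the field reports averages, not error models; the CV is configuration).
Truncations are counted and reported. Fixed seeds give byte-identical
datasets.

The recovery experiment checks that replicates fall inside the generating
scenario's envelope. Because independent noise on the flux and the Fe rate
moves points off the (thin) feasible cone, containment is assessed with a
measurement-uncertainty band of 2.5 × CV per quantity — zero noise, zero
band, exact containment. With the default 10 % CV this band gives ≥ 95 %
containment of scenario-A-generated data in the scenario-A envelope, and a
dataset generated with a sulfide-oxidizing component is contained in
scenario C but lost by scenario A.

What the synthetic exercises show — and what they do not: they demonstrate
internal consistency (the pipeline recovers what it generated, at the
noise level it assumed) and the discriminating geometry of the scenario
envelopes. They do not emulate depth structure, temporal variation,
covariance between measured quantities, or the genome-scale network
complexity of the real organisms; passing them says nothing about whether
the published yield parameters describe any particular spring.

## Problem sizes

The default test run enumerates modes on networks of ≤ 12 reactions
(the brute-force oracle is exponential in reaction count and guarded at 16
split columns), sweeps steady states over ≤ 21-point abundance grids, and
solves a few hundred small LPs; the whole suite completes in a few seconds
on one CPU, and the acceptance script in well under a second. Genome-scale
enumeration (thousands of modes) is supported by the same code path subject
to the combinatorial budget, with SBML import for externally curated
models.

## Known limitations

* The oxic zone is a single homogeneous box; no oxygen microprofile.
* Heterotroph acclimation is a two-point set (carbon-/oxygen-limited
  tabulated yields); intermediate states are not modeled beyond selecting
  either endpoint.
* The scenario LP's maintenance-on-pools encoding makes high-biomass,
  low-flux configurations infeasible (maintenance floor). This is a real
  prediction of the encoding, but it differs from reconstructions that fold
  maintenance into rate coefficients; the published feasibility of the
  landscape-carbon scenario at very low fluxes is not reproduced under this
  encoding.
* As(III) oxidation, thermodynamic (ΔG) feasibility, minimal cut sets and
  dynamic extensions are out of scope.
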