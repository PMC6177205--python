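"""Synthetic-data round trip: simulate noisy field measurements from a known
community state and check they fall inside the generating scenario's
feasible envelope.

This is the package's self-consistency exercise: observations drawn around a
feasible steady state (10 % coefficient of variation per quantity, the
default measurement-noise model) should be contained in the envelope of the
scenario that generated them.
"""

from ironmat import (
    ScenarioSpec,
    SystemGeometry,
    recovery_experiment,
    simulate_field_measurements,
    solve_steady_state,
    table1_defaults,
)

p = table1_defaults("beowulf")
g = SystemGeometry()
state, rates = solve_steady_state(p, g, j_O2=420e-9, r=0.4, X_Tot=0.4e-3)
print(
    f"true state: mu_A = {state.mu_A:.4f} h^-1, "
    f"R_Fe = {rates.R_Fe * 1e6:.3f} umol cm^-2 h^-1"
)

dataset = simulate_field_measurements(state, p, g, n=200, seed=11)
spec = ScenarioSpec("A", X_Tot=0.4e-3, j_O2=420e-9)
report = recovery_experiment(dataset, spec, p, g)
print(
    f"containment of {report['n']} noisy replicates in the scenario-A "
    f"envelope: {report['containment_frequency'] * 100:.1f} % "
    f"(uncertainty band: +/- {report['margin'] * 100:.0f} %)"
)
print(
    "-> with the stated noise model nearly all synthetic observations are "
    "consistent with the generating scenario; real measurements falling "
    "outside such an envelope would point at unmodeled oxygen sinks."
)
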