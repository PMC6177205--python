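"""Cell scale: enumerate elementary flux modes and extract per-Cmole yields.

Builds the toy Fe(II)-oxidizing autotroph network (a 4:1 Fe:O2 electron
transport chain feeding CO2 fixation), enumerates its elementary flux modes
with exact rational arithmetic, cross-checks against the brute-force
extreme-ray oracle, and reports the electron-donor and oxygen cost of one
Cmole of biomass.
"""

from ironmat import (
    brute_force_extreme_rays,
    enumerate_efms,
    limitation_optima,
    make_toy_network,
    mode_yields,
)
from ironmat.synth import ToyNetworkSpec

net = make_toy_network(ToyNetworkSpec(kind="autotroph_fixture"))
modes = enumerate_efms(net)
oracle = brute_force_extreme_rays(net)
print(f"elementary flux modes: {len(modes)} (oracle agrees: {len(oracle) == len(modes)})")

points, skipped = mode_yields(
    modes,
    biomass_rxn="BIOMASS",
    biomass_cmol_per_flux_unit=1.0,
    donor_exchanges={"Fe2": "EX_fe2"},
    o2_exchange="EX_o2",
)
best = limitation_optima(points, "oxygen")
print(f"biomass-producing modes: {len(points)} ({skipped} skipped, no biomass flux)")
print(
    f"oxygen-optimal mode: {best.o2_per_cmol_biomass:.1f} mol O2 and "
    f"{best.donor_per_cmol_biomass:.1f} mol Fe(II) per Cmole biomass"
)
print(
    "-> chemolithoautotrophy on Fe(II) is oxygen-hungry: tens of moles of O2 "
    "per mole of carbon fixed, because each Fe(II) donates a single electron."
)
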