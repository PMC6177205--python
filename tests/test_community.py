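import math

import numpy as np
import pytest

from ironmat import (
    autotroph_turnover,
    exchange_variant_parameters,
    max_carrying_capacity,
    min_carrying_capacity,
    oxygen_partition,
    solve_at_mu_A,
    solve_steady_state,
    sweep_biomass,
)


class TestSteadyStateSolve:
    def test_autotroph_only_minimum_matches_closed_form(self, beowulf, geometry, observed_flux):
        """X_A = j / (depth * (mu_max*Y_O2_BA + M_A*Y_O2_EA)) at mu = mu_max."""
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=math.inf)
        expect = observed_flux / (geometry.depth * (0.1 * 1.63 + 1.1e-4 * 4))
        assert state.X_A == pytest.approx(expect, rel=1e-12)
        assert state.X_A * 1e3 == pytest.approx(0.0367, abs=0.0005)  # ~0.04 mg cm^-3

    def test_pinned_mu_H_closed_form(self, beowulf, geometry, observed_flux):
        """mu_H = (0.1 - M_H*Y_A_EH/r) / (1 + Y_A_BH/r) at r = 0.4."""
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=0.4)
        expect = (0.1 - 1.1e-4 * 16.8 / 0.4) / (1 + 2.29 / 0.4)
        assert state.mu_H == pytest.approx(expect, rel=1e-12)
        assert state.mu_H == pytest.approx(0.0142, abs=2e-4)

    def test_zero_flux_is_infeasible(self, beowulf, geometry):
        state, _ = solve_steady_state(beowulf, geometry, 0.0, 0.4, 1e-4)
        assert state.status != "feasible"

    def test_consistency_between_solvers(self, beowulf, geometry, observed_flux):
        pinned, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=0.4)
        free, _ = solve_steady_state(
            beowulf, geometry, observed_flux, 0.4, pinned.X_Tot
        )
        assert free.mu_A == pytest.approx(pinned.mu_A, rel=1e-10)
        assert free.mu_H == pytest.approx(pinned.mu_H, rel=1e-10)

    @pytest.mark.parametrize("r", [0.3, 0.4, 0.5, 1.0, 5.0])
    @pytest.mark.parametrize("X_mg", [0.1, 0.5, 1.5])
    def test_steady_state_identity_and_oxygen_conservation(
        self, beowulf, geometry, observed_flux, r, X_mg
    ):
        """R_Xnet = mu_H * X_Tot * V and O2 consumptions sum to the flux,
        both to 1e-12 relative."""
        state, rates = solve_steady_state(beowulf, geometry, observed_flux, r, X_mg * 1e-3)
        if state.status != "feasible":
            assert state.status.startswith("infeasible")
            return  # the identity is asserted on the feasible grid corners
        expect = state.mu_H * state.X_Tot * geometry.V / geometry.area
        assert rates.R_Xnet_g == pytest.approx(expect, rel=1e-12)
        Y_A_BH, Y_O2_BH, Y_A_EH, Y_O2_EH = beowulf.het(state.limitation)
        o2 = (
            (state.mu_A * beowulf.Y_O2_BA + beowulf.M_A * beowulf.Y_O2_EA) * state.X_A
            + (state.mu_H * Y_O2_BH + beowulf.M_H * Y_O2_EH) * state.X_H
        ) * geometry.V / geometry.area
        assert o2 == pytest.approx(observed_flux, rel=1e-12)
        assert state.mu_A >= state.mu_H  # predation + shared dilution

    def test_heterotroph_only_limit(self, beowulf, geometry, observed_flux):
        state, _ = solve_steady_state(beowulf, geometry, observed_flux, 0.0, 1e-4)
        assert state.X_A == 0.0
        assert state.mu_H > 0


class TestOxygenPartition:
    def test_heterotroph_free_share_is_one(self, beowulf, geometry, observed_flux):
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=math.inf)
        assert oxygen_partition(state, beowulf, geometry) == 1.0

    def test_in_situ_share(self, beowulf, geometry, observed_flux):
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=0.4)
        assert oxygen_partition(state, beowulf, geometry) == pytest.approx(0.987, abs=0.002)

    def test_shares_bounded_and_complementary(self, beowulf, geometry, observed_flux):
        for r in (0.3, 1.0, 10.0):
            state, rates = solve_steady_state(beowulf, geometry, observed_flux, r, 3e-4)
            assert 0.0 <= rates.o2_autotroph_share <= 1.0

    def test_infeasible_state_rejected(self, beowulf, geometry):
        state, _ = solve_steady_state(beowulf, geometry, 0.0, 0.4, 1e-4)
        with pytest.raises(ValueError):
            oxygen_partition(state, beowulf, geometry)


class TestTurnover:
    def test_in_situ_turnover(self, beowulf, geometry, observed_flux):
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=0.4)
        assert autotroph_turnover(state, beowulf) == pytest.approx(0.858, abs=0.005)

    def test_exceeds_80_percent_over_observed_window(self, beowulf, geometry, observed_flux):
        for r in np.linspace(0.3, 0.5, 9):
            state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=r)
            assert autotroph_turnover(state, beowulf) > 0.80

    def test_vanishes_without_heterotroph(self, beowulf, geometry, observed_flux):
        state, _ = solve_at_mu_A(beowulf, geometry, observed_flux, r=1e6)
        assert autotroph_turnover(state, beowulf) == pytest.approx(0.0, abs=1e-4)

    def test_undefined_without_autotroph_production(self, beowulf, geometry, observed_flux):
        state, _ = solve_steady_state(beowulf, geometry, observed_flux, 0.0, 1e-4)
        with pytest.raises(ValueError):
            autotroph_turnover(state, beowulf)


class TestCarryingCapacities:
    def test_autotroph_only_min_capacity_closed_form(self, beowulf, geometry, observed_flux):
        got = min_carrying_capacity(
            beowulf, geometry, observed_flux, r_range=(math.inf, math.inf)
        )
        expect = observed_flux / (geometry.depth * (0.1 * 1.63 + 1.1e-4 * 4))
        assert got == pytest.approx(expect, rel=1e-5)

    def test_window_scale_at_observed_flux(self, beowulf, geometry, observed_flux):
        x_min = min_carrying_capacity(beowulf, geometry, observed_flux)
        x_max = max_carrying_capacity(beowulf, geometry, observed_flux)
        assert x_min < x_max
        assert 0.1 <= x_min * 1e3 <= 0.4    # ~0.2 mg cm^-3
        assert 1.0 <= x_max * 1e3 <= 3.0    # ~2 mg cm^-3 scale

    def test_capacity_linear_in_flux(self, beowulf, geometry, observed_flux):
        x1 = min_carrying_capacity(beowulf, geometry, observed_flux)
        x2 = min_carrying_capacity(beowulf, geometry, 2 * observed_flux)
        assert x2 == pytest.approx(2 * x1, rel=1e-4)

    def test_max_capacity_boundary_has_zero_net_growth(self, beowulf, geometry, observed_flux):
        x_max = max_carrying_capacity(beowulf, geometry, observed_flux)
        best = max(
            solve_steady_state(beowulf, geometry, observed_flux, r, x_max)[0].mu_H
            for r in np.linspace(0.3, 0.5, 5)
        )
        assert best == pytest.approx(0.0, abs=1e-7)

    def test_max_capacity_closed_form_oracle(self, beowulf, geometry, observed_flux):
        """At mu_H = 0: X = j / (depth * ((mu_A0*Y_O2_BA + M_A*Y_O2_EA)*r/(1+r)
        + M_H*Y_O2_EH/(1+r))) with mu_A0 = M_H*Y_A_EH/r."""
        r = 0.5
        mu_A0 = 1.1e-4 * 16.8 / r
        denom = (mu_A0 * 1.63 + 1.1e-4 * 4) * r / (1 + r) + 1.1e-4 * 0.35 / (1 + r)
        expect = observed_flux / (geometry.depth * denom)
        got = max_carrying_capacity(beowulf, geometry, observed_flux, r_range=(r, r))
        assert got == pytest.approx(expect, rel=1e-5)

    def test_no_bracket_raises_with_diagnostics(self, beowulf, geometry):
        with pytest.raises(ValueError, match="bracket"):
            min_carrying_capacity(beowulf, geometry, 0.0)


class TestSweep:
    def test_three_flux_structure(self, beowulf, geometry, observed_flux):
        fluxes = [0.5 * observed_flux, observed_flux, 2 * observed_flux]
        df = sweep_biomass(beowulf, geometry, fluxes, [0.4], np.geomspace(1e-5, 2e-3, 12))
        assert len(df) == 36
        assert set(df["j_O2_nmol_cm2_h"].round(0)) == {210.0, 420.0, 840.0}

    def test_mu_decreases_with_biomass(self, beowulf, geometry, observed_flux):
        df = sweep_biomass(beowulf, geometry, [observed_flux], [0.4],
                           np.geomspace(1e-4, 1e-3, 8))
        assert (np.diff(df["mu_A"]) < 0).all()
        assert (np.diff(df["mu_H"]) < 0).all()

    def test_flux_doubling_is_affine_in_mu(self, beowulf, geometry, observed_flux):
        X = 5e-4
        lo = solve_steady_state(beowulf, geometry, observed_flux, 0.4, X)[0]
        hi = solve_steady_state(beowulf, geometry, 2 * observed_flux, 0.4, X)[0]
        # doubling j doubles the mu-linear oxygen terms up to maintenance offset
        qa_lo = lo.mu_A * beowulf.Y_O2_BA
        qa_hi = hi.mu_A * beowulf.Y_O2_BA
        j_growth_lo = observed_flux / geometry.depth - (
            beowulf.M_A * beowulf.Y_O2_EA * lo.X_A + beowulf.M_H * 0.35 * lo.X_H
        )
        j_growth_hi = 2 * observed_flux / geometry.depth - (
            beowulf.M_A * beowulf.Y_O2_EA * hi.X_A + beowulf.M_H * 0.35 * hi.X_H
        )
        ratio = (hi.mu_A * 1.63 + hi.mu_H * 0.057 / 0.4) / (
            lo.mu_A * 1.63 + lo.mu_H * 0.057 / 0.4
        )
        assert ratio == pytest.approx(j_growth_hi / j_growth_lo, rel=1e-9)


class TestIronToOxygenRatio:
    @pytest.mark.parametrize("r", [math.inf, 50.0])
    def test_autotroph_dominated_ratio(self, beowulf, geometry, observed_flux, r):
        """R_Fe / j_O2 reflects the 4 Fe : 1 O2 electron stoichiometry."""
        state, rates = solve_at_mu_A(beowulf, geometry, observed_flux, r=r)
        assert 3.9 <= rates.R_Fe / observed_flux <= 4.2


class TestExchangeVariant:
    def test_zero_credit_is_identity(self, beowulf):
        assert exchange_variant_parameters(beowulf, 0.0) == beowulf

    def test_capacities_within_ten_percent_at_default(self, beowulf, geometry, observed_flux):
        q = exchange_variant_parameters(beowulf)
        for fn in (min_carrying_capacity, max_carrying_capacity):
            base = fn(beowulf, geometry, observed_flux)
            var = fn(q, geometry, observed_flux)
            assert abs(var - base) / base < 0.10

    def test_credit_monotonically_increases_max_capacity(self, beowulf, geometry, observed_flux):
        caps = [
            max_carrying_capacity(
                exchange_variant_parameters(beowulf, c), geometry, observed_flux
            )
            for c in (0.0, 0.02, 0.04, 0.08)
        ]
        assert all(b > a for a, b in zip(caps, caps[1:]))

    def test_overlarge_credit_rejected(self, beowulf):
        with pytest.raises(ValueError):
            exchange_variant_parameters(beowulf, 1.0)
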