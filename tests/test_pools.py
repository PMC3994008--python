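"""Pool mechanics: litter split, decay, routing, mass balance, spin-up."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censoc.pools import (
    POOLS,
    DecompParams,
    PoolState,
    SiteProfile,
    active_turnover_modifier,
    decompose_month,
    fit_efolding_years,
    flow_fractions,
    isolated_decay,
    monthly_transition,
    partition_litter,
    spinup,
    stabilization_fraction,
)

IDX = {p: i for i, p in enumerate(POOLS)}


class TestPartitionLitter:
    def test_zero_input_gives_zero_shares(self):
        assert partition_litter(0.0, 0.1, 0.01) == (0.0, 0.0)

    @pytest.mark.parametrize("c,lig,n", [(1000, 0.1, 0.005), (250, 0.25, 0.02), (7.5, 0.0, 0.01)])
    def test_shares_conserve_input(self, c, lig, n):
        met, struc = partition_litter(c, lig, n)
        assert met >= 0 and struc >= 0
        assert met + struc == pytest.approx(c, rel=1e-12)

    def test_metabolic_share_matches_lignin_nitrogen_rule(self):
        # L/N = 0.10/0.005 = 20 -> Fm = 0.85 - 0.018*20 = 0.49
        met, struc = partition_litter(1000.0, 0.10, 0.005)
        assert met == pytest.approx(490.0, rel=1e-12)
        assert struc == pytest.approx(510.0, rel=1e-12)

    def test_higher_lignin_to_n_drives_more_structural(self):
        met_low, _ = partition_litter(100.0, 0.05, 0.01)
        met_high, _ = partition_litter(100.0, 0.25, 0.01)
        assert met_high < met_low

    def test_negative_input_rejected_naming_event(self):
        with pytest.raises(ValueError, match="1995-10"):
            partition_litter(-1.0, 0.1, 0.01, when="1995-10")


class TestTextureResponses:
    def test_reference_texture_modifier_is_one(self, loam):
        assert active_turnover_modifier(loam) == pytest.approx(1.0)

    def test_sandier_soil_turns_over_faster(self):
        sandy = SiteProfile(sand=0.9, silt=0.05, clay=0.05, ph=7, bulk_density=1.4)
        fine = SiteProfile(sand=0.1, silt=0.45, clay=0.45, ph=7, bulk_density=1.4)
        assert active_turnover_modifier(sandy) > active_turnover_modifier(fine)

    def test_changping_modifier_value(self, changping):
        # (0.25 + 0.75*0.162) / (0.25 + 0.75*0.4) = 0.3715 / 0.55
        assert active_turnover_modifier(changping.config.profile) == pytest.approx(
            0.3715 / 0.55, rel=1e-12
        )

    def test_invalid_texture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SiteProfile(sand=0.5, silt=0.5, clay=0.3, ph=7, bulk_density=1.4)

    def test_stabilization_bounds_and_monotonicity(self):
        pure_sand = SiteProfile(sand=1.0, silt=0.0, clay=0.0, ph=7, bulk_density=1.4)
        f0 = stabilization_fraction(pure_sand)
        assert f0 == pytest.approx(1.0 - 0.85 - 0.003)  # minimum of the linear form
        low = SiteProfile(sand=0.7, silt=0.2, clay=0.1, ph=7, bulk_density=1.4)
        high = SiteProfile(sand=0.2, silt=0.5, clay=0.3, ph=7, bulk_density=1.4)
        assert stabilization_fraction(high) >= stabilization_fraction(low)
        assert 0.0 <= stabilization_fraction(high) <= 1.0

    def test_qiyang_stabilization_value(self, qiyang):
        # silt+clay = 0.686: 1 - (0.85 - 0.68*0.686) - (0.003 + 0.032*0.409)
        expect = 1.0 - (0.85 - 0.68 * 0.686) - (0.003 + 0.032 * 0.409)
        assert stabilization_fraction(qiyang.config.profile) == pytest.approx(expect, rel=1e-12)


class TestDecomposeMonth:
    def test_no_decomposition_without_abiotic_drive(self, loam, neutral_params):
        state = PoolState(active=500.0, slow=2000.0, passive=5000.0)
        new, record = decompose_month(state, 0.0, neutral_params, loam)
        assert new.as_array() == pytest.approx(state.as_array())
        assert record.co2 == 0.0

    def test_isolated_slow_pool_decays_exponentially(self, loam, neutral_params):
        # slow turnover 25 yr at DEFAC=1: after 600 months mass = m0 * exp(-2)
        traj = isolated_decay("slow", 600, neutral_params, loam, defac=1.0)
        assert traj[-1] == pytest.approx(1000.0 * math.exp(-600.0 / (12 * 25)), rel=1e-6)

    def test_flux_record_closes_per_pool_budget(self, loam, neutral_params):
        """new mass = old mass - outflow + transfers received, per pool."""
        state = PoolState(**{p: 100.0 * (i + 1) for i, p in enumerate(POOLS)})
        new, record = decompose_month(state, 0.7, neutral_params, loam)
        for pool in POOLS:
            received = sum(f.get(pool, 0.0) for f in record.flows.values())
            expect = getattr(state, pool) - record.outflow(pool) + received
            assert getattr(new, pool) == pytest.approx(expect, rel=1e-12)
        assert all(v >= 0 for f in record.flows.values() for v in f.values())

    @settings(max_examples=50, deadline=None)
    @given(
        masses=st.lists(st.floats(0, 1e5), min_size=7, max_size=7),
        defac=st.floats(0, 1),
        till=st.floats(1.0, 1.6),
    )
    def test_mass_balance_every_step(self, masses, defac, till):
        """With no inputs, the drop in total carbon equals the CO2 released."""
        loam = SiteProfile(sand=0.4, silt=0.4, clay=0.2, ph=7, bulk_density=1.4)
        params = DecompParams()
        state = PoolState(**dict(zip(POOLS, masses)))
        new, record = decompose_month(state, defac, params, loam, till)
        total_before = state.total_carbon()
        total_after = new.total_carbon()
        scale = max(total_before, 1.0)
        assert abs((total_before - total_after) - record.co2) <= 1e-9 * scale
        assert min(new.as_array()) >= 0

    def test_routing_fractions_sum_to_one(self, loam, qiyang):
        params = DecompParams()
        for site in (loam, qiyang.config.profile):
            for donor, flows in flow_fractions(params, site).items():
                assert sum(flows.values()) == pytest.approx(1.0, abs=1e-12), donor

    def test_transition_matrix_matches_stepwise_decomposition(self, loam, params, rng):
        masses = rng.uniform(0, 1e4, size=7)
        state = PoolState(**dict(zip(POOLS, masses)))
        new, _ = decompose_month(state, 0.43, params, loam, 1.6)
        D = monthly_transition(params, loam, 0.43, 1.6)
        assert D @ masses == pytest.approx(new.as_array(), rel=1e-12)

    def test_mis_scaled_rate_raises(self, loam):
        bad = DecompParams(turnover_metabolic=0.02, defac_reference=1.0)
        with pytest.raises(ValueError, match="mis-scaled"):
            decompose_month(PoolState(metabolic_soil=10.0), 1.0, bad, loam)


def _efold_years(params, site, pool, months, defac=1.0):
    return fit_efolding_years(isolated_decay(pool, months, params, site, defac=defac))


class TestTurnoverRecovery:
    @pytest.mark.parametrize(
        "pool,months,expected",
        [("active", 120, 1.5), ("slow", 600, 25.0), ("passive", 6000, 1000.0)],
    )
    def test_isolated_pool_efolding_matches_turnover(self, loam, pool, months, expected):
        params = DecompParams.from_turnover(25.0, defac_reference=1.0)
        assert _efold_years(params, loam, pool, months) == pytest.approx(expected, rel=0.01)

    def test_effective_turnover_scales_with_reference_defac(self, loam):
        """At DEFAC = defac_reference the configured turnover is realized."""
        params = DecompParams.from_turnover(25.0, defac_reference=0.2)
        assert _efold_years(params, loam, "slow", 600, defac=0.2) == pytest.approx(25.0, rel=0.01)


class TestSpinup:
    def _drivers(self, inputs_total=100.0, defac=0.5):
        inp = np.zeros(len(POOLS))
        inp[IDX["metabolic_soil"]] = 0.6 * inputs_total
        inp[IDX["structural_soil"]] = 0.4 * inputs_total
        return [(defac, 1.0, inp.copy()) for _ in range(12)]

    def test_zero_inputs_decay_to_nothing(self, loam, params):
        zero = [(0.5, 1.0, np.zeros(len(POOLS))) for _ in range(12)]
        start = PoolState(active=100.0, slow=1000.0, metabolic_soil=50.0)
        state = spinup(zero, params, loam, years=4000, initial=start)
        assert state.total_carbon() < 1e-4 * start.total_carbon()

    def test_equilibrium_matches_closed_form_fixed_point(self, loam, params):
        """The linear-flow fixed point x = D(x+u) solved directly agrees to 0.1%."""
        drivers = self._drivers()
        state = spinup(drivers, params, loam, years=4000)
        D = monthly_transition(params, loam, 0.5, 1.0)
        u = drivers[0][2]
        x_star = np.linalg.solve(np.eye(len(POOLS)) - D, D @ u)
        assert state.as_array() == pytest.approx(x_star, rel=1e-3)

    def test_doubling_inputs_doubles_every_pool(self, loam, params):
        s1 = spinup(self._drivers(100.0), params, loam, years=3000)
        s2 = spinup(self._drivers(200.0), params, loam, years=3000)
        assert s2.as_array() == pytest.approx(2.0 * s1.as_array(), rel=1e-6)

    def test_superposition_of_input_streams(self, loam, params):
        """The flow network is linear: response to summed inputs = sum of responses."""
        inp_a = np.zeros(len(POOLS))
        inp_a[IDX["metabolic_surface"]] = 80.0
        inp_b = np.zeros(len(POOLS))
        inp_b[IDX["structural_soil"]] = 50.0
        mk = lambda inp: [(0.4, 1.0, inp.copy()) for _ in range(12)]
        sa = spinup(mk(inp_a), params, loam, years=3000).as_array()
        sb = spinup(mk(inp_b), params, loam, years=3000).as_array()
        sab = spinup(mk(inp_a + inp_b), params, loam, years=3000).as_array()
        assert sab == pytest.approx(sa + sb, rel=1e-9)

    def test_larger_dec4_lowers_equilibrium_slow_and_total(self, loam):
        drivers = self._drivers()
        lo = spinup(drivers, DecompParams(dec4=0.0023), loam, years=4000)
        hi = spinup(drivers, DecompParams(dec4=0.0045), loam, years=4000)
        assert hi.slow < lo.slow
        assert hi.total_soc() < lo.total_soc()

    def test_non_convergence_warns(self, loam, params):
        with pytest.warns(UserWarning, match="not converged"):
            spinup(self._drivers(), params, loam, years=150)
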