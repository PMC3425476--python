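"""Growth engine: production, demand, allocation, allometry and the yearly loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinewater.architecture import (
    INTERNODE,
    NEEDLE,
    BranchingRules,
    TreeTopology,
    develop_cycle,
)
from pinewater.growth import (
    AllocationError,
    PlantParams,
    allocate_primary,
    allocate_rings,
    biomass_production,
    demand,
    internode_dimensions,
    leaf_metrics,
    simulate,
)

from test_weather import et0_oracle


class TestBiomassProduction:
    def test_no_transpiration_no_biomass(self, params):
        assert biomass_production(0.0, 1.0, params) == 0.0

    def test_reference_parameter_arithmetic(self):
        # wue 4.5 g kg-1, 100 mm over 1 m2, c_w 0.6: dry 450 g, fresh 1125 g
        p = PlantParams(wue=4.5, c_w=0.6)
        assert biomass_production(100.0, 1.0, p) == pytest.approx(1125.0)

    def test_linear_in_transpiration(self, params):
        q1 = biomass_production(37.0, 1.0, params)
        q2 = biomass_production(74.0, 1.0, params)
        assert q2 == pytest.approx(2 * q1)


class TestDemand:
    def test_single_trunk_unit_with_reference_sinks(self, params):
        census = {INTERNODE: {1: 1}, NEEDLE: {1: 1}}
        # 1.37 + 1 + 11.09
        assert demand(census, params) == pytest.approx(13.46)

    def test_empty_census_without_ring_sink_is_zero(self):
        p = PlantParams(p_c=0.0)
        assert demand({}, p) == 0.0

    def test_additive_over_disjoint_censuses(self, params):
        a = {INTERNODE: {1: 2}, NEEDLE: {1: 2}}
        b = {INTERNODE: {2: 5}, NEEDLE: {2: 5, 3: 1}}
        merged = {
            INTERNODE: {1: 2, 2: 5},
            NEEDLE: {1: 2, 2: 5, 3: 1},
        }
        assert demand(merged, params) == pytest.approx(
            demand(a, params) + demand(b, params) - params.p_c
        )


class TestAllocatePrimary:
    def test_hand_evaluated_trunk_shares(self, params):
        census = {INTERNODE: {1: 1}, NEEDLE: {1: 1}}
        shares, ring = allocate_primary(134.6, 13.46, census, params)
        assert shares[(INTERNODE, 1)] == pytest.approx(13.7)
        assert shares[(NEEDLE, 1)] == pytest.approx(10.0)
        assert ring == pytest.approx(110.9)

    def test_zero_demand_with_supply_errors(self, params):
        with pytest.raises(AllocationError):
            allocate_primary(5.0, 0.0, {}, params)

    @given(
        q=st.floats(0.1, 1e4),
        n1=st.integers(0, 40),
        n2=st.integers(0, 40),
        n3=st.integers(1, 40),
    )
    @settings(max_examples=100, derandomize=True)
    def test_conservation_on_random_censuses(self, q, n1, n2, n3):
        params = PlantParams()
        census = {
            INTERNODE: {1: n3, 2: n1, 4: n2},
            NEEDLE: {1: n3, 3: n2},
        }
        d = demand(census, params)
        shares, ring = allocate_primary(q, d, census, params)
        total = ring + sum(
            shares[(kind, pa)] * n
            for kind, by_pa in census.items()
            for pa, n in by_pa.items()
        )
        assert total == pytest.approx(q, rel=1e-9)

    def test_equal_sinks_receive_equal_biomass(self):
        p = PlantParams(p_e=(0.3, 0.3, 0.3, 0.3), p_c=0.0)
        census = {INTERNODE: {1: 1, 3: 1}}
        shares, _ = allocate_primary(10.0, demand(census, p), census, p)
        assert shares[(INTERNODE, 1)] == pytest.approx(shares[(INTERNODE, 3)])


def axis_of_three(params, lengths=(10.0, 8.0, 6.0), areas=(50.0, 80.0, 120.0)):
    """A bare 3-unit trunk with set internode lengths and needle areas."""
    rules = BranchingRules(laterals={})
    topo = TreeTopology()
    for _ in range(3):
        develop_cycle(topo, rules)
    for u, length, area in zip(topo.units, lengths, areas):
        u.internode.length = length
        u.internode.diameter = 0.5
        u.needle.leaf_area = area
        u.needle.alive = True
    return topo


class TestAllocateRings:
    def test_single_internode_takes_whole_pool(self, params):
        rules = BranchingRules(laterals={})
        topo = TreeTopology()
        develop_cycle(topo, rules)
        topo.units[0].internode.length = 12.0
        inc = allocate_rings(7.0, topo, params)
        assert sum(inc.values()) == pytest.approx(7.0)
        assert topo.units[0].internode.ring_biomass == pytest.approx(7.0)

    def test_lambda_zero_weights_by_length_only(self):
        p = PlantParams(lambda_ring=0.0)
        topo = axis_of_three(p)
        inc = allocate_rings(24.0, topo, p)
        lengths = np.array([10.0, 8.0, 6.0])
        expected = 24.0 * lengths / lengths.sum()
        got = np.array([inc[u.uid] for u in topo.units])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_hand_computed_weight_table(self):
        # trunk axis, lambda = 0.03, Rp[1] = 1 (reference)
        p = PlantParams(lambda_ring=0.03)
        topo = axis_of_three(p)
        total_area = 50.0 + 80.0 + 120.0
        a_above = [1.0, (80.0 + 120.0) / total_area, 120.0 / total_area]
        w = [
            1.0 * l * (0.03 * a + 0.97)
            for l, a in zip([10.0, 8.0, 6.0], a_above)
        ]
        expected = 24.0 * np.array(w) / sum(w)
        inc = allocate_rings(24.0, topo, p)
        got = np.array([inc[u.uid] for u in topo.units])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_ring_mass_thickens_diameter_consistently(self, params):
        topo = axis_of_three(params)
        before = [u.internode.diameter for u in topo.units]
        inc = allocate_rings(30.0, topo, params)
        for u, d0 in zip(topo.units, before):
            organ = u.internode
            added_area = math.pi / 4 * (organ.diameter**2 - d0**2)
            assert added_area * params.rho * organ.length == pytest.approx(
                inc[u.uid], rel=1e-9
            )

    def test_empty_pool_is_a_no_op(self, params):
        topo = axis_of_three(params)
        assert allocate_rings(0.0, topo, params) == {
            u.uid: 0.0 for u in topo.units
        }


class TestInternodeDimensions:
    @given(q=st.floats(0.01, 500.0), pa=st.integers(1, 4))
    @settings(max_examples=100, derandomize=True)
    def test_cylinder_identity(self, q, pa):
        params = PlantParams()
        length, diameter = internode_dimensions(q, pa, params)
        volume = math.pi / 4 * length * diameter**2
        assert volume * params.rho == pytest.approx(q, rel=1e-9)

    def test_hand_evaluated_trunk_allometry(self):
        # q = 50 g, b = 76.4, beta = -0.24, rho = 1
        p = PlantParams()
        length, diameter = internode_dimensions(50.0, 1, p)
        s = 76.4 * 50.0 ** (-0.24)
        assert length == pytest.approx((4 * s * s * 50.0 / math.pi) ** (1 / 3), rel=1e-12)
        assert length == pytest.approx(38.45, abs=0.01)
        assert diameter == pytest.approx(1.287, abs=0.001)

    def test_length_increases_with_biomass(self, params):
        qs = np.linspace(0.5, 100.0, 50)
        for pa in range(1, 5):
            lengths = [internode_dimensions(q, pa, params)[0] for q in qs]
            assert all(a < b for a, b in zip(lengths, lengths[1:]))

    def test_non_positive_biomass_rejected(self, params):
        with pytest.raises(ValueError):
            internode_dimensions(0.0, 1, params)


class TestLeafMetrics:
    def test_no_living_needles_means_zero_lai(self, params, rules):
        topo = TreeTopology()
        develop_cycle(topo, rules)
        topo.units[0].needle.leaf_area = 500.0
        topo.age = 10  # far beyond functioning time
        s_a, lai = leaf_metrics(topo, params, s_p=1.0)
        assert s_a == 0.0
        assert lai == 0.0

    def test_reference_area_arithmetic(self):
        # fresh 10 g, c_w 0.6, epsilon 0.035 -> 114.29 cm2
        p = PlantParams()
        area = 10.0 * (1 - p.c_w) / p.epsilon
        assert area == pytest.approx(114.29, abs=0.01)

    def test_area_additive_over_entities(self, params):
        topo = axis_of_three(params)
        s_a, lai = leaf_metrics(topo, params, s_p=1.0)
        assert s_a == pytest.approx((50.0 + 80.0 + 120.0) / 1e4)
        assert lai == pytest.approx(s_a)


class TestSimulate:
    def test_dead_seed_is_a_fixed_point(self, weather_years, soil, site, rules):
        params = PlantParams(q0=0.0)
        ledgers, topo = simulate(weather_years, soil, site, rules, params, n_cycles=3)
        for led in ledgers:
            assert led.q_produced == 0.0
            assert led.lai == 0.0
            assert led.t_a == 0.0
            assert led.aboveground == 0.0

    def test_biomass_conservation_each_cycle(self, weather_years, soil, site, rules, params):
        ledgers, _ = simulate(weather_years, soil, site, rules, params, n_cycles=5)
        allocated = params.q0 + sum(l.q_produced for l in ledgers[:-1])
        assert ledgers[-1].aboveground == pytest.approx(allocated, rel=1e-9)

    def test_trunk_organs_outweigh_branch_organs(self, weather_years, soil, site, rules, params):
        _, topo = simulate(weather_years, soil, site, rules, params, n_cycles=4)
        for cycle in range(1, 5):
            by_pa = {}
            for u in topo.units:
                if u.birth_cycle == cycle:
                    by_pa.setdefault(u.pa, u.internode.fresh_biomass)
            pas = sorted(by_pa)
            masses = [by_pa[pa] for pa in pas]
            assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_more_precipitation_never_hurts(self, weather_years, soil, site, rules, params):
        import dataclasses

        from pinewater.soil import compute_forcing

        forcings = [compute_forcing(y, site) for y in weather_years[:3]]
        produced = []
        for scale in (0.8, 1.0, 1.2):
            scaled = [
                dataclasses.replace(f, precip=f.precip * scale) for f in forcings
            ]
            ledgers, _ = simulate(
                None, soil, site, rules, params, n_cycles=3, forcings=scaled
            )
            produced.append([l.q_produced for l in ledgers])
        for a, b in zip(produced, produced[1:]):
            assert all(x <= y + 1e-12 for x, y in zip(a, b))


class TestTwoCycleHandStepped:
    """Every ledger quantity of a 2-cycle run vs an independent literal re-computation.

    Constant weather, a single lateral at PA 1->2, reference plant
    parameters: the five stages (develop, allocate, allometry+rings, water
    season, production) are re-stepped below with nothing shared with the
    engine except the weather fixture and the independent ET0 oracle.
    """

    def test_matches_hand_computation(self, constant_weather_year, soil, site):
        params = PlantParams()
        rules = BranchingRules(laterals={1: 1})
        ledgers, topo = simulate(
            [constant_weather_year], soil, site, rules, params, n_cycles=2
        )

        et0_days = [et0_oracle(d, site) for d in constant_weather_year]

        def season(lai):
            d_r, eta_sum, ta_sum = 0.0, 0.0, 0.0
            frac = 1 - math.exp(-0.5 * lai)
            for e, day in zip(et0_days, constant_weather_year):
                ks = 1.0 if d_r <= 25.0 else (50.0 - d_r) / (0.5 * 50.0)
                eta = ks * e
                eta_sum += eta
                ta_sum += eta * frac
                d_r = min(max(d_r - day.precip + eta, 0.0), 50.0)
            return eta_sum, ta_sum

        def dims(q, b, beta):
            s = b * q**beta
            length = (4 * s * s * q / math.pi) ** (1 / 3)
            return length, length / s

        # --- cycle 1: one trunk unit
        d1 = 1.37 + 1.0 + 11.09
        q_int1 = 1.37 / d1 * 10.0
        q_ndl1 = 1.0 / d1 * 10.0
        ring1 = 11.09 / d1 * 10.0
        l1, dia1 = dims(q_int1, 76.4, -0.24)
        area1 = q_ndl1 * 0.4 / 0.035
        # whole ring pool lands on the only internode
        dia1_ringed = math.sqrt(4 * (math.pi / 4 * dia1**2 + ring1 / l1) / math.pi)
        lai1 = area1 / 1e4
        eta1, ta1 = season(lai1)
        q1 = 4.5 * ta1 / 0.4

        led = ledgers[0]
        assert led.demand == pytest.approx(d1)
        assert led.q_allocated == pytest.approx(10.0)
        assert led.lai == pytest.approx(lai1, rel=1e-12)
        assert led.et_a == pytest.approx(eta1, rel=1e-9)
        assert led.t_a == pytest.approx(ta1, rel=1e-9)
        assert led.q_produced == pytest.approx(q1, rel=1e-9)
        assert led.height == pytest.approx(l1, rel=1e-12)
        assert led.basal_diameter == pytest.approx(dia1_ringed, rel=1e-12)
        assert led.aboveground == pytest.approx(10.0, rel=1e-12)

        # --- cycle 2: trunk extension + one PA-2 lateral
        d2 = 1.37 + 0.12 + 1.0 + 0.42 + 11.09
        q_int2 = 1.37 / d2 * q1
        q_int2b = 0.12 / d2 * q1
        q_ndl2 = 1.0 / d2 * q1
        q_ndl2b = 0.42 / d2 * q1
        ring2 = 11.09 / d2 * q1
        l2, dia2 = dims(q_int2, 76.4, -0.24)
        l2b, dia2b = dims(q_int2b, 163.3, -0.30)
        area2 = q_ndl2 * 0.4 / 0.035
        area2b = q_ndl2b * 0.4 / 0.035
        total_area = area1 + area2 + area2b
        w_base = 1.0 * l1 * (0.03 * 1.0 + 0.97)
        w_ext = 1.0 * l2 * (0.03 * area2 / total_area + 0.97)
        w_lat = 0.07 * l2b * (0.03 * area2b / total_area + 0.97)
        w_sum = w_base + w_ext + w_lat
        inc_base = ring2 * w_base / w_sum
        dia1_final = math.sqrt(
            4 * (math.pi / 4 * dia1_ringed**2 + inc_base / l1) / math.pi
        )
        lai2 = total_area / 1e4
        eta2, ta2 = season(lai2)
        q2 = 4.5 * ta2 / 0.4

        led = ledgers[1]
        assert led.demand == pytest.approx(d2)
        assert led.q_allocated == pytest.approx(q1, rel=1e-9)
        assert led.lai == pytest.approx(lai2, rel=1e-9)
        assert led.et_a == pytest.approx(eta2, rel=1e-9)
        assert led.t_a == pytest.approx(ta2, rel=1e-9)
        assert led.q_produced == pytest.approx(q2, rel=1e-9)
        assert led.height == pytest.approx(l1 + l2, rel=1e-9)
        assert led.basal_diameter == pytest.approx(dia1_final, rel=1e-9)
        assert led.trunk_mass == pytest.approx(
            q_int1 + ring1 + q_ndl1 + q_int2 + q_ndl2 + ring2 * w_ext / w_sum
            + inc_base,
            rel=1e-9,
        )
        assert led.internode_mass == pytest.approx(
            q_int1 + ring1 + q_int2 + q_int2b + ring2, rel=1e-9
        )
        assert led.needle_mass == pytest.approx(
            q_ndl1 + q_ndl2 + q_ndl2b, rel=1e-9
        )
        assert led.aboveground == pytest.approx(10.0 + q1, rel=1e-9)
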