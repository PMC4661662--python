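"""Catchment-search rules: worked values, bracketing, monotonicity, oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

from catchaccess.catchment import (
    compute_all_catchments,
    facility_catchment,
    facility_fpr,
    population_catchment,
    v2sfca_demand_catchment,
    v2sfca_supply_catchment,
)
from catchaccess.core import (
    SENTINEL_INF,
    DecaySpec,
    EVConfig,
    FacilitySite,
    ODMatrix,
    PopulationSite,
    V2Config,
)

from conftest import (
    oracle_facility_catchment,
    oracle_grid,
    oracle_population_catchment,
    random_instance,
)


def _simple(populations_at):
    """One facility at the origin plus populations at given (pop, minutes)."""
    fac = FacilitySite("f", 0, 0, 10)
    pops = []
    od = ODMatrix(t_max=120)
    for k, (count, minutes) in enumerate(populations_at):
        p = PopulationSite(f"p{k}", 0, 0, count)
        pops.append(p)
        od.set_time("f", p.id, minutes)
    return fac, pops, od


class TestFacilityFPR:
    def test_single_reachable_population(self):
        fac, pops, od = _simple([(2000, 5)])
        assert facility_fpr(fac, pops, od, 5) == pytest.approx(0.005)

    def test_empty_window_gives_sentinel(self):
        fac, pops, od = _simple([(2000, 50)])
        assert facility_fpr(fac, pops, od, 10) == SENTINEL_INF

    def test_cumulative_window(self):
        fac, pops, od = _simple([(2000, 5), (4000, 10)])
        assert facility_fpr(fac, pops, od, 10) == pytest.approx(10 / 6000, abs=1e-7)


class TestFacilityCatchment:
    def test_expands_until_ratio_drops(self):
        fac, pops, od = _simple([(2000, 5), (4000, 10)])
        cfg = EVConfig(t0=5, dt=1, fprt1=0.0027)
        rec = facility_catchment(fac, pops, od, cfg)
        assert rec.catchment == 10
        assert rec.fpr == pytest.approx(10 / 6000, abs=1e-7)
        assert not rec.capped

    def test_stops_at_t0_when_already_below(self):
        fac, pops, od = _simple([(5000, 5)])
        rec = facility_catchment(fac, pops, od, EVConfig(fprt1=0.0027))
        assert rec.catchment == 5 and not rec.capped

    def test_caps_with_sentinel_when_isolated(self):
        fac, pops, od = _simple([])
        rec = facility_catchment(fac, pops, od, EVConfig())
        assert rec.catchment == 120 and rec.capped
        assert math.isinf(rec.fpr)


class TestPopulationCatchment:
    def test_accumulates_facility_ratios(self):
        pop = PopulationSite("p", 0, 0, 100)
        od = ODMatrix(t_max=120)
        od.set_time("f1", "p", 5)
        od.set_time("f2", "p", 12)
        cfg = EVConfig(t0=5, dt=1, fprt2=0.03)
        rec = population_catchment(pop, [("f1", 0.01), ("f2", 0.025)], od, cfg)
        assert rec.catchment == 12 and not rec.capped

    def test_satisfied_at_t0(self):
        pop = PopulationSite("p", 0, 0, 100)
        od = ODMatrix(t_max=120)
        od.set_time("f1", "p", 5)
        rec = population_catchment(pop, [("f1", 0.05)], od, EVConfig())
        assert rec.catchment == 5 and not rec.capped

    def test_caps_when_no_facility_reachable(self):
        pop = PopulationSite("p", 0, 0, 100)
        rec = population_catchment(pop, [("f1", 0.05)], ODMatrix(t_max=120), EVConfig())
        assert rec.catchment == 120 and rec.capped

    def test_infinite_summand_satisfies_immediately(self):
        pop = PopulationSite("p", 0, 0, 100)
        od = ODMatrix(t_max=120)
        od.set_time("f1", "p", 9)
        rec = population_catchment(pop, [("f1", SENTINEL_INF)], od, EVConfig())
        assert rec.catchment == 9 and not rec.capped


class TestV2Catchments:
    def test_supply_expands_to_base_population(self):
        fac, pops, od = _simple([(4000, 5), (6000, 20)])
        cfg = V2Config(base_population=5000, t0=5, dt=1)
        rec = v2sfca_supply_catchment(fac, pops, od, cfg)
        assert rec.catchment == 20
        assert rec.fpr == pytest.approx(10 / 10_000)

    def test_supply_satisfied_at_t0(self):
        fac, pops, od = _simple([(6000, 5)])
        rec = v2sfca_supply_catchment(fac, pops, od, V2Config(base_population=5000))
        assert rec.catchment == 5 and not rec.capped

    def test_supply_caps_when_population_insufficient(self):
        fac, pops, od = _simple([(3000, 10)])
        rec = v2sfca_supply_catchment(fac, pops, od, V2Config(base_population=5000))
        assert rec.catchment == 120 and rec.capped

    def test_demand_mirror_of_population_catchment(self):
        pop = PopulationSite("p", 0, 0, 100)
        od = ODMatrix(t_max=120)
        od.set_time("f1", "p", 5)
        od.set_time("f2", "p", 12)
        cfg = V2Config(ppr=0.03, t0=5, dt=1)
        rec = v2sfca_demand_catchment(pop, [("f1", 0.01), ("f2", 0.025)], od, cfg)
        assert rec.catchment == 12

    def test_supply_catchment_invariant_to_capacity(self, rng):
        """The baseline's central deficiency: beds never change the catchment."""
        for _ in range(10):
            facilities, populations, od = random_instance(rng)
            cfg = V2Config(base_population=10_000)
            for f in facilities:
                base = v2sfca_supply_catchment(f, populations, od, cfg)
                bigger = FacilitySite(f.id, f.x, f.y, f.capacity * 50)
                again = v2sfca_supply_catchment(bigger, populations, od, cfg)
                assert again.catchment == base.catchment
                assert again.capped == base.capped


class TestBatch:
    def test_worked_instance_catchments(self, toy):
        facilities, populations, od, cfg = toy
        table = compute_all_catchments(facilities, populations, od, cfg, "ev2sfca")
        assert table.facility["a"].catchment == 20
        assert table.facility["a"].fpr == pytest.approx(0.0025)
        assert table.facility["b"].catchment == 5
        assert table.population["A"].catchment == 120 and table.population["A"].capped
        assert table.population["B"].catchment == 120 and table.population["B"].capped

    def test_empty_facility_list_caps_all_populations(self, toy):
        _, populations, _, cfg = toy
        table = compute_all_catchments([], populations, ODMatrix(t_max=120), cfg)
        assert not table.facility
        assert all(r.capped for r in table.population.values())

    def test_colocated_pair_stops_at_t0(self):
        fac = FacilitySite("f", 0, 0, 10)
        pop = PopulationSite("p", 0, 0, 10_000)
        od = ODMatrix(t_max=120)
        od.set_time("f", "p", 0)
        table = compute_all_catchments([fac], [pop], od, EVConfig())
        assert table.facility["f"].catchment == 5

    def test_unknown_od_id_is_hard_error(self, toy):
        facilities, populations, od, cfg = toy
        od.set_time("ghost", "A", 3)
        with pytest.raises(ValueError, match="ghost"):
            compute_all_catchments(facilities, populations, od, cfg)


class TestSearchProperties:
    def test_grid_membership_and_bracketing_randomized(self, rng):
        """Any uncapped catchment is the first grid point meeting its rule."""
        cfg = EVConfig(t0=5, dt=3, fprt1=0.005, fprt2=0.02)
        grid = set(oracle_grid(cfg.t0, cfg.dt, cfg.t_max))
        for _ in range(50):
            facilities, populations, od = random_instance(rng)
            table = compute_all_catchments(facilities, populations, od, cfg)
            fprs = [(fid, r.fpr) for fid, r in table.facility.items()]
            for f in facilities:
                rec = table.facility[f.id]
                assert rec.catchment in grid if not rec.capped else rec.catchment == cfg.t_max
                if not rec.capped and rec.catchment > cfg.t0:
                    assert facility_fpr(f, populations, od, rec.catchment) <= cfg.fprt1
                    assert facility_fpr(f, populations, od, rec.catchment - cfg.dt) > cfg.fprt1
            for p in populations:
                rec = table.population[p.id]
                assert rec.catchment in grid if not rec.capped else rec.catchment == cfg.t_max
                if not rec.capped and rec.catchment > cfg.t0:
                    def cum(t):
                        return sum(v for fid, v in fprs if od.time(fid, p.id) <= t)
                    assert cum(rec.catchment) >= cfg.fprt2
                    assert cum(rec.catchment - cfg.dt) < cfg.fprt2

    def test_matches_bruteforce_oracle(self, rng):
        cfg = EVConfig(t0=5, dt=2, fprt1=0.004, fprt2=0.025)
        for _ in range(40):
            facilities, populations, od = random_instance(rng)
            table = compute_all_catchments(facilities, populations, od, cfg)
            fprs = {fid: r.fpr for fid, r in table.facility.items()}
            for f in facilities:
                c, r, capped = oracle_facility_catchment(f, populations, od, cfg)
                assert table.facility[f.id].catchment == c
                assert table.facility[f.id].capped == capped
                if not math.isinf(r):
                    assert table.facility[f.id].fpr == pytest.approx(r, abs=1e-12)
            for p in populations:
                c, capped = oracle_population_catchment(p, list(fprs.items()), od, cfg)
                assert table.population[p.id].catchment == c
                assert table.population[p.id].capped == capped

    def test_capacity_monotonicity(self, rng):
        """More beds never shrink the facility catchment."""
        cfg = EVConfig(fprt1=0.005)
        for _ in range(20):
            facilities, populations, od = random_instance(rng, n_fac=1)
            f = facilities[0]
            c1 = facility_catchment(f, populations, od, cfg).catchment
            f2 = FacilitySite(f.id, f.x, f.y, f.capacity * 3)
            c2 = facility_catchment(f2, populations, od, cfg).catchment
            assert c2 >= c1

    def test_demand_monotonicity(self, rng):
        """Extra reachable population never grows the facility catchment."""
        cfg = EVConfig(fprt1=0.005)
        for _ in range(20):
            facilities, populations, od = random_instance(rng, n_fac=1)
            f = facilities[0]
            c1 = facility_catchment(f, populations, od, cfg).catchment
            extra = PopulationSite("extra", 0, 0, 5000)
            od.set_time(f.id, "extra", float(rng.integers(0, 120)))
            c2 = facility_catchment(f, populations + [extra], od, cfg).catchment
            assert c2 <= c1

    def test_threshold_monotonicity(self, rng):
        """Lower FPRT1 -> larger facility catchments; higher FPRT2 -> larger
        population catchments."""
        for _ in range(15):
            facilities, populations, od = random_instance(rng)
            lo = EVConfig(fprt1=135 / 60_000, fprt2=0.03)
            hi = EVConfig(fprt1=135 / 40_000, fprt2=0.03)
            t_lo = compute_all_catchments(facilities, populations, od, lo)
            t_hi = compute_all_catchments(facilities, populations, od, hi)
            for fid in t_lo.facility:
                assert t_lo.facility[fid].catchment >= t_hi.facility[fid].catchment
            small = compute_all_catchments(
                facilities, populations, od, EVConfig(fprt2=0.02)
            )
            large = compute_all_catchments(
                facilities, populations, od, EVConfig(fprt2=0.04)
            )
            for pid in small.population:
                assert large.population[pid].catchment >= small.population[pid].catchment

    def test_strict_thresholds_never_stop_earlier(self, rng):
        for _ in range(10):
            facilities, populations, od = random_instance(rng)
            cfg = EVConfig(fprt1=0.005, fprt2=0.02)
            strict = replace(cfg, strict_thresholds=True)
            a = compute_all_catchments(facilities, populations, od, cfg)
            b = compute_all_catchments(facilities, populations, od, strict)
            for fid in a.facility:
                assert b.facility[fid].catchment >= a.facility[fid].catchment
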