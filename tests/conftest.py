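"""Shared fixtures and an independent brute-force oracle.

The oracle re-derives the whole four-step pipeline from first principles
over plain dicts — every candidate travel time is evaluated from scratch
with no incremental state — so it shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from catchaccess.core import (
    DecaySpec,
    EVConfig,
    FacilitySite,
    ODMatrix,
    PopulationSite,
)


# ---------------------------------------------------------------------------
# Worked toy instance (2 facilities x 2 populations, hand-enumerable)


@pytest.fixture
def toy():
    facilities = [FacilitySite("a", 0, 0, 25), FacilitySite("b", 10_000, 0, 10)]
    populations = [
        PopulationSite("A", 2_000, 0, 4_000),
        PopulationSite("B", 11_000, 0, 6_000),
    ]
    od = ODMatrix(t_max=120)
    od.set_time("a", "A", 5)
    od.set_time("a", "B", 20)
    od.set_time("b", "A", 15)
    od.set_time("b", "B", 5)
    cfg = EVConfig(t0=5, dt=5, t_max=120, decay=DecaySpec(family="none"))
    return facilities, populations, od, cfg


# ---------------------------------------------------------------------------
# Random small-instance factory


def random_instance(rng: np.random.Generator, n_fac=None, n_pop=None):
    """A random small instance with integer travel times on a dense-ish OD."""
    n_fac = n_fac if n_fac is not None else int(rng.integers(1, 6))
    n_pop = n_pop if n_pop is not None else int(rng.integers(1, 6))
    facilities = [
        FacilitySite(f"f{i}", float(rng.uniform(0, 1e4)), float(rng.uniform(0, 1e4)),
                     float(rng.integers(5, 500)))
        for i in range(n_fac)
    ]
    populations = [
        PopulationSite(f"p{j}", float(rng.uniform(0, 1e4)), float(rng.uniform(0, 1e4)),
                       float(rng.integers(0, 20_000)))
        for j in range(n_pop)
    ]
    od = ODMatrix(t_max=120)
    for f in facilities:
        for p in populations:
            if rng.random() < 0.85:
                od.set_time(f.id, p.id, float(rng.integers(0, 130)))
    return facilities, populations, od


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926)


# ---------------------------------------------------------------------------
# Brute-force oracle


def oracle_grid(t0, dt, t_max):
    ts = []
    k = 0
    while t0 + k * dt <= t_max + 1e-9:
        ts.append(min(t0 + k * dt, t_max))
        k += 1
    return ts


def oracle_facility_catchment(fac, populations, od, cfg):
    """First grid t (full scan) where S / reachable population <= FPRT1."""
    for t in oracle_grid(cfg.t0, cfg.dt, cfg.t_max):
        pop = sum(p.population for p in populations if od.time(fac.id, p.id) <= t)
        ratio = fac.capacity / pop if pop > 0 else math.inf
        if ratio <= cfg.fprt1:
            return t, ratio, False
    pop = sum(p.population for p in populations if od.time(fac.id, p.id) <= cfg.t_max)
    return cfg.t_max, (fac.capacity / pop if pop > 0 else math.inf), True


def oracle_population_catchment(pop_site, fprs, od, cfg):
    for t in oracle_grid(cfg.t0, cfg.dt, cfg.t_max):
        total = sum(v for fid, v in fprs if od.time(fid, pop_site.id) <= t)
        if total >= cfg.fprt2:
            return t, False
    return cfg.t_max, True


def oracle_run_ev2sfca(facilities, populations, od, cfg):
    """Materialize all four steps from scratch; returns (Ci, Cj, Di, Aj) dicts."""
    from catchaccess.decay import make_decay

    w = make_decay(cfg.decay)
    ci, fpr = {}, {}
    for f in facilities:
        c, r, _ = oracle_facility_catchment(f, populations, od, cfg)
        ci[f.id], fpr[f.id] = c, r
    cj = {}
    for p in populations:
        cj[p.id], _ = oracle_population_catchment(p, list(fpr.items()), od, cfg)

    def weight(d, a, b, side):
        if cfg.weight_param == "symmetric_min":
            return w(d, min(a, b))
        return w(d, a if side == "fac" else b)

    def eligible(f, p):
        d = od.time(f.id, p.id)
        if math.isinf(d):
            return None
        if cfg.constraint_mode == "mutual":
            ok = d <= ci[f.id] and d <= cj[p.id]
        elif cfg.constraint_mode == "facility_side":
            ok = d <= ci[f.id]
        else:
            ok = d <= cj[p.id]
        return d if ok else None

    di = {}
    for f in facilities:
        denom = 0.0
        for p in populations:
            d = eligible(f, p)
            if d is not None:
                denom += p.population * weight(d, ci[f.id], cj[p.id], "fac")
        di[f.id] = f.capacity / denom if denom > 0 else 0.0
    aj = {}
    for p in populations:
        total = 0.0
        for f in facilities:
            d = eligible(f, p)
            if d is not None:
                total += di[f.id] * weight(d, ci[f.id], cj[p.id], "pop")
        aj[p.id] = total
    return ci, cj, di, aj
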