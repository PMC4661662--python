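"""Dynamic catchment-size determination (Steps 1-2 of both FCA variants).

Two search rules are implemented over the common travel-time grid
``t0, t0+dt, ..., t_max``:

* EV2SFCA — the facility catchment grows until the facility-to-population
  ratio (FPR = capacity / reachable population) drops to the threshold
  FPRT1; the population catchment grows until the summed facility FPRs
  reach FPRT2.  The facility rule is capacity-aware: a big facility keeps
  expanding until it has gathered enough demand to dilute its ratio.
* V2SFCA baseline — the supply catchment grows until a fixed base
  population BP is reached (capacity plays no role); the demand catchment
  grows until the summed supply ratios reach the provider-to-population
  target PPR.

All sums in this module are unweighted: distance decay enters only in the
scoring steps.  Searches that never meet their threshold stop at ``t_max``
with ``capped=True``; the site is kept, not dropped.  Threshold comparisons
are inclusive by default (stop at FPR <= FPRT1, at sum >= FPRT2/PPR, at
population >= BP); set ``strict_thresholds`` on the config for strict
inequalities.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Literal, Sequence

from .core import (
    SENTINEL_INF,
    CatchmentRecord,
    CatchmentTable,
    EVConfig,
    FacilitySite,
    ODMatrix,
    PopulationSite,
    V2Config,
    time_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "facility_fpr",
    "facility_catchment",
    "population_catchment",
    "v2sfca_supply_catchment",
    "v2sfca_demand_catchment",
    "compute_all_catchments",
]


def _reachable_population(
    facility: FacilitySite,
    populations: Sequence[PopulationSite],
    od: ODMatrix,
    t: float,
) -> float:
    return sum(
        p.population for p in populations if od.time(facility.id, p.id) <= t
    )


def facility_fpr(
    facility: FacilitySite,
    populations: Sequence[PopulationSite],
    od: ODMatrix,
    t: float,
) -> float:
    """Facility-to-population ratio ``S_i / sum(P_j : d_ji <= t)``.

    Returns ``SENTINEL_INF`` (an empty-window sentinel that can never
    satisfy the stopping rule) when no population is reachable within
    ``t`` minutes.
    """
    pop = _reachable_population(facility, populations, od, t)
    if pop <= 0:
        return SENTINEL_INF
    return facility.capacity / pop


def _met_le(value: float, threshold: float, strict: bool) -> bool:
    return value < threshold if strict else value <= threshold


def _met_ge(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def facility_catchment(
    facility: FacilitySite,
    populations: Sequence[PopulationSite],
    od: ODMatrix,
    cfg: EVConfig,
) -> CatchmentRecord:
    """EV2SFCA Step 1: smallest grid t with FPR(t) at or below FPRT1.

    The saved ratio is the FPR at the returned catchment; at the cap it may
    be ``SENTINEL_INF`` (no reachable population at all).
    """
    last = None
    for t in time_grid(cfg.t0, cfg.dt, cfg.t_max):
        ratio = facility_fpr(facility, populations, od, t)
        if _met_le(ratio, cfg.fprt1, cfg.strict_thresholds):
            return CatchmentRecord(catchment=t, fpr=ratio, capped=False)
        last = ratio
    if last is not None and math.isinf(last):
        logger.warning(
            "facility %s: no reachable population within %.0f min", facility.id, cfg.t_max
        )
    return CatchmentRecord(
        catchment=cfg.t_max,
        fpr=facility_fpr(facility, populations, od, cfg.t_max),
        capped=True,
    )


def population_catchment(
    population: PopulationSite,
    facility_fprs: Iterable[tuple[str, float]],
    od: ODMatrix,
    cfg: EVConfig,
) -> CatchmentRecord:
    """EV2SFCA Step 2: smallest grid t with the summed facility FPRs at or
    above FPRT2.

    ``facility_fprs`` holds the Step-1 ``(facility_id, FPR_i)`` pairs; an
    infinite summand (a facility that never found demand) satisfies the
    threshold as soon as it enters the window — degenerate, logged.
    """
    fprs = list(facility_fprs)
    for t in time_grid(cfg.t0, cfg.dt, cfg.t_max):
        total = 0.0
        for fid, fpr in fprs:
            if od.time(fid, population.id) <= t:
                total += fpr
        if math.isinf(total):
            logger.warning(
                "population %s: infinite facility FPR inside window at t=%g",
                population.id,
                t,
            )
        if _met_ge(total, cfg.fprt2, cfg.strict_thresholds):
            return CatchmentRecord(catchment=t, fpr=math.nan, capped=False)
    return CatchmentRecord(catchment=cfg.t_max, fpr=math.nan, capped=True)


def v2sfca_supply_catchment(
    facility: FacilitySite,
    populations: Sequence[PopulationSite],
    od: ODMatrix,
    cfg: V2Config,
) -> CatchmentRecord:
    """V2SFCA supply side: smallest grid t reaching the base population BP.

    The saved ratio is ``S_i`` over the reachable population at the
    returned catchment.  Capacity never influences the catchment size —
    the behaviour the enhanced method was designed to fix.
    """
    for t in time_grid(cfg.t0, cfg.dt, cfg.t_max):
        pop = _reachable_population(facility, populations, od, t)
        if _met_ge(pop, cfg.base_population, cfg.strict_thresholds):
            return CatchmentRecord(catchment=t, fpr=facility.capacity / pop, capped=False)
    pop = _reachable_population(facility, populations, od, cfg.t_max)
    ratio = facility.capacity / pop if pop > 0 else SENTINEL_INF
    return CatchmentRecord(catchment=cfg.t_max, fpr=ratio, capped=True)


def v2sfca_demand_catchment(
    population: PopulationSite,
    supply_ratios: Iterable[tuple[str, float]],
    od: ODMatrix,
    cfg: V2Config,
) -> CatchmentRecord:
    """V2SFCA demand side: smallest grid t with summed supply ratios >= PPR."""
    ratios = list(supply_ratios)
    for t in time_grid(cfg.t0, cfg.dt, cfg.t_max):
        total = sum(r for fid, r in ratios if od.time(fid, population.id) <= t)
        if _met_ge(total, cfg.ppr, cfg.strict_thresholds):
            return CatchmentRecord(catchment=t, fpr=math.nan, capped=False)
    return CatchmentRecord(catchment=cfg.t_max, fpr=math.nan, capped=True)


def _check_ids(
    facilities: Sequence[FacilitySite],
    populations: Sequence[PopulationSite],
    od: ODMatrix,
) -> None:
    fids = {f.id for f in facilities}
    pids = {p.id for p in populations}
    unknown_f = od.facility_ids() - fids
    unknown_p = od.population_ids() - pids
    if unknown_f or unknown_p:
        raise ValueError(
            "OD matrix references unknown ids: "
            f"facilities {sorted(unknown_f)}, populations {sorted(unknown_p)}"
        )


def compute_all_catchments(
    facilities: Sequence[FacilitySite],
    populations: Sequence[PopulationSite],
    od: ODMatrix,
    cfg: EVConfig | V2Config,
    method: Literal["ev2sfca", "v2sfca"] = "ev2sfca",
) -> CatchmentTable:
    """Steps 1-2 for every site; one row per site, ids processed in sorted
    order so outputs are bit-reproducible."""
    _check_ids(facilities, populations, od)
    facilities = sorted(facilities, key=lambda f: f.id)
    populations = sorted(populations, key=lambda p: p.id)
    table = CatchmentTable()
    if method == "ev2sfca":
        assert isinstance(cfg, EVConfig)
        for f in facilities:
            table.facility[f.id] = facility_catchment(f, populations, od, cfg)
        fprs = [(fid, rec.fpr) for fid, rec in table.facility.items()]
        for p in populations:
            table.population[p.id] = population_catchment(p, fprs, od, cfg)
    elif method == "v2sfca":
        assert isinstance(cfg, V2Config)
        for f in facilities:
            table.facility[f.id] = v2sfca_supply_catchment(f, populations, od, cfg)
        ratios = [(fid, rec.fpr) for fid, rec in table.facility.items()]
        for p in populations:
            table.population[p.id] = v2sfca_demand_catchment(p, ratios, od, cfg)
    else:
        raise ValueError(f"unknown method {method!r}")
    return table
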