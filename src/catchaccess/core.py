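"""Domain types, configuration, and tabular I/O shared by all pipeline stages.

The package measures spatial accessibility of a population to
capacity-limited facilities (e.g., residential care facilities with a fixed
number of beds) with floating catchment area (FCA) methods.  Everything
downstream is driven by three inputs: facility points with capacities
``S_i``, population points with counts ``P_j``, and an origin-destination
(OD) matrix of pairwise travel times in minutes.

Coordinates are projected planar meters throughout; the algorithms
themselves only ever consume travel times, so no geographic math happens
here.  Pairs whose travel time exceeds the cap ``t_max`` are treated as
unreachable and excluded from every sum and every eligibility set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SENTINEL_INF",
    "UNREACHABLE",
    "FacilitySite",
    "PopulationSite",
    "ODMatrix",
    "DecaySpec",
    "EVConfig",
    "V2Config",
    "CatchmentRecord",
    "CatchmentTable",
    "AccessibilityResult",
    "read_sites",
    "read_od",
    "write_od",
    "write_catchments",
    "write_accessibility",
    "load_config",
    "time_grid",
]

#: Sentinel for a facility-to-population ratio over an empty window
#: (capacity divided by zero reachable population).
SENTINEL_INF = math.inf

#: Sentinel for an OD pair with no connection within ``t_max``.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class FacilitySite:
    """A supply point with bed capacity ``S_i``."""

    id: str
    x: float
    y: float
    capacity: float

    def __post_init__(self) -> None:
        if not self.capacity > 0:
            raise ValueError(
                f"facility {self.id!r}: capacity must be > 0, got {self.capacity}"
            )


@dataclass(frozen=True)
class PopulationSite:
    """A demand point with population count ``P_j``."""

    id: str
    x: float
    y: float
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(
                f"population {self.id!r}: population must be >= 0, "
                f"got {self.population}"
            )


class ODMatrix:
    """Sparse facility x population travel-time matrix in minutes.

    One undirected time per pair (``d_ji = d_ij``); absent pairs are
    unreachable.  Entries above ``t_max`` are dropped on insertion, which
    enforces the travel-time cap uniformly at the data boundary.
    """

    def __init__(self, t_max: float = 120.0) -> None:
        if not t_max > 0:
            raise ValueError(f"t_max must be > 0, got {t_max}")
        self.t_max = float(t_max)
        self._times: dict[tuple[str, str], float] = {}
        self._by_facility: dict[str, list[tuple[str, float]]] | None = None
        self._by_population: dict[str, list[tuple[str, float]]] | None = None

    def set_time(self, facility_id: str, population_id: str, minutes: float) -> None:
        if minutes < 0:
            raise ValueError(
                f"negative travel time {minutes} for pair "
                f"({facility_id!r}, {population_id!r})"
            )
        if minutes > self.t_max or math.isinf(minutes):
            self._times.pop((facility_id, population_id), None)
        else:
            self._times[(facility_id, population_id)] = float(minutes)
        self._by_facility = None
        self._by_population = None

    def time(self, facility_id: str, population_id: str) -> float:
        """Travel time in minutes, or ``UNREACHABLE`` if absent/over cap."""
        return self._times.get((facility_id, population_id), UNREACHABLE)

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """All reachable ``(facility_id, population_id, minutes)`` triples."""
        for (fid, pid), d in sorted(self._times.items()):
            yield fid, pid, d

    def __len__(self) -> int:
        return len(self._times)

    def _index(self) -> None:
        by_f: dict[str, list[tuple[str, float]]] = {}
        by_p: dict[str, list[tuple[str, float]]] = {}
        for (fid, pid), d in self._times.items():
            by_f.setdefault(fid, []).append((pid, d))
            by_p.setdefault(pid, []).append((fid, d))
        for lst in by_f.values():
            lst.sort(key=lambda t: (t[1], t[0]))
        for lst in by_p.values():
            lst.sort(key=lambda t: (t[1], t[0]))
        self._by_facility = by_f
        self._by_population = by_p

    def facility_neighbors(self, facility_id: str) -> list[tuple[str, float]]:
        """Reachable populations of a facility as ``(pid, minutes)``, nearest first."""
        if self._by_facility is None:
            self._index()
        assert self._by_facility is not None
        return self._by_facility.get(facility_id, [])

    def population_neighbors(self, population_id: str) -> list[tuple[str, float]]:
        """Reachable facilities of a population as ``(fid, minutes)``, nearest first."""
        if self._by_population is None:
            self._index()
        assert self._by_population is not None
        return self._by_population.get(population_id, [])

    def facility_ids(self) -> set[str]:
        return {fid for fid, _ in self._times}

    def population_ids(self) -> set[str]:
        return {pid for _, pid in self._times}


@dataclass(frozen=True)
class DecaySpec:
    """Distance-decay specification.

    family
        ``gaussian`` — catchment-normalized truncated Gaussian (1 at the
        origin, 0 at the catchment edge), shape exponent ``beta``;
        ``gaussian_raw`` — un-normalized ``exp(-d^2/beta)`` truncated at the
        catchment edge (provided for experimentation);
        ``stepwise`` — equal-width travel-time zones with fixed weights;
        ``none`` — weight 1 inside the catchment.
    beta
        Shape parameter of the Gaussian families, > 0; default 1.
    zone_weights
        Strictly decreasing per-zone weights for the stepwise family,
        first weight 1.0; default (1.00, 0.42, 0.03).
    """

    family: Literal["gaussian", "gaussian_raw", "stepwise", "none"] = "gaussian"
    beta: float = 1.0
    zone_weights: tuple[float, ...] = (1.00, 0.42, 0.03)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gaussian_raw", "stepwise", "none"):
            raise ValueError(f"unknown decay family {self.family!r}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not self.zone_weights:
            raise ValueError("zone_weights must be non-empty")
        if self.family == "stepwise":
            if abs(self.zone_weights[0] - 1.0) > 1e-12:
                raise ValueError("first zone weight must be 1.0")
            if any(
                b >= a for a, b in zip(self.zone_weights, self.zone_weights[1:])
            ):
                raise ValueError("zone_weights must be strictly decreasing")


@dataclass(frozen=True)
class EVConfig:
    """Run parameters for the enhanced-variable 2SFCA (EV2SFCA) method.

    Defaults reproduce the published elder-care study configuration:
    t0=5 min, dt=1 min, t_max=120 min, FPRT1=135/50,000, FPRT2=30/1000,
    continuous Gaussian decay with beta=1, mutual catchment containment.
    """

    t0: float = 5.0
    dt: float = 1.0
    t_max: float = 120.0
    fprt1: float = 135.0 / 50_000.0
    fprt2: float = 30.0 / 1000.0
    decay: DecaySpec = field(default_factory=lambda: DecaySpec(family="gaussian"))
    constraint_mode: Literal["mutual", "facility_side", "population_side"] = "mutual"
    weight_param: Literal["own_catchment", "symmetric_min"] = "own_catchment"
    strict_thresholds: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.t0 <= self.t_max:
            raise ValueError(f"need 0 < t0 <= t_max, got t0={self.t0}, t_max={self.t_max}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.fprt1 > 0 or not self.fprt2 > 0:
            raise ValueError("FPRT1 and FPRT2 must be > 0")
        if self.constraint_mode not in ("mutual", "facility_side", "population_side"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")
        if self.weight_param not in ("own_catchment", "symmetric_min"):
            raise ValueError(f"unknown weight_param {self.weight_param!r}")


@dataclass(frozen=True)
class V2Config:
    """Run parameters for the variable-catchment 2SFCA (V2SFCA) baseline.

    Supply catchments grow until a base population BP is reached; demand
    catchments grow until the summed supply ratio reaches the
    provider-to-population target PPR.  Defaults: BP=50,000, PPR=30/1000,
    stepwise decay (the scheme the baseline is conventionally run with).
    """

    base_population: float = 50_000.0
    ppr: float = 30.0 / 1000.0
    t0: float = 5.0
    dt: float = 1.0
    t_max: float = 120.0
    decay: DecaySpec = field(default_factory=lambda: DecaySpec(family="stepwise"))
    strict_thresholds: bool = False

    def __post_init__(self) -> None:
        if not self.base_population > 0:
            raise ValueError("base_population must be > 0")
        if not self.ppr > 0:
            raise ValueError("ppr must be > 0")
        if not 0 < self.t0 <= self.t_max:
            raise ValueError(f"need 0 < t0 <= t_max, got t0={self.t0}, t_max={self.t_max}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class CatchmentRecord:
    """One site's catchment: size in minutes, saved ratio, cap flag."""

    catchment: float
    fpr: float  # facility FPR_i or V2SFCA supply ratio R_i; NaN for populations
    capped: bool


@dataclass
class CatchmentTable:
    """Per-facility and per-population catchment sizes (minutes)."""

    facility: dict[str, CatchmentRecord] = field(default_factory=dict)
    population: dict[str, CatchmentRecord] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.facility):
            rec = self.facility[sid]
            rows.append(
                {"id": sid, "type": "facility", "catchment_min": rec.catchment,
                 "fpr": rec.fpr, "capped": rec.capped}
            )
        for sid in sorted(self.population):
            rec = self.population[sid]
            rows.append(
                {"id": sid, "type": "population", "catchment_min": rec.catchment,
                 "fpr": rec.fpr, "capped": rec.capped}
            )
        return pd.DataFrame(
            rows, columns=["id", "type", "catchment_min", "fpr", "capped"]
        )


@dataclass
class AccessibilityResult:
    """Outcome of a full FCA run.

    ``facility_dfpr`` maps facility id to the discounted supply-to-demand
    ratio ``D_i`` (beds per person); ``accessibility`` maps population id to
    the accessibility score ``A_j`` (beds per person).
    """

    facility_dfpr: dict[str, float]
    accessibility: dict[str, float]
    catchments: CatchmentTable
    config: EVConfig | V2Config
    method: str
    rejection_counts: dict[str, int] = field(default_factory=dict)


def time_grid(t0: float, dt: float, t_max: float) -> Iterator[float]:
    """Search grid ``t0, t0+dt, ...`` truncated at ``t_max`` (inclusive)."""
    k = 0
    while True:
        t = t0 + k * dt
        if t > t_max + 1e-9:
            return
        yield min(t, t_max)
        k += 1


# ---------------------------------------------------------------------------
# I/O


def _records_from_frame(df: pd.DataFrame, kind: str, source: str):
    value_col = "capacity" if kind == "facility" else "population"
    for col in ("id", "x", "y", value_col):
        if col not in df.columns:
            raise ValueError(f"{source}: missing required column {col!r}")
    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{source}: duplicate id {dup.iloc[0]!r}")
    cls = FacilitySite if kind == "facility" else PopulationSite
    sites = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sites.append(
                cls(
                    id=str(getattr(row, "id")),
                    x=float(getattr(row, "x")),
                    y=float(getattr(row, "y")),
                    **{value_col: float(getattr(row, value_col))},
                )
            )
        except ValueError as exc:
            raise ValueError(f"{source}: row {row_no}: {exc}") from exc
    return sites


def read_sites(path: str | Path, kind: Literal["facility", "population"]):
    """Read facility or population points from CSV or GeoJSON.

    CSV needs columns ``id,x,y,capacity`` (facilities) or
    ``id,x,y,population``.  GeoJSON must be a Point FeatureCollection with
    the same names as feature properties (``id`` may sit at the feature
    level).  Row order is preserved; duplicate ids and negative counts are
    hard errors.
    """
    if kind not in ("facility", "population"):
        raise ValueError(f"kind must be 'facility' or 'population', got {kind!r}")
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _geojson_to_frame(path, kind)
    else:
        df = pd.read_csv(path, dtype={"id": str})
    return _records_from_frame(df, kind, str(path))


def _geojson_to_frame(path: Path, kind: str) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    value_col = "capacity" if kind == "facility" else "population"
    rows = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: only Point geometries are supported")
        props = feat.get("properties") or {}
        fid = props.get("id", feat.get("id"))
        if fid is None:
            raise ValueError(f"{path}: feature without an 'id'")
        x, y = geom["coordinates"][:2]
        rows.append({"id": str(fid), "x": x, "y": y, value_col: props.get(value_col)})
    return pd.DataFrame(rows, columns=["id", "x", "y", value_col])


def read_od(
    path: str | Path,
    t_max: float = 120.0,
    facility_ids: Iterable[str] | None = None,
    population_ids: Iterable[str] | None = None,
) -> ODMatrix:
    """Read a long-format OD CSV (``facility_id,population_id,minutes``).

    Entries above ``t_max`` become unreachable.  If id universes are given,
    rows referencing unknown ids are hard errors.
    """
    df = pd.read_csv(path, dtype={"facility_id": str, "population_id": str})
    for col in ("facility_id", "population_id", "minutes"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    fset = set(facility_ids) if facility_ids is not None else None
    pset = set(population_ids) if population_ids is not None else None
    od = ODMatrix(t_max=t_max)
    for row in df.itertuples(index=False):
        minutes = float(row.minutes)
        if minutes < 0:
            raise ValueError(
                f"{path}: negative travel time {minutes} for pair "
                f"({row.facility_id!r}, {row.population_id!r})"
            )
        if fset is not None and row.facility_id not in fset:
            raise ValueError(f"{path}: unknown facility id {row.facility_id!r}")
        if pset is not None and row.population_id not in pset:
            raise ValueError(f"{path}: unknown population id {row.population_id!r}")
        od.set_time(row.facility_id, row.population_id, minutes)
    return od


def write_od(od: ODMatrix, path: str | Path) -> None:
    """Write the reachable entries of an OD matrix as long-format CSV."""
    df = pd.DataFrame(
        list(od.pairs()), columns=["facility_id", "population_id", "minutes"]
    )
    df.to_csv(path, index=False)


def write_catchments(table: CatchmentTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.10g")


def write_accessibility(result: AccessibilityResult, prefix: str | Path) -> None:
    """Write ``<prefix>accessibility.csv`` and ``<prefix>facility_dfpr.csv``."""
    prefix = str(prefix)
    pd.DataFrame(
        sorted(result.accessibility.items()),
        columns=["population_id", "accessibility"],
    ).to_csv(prefix + "accessibility.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        sorted(result.facility_dfpr.items()),
        columns=["facility_id", "discounted_fpr"],
    ).to_csv(prefix + "facility_dfpr.csv", index=False, float_format="%.10g")


def _decay_from_mapping(m: Mapping) -> DecaySpec:
    kwargs: dict = {}
    if "family" in m:
        kwargs["family"] = m["family"]
    if "beta" in m:
        kwargs["beta"] = float(m["beta"])
    if "zone_weights" in m:
        kwargs["zone_weights"] = tuple(float(w) for w in m["zone_weights"])
    return DecaySpec(**kwargs)


def load_config(path: str | Path, method: Literal["ev2sfca", "v2sfca"] = "ev2sfca"):
    """Load an :class:`EVConfig` or :class:`V2Config` from YAML/JSON.

    Keys mirror the dataclass field names; ``decay`` is a nested mapping
    with ``family``, ``beta``, ``zone_weights``.  Missing keys keep the
    published defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    raw = dict(raw)
    decay = raw.pop("decay", None)
    cls = EVConfig if method == "ev2sfca" else V2Config
    allowed = set(cls.__dataclass_fields__) - {"decay"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = cls(**{k: v for k, v in raw.items()})
    if decay is not None:
        cfg = replace(cfg, decay=_decay_from_mapping(decay))
    return cfg
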