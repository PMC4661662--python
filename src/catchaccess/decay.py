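"""Distance-decay weight functions.

A decay function maps a travel time ``d`` (minutes) and a catchment size
``C`` (minutes) to a weight in [0, 1] that discounts interaction between a
facility and a population location.  Every family returns 0 strictly beyond
the catchment edge, so decay also enforces the catchment boundary.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

from .core import DecaySpec

__all__ = ["gaussian_weight", "raw_gaussian_weight", "stepwise_weight", "make_decay"]

_EDGE = math.exp(-0.5)  # value of exp(-d^2/2C^2) at d = C


def gaussian_weight(d: float, C: float, beta: float = 1.0) -> float:
    """Catchment-normalized truncated Gaussian weight.

    ``w = [(exp(-d^2 / 2C^2) - exp(-1/2)) / (1 - exp(-1/2))]^beta`` for
    ``d <= C`` and 0 beyond.  The normalization pins w(0)=1 and w(C)=0, so
    the weight is continuous across the catchment edge regardless of the
    catchment size; ``beta`` sharpens (``>1``) or flattens (``<1``) the
    interior profile.
    """
    if not C > 0:
        raise ValueError(f"catchment must be > 0, got {C}")
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if d < 0:
        raise ValueError(f"travel time must be >= 0, got {d}")
    if d > C:
        return 0.0
    core = (math.exp(-(d * d) / (2.0 * C * C)) - _EDGE) / (1.0 - _EDGE)
    return core**beta


def raw_gaussian_weight(d: float, C: float, beta: float = 1.0) -> float:
    """Un-normalized Gaussian ``exp(-d^2/beta)`` truncated at the edge.

    Discontinuous at ``d = C``; kept behind the same contract for
    experimentation with alternative decay literatures where ``beta`` is an
    impedance parameter on squared minutes.
    """
    if not C > 0:
        raise ValueError(f"catchment must be > 0, got {C}")
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if d < 0:
        raise ValueError(f"travel time must be >= 0, got {d}")
    if d > C:
        return 0.0
    return math.exp(-(d * d) / beta)


def stepwise_weight(
    d: float, C: float, zone_weights: Sequence[float] = (1.00, 0.42, 0.03)
) -> float:
    """Stepwise zone weight over K equal-width travel-time zones.

    The catchment is split into ``K = len(zone_weights)`` zones of width
    ``C/K``; zone 1 is ``[0, C/K]`` and later zones are half-open
    ``(lo, hi]``, so a boundary time belongs to the inner zone.  E.g., with
    a 45-min catchment and weights (1.00, 0.42, 0.03): zone 1 is within
    15 min, zone 2 from 15 to 30 min, zone 3 from 30 to 45 min.
    """
    if not zone_weights:
        raise ValueError("zone_weights must be non-empty")
    if not C > 0:
        raise ValueError(f"catchment must be > 0, got {C}")
    if d < 0:
        raise ValueError(f"travel time must be >= 0, got {d}")
    if d > C:
        return 0.0
    K = len(zone_weights)
    width = C / K
    # zone index such that d in (k*width, (k+1)*width]; d=0 falls in zone 0
    k = max(0, math.ceil(d / width - 1e-12) - 1)
    return float(zone_weights[min(k, K - 1)])


def make_decay(spec: DecaySpec) -> Callable[[float, float], float]:
    """Build a ``(d, C) -> weight`` function from a :class:`DecaySpec`."""
    if spec.family == "gaussian":
        beta = spec.beta
        return lambda d, C: gaussian_weight(d, C, beta)
    if spec.family == "gaussian_raw":
        beta = spec.beta
        return lambda d, C: raw_gaussian_weight(d, C, beta)
    if spec.family == "stepwise":
        weights = spec.zone_weights
        return lambda d, C: stepwise_weight(d, C, weights)
    if spec.family == "none":
        return lambda d, C: 1.0 if 0 <= d <= C else 0.0
    raise ValueError(f"unknown decay family {spec.family!r}")
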