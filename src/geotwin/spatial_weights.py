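"""Inverse-distance weights linking twin pairs to map target locations.

Every pair contributes to the estimate at every target location with weight
w_i(x) = 1 / d(x, x_i)^p, where d is Euclidean distance in projected planar
coordinates and p (default 0.5) controls the rate of drop-off.  Distances
are floored at d_floor so coincident pair/target locations yield a large but
finite weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import GEOGRAPHIC_CRS, CohortData, TwinPairRecord, _kish_ess

__all__ = [
    "TargetLocation",
    "WeightSet",
    "pair_weight",
    "weight_matrix",
    "effective_sample_size",
    "DEFAULT_P",
    "DEFAULT_D_FLOOR",
]

DEFAULT_P = 0.5
DEFAULT_D_FLOOR = 1e-6


@dataclass(frozen=True)
class TargetLocation:
    """A location at which the weighted model is estimated and mapped."""

    target_id: str
    x: float
    y: float
    source: str = "user"  # region_centroid | density_representative | user

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"target {self.target_id!r}: non-finite coordinates")
        if self.source not in ("region_centroid", "density_representative", "user"):
            raise ValueError(f"target {self.target_id!r}: unknown source {self.source!r}")


@dataclass
class WeightSet:
    """Per-pair weights for one target, aligned to cohort order."""

    target_id: str
    weights: np.ndarray
    p: float
    ess_mz: float
    ess_dz: float


def pair_weight(target: TargetLocation, pair_xy: Sequence[float],
                p: float = DEFAULT_P, d_floor: float = DEFAULT_D_FLOOR) -> float:
    """Inverse-power-distance weight of one pair at one target."""
    if p < 0:
        raise ValueError("power parameter p must be >= 0")
    if d_floor <= 0:
        raise ValueError("d_floor must be > 0")
    xy = np.asarray(pair_xy, dtype=float)
    if xy.shape != (2,) or not np.all(np.isfinite(xy)):
        raise ValueError("pair coordinates must be two finite numbers")
    d = float(np.hypot(xy[0] - target.x, xy[1] - target.y))
    return float(max(d, d_floor) ** -p)


def _check_projected(pairs: Sequence[TwinPairRecord]) -> None:
    for rec in pairs:
        if rec.crs is not None and rec.crs in GEOGRAPHIC_CRS:
            raise ValueError(
                f"pair {rec.pair_id!r} has geographic (degree) coordinates "
                f"({rec.crs}); project to a planar CRS before weighting"
            )


def weight_matrix(targets: Sequence[TargetLocation],
                  pairs: Sequence[TwinPairRecord] | CohortData,
                  p: float = DEFAULT_P,
                  d_floor: float = DEFAULT_D_FLOOR) -> list[WeightSet]:
    """One WeightSet per target; every pair gets a strictly positive weight."""
    data = CohortData.from_pairs(pairs)
    _check_projected(data.pairs)
    if p < 0:
        raise ValueError("power parameter p must be >= 0")
    if d_floor <= 0:
        raise ValueError("d_floor must be > 0")
    out = []
    for t in targets:
        d = np.hypot(data.xy[:, 0] - t.x, data.xy[:, 1] - t.y)
        w = np.maximum(d, d_floor) ** -p
        out.append(WeightSet(
            target_id=t.target_id,
            weights=w,
            p=p,
            ess_mz=_kish_ess(w[data.is_mz]),
            ess_dz=_kish_ess(w[data.is_dz]),
        ))
    return out


def effective_sample_size(weights: Sequence[float]) -> float:
    """Kish effective sample size (sum w)^2 / sum(w^2).

    Equals n for equal weights and 1 when a single weight carries all the
    mass; invariant to rescaling all weights by a positive constant.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    if np.all(w == 0):
        raise ValueError("all weights are zero")
    return _kish_ess(w)
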