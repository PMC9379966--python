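"""Orchestration of the geographically weighted twin analysis.

For each target location the engine computes inverse-distance weights over
the whole cohort, maximizes the weighted FIML twin model there, and collects
raw and proportional variance components, confidence intervals, effective
sample sizes and the distance-weighted mean trait into one table ready for
mapping.  Per-target computations are pure functions of (cohort, target,
config): results do not depend on target order and may be computed in any
order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (CohortData, FitConfig, FitResult, ModelSpec,
                         TwinPairRecord, fit_model)
from .spatial_weights import (DEFAULT_D_FLOOR, DEFAULT_P, TargetLocation,
                              weight_matrix)

__all__ = [
    "SpaceConfig",
    "SpaceResult",
    "SensitivityResult",
    "standardize_phenotype",
    "region_centroid_targets",
    "density_representative_targets",
    "run_space",
    "weighted_mean_map",
    "location_sensitivity",
]

logger = logging.getLogger(__name__)

#: Column order of the per-target result table.
RESULT_COLUMNS = [
    "target_id", "x", "y",
    "a2_raw", "c2_or_d2_raw", "e2_raw",
    "a2_std", "c2_or_d2_std", "e2_std",
    "total_variance",
    "a2_lo", "a2_hi", "c2_or_d2_lo", "c2_or_d2_hi", "e2_lo", "e2_hi",
    "ess_mz", "ess_dz", "converged", "weighted_mean_trait",
]


@dataclass(frozen=True)
class SpaceConfig:
    """Knobs for a spatial analysis run."""

    p: float = DEFAULT_P
    d_floor: float = DEFAULT_D_FLOOR
    compute_ci: bool = True
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class SpaceResult:
    """Per-target fit results over all target locations, ready for mapping."""

    table: pd.DataFrame
    spec: ModelSpec
    config: SpaceConfig
    population_fit: FitResult

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_geojson(self, path) -> None:
        features = []
        for row in self.table.to_dict("records"):
            props = {k: v for k, v in row.items() if k not in ("x", "y")}
            props["converged"] = bool(props["converged"])
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [row["x"], row["y"]]},
                "properties": props,
            })
        doc = {"type": "FeatureCollection", "features": features}
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def read_csv(cls, path) -> "SpaceResult":
        """Load a bare result table (spec/config/population fit not restored)."""
        table = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in RESULT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"result table is missing columns: {missing}")
        return cls(table=table, spec=ModelSpec(), config=SpaceConfig(),
                   population_fit=None)  # type: ignore[arg-type]


@dataclass
class SensitivityResult:
    """Per-snapshot spatial results plus cross-snapshot a2 map correlations."""

    results: list[tuple[str, SpaceResult]]
    a2_correlation: pd.DataFrame  # label x label Pearson correlation of a2_raw


# ---------------------------------------------------------------------------
# Phenotype standardization and target construction
# ---------------------------------------------------------------------------

def standardize_phenotype(pairs: Sequence[TwinPairRecord]) -> list[TwinPairRecord]:
    """Scale phenotypes to population mean 0, SD 1 (population-SD convention).

    The pooled moments are taken over every observed twin score; missing
    cells stay missing.
    """
    obs = [v for p in pairs for v in (p.y1, p.y2) if v is not None]
    if len(set(obs)) < 2:
        raise ValueError("phenotype is constant; cannot standardize")
    arr = np.asarray(obs, dtype=float)
    mu = float(arr.mean())
    sd = float(arr.std())  # population SD (ddof=0)

    def z(v: Optional[float]) -> Optional[float]:
        return None if v is None else (v - mu) / sd

    return [replace(p, y1=z(p.y1), y2=z(p.y2)) for p in pairs]


def region_centroid_targets(pairs: Sequence[TwinPairRecord],
                            centroid_table: pd.DataFrame) -> list[TargetLocation]:
    """One target per unique region that contains at least one pair.

    ``centroid_table`` must have columns region_id, x, y covering every
    region id present in the cohort.
    """
    for col in ("region_id", "x", "y"):
        if col not in centroid_table.columns:
            raise ValueError(f"centroid table lacks column {col!r}")
    lookup = {str(r.region_id): (float(r.x), float(r.y))
              for r in centroid_table.itertuples()}
    seen: dict[str, tuple[float, float]] = {}
    for p in pairs:
        if p.region_id is None:
            raise ValueError(f"pair {p.pair_id!r} has no region_id")
        rid = str(p.region_id)
        if rid in seen:
            continue
        if rid not in lookup:
            raise ValueError(f"region_id {rid!r} not found in centroid table")
        seen[rid] = lookup[rid]
    return [TargetLocation(rid, x, y, source="region_centroid")
            for rid, (x, y) in sorted(seen.items())]


def density_representative_targets(pair_coordinates: np.ndarray | Sequence[TwinPairRecord],
                                   k: int, seed: int = 0) -> list[TargetLocation]:
    """k seeded k-means centroids of the pair coordinates.

    Mirrors how targets can be placed to reflect population density without
    disclosing any participant's exact location.
    """
    from sklearn.cluster import KMeans

    if k <= 0:
        raise ValueError("k must be positive")
    if len(pair_coordinates) and isinstance(pair_coordinates[0], TwinPairRecord):
        coords = np.array([[p.x, p.y] for p in pair_coordinates])
    else:
        coords = np.asarray(pair_coordinates, dtype=float)
    if k > len(coords):
        raise ValueError(f"k={k} exceeds the number of pairs ({len(coords)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(coords)
    centers = km.cluster_centers_
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    width = len(str(k))
    return [TargetLocation(f"T{i:0{width}d}", float(centers[j, 0]),
                           float(centers[j, 1]), source="density_representative")
            for i, j in enumerate(order)]


# ---------------------------------------------------------------------------
# The spatial run
# ---------------------------------------------------------------------------

def _weighted_trait_mean(data: CohortData, w: np.ndarray) -> float:
    """Distance-weighted mean of per-pair mean observed scores."""
    with np.errstate(invalid="ignore"):
        pair_mean = np.nanmean(np.column_stack([data.y1, data.y2]), axis=1)
    return float(np.sum(w * pair_mean) / np.sum(w))


def run_space(pairs: Sequence[TwinPairRecord] | CohortData,
              targets: Sequence[TargetLocation],
              spec: ModelSpec | None = None,
              config: SpaceConfig | None = None) -> SpaceResult:
    """Fit the weighted twin model at every target location.

    Every pair contributes at every target (weights strictly positive); the
    target set only chooses where results are reported.  Non-convergent
    locations are flagged in the ``converged`` column, never dropped.
    """
    spec = spec or ModelSpec()
    config = config or SpaceConfig()
    data = CohortData.from_pairs(pairs)
    if len(targets) == 0:
        raise ValueError("no target locations")

    pop_cfg = replace(config.fit, compute_ci=False, start=None)
    population_fit = fit_model(data, None, spec, pop_cfg)
    start = tuple(population_fit.theta_)

    weight_sets = weight_matrix(targets, data, p=config.p, d_floor=config.d_floor)
    fit_cfg = replace(config.fit, compute_ci=config.compute_ci, start=start)

    rows = []
    n_failed = 0
    for target, ws in zip(targets, weight_sets):
        try:
            fit = fit_model(data, ws.weights, spec, fit_cfg)
        except Exception as exc:  # keep the run alive; flag the row
            logger.warning("fit failed at target %s: %s", target.target_id, exc)
            n_failed += 1
            rows.append({c: np.nan for c in RESULT_COLUMNS}
                        | {"target_id": target.target_id, "x": target.x,
                           "y": target.y, "converged": False,
                           "ess_mz": ws.ess_mz, "ess_dz": ws.ess_dz})
            continue
        comps, std = fit.components, fit.components_std
        ci = fit.ci or {}
        a2_ci = ci.get("a2", (np.nan, np.nan))
        c2_ci = ci.get("c2_or_d2", (np.nan, np.nan))
        e2_ci = ci.get("e2", (np.nan, np.nan))
        rows.append({
            "target_id": target.target_id, "x": target.x, "y": target.y,
            "a2_raw": comps.a2, "c2_or_d2_raw": comps.c2_or_d2,
            "e2_raw": comps.e2,
            "a2_std": std.a2, "c2_or_d2_std": std.c2_or_d2, "e2_std": std.e2,
            "total_variance": comps.total,
            "a2_lo": a2_ci[0], "a2_hi": a2_ci[1],
            "c2_or_d2_lo": c2_ci[0], "c2_or_d2_hi": c2_ci[1],
            "e2_lo": e2_ci[0], "e2_hi": e2_ci[1],
            "ess_mz": fit.ess_mz, "ess_dz": fit.ess_dz,
            "converged": fit.converged,
            "weighted_mean_trait": _weighted_trait_mean(data, ws.weights),
        })
        if not fit.converged:
            n_failed += 1
    if n_failed:
        logger.warning("%d of %d locations failed to converge",
                       n_failed, len(targets))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return SpaceResult(table=table, spec=spec, config=config,
                       population_fit=population_fit)


def weighted_mean_map(pairs: Sequence[TwinPairRecord] | CohortData,
                      targets: Sequence[TargetLocation],
                      p: float = DEFAULT_P,
                      d_floor: float = DEFAULT_D_FLOOR) -> pd.DataFrame:
    """Distance-weighted mean of the standardized trait at each target.

    Uses the per-pair mean of observed scores, so incomplete pairs still
    contribute their single observation.
    """
    data = CohortData.from_pairs(pairs)
    weight_sets = weight_matrix(targets, data, p=p, d_floor=d_floor)
    rows = [{"target_id": t.target_id, "x": t.x, "y": t.y,
             "weighted_mean_trait": _weighted_trait_mean(data, ws.weights)}
            for t, ws in zip(targets, weight_sets)]
    return pd.DataFrame(rows)


def location_sensitivity(pairs: Sequence[TwinPairRecord],
                         targets: Sequence[TargetLocation],
                         spec: ModelSpec | None = None,
                         config: SpaceConfig | None = None,
                         labels: Optional[Sequence[str]] = None) -> SensitivityResult:
    """Re-run the spatial analysis with each historical-location snapshot.

    Each pair's coordinates are replaced by its snapshot for the given label;
    the cross-snapshot Pearson correlation of the a2 maps quantifies how
    robust the geography of the genetic component is to residence history.
    """
    if labels is None:
        first = pairs[0].location_snapshots or []
        labels = [lbl for lbl, _, _ in first]
    if not labels:
        raise ValueError("no snapshot labels available")
    for p in pairs:
        have = {lbl for lbl, _, _ in (p.location_snapshots or [])}
        missing = [lbl for lbl in labels if lbl not in have]
        if missing:
            raise ValueError(
                f"pair {p.pair_id!r} lacks snapshot label(s) {missing}")

    results: list[tuple[str, SpaceResult]] = []
    for lbl in labels:
        moved = []
        for p in pairs:
            coords = {l: (sx, sy) for l, sx, sy in p.location_snapshots}
            sx, sy = coords[lbl]
            moved.append(replace(p, x=sx, y=sy))
        results.append((lbl, run_space(moved, targets, spec, config)))

    a2 = pd.DataFrame({lbl: res.table["a2_raw"].to_numpy()
                       for lbl, res in results})
    return SensitivityResult(results=results, a2_correlation=a2.corr())
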