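"""Twin ACE/ADE variance-component models with weighted FIML estimation.

The model decomposes a standardized trait into additive-genetic (A),
shared-environmental (C) or dominance (D), and non-shared environmental (E)
variance, estimated from the differing within-pair covariance of MZ and DZ
twins.  Estimation maximizes a *weighted* full-information maximum-likelihood
objective: every pair contributes its (possibly univariate, when one twin's
phenotype is missing) normal log-density times a non-negative weight.

Parameterization is by path coefficients (variance = coefficient^2), which
keeps variance components non-negative by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MZ",
    "DZ_SAME_SEX",
    "DZ_OPPOSITE_SEX",
    "ZYGOSITIES",
    "SEXES",
    "TwinPairRecord",
    "ModelSpec",
    "VarianceComponents",
    "MeanModel",
    "FitResult",
    "FitConfig",
    "SexLimitationResult",
    "CohortData",
    "expected_covariance",
    "pair_loglik",
    "weighted_loglik",
    "fit_model",
    "confidence_intervals",
    "fit_sex_limitation",
    "variance_explained_by_covariates",
]

# Zygosity codes (shared with the cohort CSV dialect).
MZ = "MZ"
DZ_SAME_SEX = "DZss"
DZ_OPPOSITE_SEX = "DZos"
ZYGOSITIES = (MZ, DZ_SAME_SEX, DZ_OPPOSITE_SEX)
SEXES = ("M", "F")

#: CRS tags treated as geographic (degrees); spatial weighting rejects these.
GEOGRAPHIC_CRS = frozenset({"EPSG:4326", "WGS84", "lonlat", "latlon", "geographic"})

_LN_2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12  # finite penalty for invalid covariance during optimization


@dataclass
class TwinPairRecord:
    """One twin pair: phenotypes, zygosity, sexes, age and planar location.

    ``y1``/``y2`` are standardized trait scores; either may be ``None``
    (missing) but not both.  ``x``/``y`` are planar coordinates in a projected
    CRS with consistent units.  ``location_snapshots`` optionally stores
    historical residences as ``(label, x, y)`` tuples.
    """

    pair_id: str
    zygosity: str
    sex1: str
    sex2: str
    y1: Optional[float]
    y2: Optional[float]
    x: float
    y: float
    age: Optional[float] = None
    region_id: Optional[str] = None
    location_snapshots: Optional[list[tuple[str, float, float]]] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(
                f"pair {self.pair_id!r}: unknown zygosity {self.zygosity!r}; "
                f"expected one of {ZYGOSITIES}"
            )
        if self.sex1 not in SEXES or self.sex2 not in SEXES:
            raise ValueError(f"pair {self.pair_id!r}: sexes must be in {SEXES}")
        if self.zygosity == MZ and self.sex1 != self.sex2:
            raise ValueError(f"pair {self.pair_id!r}: MZ twins must be same-sex")
        if self.zygosity == DZ_OPPOSITE_SEX and self.sex1 == self.sex2:
            raise ValueError(f"pair {self.pair_id!r}: DZos twins must be opposite-sex")
        if self.y1 is None and self.y2 is None:
            raise ValueError(f"pair {self.pair_id!r}: both phenotypes missing")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"pair {self.pair_id!r}: non-finite coordinates")


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components to fit and how.

    ``components``: one of ACE, ADE, AE, CE, E (E is always present).
    ``sex_limitation``: ``equated`` (single set of paths) or ``quantitative``
    (separate path magnitudes by sex).  ADE cannot be combined with the
    quantitative sex-limitation model.
    """

    components: str = "ACE"
    sex_limitation: str = "equated"
    covariates: tuple[str, ...] = ("sex",)

    def __post_init__(self) -> None:
        if self.components not in ("ACE", "ADE", "AE", "CE", "E"):
            raise ValueError(f"unknown component set {self.components!r}")
        if self.sex_limitation not in ("equated", "quantitative"):
            raise ValueError(f"unknown sex_limitation {self.sex_limitation!r}")
        if self.components == "ADE" and self.sex_limitation == "quantitative":
            raise ValueError("ADE and quantitative sex-limitation cannot be combined")
        for cov in self.covariates:
            if cov not in ("sex", "age"):
                raise ValueError(f"unknown covariate {cov!r}")

    @property
    def has_a(self) -> bool:
        return "A" in self.components

    @property
    def has_c(self) -> bool:
        # the middle slot: C for ACE/CE, D for ADE
        return "C" in self.components or "D" in self.components

    @property
    def is_ade(self) -> bool:
        return self.components == "ADE"

    @property
    def dz_c_coef(self) -> float:
        """DZ cross-twin coefficient on the middle component: 1 for C, 1/4 for D."""
        return 0.25 if self.is_ade else 1.0


@dataclass
class VarianceComponents:
    """A/C(or D)/E variances on the raw or proportional scale."""

    a2: float
    c2_or_d2: float
    e2: float
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "proportional"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.a2 < 0 or self.c2_or_d2 < 0 or self.e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.scale == "proportional":
            total = self.a2 + self.c2_or_d2 + self.e2
            if abs(total - 1.0) > 1e-10:
                raise ValueError(f"proportional components must sum to 1, got {total}")

    @property
    def total(self) -> float:
        return self.a2 + self.c2_or_d2 + self.e2

    def standardized(self) -> "VarianceComponents":
        """Return components divided by their sum (proportional scale)."""
        t = self.total
        if t <= 0:
            raise ValueError("cannot standardize all-zero components")
        return VarianceComponents(self.a2 / t, self.c2_or_d2 / t, self.e2 / t,
                                  scale="proportional")


@dataclass
class MeanModel:
    intercept: float
    beta_sex: float = 0.0
    beta_age: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.intercept, self.beta_sex, self.beta_age):
            if not np.isfinite(v):
                raise ValueError("mean-model coefficients must be finite")


@dataclass
class FitResult:
    """A fitted weighted twin model at one set of weights."""

    components: VarianceComponents
    components_std: VarianceComponents
    mean_model: MeanModel
    loglik: float
    ci: dict[str, tuple[float, float]]
    ess_mz: float
    ess_dz: float
    converged: bool
    n_eval: int
    spec: ModelSpec = field(default_factory=ModelSpec)
    # Internal optimizer state, kept so confidence_intervals can recompute
    # curvature at the optimum without refitting.
    theta_: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and interval settings for :func:`fit_model`."""

    max_iter: int = 500
    gtol: float = 1e-9
    compute_ci: bool = True
    ci_method: str = "observed_information"
    normalize_weights: bool = True
    ci_level: float = 0.95
    start: Optional[Sequence[float]] = None  # optional explicit theta start

    def __post_init__(self) -> None:
        if self.ci_method != "observed_information":
            raise ValueError(
                "only ci_method='observed_information' is implemented"
            )


@dataclass
class SexLimitationResult:
    male: VarianceComponents
    female: VarianceComponents
    mean_model: MeanModel
    loglik: float
    lrt_vs_equated: tuple[float, int, float]  # (statistic, df, p)
    equated_fit: FitResult
    converged: bool


# ---------------------------------------------------------------------------
# Expected covariance
# ---------------------------------------------------------------------------

def expected_covariance(components: VarianceComponents, zygosity: str,
                        spec: ModelSpec | None = None) -> np.ndarray:
    """Model-implied 2x2 covariance of a twin pair's phenotypes.

    MZ twins share A fully (correlation 1) and C fully; DZ twins share half
    of A and all of C.  Under ADE the middle component is dominance variance
    with DZ coefficient 1/4.  E is uncorrelated across twins.
    """
    spec = spec or ModelSpec()
    if components.scale != "raw":
        raise ValueError("expected_covariance requires raw-scale components")
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    a2, m2, e2 = components.a2, components.c2_or_d2, components.e2
    total = a2 + m2 + e2
    if zygosity == MZ:
        cross = a2 + m2
    else:
        cross = 0.5 * a2 + spec.dz_c_coef * m2
    return np.array([[total, cross], [cross, total]])


# ---------------------------------------------------------------------------
# Cohort arrays
# ---------------------------------------------------------------------------

class CohortData:
    """Vectorized array view of a twin cohort for fast repeated likelihoods.

    Built once from a list of :class:`TwinPairRecord`; all likelihood
    evaluations (thousands per spatial analysis) operate on these arrays.
    """

    def __init__(self, pairs: Sequence[TwinPairRecord]):
        if len(pairs) == 0:
            raise ValueError("empty cohort")
        n = len(pairs)
        self.pairs = list(pairs)
        self.n = n
        self.y1 = np.array([np.nan if p.y1 is None else p.y1 for p in pairs])
        self.y2 = np.array([np.nan if p.y2 is None else p.y2 for p in pairs])
        self.sex1 = np.array([1.0 if p.sex1 == "M" else 0.0 for p in pairs])
        self.sex2 = np.array([1.0 if p.sex2 == "M" else 0.0 for p in pairs])
        self.age = np.array([0.0 if p.age is None else p.age for p in pairs])
        self.is_mz = np.array([p.zygosity == MZ for p in pairs])
        self.is_dz = ~self.is_mz
        self.xy = np.array([[p.x, p.y] for p in pairs])
        self.miss1 = np.isnan(self.y1)
        self.miss2 = np.isnan(self.y2)
        if np.any(self.miss1 & self.miss2):
            raise ValueError("a pair with both phenotypes missing is not allowed")
        self.complete = ~(self.miss1 | self.miss2)

    @classmethod
    def from_pairs(cls, pairs: Sequence[TwinPairRecord] | "CohortData") -> "CohortData":
        if isinstance(pairs, CohortData):
            return pairs
        return cls(pairs)


def _kish_ess(w: np.ndarray) -> float:
    s = float(np.sum(w))
    if s <= 0:
        return 0.0
    return s * s / float(np.sum(w * w))


# ---------------------------------------------------------------------------
# Vectorized log-likelihood
# ---------------------------------------------------------------------------

def _pair_loglik_vector(data: CohortData,
                        a_m: float, c_m: float, e_m: float,
                        a_f: float, c_f: float, e_f: float,
                        mu: float, b_sex: float, b_age: float,
                        dz_c_coef: float) -> Optional[np.ndarray]:
    """Per-pair log-densities under sex-specific paths.

    The equated model passes identical male/female paths.  Returns None when
    any pair's model-implied covariance is not positive definite.
    """
    # per-twin total variance, by that twin's sex (M code 1, F code 0)
    v_m = a_m * a_m + c_m * c_m + e_m * e_m
    v_f = a_f * a_f + c_f * c_f + e_f * e_f
    v1 = np.where(data.sex1 == 1.0, v_m, v_f)
    v2 = np.where(data.sex2 == 1.0, v_m, v_f)

    # cross-twin covariance by zygosity; opposite-sex DZ uses path products
    a1 = np.where(data.sex1 == 1.0, a_m, a_f)
    a2p = np.where(data.sex2 == 1.0, a_m, a_f)
    c1 = np.where(data.sex1 == 1.0, c_m, c_f)
    c2p = np.where(data.sex2 == 1.0, c_m, c_f)
    cross = np.where(data.is_mz,
                     a1 * a2p + c1 * c2p,
                     0.5 * a1 * a2p + dz_c_coef * c1 * c2p)

    m1 = mu + b_sex * data.sex1 + b_age * data.age
    m2 = mu + b_sex * data.sex2 + b_age * data.age
    r1 = data.y1 - m1
    r2 = data.y2 - m2

    det = v1 * v2 - cross * cross
    comp = data.complete
    if np.any(v1 <= 0) or np.any(v2 <= 0) or np.any(det[comp] <= 0):
        return None

    ll = np.empty(data.n)
    quad = (v2[comp] * r1[comp] ** 2 - 2.0 * cross[comp] * r1[comp] * r2[comp]
            + v1[comp] * r2[comp] ** 2) / det[comp]
    ll[comp] = -_LN_2PI - 0.5 * np.log(det[comp]) - 0.5 * quad

    m1only = data.miss2  # y1 observed, y2 missing
    if np.any(m1only):
        ll[m1only] = (-0.5 * np.log(2.0 * math.pi * v1[m1only])
                      - 0.5 * r1[m1only] ** 2 / v1[m1only])
    m2only = data.miss1
    if np.any(m2only):
        ll[m2only] = (-0.5 * np.log(2.0 * math.pi * v2[m2only])
                      - 0.5 * r2[m2only] ** 2 / v2[m2only])
    return ll


def pair_loglik(pair: TwinPairRecord, components: VarianceComponents,
                mean_model: MeanModel, spec: ModelSpec | None = None) -> float:
    """FIML log-likelihood contribution of a single twin pair.

    Complete pairs contribute a bivariate normal log-density under the
    model-implied covariance; pairs missing one phenotype contribute the
    univariate marginal normal log-density.
    """
    spec = spec or ModelSpec()
    sigma = expected_covariance(components, pair.zygosity, spec)
    if np.linalg.det(sigma) <= 0:
        raise np.linalg.LinAlgError(
            f"singular model-implied covariance for pair {pair.pair_id!r}: "
            f"total={sigma[0, 0]:.6g}, cross={sigma[0, 1]:.6g}"
        )
    data = CohortData([pair])
    a = math.sqrt(components.a2)
    c = math.sqrt(components.c2_or_d2)
    e = math.sqrt(components.e2)
    ll = _pair_loglik_vector(data, a, c, e, a, c, e,
                             mean_model.intercept, mean_model.beta_sex,
                             mean_model.beta_age, spec.dz_c_coef)
    assert ll is not None
    return float(ll[0])


def weighted_loglik(pairs: Sequence[TwinPairRecord] | CohortData,
                    weights: Sequence[float],
                    components: VarianceComponents, mean_model: MeanModel,
                    spec: ModelSpec | None = None) -> float:
    """Weighted FIML objective: sum of per-pair log-densities times weights.

    With unit weights this is the ordinary FIML log-likelihood.
    """
    spec = spec or ModelSpec()
    data = CohortData.from_pairs(pairs)
    w = np.asarray(weights, dtype=float)
    if w.shape != (data.n,):
        raise ValueError(f"{w.size} weights for {data.n} pairs")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    a = math.sqrt(components.a2)
    c = math.sqrt(components.c2_or_d2)
    e = math.sqrt(components.e2)
    ll = _pair_loglik_vector(data, a, c, e, a, c, e,
                             mean_model.intercept, mean_model.beta_sex,
                             mean_model.beta_age, spec.dz_c_coef)
    if ll is None:
        raise np.linalg.LinAlgError("singular model-implied covariance")
    return float(np.sum(w * ll))


# ---------------------------------------------------------------------------
# Parameter layout and objective
# ---------------------------------------------------------------------------

class _ParamLayout:
    """Maps the flat optimizer vector theta onto model quantities."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.sexlim = spec.sex_limitation == "quantitative"
        names: list[str] = []
        if self.sexlim:
            names += ["a_m", "c_m", "e_m", "a_f", "c_f", "e_f"]
        else:
            if spec.has_a:
                names.append("a")
            if spec.has_c:
                names.append("c")
            names.append("e")
        names.append("mu")
        if "sex" in spec.covariates:
            names.append("b_sex")
        if "age" in spec.covariates:
            names.append("b_age")
        self.names = names
        self.idx = {n: i for i, n in enumerate(names)}
        self.k = len(names)

    def unpack(self, theta: np.ndarray) -> tuple[float, ...]:
        g = lambda n, d=0.0: theta[self.idx[n]] if n in self.idx else d
        if self.sexlim:
            a_m, c_m, e_m = g("a_m"), g("c_m"), g("e_m")
            a_f, c_f, e_f = g("a_f"), g("c_f"), g("e_f")
        else:
            a_m = a_f = g("a")
            c_m = c_f = g("c")
            e_m = e_f = g("e")
        return (a_m, c_m, e_m, a_f, c_f, e_f, g("mu"), g("b_sex"), g("b_age"))


def _neg_weighted_loglik(theta: np.ndarray, data: CohortData, w: np.ndarray,
                         layout: _ParamLayout) -> float:
    a_m, c_m, e_m, a_f, c_f, e_f, mu, b_sex, b_age = layout.unpack(theta)
    ll = _pair_loglik_vector(data, a_m, c_m, e_m, a_f, c_f, e_f,
                             mu, b_sex, b_age, layout.spec.dz_c_coef)
    if ll is None:
        return _PENALTY + float(np.sum(theta * theta))
    return -float(np.sum(w * ll))


def _weighted_moments(data: CohortData, w: np.ndarray) -> tuple[float, float, float, float]:
    """Weighted mean/variance of observed scores and MZ/DZ pair correlations."""
    ys = np.concatenate([data.y1[~data.miss1], data.y2[~data.miss2]])
    ws = np.concatenate([w[~data.miss1], w[~data.miss2]])
    sw = np.sum(ws)
    mean = float(np.sum(ws * ys) / sw)
    var = float(np.sum(ws * (ys - mean) ** 2) / sw)

    def wcorr(mask: np.ndarray) -> float:
        m = mask & data.complete
        if np.sum(m) < 3:
            return 0.0
        wi = w[m]
        if np.sum(wi) <= 0:
            return 0.0
        y1, y2 = data.y1[m], data.y2[m]
        mu1 = np.sum(wi * y1) / np.sum(wi)
        mu2 = np.sum(wi * y2) / np.sum(wi)
        cov = np.sum(wi * (y1 - mu1) * (y2 - mu2))
        v1 = np.sum(wi * (y1 - mu1) ** 2)
        v2 = np.sum(wi * (y2 - mu2) ** 2)
        if v1 <= 0 or v2 <= 0:
            return 0.0
        return float(cov / math.sqrt(v1 * v2))

    return mean, var, wcorr(data.is_mz), wcorr(data.is_dz)


def _default_start(data: CohortData, w: np.ndarray, layout: _ParamLayout) -> np.ndarray:
    """Falconer-style moment start values, clipped into (0, 1) proportions."""
    mean, var, r_mz, r_dz = _weighted_moments(data, w)
    var = max(var, 1e-6)
    a2 = float(np.clip(2.0 * (r_mz - r_dz), 0.01, 0.99)) * var
    c2 = float(np.clip(2.0 * r_dz - r_mz, 0.01, 0.99)) * var
    e2 = float(np.clip(1.0 - r_mz, 0.01, 0.99)) * var
    theta = np.zeros(layout.k)
    vals = {"a": math.sqrt(a2), "c": math.sqrt(c2), "e": math.sqrt(e2),
            "a_m": math.sqrt(a2), "c_m": math.sqrt(c2), "e_m": math.sqrt(e2),
            "a_f": math.sqrt(a2), "c_f": math.sqrt(c2), "e_f": math.sqrt(e2),
            "mu": mean, "b_sex": 0.0, "b_age": 0.0}
    for name, i in layout.idx.items():
        theta[i] = vals[name]
    return theta


def _check_identifiable(data: CohortData, w: np.ndarray, spec: ModelSpec) -> None:
    n_mz = int(np.sum((w > 0) & data.is_mz))
    n_dz = int(np.sum((w > 0) & data.is_dz))
    if spec.components == "E":
        if n_mz + n_dz < 2:
            raise ValueError("need at least 2 pairs with positive weight")
        return
    if n_mz < 2 or n_dz < 2:
        raise ValueError(
            "variance components are not identifiable: need >=2 MZ and >=2 DZ "
            f"pairs with positive weight (got {n_mz} MZ, {n_dz} DZ)"
        )


def _normalize(w: np.ndarray) -> np.ndarray:
    """Rescale weights to sum to the number of contributing (positive) pairs."""
    n_pos = int(np.sum(w > 0))
    s = float(np.sum(w))
    if s <= 0:
        raise ValueError("weights sum to zero")
    return w * (n_pos / s)


def fit_model(pairs: Sequence[TwinPairRecord] | CohortData,
              weights: Sequence[float] | None = None,
              spec: ModelSpec | None = None,
              config: FitConfig | None = None) -> FitResult:
    """Maximize the weighted FIML objective and return point estimates.

    Deterministic given fixed start values: quasi-Newton (L-BFGS-B) from
    moment-based starts, or from ``config.start`` when supplied.  Weights are
    normalized to sum to the number of contributing pairs before fitting,
    which leaves point estimates unchanged but makes log-likelihoods and
    curvature comparable across locations.
    """
    spec = spec or ModelSpec()
    config = config or FitConfig()
    data = CohortData.from_pairs(pairs)
    w = (np.ones(data.n) if weights is None
         else np.asarray(weights, dtype=float))
    if w.shape != (data.n,):
        raise ValueError(f"{w.size} weights for {data.n} pairs")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    _check_identifiable(data, w, spec)
    if config.normalize_weights:
        w = _normalize(w)

    layout = _ParamLayout(spec)
    if config.start is not None:
        theta0 = np.asarray(config.start, dtype=float)
        if theta0.shape != (layout.k,):
            raise ValueError(f"start has {theta0.size} values, expected {layout.k}")
    else:
        theta0 = _default_start(data, w, layout)

    res = optimize.minimize(
        _neg_weighted_loglik, theta0, args=(data, w, layout),
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "gtol": config.gtol,
                 "ftol": 1e-12},
    )
    theta = res.x
    a_m, c_m, e_m, a_f, c_f, e_f, mu, b_sex, b_age = layout.unpack(theta)
    comps = VarianceComponents(a_m * a_m, c_m * c_m, e_m * e_m, scale="raw")
    # e2 -> 0 makes the MZ covariance singular and the likelihood unbounded;
    # such boundary solutions are flagged, not silently reported
    e2_min = min(e_m * e_m, e_f * e_f)
    at_boundary = e2_min <= 1e-3 * max(comps.total, 1e-12)
    if at_boundary:
        warnings.warn("fit terminated at the e2 -> 0 singular boundary")
    fit = FitResult(
        components=comps,
        components_std=comps.standardized(),
        mean_model=MeanModel(mu, b_sex, b_age),
        loglik=-float(res.fun),
        ci={},
        ess_mz=_kish_ess(w[data.is_mz]),
        ess_dz=_kish_ess(w[data.is_dz]),
        converged=bool(res.success) and not at_boundary,
        n_eval=int(res.nfev),
        spec=spec,
        theta_=theta,
    )
    if config.compute_ci and fit.converged:
        fit.ci = confidence_intervals(fit, data, w, config, _prenormalized=True)
    return fit


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction."""
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
            else:
                val = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def confidence_intervals(fit: FitResult,
                         pairs: Sequence[TwinPairRecord] | CohortData,
                         weights: Sequence[float] | None = None,
                         config: FitConfig | None = None,
                         _prenormalized: bool = False) -> dict[str, tuple[float, float]]:
    """Observed-information 95% intervals for the raw variance components.

    Curvature of the weighted objective at the optimum (weights normalized to
    sum to the contributing-pair count), delta-method-propagated from path
    coefficients to variances (var(a^2) = (2a)^2 var(a)).  Lower bounds are
    truncated at 0.  A singular information matrix marks the interval
    unavailable (NaN bounds) instead of aborting.
    """
    config = config or FitConfig()
    if fit.theta_ is None:
        raise ValueError("fit carries no optimizer state; refit with fit_model")
    if not fit.converged:
        warnings.warn("confidence intervals requested for a non-converged fit")
    data = CohortData.from_pairs(pairs)
    w = (np.ones(data.n) if weights is None
         else np.asarray(weights, dtype=float))
    if not _prenormalized and config.normalize_weights:
        w = _normalize(w)
    layout = _ParamLayout(fit.spec)
    H = _numeric_hessian(
        lambda t: _neg_weighted_loglik(t, data, w, layout), fit.theta_)
    z = stats.norm.ppf(0.5 + config.ci_level / 2.0)

    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(~np.isfinite(diag)):
            raise np.linalg.LinAlgError("non-finite curvature")
        singular = False
    except np.linalg.LinAlgError:
        singular = True

    out: dict[str, tuple[float, float]] = {}
    path_names = ([("a2", "a"), ("c2_or_d2", "c"), ("e2", "e")]
                  if not layout.sexlim else
                  [("a2_m", "a_m"), ("c2_m", "c_m"), ("e2_m", "e_m"),
                   ("a2_f", "a_f"), ("c2_f", "c_f"), ("e2_f", "e_f")])
    for comp_name, path in path_names:
        if path not in layout.idx:
            continue
        i = layout.idx[path]
        est = fit.theta_[i] ** 2
        if singular or diag[i] < 0:
            out[comp_name] = (math.nan, math.nan)
            continue
        se = 2.0 * abs(fit.theta_[i]) * math.sqrt(diag[i])
        out[comp_name] = (max(0.0, est - z * se), est + z * se)
    return out


# ---------------------------------------------------------------------------
# Sex-limitation model
# ---------------------------------------------------------------------------

def fit_sex_limitation(pairs: Sequence[TwinPairRecord] | CohortData,
                       weights: Sequence[float] | None = None,
                       config: FitConfig | None = None,
                       covariates: tuple[str, ...] = ("sex",)) -> SexLimitationResult:
    """Quantitative sex-limitation ACE model vs. the sex-equated model.

    Separate a/c/e path magnitudes by sex; opposite-sex DZ pairs carry the
    cross-sex covariance 0.5*a_m*a_f + c_m*c_f.  The likelihood-ratio test
    statistic is 2*(loglik_full - loglik_equated) on 3 df (a, c, e equated);
    no boundary correction is applied.
    """
    config = config or FitConfig()
    data = CohortData.from_pairs(pairs)
    has_os = any(p.zygosity == DZ_OPPOSITE_SEX for p in data.pairs)
    if not has_os:
        warnings.warn(
            "no opposite-sex DZ pairs: male and female shared-environment "
            "paths are confounded in the sex-limitation model"
        )
    eq_spec = ModelSpec("ACE", "equated", covariates)
    full_spec = ModelSpec("ACE", "quantitative", covariates)
    eq_fit = fit_model(data, weights, eq_spec,
                       replace(config, compute_ci=False, start=None))
    # start the full model at the equated optimum for determinism and speed
    eq_theta = eq_fit.theta_
    layout_eq = _ParamLayout(eq_spec)
    layout_full = _ParamLayout(full_spec)
    start = np.zeros(layout_full.k)
    for n in ("a", "c", "e"):
        for sexed in (n + "_m", n + "_f"):
            start[layout_full.idx[sexed]] = eq_theta[layout_eq.idx[n]]
    for n in ("mu", "b_sex", "b_age"):
        if n in layout_full.idx:
            start[layout_full.idx[n]] = eq_theta[layout_eq.idx[n]]
    full_fit = fit_model(data, weights, full_spec,
                         replace(config, compute_ci=False, start=tuple(start)))

    a_m, c_m, e_m, a_f, c_f, e_f, mu, b_sex, b_age = layout_full.unpack(full_fit.theta_)
    lrt = max(0.0, 2.0 * (full_fit.loglik - eq_fit.loglik))
    df = 3
    p = float(stats.chi2.sf(lrt, df))
    return SexLimitationResult(
        male=VarianceComponents(a_m * a_m, c_m * c_m, e_m * e_m),
        female=VarianceComponents(a_f * a_f, c_f * c_f, e_f * e_f),
        mean_model=MeanModel(mu, b_sex, b_age),
        loglik=full_fit.loglik,
        lrt_vs_equated=(lrt, df, p),
        equated_fit=eq_fit,
        converged=full_fit.converged and eq_fit.converged,
    )


# ---------------------------------------------------------------------------
# Covariate variance shares
# ---------------------------------------------------------------------------

def variance_explained_by_covariates(pairs: Sequence[TwinPairRecord] | CohortData,
                                     mean_model: MeanModel) -> dict[str, float]:
    """Proportion of phenotypic variance attributable to each mean covariate.

    Computed as var(fitted covariate term) / var(observed phenotypes) across
    all observed twin scores; invariant to the covariate coding.
    """
    data = CohortData.from_pairs(pairs)
    ys = np.concatenate([data.y1[~data.miss1], data.y2[~data.miss2]])
    var_y = float(np.var(ys))
    if var_y <= 0:
        raise ValueError("zero phenotypic variance")
    sex = np.concatenate([data.sex1[~data.miss1], data.sex2[~data.miss2]])
    age = np.concatenate([data.age[~data.miss1], data.age[~data.miss2]])
    return {
        "sex": float(np.var(mean_model.beta_sex * sex)) / var_y,
        "age": float(np.var(mean_model.beta_age * age)) / var_y,
    }
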