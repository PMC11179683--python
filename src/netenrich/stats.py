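"""Per-location brain-phenotype association statistics.

Each analysis location (vertex or parcel) carries a signed scalar ``T_v``
quantifying the association between the brain measurement at that location
and a phenotype of interest. The default statistic fits, at every location,
a generalized additive model

    x_v = a0 + a1 * I(sex=female) + f1(age) + f2(age) * I(sex=female) + eps

where ``f1`` and ``f2`` are fixed-degrees-of-freedom natural cubic
regression splines with knots at age quantiles, and summarizes each effect
of interest with a multivariate Wald statistic (a quadratic form over the
effect's coefficient block), signed by the corresponding coefficient of a
plain multiple linear regression so that the sign reflects the overall
trend of a possibly nonlinear association.

Simpler plug-in statistics (Pearson correlation with the effect covariate,
signed squared t from a linear model) share the same interface and are
registered by name; any callable mapping ``(X, phenotypes, effect)`` to a
vector of signed finite scalars may be registered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

EFFECTS = ("age", "sex", "age:sex")
STAT_KINDS = ("gam_wald", "ols_wald", "pearson")


class DegenerateFitWarning(UserWarning):
    """Raised when a location has zero residual variance (statistic set to 0)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: one row per subject, finite age, sex in {0,1}.

    The table is indexed by subject identifier, with columns ``age`` (years)
    and ``sex`` (1 = female) plus optional numeric covariates. Row order must
    match the rows of the measurement matrix.
    """
    for col in ("age", "sex"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table is missing required column {col!r}")
    if pheno.index.has_duplicates:
        dup = pheno.index[pheno.index.duplicated()][0]
        raise ValueError(f"duplicate subject_id in phenotype table: {dup!r}")
    age = np.asarray(pheno["age"], dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("non-finite age in phenotype table")
    sex = np.asarray(pheno["sex"], dtype=float)
    if not np.isin(sex, (0.0, 1.0)).all():
        raise ValueError("sex must be coded 0/1 (1 = female)")
    return pheno


@dataclass
class SubjectDataset:
    """Subjects x locations measurement matrix plus phenotype table.

    ``X[i, v]`` is the brain measurement of subject ``i`` at location ``v``
    (e.g., cortical thickness in mm, or task-activation % signal change).
    Excluded locations (such as a medial-wall analogue) must be dropped
    before constructing the dataset.
    """

    X: np.ndarray
    location_ids: list[str]
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.location_ids = [str(s) for s in self.location_ids]
        if self.X.ndim != 2:
            raise ValueError("measurement matrix must be 2-D (subjects x locations)")
        if self.X.shape[1] != len(self.location_ids):
            raise ValueError(
                f"matrix has {self.X.shape[1]} columns but "
                f"{len(self.location_ids)} location ids"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing or non-finite values in measurement matrix")
        if self.X.shape[0] < 3:
            raise ValueError("at least 3 subjects are required")
        validate_phenotypes(self.phenotypes)
        if len(self.phenotypes) != self.X.shape[0]:
            raise ValueError(
                f"phenotype table has {len(self.phenotypes)} rows but matrix has "
                f"{self.X.shape[0]} subjects"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_locations(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ModelSpec:
    """Which effect to test and which statistic to use.

    spline_df is the number of basis functions for each smooth (f1 and f2);
    4 is a conventional default for smooth developmental age trends.
    """

    effect: str = "age"
    stat_kind: str = "gam_wald"
    spline_df: int = 4
    robust: bool = False  # sandwich covariance instead of model-based

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {self.effect!r}")
        if self.stat_kind not in STAT_KINDS and self.stat_kind not in _REGISTRY:
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")
        if self.stat_kind == "gam_wald" and self.spline_df < 2:
            raise ValueError("spline_df must be >= 2 for gam_wald")


@dataclass
class VertexFit:
    """Least-squares fit of one location's GAM.

    coefficients: (intercept, sex, f1 spline coefs, f2 spline coefs)
    covariance: model-based covariance of the coefficients
    linear_coefficients: coefficients of the sign-assigning linear model
        [intercept, sex, age, age:sex]
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    residual_df: int
    slices: dict[str, np.ndarray]
    linear_coefficients: dict[str, float]
    degenerate: bool = False


@dataclass
class AssociationMap:
    """Signed association statistic per analysis location."""

    T: np.ndarray
    location_ids: list[str]
    effect: str
    stat_kind: str

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.ndim != 1 or len(self.T) != len(self.location_ids):
            raise ValueError("T must be a vector aligned to location_ids")
        if not np.all(np.isfinite(self.T)):
            raise ValueError("association statistics must be finite")


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------


def natural_cubic_basis(
    x: np.ndarray, df: int, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic regression spline basis (no intercept column).

    Returns an (n, df) matrix spanning the natural cubic splines on df + 1
    knots placed at evenly spaced quantiles of ``x`` (boundary knots at the
    extremes). Natural splines are linear beyond the boundary knots; the
    span includes every linear function of ``x``, so a linear trend is
    reproduced exactly by the fitted model.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return (x - x.mean())[:, None]
    if knots is None:
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(x, qs)
        knots = np.unique(knots)
        if len(knots) < df + 1:
            raise ValueError(
                "could not place distinct spline knots; covariate has too few "
                "distinct values for requested df"
            )
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dKm2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm2)
    B = np.column_stack(cols)
    # center columns for numerical conditioning (span unchanged)
    return B - B.mean(axis=0)


def effect_covariate(pheno: pd.DataFrame, effect: str) -> np.ndarray:
    """The single covariate summarizing an effect: centered age, the female
    indicator, or their product (centered age x female)."""
    age = np.asarray(pheno["age"], dtype=float)
    sex = np.asarray(pheno["sex"], dtype=float)
    if effect == "age":
        return age - age.mean()
    if effect == "sex":
        return sex
    if effect == "age:sex":
        return (age - age.mean()) * sex
    raise ValueError(f"unknown effect {effect!r}")


def _gam_design(pheno: pd.DataFrame, spline_df: int):
    """Design matrix [1, sex, B_age, B_age*sex] and per-effect column blocks.

    Effect blocks for the joint Wald test:
      age     -> all f1 and f2 columns (nonlinear age effects that may differ by sex)
      sex     -> the sex main-effect column and all f2 columns
      age:sex -> all f2 columns
    """
    age = np.asarray(pheno["age"], dtype=float)
    sex = np.asarray(pheno["sex"], dtype=float)
    B = natural_cubic_basis(age, spline_df)
    n, df = B.shape
    D = np.column_stack([np.ones(n), sex, B, B * sex[:, None]])
    f1 = np.arange(2, 2 + df)
    f2 = np.arange(2 + df, 2 + 2 * df)
    slices = {
        "age": np.concatenate([f1, f2]),
        "sex": np.concatenate([[1], f2]),
        "age:sex": f2,
        "_f1": f1,
        "_f2": f2,
    }
    return D, slices


def _linear_design(pheno: pd.DataFrame) -> np.ndarray:
    """Sign-assigning linear model design: [1, sex, age, age x sex]."""
    age = np.asarray(pheno["age"], dtype=float)
    sex = np.asarray(pheno["sex"], dtype=float)
    agec = age - age.mean()
    return np.column_stack([np.ones(len(age)), sex, agec, agec * sex])


_LINEAR_COEF_INDEX = {"sex": 1, "age": 2, "age:sex": 3}


def _check_full_rank(D: np.ndarray, what: str) -> None:
    n, p = D.shape
    if n <= p:
        raise ValueError(
            f"{what}: {n} subjects cannot identify {p} coefficients; "
            "reduce spline_df or add subjects"
        )
    s = np.linalg.svd(D, compute_uv=False)
    if s[-1] < 1e-8 * s[0]:
        # identify the offending column by dropping columns in turn
        for j in range(1, p):
            sub = np.delete(D, j, axis=1)
            ssub = np.linalg.svd(sub, compute_uv=False)
            if ssub[-1] >= 1e-8 * ssub[0]:
                raise ValueError(
                    f"{what}: design matrix is rank deficient; column {j} is "
                    "collinear with the others (e.g., a single sex present)"
                )
        raise ValueError(f"{what}: design matrix is rank deficient")


# ---------------------------------------------------------------------------
# Vertex-level fit and signed Wald statistic
# ---------------------------------------------------------------------------


def fit_vertex_model(
    x_v: np.ndarray, pheno: pd.DataFrame, spec: ModelSpec
) -> VertexFit:
    """Fit the spline GAM at one location by least squares.

    Returns the coefficient vector, its model-based covariance
    sigma^2 (D'D)^-1 (or an HC0 sandwich if ``spec.robust``), and the
    coefficients of the sign-assigning linear regression. A location with
    zero residual variance is flagged degenerate (its statistic is defined
    to be 0 rather than +-inf).
    """
    x_v = np.asarray(x_v, dtype=float)
    pheno = validate_phenotypes(pheno)
    if len(x_v) != len(pheno):
        raise ValueError("measurement vector and phenotype table differ in length")
    D, slices = _gam_design(pheno, spec.spline_df)
    _check_full_rank(D, "GAM fit")
    n, p = D.shape
    coef, _, _, _ = np.linalg.lstsq(D, x_v, rcond=None)
    resid = x_v - D @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    DtD_inv = np.linalg.inv(D.T @ D)
    if spec.robust:
        meat = (D * (resid**2)[:, None]).T @ D
        cov = DtD_inv @ meat @ DtD_inv
    else:
        cov = sigma2 * DtD_inv
    cov = 0.5 * (cov + cov.T)

    L = _linear_design(pheno)
    _check_full_rank(L, "sign-assigning linear fit")
    lin_coef, _, _, _ = np.linalg.lstsq(L, x_v, rcond=None)
    linear = {name: float(lin_coef[j]) for name, j in _LINEAR_COEF_INDEX.items()}

    degenerate = sigma2 <= 1e-12 * max(1.0, float(x_v.var()))
    if float(x_v.var()) == 0.0:
        degenerate = True
    if degenerate:
        warnings.warn(
            "zero residual variance at this location; statistic will be 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
    return VertexFit(
        coefficients=coef,
        covariance=cov,
        residual_df=dof,
        slices=slices,
        linear_coefficients=linear,
        degenerate=degenerate,
    )


def signed_wald(fit: VertexFit, effect: str) -> float:
    """Signed multivariate Wald statistic for one effect.

    Magnitude is the quadratic form theta' Sigma^-1 theta over the effect's
    coefficient block; the sign is that of the corresponding coefficient in
    the plain linear model (age coefficient for effect=age, etc.), with an
    exact zero tied to +1. A singular covariance block is an error; it is
    never silently pseudo-inverted.
    """
    if effect not in _LINEAR_COEF_INDEX:
        raise ValueError(f"unknown effect {effect!r}")
    if fit.degenerate:
        return 0.0
    idx = fit.slices[effect]
    theta = fit.coefficients[idx]
    Sigma = fit.covariance[np.ix_(idx, idx)]
    if np.allclose(theta, 0.0):
        return 0.0
    cond = np.linalg.cond(Sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular covariance block for effect {effect!r} (cond={cond:.3g})"
        )
    w = float(theta @ np.linalg.solve(Sigma, theta))
    sign = 1.0 if fit.linear_coefficients[effect] >= 0.0 else -1.0
    return sign * w


# ---------------------------------------------------------------------------
# Whole-map computation (vectorized across locations)
# ---------------------------------------------------------------------------


def _pearson_map(X: np.ndarray, pheno: pd.DataFrame, effect: str) -> np.ndarray:
    g = effect_covariate(pheno, effect)
    g = g - g.mean()
    gnorm = np.sqrt(g @ g)
    if gnorm == 0.0:
        raise ValueError(f"effect covariate for {effect!r} is constant")
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ g) / (xnorm * gnorm)
    bad = ~np.isfinite(r)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} constant location(s); correlation set to 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
        r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def _ols_wald_map(X: np.ndarray, pheno: pd.DataFrame, effect: str) -> np.ndarray:
    """Signed squared t of the effect coefficient in [1, sex, age, age:sex]."""
    L = _linear_design(pheno)
    _check_full_rank(L, "linear fit")
    n, p = L.shape
    pinv = np.linalg.pinv(L)
    coef = pinv @ X  # (p, V)
    resid = X - L @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    j = _LINEAR_COEF_INDEX[effect]
    var_j = np.linalg.inv(L.T @ L)[j, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        t2 = coef[j] ** 2 / (sigma2 * var_j)
    bad = ~np.isfinite(t2)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} degenerate location(s); statistic set to 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
        t2[bad] = 0.0
    return np.where(coef[j] >= 0.0, 1.0, -1.0) * t2


def _gam_wald_map(
    X: np.ndarray, pheno: pd.DataFrame, effect: str, spline_df: int
) -> np.ndarray:
    """Vectorized GAM + signed Wald over all locations.

    The design is shared across locations, so (D'D)^-1 and the inverse of its
    effect block are computed once; only the residual variance varies by
    location. Agrees with a per-location fit_vertex_model/signed_wald loop.
    """
    D, slices = _gam_design(pheno, spline_df)
    _check_full_rank(D, "GAM fit")
    n, p = D.shape
    pinv = np.linalg.pinv(D)
    coef = pinv @ X  # (p, V)
    resid = X - D @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - p)
    idx = slices[effect]
    A = np.linalg.inv(D.T @ D)[np.ix_(idx, idx)]
    M = np.linalg.inv(A)
    theta = coef[idx]  # (q, V)
    quad = np.einsum("qv,qr,rv->v", theta, M, theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = quad / sigma2
    bad = ~np.isfinite(w)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} degenerate location(s); statistic set to 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
        w[bad] = 0.0

    L = _linear_design(pheno)
    lin_coef = np.linalg.pinv(L) @ X
    sign = np.where(lin_coef[_LINEAR_COEF_INDEX[effect]] >= 0.0, 1.0, -1.0)
    return sign * w


_REGISTRY: dict[str, Callable[[np.ndarray, pd.DataFrame, str], np.ndarray]] = {}


def register_statistic(
    name: str, fn: Callable[[np.ndarray, pd.DataFrame, str], np.ndarray]
) -> None:
    """Register a plug-in statistic: (X, phenotypes, effect) -> signed vector."""
    _REGISTRY[name] = fn


def compute_statistic(
    X: np.ndarray, pheno: pd.DataFrame, spec: ModelSpec
) -> np.ndarray:
    """Dispatch to the statistic named by ``spec.stat_kind``."""
    if spec.stat_kind == "pearson":
        return _pearson_map(X, pheno, spec.effect)
    if spec.stat_kind == "ols_wald":
        return _ols_wald_map(X, pheno, spec.effect)
    if spec.stat_kind == "gam_wald":
        if spec.robust:
            # robust covariance has no shared-design shortcut: per-location loop
            T = np.empty(X.shape[1])
            for v in range(X.shape[1]):
                fit = fit_vertex_model(X[:, v], pheno, spec)
                T[v] = signed_wald(fit, spec.effect)
            return T
        return _gam_wald_map(X, pheno, spec.effect, spec.spline_df)
    fn = _REGISTRY.get(spec.stat_kind)
    if fn is None:
        raise ValueError(f"unknown statistic {spec.stat_kind!r}")
    return np.asarray(fn(X, pheno, spec.effect), dtype=float)


def association_map(
    data: SubjectDataset, spec: ModelSpec, on_error: str = "fail"
) -> AssociationMap:
    """Compute the signed association statistic at every analysis location.

    Deterministic given inputs; output order matches ``data.location_ids``.
    ``on_error`` controls the policy when a location fails: "fail" (default)
    re-raises naming the location, "drop" removes it from the map.
    """
    if on_error not in ("fail", "drop"):
        raise ValueError("on_error must be 'fail' or 'drop'")
    try:
        T = compute_statistic(data.X, data.phenotypes, spec)
    except (ValueError, np.linalg.LinAlgError):
        if on_error == "fail":
            # rerun per location to name the offender
            for v, loc in enumerate(data.location_ids):
                try:
                    compute_statistic(data.X[:, [v]], data.phenotypes, spec)
                except (ValueError, np.linalg.LinAlgError) as exc2:
                    raise RuntimeError(
                        f"statistic failed at location {loc!r}: {exc2}"
                    ) from exc2
            raise
        keep, Ts = [], []
        for v, loc in enumerate(data.location_ids):
            try:
                Ts.append(compute_statistic(data.X[:, [v]], data.phenotypes, spec)[0])
                keep.append(loc)
            except (ValueError, np.linalg.LinAlgError):
                continue
        return AssociationMap(np.asarray(Ts), keep, spec.effect, spec.stat_kind)
    return AssociationMap(T, list(data.location_ids), spec.effect, spec.stat_kind)
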