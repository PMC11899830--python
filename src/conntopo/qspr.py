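"""QSPR statistical battery.

Multiple linear correlation screening, ordinary-least-squares regression with
t-based 95% confidence intervals, leave-one-out cross-validation, and
univariate polynomial structure-property models.

Conventions: the multiple linear correlation (MLC) rho of a descriptor
against two physicochemical properties is the square root of R^2 of the OLS
fit *of the descriptor on the properties* (with intercept) — the direction
used in the benzenoid screening study this package reproduces.  The standard
error of estimate uses the residual degrees of freedom n - p - 1, and the F
statistic is the usual overall-significance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .indices import DescriptorSpec, registry_position, spec_from_name

__all__ = [
    "QsprError",
    "MLCResult",
    "RegressionFit",
    "CrossValidationResult",
    "R2Grid",
    "multiple_correlation",
    "fit_mlr",
    "loocv_rmse",
    "fit_polynomial",
    "rank_by_mlc",
    "r2_grid",
    "screening_report",
]


class QsprError(ValueError):
    """A regression problem is ill-posed (collinear, degenerate, too small)."""


@dataclass(frozen=True)
class MLCResult:
    """Multiple correlation coefficient rho in [0, 1] of one descriptor
    regressed on the two test properties."""

    descriptor: DescriptorSpec | str
    rho: float
    n: int

    @property
    def label(self) -> str:
        return self.descriptor if isinstance(self.descriptor, str) else self.descriptor.name


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit: coefficients (intercept first), symmetric 95% CI
    half-widths, R^2, r, standard error of estimate s, F statistic."""

    coefficients: np.ndarray
    ci95: np.ndarray
    r_squared: float
    s: float
    f: float
    n: int
    p: int
    term_names: Tuple[str, ...] = field(default=())

    @property
    def r(self) -> float:
        return float(np.sqrt(self.r_squared))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.coefficients[0] + X @ self.coefficients[1:]

    def summary(self) -> str:
        names = self.term_names or ("intercept",) + tuple(
            f"x{i}" for i in range(1, self.p + 1))
        lines = [
            f"OLS fit: n={self.n}, p={self.p}",
            f"  r^2 = {self.r_squared:.4f}   r = {self.r:.4f}",
            f"  s = {self.s:.4f}   F = {self.f:.4f}",
        ]
        for name, b, w in zip(names, self.coefficients, self.ci95):
            lines.append(f"  {name:>12s} = {b:+.6g} +/- {w:.6g} (95% CI)")
        return "\n".join(lines)


@dataclass(frozen=True)
class CrossValidationResult:
    """Root mean squared error of held-out predictions under LOOCV."""

    descriptor: DescriptorSpec | str | None
    loocv_rmse: float
    n: int


def _design(predictors: Sequence[Sequence[float]], n: int) -> np.ndarray:
    cols = [np.asarray(c, dtype=float) for c in predictors]
    for c in cols:
        if c.shape != (n,):
            raise QsprError("predictor columns must match the response length")
    return np.column_stack([np.ones(n)] + cols)


def _ols(y: np.ndarray, X: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise QsprError("rank-deficient design (collinear predictors)")
    model = sm.OLS(y, X)
    return model.fit()


def multiple_correlation(y: Sequence[float], x1: Sequence[float],
                         x2: Sequence[float],
                         descriptor: DescriptorSpec | str = "") -> MLCResult:
    """MLC rho = sqrt(R^2) of the OLS fit of y on (1, x1, x2).

    Equivalently expressible through the three pairwise Pearson correlations;
    the OLS route is used here and the closed form serves as an independent
    cross-check in the test suite.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise QsprError(f"need at least 4 samples, got {n}")
    if np.ptp(y) == 0:
        raise QsprError("response has zero variance")
    X = _design([x1, x2], n)
    if np.linalg.matrix_rank(X) < 3:
        raise QsprError("collinear predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    rho = float(np.sqrt(max(r2, 0.0)))
    return MLCResult(descriptor=descriptor, rho=rho, n=n)


def fit_mlr(y: Sequence[float], predictors: Sequence[Sequence[float]],
            term_names: Sequence[str] = ()) -> RegressionFit:
    """OLS of y on the given predictor columns, with intercept.

    Returns coefficients, t-based 95% confidence half-widths, R^2, the
    standard error of estimate s (denominator n - p - 1) and the F statistic.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    p = len(predictors)
    if n <= p + 1:
        raise QsprError(f"need n > p + 1 (n={n}, p={p})")
    X = _design(predictors, n)
    res = _ols(y, X)
    ci = res.conf_int(alpha=0.05)
    half = (ci[:, 1] - ci[:, 0]) / 2.0
    s = float(np.sqrt(res.ssr / res.df_resid))
    names = ("intercept",) + tuple(term_names) if term_names else ()
    return RegressionFit(
        coefficients=np.asarray(res.params, dtype=float),
        ci95=np.asarray(half, dtype=float),
        r_squared=float(res.rsquared),
        s=s,
        f=float(res.fvalue),
        n=n, p=p,
        term_names=tuple(names),
    )


def loocv_rmse(y: Sequence[float], predictors: Sequence[Sequence[float]],
               descriptor: DescriptorSpec | str | None = None) -> CrossValidationResult:
    """Leave-one-out cross-validation RMSE of the OLS model.

    Each sample is predicted from a model refit on the remaining n - 1; the
    algebraically equivalent hat-matrix shortcut residual/(1 - leverage) is
    kept out of this routine so the two can check each other in tests.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    p = len(predictors)
    if n <= p + 2:
        raise QsprError(f"need n > p + 2 (n={n}, p={p})")
    X = _design(predictors, n)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise QsprError("rank-deficient design (collinear predictors)")
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xi, yi = X[mask], y[mask]
        if np.linalg.matrix_rank(Xi) < X.shape[1]:
            raise QsprError(f"leave-one-out design without sample {i} is rank-deficient")
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        errs[i] = y[i] - X[i] @ beta
    rmse = float(np.sqrt(np.mean(errs ** 2)))
    return CrossValidationResult(descriptor=descriptor, loocv_rmse=rmse, n=n)


def fit_polynomial(y: Sequence[float], x: Sequence[float], degree: int,
                   cond_warn: float = 1e10) -> RegressionFit:
    """Univariate polynomial OLS model y ~ 1 + x + ... + x^degree.

    Raw powers (not orthogonal polynomials) are used so the reported
    coefficients read directly as the printed model equations; a condition
    number above ``cond_warn`` triggers a warning.
    """
    if degree not in (1, 2, 3):
        raise QsprError(f"degree must be 1, 2 or 3, got {degree}")
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise QsprError(
            f"degenerate x: need at least {degree + 1} distinct values for degree {degree}")
    powers = [x ** d for d in range(1, degree + 1)]
    cond = np.linalg.cond(_design(powers, x.shape[0]))
    if cond > cond_warn:
        warnings.warn(f"ill-conditioned polynomial design (cond={cond:.3g})",
                      stacklevel=2)
    names = tuple(f"x^{d}" if d > 1 else "x" for d in range(1, degree + 1))
    return fit_mlr(y, powers, term_names=names)


def rank_by_mlc(results: Sequence[MLCResult], k: int) -> List[MLCResult]:
    """Top-k descriptors by descending rho; ties broken by registry order."""
    if not results:
        raise QsprError("no MLC results to rank")
    if k < 1:
        raise QsprError("k must be positive")
    if k > len(results):
        warnings.warn(f"k={k} exceeds the {len(results)} available results; "
                      "returning all", stacklevel=2)
        k = len(results)

    def tie_key(item):
        pos, r = item
        reg = registry_position(r.descriptor) if isinstance(r.descriptor, DescriptorSpec) else pos
        return (-r.rho, reg, pos)

    ranked = sorted(enumerate(results), key=tie_key)
    return [r for _, r in ranked[:k]]


@dataclass
class R2Grid:
    """R^2 of the degree-1/2/3 polynomial model for every (descriptor,
    property) pair; cells whose fit failed are NaN with the reason recorded."""

    tables: Dict[int, pd.DataFrame]
    failures: List[Tuple[str, str, int, str]]

    def to_frames(self) -> Dict[int, pd.DataFrame]:
        return self.tables


def screening_report(descriptors: pd.DataFrame, properties: pd.DataFrame,
                     mlc_targets: Tuple[str, str] = ("bp", "hf"),
                     top_k: int = 5, loocv: bool = True,
                     poly_degrees: Sequence[int] = ()) -> Dict[str, pd.DataFrame]:
    """The full descriptor-screening battery as a set of report tables.

    Every descriptor column is screened by its MLC against the two target
    property columns; the top-k descriptors get full two-predictor OLS models
    with 95% CIs and (optionally) LOOCV RMSEs; if ``poly_degrees`` is given,
    per-degree univariate R^2 grids over *all* property columns are added.

    Returns a dict with keys ``mlc``, ``ranking``, ``mlr``, ``loocv`` and
    ``r2_degree{d}``.
    """
    missing = set(descriptors.index) ^ set(properties.index)
    if missing:
        raise QsprError(f"compound sets misaligned: {sorted(missing)[:5]}")
    props = properties.loc[descriptors.index]
    x1 = props[mlc_targets[0]].to_numpy(dtype=float)
    x2 = props[mlc_targets[1]].to_numpy(dtype=float)

    mlcs = []
    for col in descriptors.columns:
        y = descriptors[col].to_numpy(dtype=float)
        try:
            spec = spec_from_name(col)
        except ValueError:
            spec = col
        mlcs.append(multiple_correlation(y, x1, x2, descriptor=spec))
    mlc_df = pd.DataFrame({"descriptor": [r.label for r in mlcs],
                           "rho": [r.rho for r in mlcs]}).set_index("descriptor")

    top = rank_by_mlc(mlcs, top_k)
    rank_df = pd.DataFrame({
        "position": range(1, len(top) + 1),
        "descriptor": [r.label for r in top],
        "rho": [r.rho for r in top],
    }).set_index("position")

    mlr_rows, cv_rows = [], []
    for r in top:
        y = descriptors[r.label].to_numpy(dtype=float)
        fit = fit_mlr(y, [x1, x2], term_names=mlc_targets)
        row = {"descriptor": r.label, "r_squared": fit.r_squared, "s": fit.s,
               "f": fit.f, "intercept": fit.coefficients[0],
               "intercept_ci95": fit.ci95[0]}
        for i, t in enumerate(mlc_targets, start=1):
            row[f"coef_{t}"] = fit.coefficients[i]
            row[f"coef_{t}_ci95"] = fit.ci95[i]
        mlr_rows.append(row)
        if loocv:
            cv = loocv_rmse(y, [x1, x2], descriptor=r.descriptor)
            cv_rows.append({"descriptor": r.label, "loocv_rmse": cv.loocv_rmse})
    out = {"mlc": mlc_df, "ranking": rank_df,
           "mlr": pd.DataFrame(mlr_rows).set_index("descriptor")}
    if loocv:
        out["loocv"] = pd.DataFrame(cv_rows).set_index("descriptor")
    if poly_degrees:
        grid = r2_grid(props, descriptors, degrees=tuple(poly_degrees))
        for d, tab in grid.tables.items():
            out[f"r2_degree{d}"] = tab
    return out


def r2_grid(properties: pd.DataFrame, descriptors: pd.DataFrame,
            degrees: Sequence[int] = (1, 2, 3)) -> R2Grid:
    """Polynomial-model R^2 grid shaped like the published per-degree tables:
    one row per descriptor, one column per property, one table per degree.

    ``properties`` and ``descriptors`` are compound-indexed DataFrames and
    must align on the same compound set.
    """
    if set(properties.index) != set(descriptors.index):
        missing = set(properties.index) ^ set(descriptors.index)
        raise QsprError(f"compound sets misaligned: {sorted(missing)[:5]}")
    props = properties.loc[descriptors.index]
    tables = {}
    failures = []
    for deg in degrees:
        tab = pd.DataFrame(index=descriptors.columns, columns=properties.columns,
                           dtype=float)
        for dname in descriptors.columns:
            x = descriptors[dname].astype(float).to_numpy()
            for pname in properties.columns:
                y = props[pname].astype(float).to_numpy()
                try:
                    tab.loc[dname, pname] = fit_polynomial(y, x, deg).r_squared
                except QsprError as exc:
                    tab.loc[dname, pname] = np.nan
                    failures.append((dname, pname, deg, str(exc)))
        tables[deg] = tab
    return R2Grid(tables=tables, failures=failures)
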