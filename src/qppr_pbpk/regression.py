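"""Multilinear regression engine for the clearance QPPR.

Ordinary least squares with the classical diagnostics used in QSAR/QPPR
practice: stepwise predictor selection on partial-F p-values, leave-one-out
cross-validated Q², variance inflation factors, 95% confidence intervals of
the mean response at a new descriptor vector, and an applicability-domain
box check.

Q² follows the cross-validation convention

    Q² = 1 - PRESS / SSY

with PRESS the sum of squared leave-one-out prediction errors (each point
predicted by a model refit without it) and SSY the mean-centered total sum
of squares of the response.  Under this convention Q² <= R² always.

The confidence interval of the mean response at descriptor vector x0 uses
the hat-leverage formula: half-width = t_{(1+level)/2, n-p-1} * s *
sqrt(x0' (X'X)^-1 x0), with x0 carrying the intercept entry.  This is the
uncertainty of the mean prediction, not a prediction interval for a new
observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionFit",
    "PredictionInterval",
    "DomainBox",
    "fit_multilinear",
    "stepwise_select",
    "loo_q2",
    "vif",
    "predict_mean_ci",
    "check_domain",
    "normality_plot_data",
]


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit with the diagnostics needed for CI propagation.

    ``coefficients[0]`` is the intercept; the remaining entries follow
    ``predictor_names``.  ``xtx_inverse`` is (X'X)^-1 for the design with
    intercept column, kept so mean-response confidence intervals can be
    computed at arbitrary descriptor vectors.
    """

    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    coef_standard_errors: np.ndarray
    coef_p_values: np.ndarray
    r2: float
    r2_adj: float
    q2: float
    s: float                 # standard error of the estimate, log units
    f_stat: float
    f_p_value: float
    vifs: np.ndarray         # per predictor (no intercept entry)
    xtx_inverse: np.ndarray
    n: int
    residuals: np.ndarray
    selection_trace: tuple[str, ...] = ()

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_predictors - 1

    def predict(self, x0: Sequence[float]) -> float:
        """Point prediction at a bare descriptor vector (no intercept)."""
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (self.n_predictors,):
            raise ValueError(
                f"descriptor vector has shape {x0.shape}, expected "
                f"({self.n_predictors},) for {self.predictor_names}")
        return float(self.coefficients[0] + x0 @ self.coefficients[1:])


@dataclass(frozen=True)
class PredictionInterval:
    """Mean-response point estimate with its confidence bounds (log10)."""

    point: float
    lmci: float
    umci: float
    level: float = 0.95
    in_domain: bool = True

    def __post_init__(self) -> None:
        if not (self.lmci <= self.point <= self.umci):
            raise ValueError("bounds must bracket the point estimate")

    @property
    def width(self) -> float:
        return self.umci - self.lmci


@dataclass(frozen=True)
class DomainBox:
    """Per-descriptor [min, max] applicability ranges (closed intervals)."""

    ranges: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"domain range for {k} has min > max")


def _design(records, predictor_names):
    """(X with intercept, y) from (descriptor-mapping, response) pairs."""
    rows, y = [], []
    for desc, resp in records:
        rows.append([float(desc[p]) for p in predictor_names])
        y.append(float(resp))
    X = np.column_stack([np.ones(len(rows)), np.asarray(rows)])
    return X, np.asarray(y)


def fit_multilinear(records: Sequence[tuple[Mapping[str, float], float]],
                    predictor_names: Sequence[str],
                    compute_q2: bool = True) -> RegressionFit:
    """OLS of the response on the named descriptors, with diagnostics.

    ``records`` are (descriptor-mapping, response) pairs; the response is
    log10 intrinsic clearance in this package's use, but the engine is
    generic.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    predictor_names = tuple(predictor_names)
    X, y = _design(records, predictor_names)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError(f"need n > p+1 (= {p1}) observations, got {n}")
    if np.linalg.matrix_rank(X) < p1:
        # identify which predictor is linearly dependent on the rest
        dep = []
        for j in range(1, p1):
            others = np.delete(X, j, axis=1)
            r = X[:, j] - others @ np.linalg.lstsq(others, X[:, j],
                                                   rcond=None)[0]
            if np.allclose(r, 0, atol=1e-10 * max(1.0, np.abs(X[:, j]).max())):
                dep.append(predictor_names[j - 1])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: "
            f"{dep or 'intercept-related'}")

    res = sm.OLS(y, X).fit()
    xtx_inv = np.linalg.inv(X.T @ X)
    vifs = (vif([dict(zip(predictor_names, row)) for row in X[:, 1:]],
                predictor_names)
            if len(predictor_names) >= 2 else
            np.ones(len(predictor_names)))
    q2 = (loo_q2(records, predictor_names)
          if compute_q2 and n >= p1 + 2 else np.nan)
    return RegressionFit(
        predictor_names=predictor_names,
        coefficients=np.asarray(res.params),
        coef_standard_errors=np.asarray(res.bse),
        coef_p_values=np.asarray(res.pvalues),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        q2=q2,
        s=float(np.sqrt(res.mse_resid)),
        f_stat=float(res.fvalue),
        f_p_value=float(res.f_pvalue),
        vifs=np.asarray(vifs),
        xtx_inverse=xtx_inv,
        n=n,
        residuals=np.asarray(res.resid),
    )


def stepwise_select(records, candidate_descriptors: Sequence[str],
                    p_enter: float = 0.05,
                    p_remove: float = 0.10) -> RegressionFit:
    """Forward-entry / backward-removal predictor selection.

    At each step the unselected candidate with the smallest partial-t
    p-value below ``p_enter`` is added (ties broken by candidate order),
    then any selected predictor whose p-value exceeds ``p_remove`` is
    dropped, worst first.  Deterministic given the candidate order.  If no
    candidate ever passes entry, an intercept-only fit is returned with an
    empty predictor tuple and a trace recording the failure.
    """
    if not candidate_descriptors:
        raise ValueError("candidate_descriptors must be non-empty")
    if not p_enter < p_remove:
        raise ValueError("need p_enter < p_remove for a stable procedure")
    selected: list[str] = []
    trace: list[str] = []
    while True:
        changed = False
        best_name, best_p = None, p_enter
        for cand in candidate_descriptors:
            if cand in selected:
                continue
            trial = fit_multilinear(records, selected + [cand],
                                    compute_q2=False)
            p = trial.coef_p_values[-1]
            if p < best_p:
                best_name, best_p = cand, p
        if best_name is not None:
            selected.append(best_name)
            trace.append(f"enter:{best_name}(p={best_p:.3g})")
            changed = True
        while selected:
            fit = fit_multilinear(records, selected, compute_q2=False)
            ps = fit.coef_p_values[1:]
            worst = int(np.argmax(ps))
            if ps[worst] > p_remove:
                trace.append(f"remove:{selected[worst]}(p={ps[worst]:.3g})")
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        trace.append("no-candidate-entered")
        X, y = _design(records, ())
        resid = y - y.mean()
        fit = RegressionFit(
            predictor_names=(), coefficients=np.array([y.mean()]),
            coef_standard_errors=np.array([resid.std(ddof=1)
                                           / np.sqrt(len(y))]),
            coef_p_values=np.array([np.nan]), r2=0.0, r2_adj=0.0, q2=np.nan,
            s=float(resid.std(ddof=1)), f_stat=np.nan, f_p_value=np.nan,
            vifs=np.array([]), xtx_inverse=np.array([[1.0 / len(y)]]),
            n=len(y), residuals=resid, selection_trace=tuple(trace))
        return fit
    final = fit_multilinear(records, selected)
    return RegressionFit(**{**final.__dict__,
                            "selection_trace": tuple(trace)})


def loo_q2(records, predictor_names: Sequence[str]) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS/SSY.

    Each observation is predicted from an OLS refit on the remaining n-1;
    SSY is mean-centered over the full response.
    """
    predictor_names = tuple(predictor_names)
    X, y = _design(records, predictor_names)
    n = len(y)
    if n < len(predictor_names) + 3:
        raise ValueError("need n >= p+3 for leave-one-out cross-validation")
    ssy = float(((y - y.mean()) ** 2).sum())
    if ssy == 0:
        raise ValueError("degenerate response: SSY = 0")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
        press += (y[i] - X[i] @ beta) ** 2
    return 1.0 - press / ssy


def vif(descriptor_rows: Sequence[Mapping[str, float]],
        predictor_names: Sequence[str]) -> np.ndarray:
    """Variance inflation factors, VIF_i = 1/(1 - R_i²).

    R_i² is from regressing descriptor i on the other descriptors (with
    intercept).  Perfect collinearity yields ``inf``.
    """
    predictor_names = tuple(predictor_names)
    if len(predictor_names) < 2:
        raise ValueError("VIF needs at least two predictors")
    M = np.asarray([[float(r[p]) for p in predictor_names]
                    for r in descriptor_rows])
    out = np.empty(len(predictor_names))
    for j in range(len(predictor_names)):
        xj = M[:, j]
        others = np.column_stack([np.ones(len(M)),
                                  np.delete(M, j, axis=1)])
        resid = xj - others @ np.linalg.lstsq(others, xj, rcond=None)[0]
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        ss_res = float(resid @ resid)
        r2j = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2j >= 1.0 else 1.0 / (1.0 - r2j)
    return out


def predict_mean_ci(fit: RegressionFit, x0: Sequence[float],
                    level: float = 0.95,
                    box: "DomainBox | None" = None) -> PredictionInterval:
    """95% (by default) confidence interval of the mean response at x0.

    ``x0`` is the bare descriptor vector in ``fit.predictor_names`` order.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (fit.n_predictors,):
        raise ValueError(
            f"descriptor vector has shape {x0.shape}, expected "
            f"({fit.n_predictors},)")
    xa = np.concatenate([[1.0], x0])
    point = float(xa @ fit.coefficients)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.df_resid)
    half = tq * fit.s * float(np.sqrt(xa @ fit.xtx_inverse @ xa))
    in_dom = True
    if box is not None:
        in_dom = check_domain(dict(zip(fit.predictor_names, x0)),
                              box)["overall"]
    return PredictionInterval(point=point, lmci=point - half,
                              umci=point + half, level=level,
                              in_domain=in_dom)


def check_domain(x0: Mapping[str, float], box: DomainBox) -> dict:
    """Closed-interval membership per descriptor plus an overall flag."""
    flags = {}
    for name, (lo, hi) in box.ranges.items():
        v = float(x0[name])
        flags[name] = bool(lo <= v <= hi)
    flags["overall"] = all(flags.values())
    return flags


def normality_plot_data(residuals: Sequence[float]) -> np.ndarray:
    """Paired (observed, expected) cumulative probabilities of residuals.

    Residuals are standardized, ranked, and given Blom plotting positions
    (i - 3/8)/(n + 1/4) for the observed cumulative probability; the
    expected probability is the standard-normal CDF at the standardized
    value.  Returns an (n, 2) array sorted ascending, suitable for a
    normal-probability plot.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance residuals")
    z = np.sort((r - r.mean()) / sd)
    n = len(z)
    observed = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    expected = stats.norm.cdf(z)
    return np.column_stack([observed, expected])
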