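"""Dose-response fitting and IC50 meta-analysis on normalised viability.

Two curve families are supported on the log10-concentration axis:

* four-parameter logistic (4PL), the standard monophasic model
      Y = bottom + (top - bottom) / (1 + 10^((logIC50 - X) * hill))
* a biphasic two-site mixture for heterogeneous populations
      Y = bottom + (top - bottom) * [ frac / (1 + 10^((logIC50_1 - X) * nH1))
                                    + (1 - frac) / (1 + 10^((logIC50_2 - X) * nH2)) ]

With this parameterisation Y -> top as X -> +inf for positive slopes, so
decreasing viability curves carry negative Hill slopes.  Fits are unweighted
least squares with asymptotic t-based 95% confidence intervals; replicates
enter as individual points so the residual degrees of freedom are preserved
for the extra-sum-of-squares F-test.

IC50s from several experimental runs can be combined three ways: pooling all
points into a single fit, averaging per-run logIC50s (the geometric mean of
the IC50s), or refitting all runs with a single shared logIC50 and testing
that constraint with an extra-sum-of-squares F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

HILL_MIN, HILL_MAX = 0.1, 10.0  # |hill| bounds


@dataclass
class DoseResponsePoint:
    """One normalised viability measurement at a positive drug concentration."""

    concentration_uM: float
    viability_pct: float
    run_id: str = "run1"
    replicate: int = 0

    @property
    def X(self) -> float:
        return math.log10(self.concentration_uM)


@dataclass
class FitResult:
    """Least-squares dose-response fit with asymptotic uncertainty."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    ss_residual: float
    df: int
    r2: float
    converged: bool
    n_points: int
    message: str = ""

    @property
    def logIC50(self) -> float:
        if self.model == "4pl":
            return self.params["logIC50"]
        raise AttributeError("biphasic fits expose logIC50_1 / logIC50_2")

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "ss_residual": self.ss_residual,
            "df": self.df,
            "r2": self.r2,
            "converged": self.converged,
            "n_points": self.n_points,
            "message": self.message,
        }

    def summary(self) -> str:
        if not self.converged:
            return f"{self.model} fit DID NOT CONVERGE ({self.message})"
        if self.model == "4pl":
            lo, hi = self.ci95["logIC50"]
            return (f"4PL IC50 = {10 ** self.params['logIC50']:.3g} uM "
                    f"(95% CI {10 ** lo:.3g}-{10 ** hi:.3g}), "
                    f"hill = {self.params['hill']:.2f}, R2 = {self.r2:.3f}")
        return (f"biphasic IC50_1 = {10 ** self.params['logIC50_1']:.3g} uM, "
                f"IC50_2 = {10 ** self.params['logIC50_2']:.3g} uM, "
                f"frac = {self.params['frac']:.2f}, R2 = {self.r2:.3f}")


@dataclass
class CombinedIC50:
    """Cross-run IC50 combination result (logIC50 scale, base-10)."""

    method: str
    logIC50: float
    ci95: tuple[float, float]
    f_statistic: float | None = None
    p_value: float | None = None
    runs_differ: bool | None = None
    per_run_logIC50: list[float] = field(default_factory=list)

    @property
    def ic50(self) -> float:
        return 10.0 ** self.logIC50

    def as_dict(self) -> dict:
        return {
            "method": self.method, "logIC50": self.logIC50,
            "ic50_uM": self.ic50, "ci95_logIC50": list(self.ci95),
            "f_statistic": self.f_statistic, "p_value": self.p_value,
            "runs_differ": self.runs_differ,
            "per_run_logIC50": self.per_run_logIC50,
        }

    def summary(self) -> str:
        lo, hi = self.ci95
        s = (f"IC50 = {self.ic50:.3g} uM "
             f"(95% CI {10 ** lo:.3g}-{10 ** hi:.3g} uM)")
        if self.f_statistic is not None:
            s += (f", F = {self.f_statistic:.3f}, p = {self.p_value:.3g}"
                  + (" *runs differ*" if self.runs_differ else ""))
        return s


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def model_4pl(X, top: float, bottom: float, logIC50: float, hill: float):
    """Four-parameter logistic response at log10 concentration X."""
    X = np.asarray(X, dtype=float)
    y = bottom + (top - bottom) / (1.0 + 10.0 ** ((logIC50 - X) * hill))
    return float(y) if y.ndim == 0 else y


def model_biphasic(X, top: float, bottom: float, frac: float,
                   logIC50_1: float, logIC50_2: float,
                   nH1: float, nH2: float):
    """Two-site logistic mixture response at log10 concentration X."""
    X = np.asarray(X, dtype=float)
    y = bottom + (top - bottom) * (
        frac / (1.0 + 10.0 ** ((logIC50_1 - X) * nH1))
        + (1.0 - frac) / (1.0 + 10.0 ** ((logIC50_2 - X) * nH2)))
    return float(y) if y.ndim == 0 else y


# ---------------------------------------------------------------------------
# Input handling
# ---------------------------------------------------------------------------

def _xy(points) -> tuple[np.ndarray, np.ndarray]:
    """Extract (log10 concentration, viability %) arrays from any input form.

    Accepts a DataFrame with concentration_uM/viability_pct columns, a
    sequence of DoseResponsePoint, or an (x_log10, y) pair of arrays.
    Zero-concentration (vehicle) points are normalisation anchors, never fit
    points, and are excluded here.
    """
    if isinstance(points, pd.DataFrame):
        conc = points["concentration_uM"].to_numpy(dtype=float)
        y = points["viability_pct"].to_numpy(dtype=float)
        keep = conc > 0
        return np.log10(conc[keep]), y[keep]
    if isinstance(points, tuple) and len(points) == 2:
        x, y = (np.asarray(a, dtype=float) for a in points)
        return x, y
    pts = list(points)
    if pts and isinstance(pts[0], DoseResponsePoint):
        pts = [p for p in pts if p.concentration_uM > 0]
        return (np.array([p.X for p in pts]),
                np.array([p.viability_pct for p in pts]))
    raise TypeError("points must be a DataFrame, DoseResponsePoint sequence "
                    "or (log10_concentration, viability) arrays")


def _orientation(x: np.ndarray, y: np.ndarray) -> int:
    """+1 for responses rising with concentration, -1 for falling."""
    order = np.argsort(x)
    k = max(1, len(x) // 4)
    lo = y[order[:k]].mean()
    hi = y[order[-k:]].mean()
    return 1 if hi >= lo else -1


def _ci_from_cov(popt: np.ndarray, pcov: np.ndarray, df: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    tq = stats.t.ppf(0.975, df) if df > 0 else np.nan
    return se, np.column_stack([popt - tq * se, popt + tq * se])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_4pl(points, *, pin_bottom: float | None = None) -> FitResult:
    """Fit the four-parameter logistic model by unweighted least squares.

    Initialisation: top/bottom from the mean response at the extreme
    concentrations, logIC50 at the concentration whose mean response is
    closest to mid-range, |hill| = 1 with the sign set by the data's
    orientation.  ``pin_bottom`` fixes the bottom plateau (e.g. at 0 on the
    normalised scale) and frees one degree of freedom.

    Non-convergence is reported via ``converged=False``, never silently.
    """
    x, y = _xy(points)
    if np.unique(x).size < 5:
        raise ValueError("4PL fit needs >= 5 distinct positive concentrations")
    sign = _orientation(x, y)
    order = np.argsort(x)
    y_lo_end = y[order][: max(1, len(x) // 4)].mean()
    y_hi_end = y[order][-max(1, len(x) // 4):].mean()
    top0 = max(y_lo_end, y_hi_end)
    bottom0 = min(y_lo_end, y_hi_end)
    mid = (top0 + bottom0) / 2.0
    logic0 = float(x[np.argmin(np.abs(y - mid))])
    span = (x.min() - 3.0, x.max() + 3.0)
    hill_lb, hill_ub = (HILL_MIN, HILL_MAX) if sign > 0 else (-HILL_MAX, -HILL_MIN)

    if pin_bottom is None:
        p0 = [top0, bottom0, logic0, sign * 1.0]
        lb = [-np.inf, -np.inf, span[0], hill_lb]
        ub = [np.inf, np.inf, span[1], hill_ub]
        fun = model_4pl
        names = ["top", "bottom", "logIC50", "hill"]
    else:
        b = float(pin_bottom)
        p0 = [top0, logic0, sign * 1.0]
        lb = [-np.inf, span[0], hill_lb]
        ub = [np.inf, span[1], hill_ub]
        fun = lambda X, top, logIC50, hill: model_4pl(X, top, b, logIC50, hill)
        names = ["top", "logIC50", "hill"]

    df = len(x) - len(p0)
    if df <= 0:
        raise ValueError("not enough points for the free parameters")
    try:
        popt, pcov = optimize.curve_fit(fun, x, y, p0=p0, bounds=(lb, ub),
                                        maxfev=20000)
        converged, message = True, ""
    except RuntimeError as exc:
        return FitResult(model="4pl", params=dict(zip(names, p0)),
                         se={}, ci95={}, ss_residual=math.nan, df=df,
                         r2=math.nan, converged=False, n_points=len(x),
                         message=str(exc))
    resid = y - fun(x, *popt)
    ss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    se, ci = _ci_from_cov(popt, pcov, df)
    params = dict(zip(names, map(float, popt)))
    if pin_bottom is not None:
        params["bottom"] = float(pin_bottom)
    return FitResult(
        model="4pl", params=params,
        se=dict(zip(names, map(float, se))),
        ci95={n: (float(c[0]), float(c[1])) for n, c in zip(names, ci)},
        ss_residual=ss, df=df, r2=1.0 - ss / sst if sst > 0 else 1.0,
        converged=converged, n_points=len(x), message=message,
    )


def fit_biphasic(points) -> FitResult:
    """Fit the two-site biphasic model by unweighted least squares.

    Initialisation: shared plateaus from the extreme concentrations,
    frac = 0.5, the two logIC50s at the 25th/75th percentile log
    concentrations, |nH| = 1 with the data's orientation.  After fitting,
    the sites are ordered so that logIC50_1 < logIC50_2 (swapping frac to
    1 - frac as needed).
    """
    x, y = _xy(points)
    if np.unique(x).size < 8:
        raise ValueError("biphasic fit needs >= 8 distinct concentrations "
                         "(7 free parameters)")
    sign = _orientation(x, y)
    order = np.argsort(x)
    k = max(1, len(x) // 4)
    y_lo_end, y_hi_end = y[order][:k].mean(), y[order][-k:].mean()
    top0, bottom0 = max(y_lo_end, y_hi_end), min(y_lo_end, y_hi_end)
    xq = np.unique(x)
    l1_0, l2_0 = np.percentile(xq, 25), np.percentile(xq, 75)
    span = (x.min() - 3.0, x.max() + 3.0)
    hill_lb, hill_ub = (HILL_MIN, HILL_MAX) if sign > 0 else (-HILL_MAX, -HILL_MIN)

    names = ["top", "bottom", "frac", "logIC50_1", "logIC50_2", "nH1", "nH2"]
    p0 = [top0, bottom0, 0.5, l1_0, l2_0, sign * 1.0, sign * 1.0]
    lb = [-np.inf, -np.inf, 0.0, span[0], span[0], hill_lb, hill_lb]
    ub = [np.inf, np.inf, 1.0, span[1], span[1], hill_ub, hill_ub]
    df = len(x) - len(p0)
    if df <= 0:
        raise ValueError("not enough points for the free parameters")
    try:
        popt, pcov = optimize.curve_fit(model_biphasic, x, y, p0=p0,
                                        bounds=(lb, ub), maxfev=40000)
        converged, message = True, ""
    except RuntimeError as exc:
        return FitResult(model="biphasic", params=dict(zip(names, p0)),
                         se={}, ci95={}, ss_residual=math.nan, df=df,
                         r2=math.nan, converged=False, n_points=len(x),
                         message=str(exc))
    se, ci = _ci_from_cov(popt, pcov, df)
    params = dict(zip(names, map(float, popt)))
    ses = dict(zip(names, map(float, se)))
    cis = {n: (float(c[0]), float(c[1])) for n, c in zip(names, ci)}
    if params["logIC50_1"] > params["logIC50_2"]:  # identifiability ordering
        swap = {"logIC50_1": "logIC50_2", "logIC50_2": "logIC50_1",
                "nH1": "nH2", "nH2": "nH1"}
        params = {n: params[swap.get(n, n)] for n in names}
        ses = {n: ses[swap.get(n, n)] for n in names}
        cis = {n: cis[swap.get(n, n)] for n in names}
        params["frac"] = 1.0 - params["frac"]
    resid = y - model_biphasic(x, *[params[n] for n in names])
    ss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    return FitResult(
        model="biphasic", params=params, se=ses, ci95=cis,
        ss_residual=ss, df=df, r2=1.0 - ss / sst if sst > 0 else 1.0,
        converged=converged, n_points=len(x), message=message,
    )


def ftest_nested(simple: FitResult, complex_: FitResult,
                 alpha: float = 0.05) -> tuple[float, float, bool]:
    """Extra-sum-of-squares F-test between nested fits on the same points.

    Returns (F, p, prefer_complex): the richer model is preferred only when
    its SS reduction is larger than chance at level ``alpha``.
    """
    if simple.df <= complex_.df:
        raise ValueError("the first fit must be the simpler (higher-df) model")
    d_df = simple.df - complex_.df
    if complex_.ss_residual <= 0 or complex_.df <= 0:
        return math.nan, math.nan, False
    num = max(simple.ss_residual - complex_.ss_residual, 0.0) / d_df
    den = complex_.ss_residual / complex_.df
    f = num / den
    p = float(stats.f.sf(f, d_df, complex_.df))
    return float(f), p, bool(p < alpha)


# ---------------------------------------------------------------------------
# Cross-run combination
# ---------------------------------------------------------------------------

def _shared_logic50_fit(runs_xy: list[tuple[np.ndarray, np.ndarray]],
                        sep_fits: list[FitResult]
                        ) -> tuple[float, float, float, int]:
    """Global 4PL fit with one shared logIC50 across runs.

    Returns (logIC50, its SE, residual SS, residual df).  Each run keeps its
    own top/bottom/hill; only logIC50 is tied.
    """
    k = len(runs_xy)
    logic0 = float(np.mean([f.params["logIC50"] for f in sep_fits]))
    theta0 = [logic0]
    lb, ub = [-np.inf], [np.inf]
    for f in sep_fits:
        p = f.params
        theta0 += [p["top"], p["bottom"], p["hill"]]
        sign = 1.0 if p["hill"] >= 0 else -1.0
        lb += [-np.inf, -np.inf, HILL_MIN if sign > 0 else -HILL_MAX]
        ub += [np.inf, np.inf, HILL_MAX if sign > 0 else -HILL_MIN]

    def resid(theta: np.ndarray) -> np.ndarray:
        logic = theta[0]
        out = []
        for i, (x, y) in enumerate(runs_xy):
            top, bottom, hill = theta[1 + 3 * i: 4 + 3 * i]
            out.append(y - model_4pl(x, top, bottom, logic, hill))
        return np.concatenate(out)

    sol = optimize.least_squares(resid, theta0, bounds=(lb, ub))
    n_total = sum(len(x) for x, _ in runs_xy)
    df = n_total - (3 * k + 1)
    ss = float(2.0 * sol.cost)
    # asymptotic covariance from the Jacobian at the solution
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (ss / df)
        se = float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se = math.nan
    return float(sol.x[0]), se, ss, df


def combine_ic50(runs, method: str = "geometric_mean", *, model: str = "4pl",
                 alpha: float = 0.05, pin_bottom: float | None = None
                 ) -> CombinedIC50:
    """Combine IC50 estimates across >= 2 experimental runs.

    Parameters
    ----------
    runs
        Either a sequence of per-run point collections (DataFrame /
        DoseResponsePoint list / (x, y) arrays), a sequence of already
        fitted ``FitResult`` objects of the same family, or, for the
        geometric-mean method only, a bare sequence of per-run logIC50s.
    method
        ``pooled`` — concatenate all points and fit once; ``geometric_mean``
        — average per-run logIC50s with a t-based CI (the geometric mean of
        the IC50s); ``shared_ftest`` — fit all runs with a common logIC50
        and test that constraint with the extra-sum-of-squares F-test.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("combining IC50s needs >= 2 runs")
    if method not in ("pooled", "geometric_mean", "shared_ftest"):
        raise ValueError(f"unknown combination method {method!r}")

    if all(isinstance(r, FitResult) for r in runs):
        models = {r.model for r in runs}
        if len(models) > 1:
            raise ValueError(f"mixed model families {sorted(models)}; "
                             "runs must share one family")
        if models != {"4pl"}:
            raise ValueError("cross-run combination operates on 4PL fits; "
                             "pool biphasic runs and refit instead")
        if method != "geometric_mean":
            raise ValueError(f"{method} needs the raw points, not fitted results")
        logs = [r.params["logIC50"] for r in runs]
        return _geomean(logs, alpha, method)
    if all(np.isscalar(r) for r in runs):
        if method != "geometric_mean":
            raise ValueError(f"{method} needs the raw points, not bare logIC50s")
        return _geomean([float(r) for r in runs], alpha, method)

    if model != "4pl":
        if method != "pooled":
            raise ValueError("biphasic runs combine via method='pooled' only")
        pooled_xy = [_xy(r) for r in runs]
        x = np.concatenate([x for x, _ in pooled_xy])
        y = np.concatenate([y for _, y in pooled_xy])
        fit = fit_biphasic((x, y))
        return CombinedIC50(method="pooled",
                            logIC50=fit.params["logIC50_1"],
                            ci95=fit.ci95.get("logIC50_1", (math.nan, math.nan)))

    runs_xy = [_xy(r) for r in runs]
    if method == "pooled":
        x = np.concatenate([x for x, _ in runs_xy])
        y = np.concatenate([y for _, y in runs_xy])
        fit = fit_4pl((x, y), pin_bottom=pin_bottom)
        return CombinedIC50(method="pooled", logIC50=fit.params["logIC50"],
                            ci95=fit.ci95.get("logIC50", (math.nan, math.nan)))

    sep_fits = [fit_4pl(xy, pin_bottom=pin_bottom) for xy in runs_xy]
    logs = [f.params["logIC50"] for f in sep_fits]
    if method == "geometric_mean":
        return _geomean(logs, alpha, method)

    # shared-logIC50 extra-sum-of-squares F-test
    ss_sep = sum(f.ss_residual for f in sep_fits)
    df_sep = sum(f.df for f in sep_fits)
    logic, se, ss_sh, df_sh = _shared_logic50_fit(runs_xy, sep_fits)
    d_df = df_sh - df_sep
    if ss_sh < ss_sep:  # numerical guard: the constrained fit cannot be better
        ss_sh = ss_sep
    f_stat = ((ss_sh - ss_sep) / d_df) / (ss_sep / df_sep) if df_sep > 0 else math.nan
    p = float(stats.f.sf(f_stat, d_df, df_sep))
    tq = stats.t.ppf(1.0 - alpha / 2.0, df_sh)
    return CombinedIC50(
        method="shared_ftest", logIC50=logic,
        ci95=(logic - tq * se, logic + tq * se),
        f_statistic=float(f_stat), p_value=p,
        runs_differ=bool(p < alpha), per_run_logIC50=[float(v) for v in logs],
    )


def _geomean(logs: list[float], alpha: float, method: str) -> CombinedIC50:
    logs = [float(v) for v in logs]
    k = len(logs)
    m = float(np.mean(logs))
    sd = float(np.std(logs, ddof=1))
    tq = stats.t.ppf(1.0 - alpha / 2.0, k - 1)
    half = tq * sd / math.sqrt(k)
    return CombinedIC50(method="geometric_mean", logIC50=m,
                        ci95=(m - half, m + half), per_run_logIC50=logs)
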