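"""Gradient regression suite: diet, density and trophic position vs beach form.

Implements the statistical battery used to relate site-level responses to
the physical beach parameters (width, foreshore slope, median grain size,
wrack biomass):

* forward stepwise multiple linear regression with backward removal,
  driven by partial-F thresholds (or p-value thresholds),
* a 3-parameter Gaussian peak model ``y = a*exp(-0.5*((x-x0)/b)**2)`` for
  hump-shaped responses,
* a 2-parameter saturating hyperbola ``y = a*(1-exp(-b*x))``,
* variance-stabilizing transforms: arcsine-square-root for proportions and
  log10 for densities.

Nonlinear fits use deterministic multi-start local least squares, so the
returned parameters never have a larger SSE than any start.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PREY_TAXA, DataError

__all__ = [
    "FitError",
    "DegenerateFitError",
    "RegressionFit",
    "arcsine_sqrt",
    "log10_density",
    "fit_linear",
    "stepwise_select",
    "fit_gaussian3",
    "fit_hyperbola2",
    "gradient_analysis",
    "GradientReport",
]

logger = logging.getLogger(__name__)

#: Conventional stepwise thresholds (partial-F units).
DEFAULT_F_ENTER = 4.0
DEFAULT_F_REMOVE = 3.9

_COLLINEAR_TOL = 1e-10


class FitError(RuntimeError):
    """A model fit failed to converge or is otherwise unusable."""


class DegenerateFitError(FitError):
    """The data admit no meaningful fit (e.g. constant response)."""


@dataclass
class RegressionFit:
    """Result of one fitted model in the gradient battery."""

    family: str  # stepwise-linear | simple-linear | gaussian3 | hyperbola2
    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    std_coefficients: dict[str, float]
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    n: int
    ss_model: float = float("nan")
    ss_resid: float = float("nan")
    f_to_remove: dict[str, float] = field(default_factory=dict)
    f_to_enter: dict[str, float] = field(default_factory=dict)
    negative_r2: bool = False

    @property
    def empty(self) -> bool:
        return not self.predictors


def arcsine_sqrt(p):
    """Arcsine-square-root transform of a proportion (radians), monotone on [0, 1]."""
    arr = np.asarray(p, float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DataError(f"proportion outside [0, 1]: {arr}")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def log10_density(d, zero_offset: float = 0.01):
    """Log10 transform of a density; zeros get a small documented offset.

    Returns ``(transformed, offset_applied)`` where ``offset_applied`` marks
    values that were 0 and were shifted by ``zero_offset`` before the log.
    Negative densities raise.
    """
    arr = np.asarray(d, float)
    if np.any(arr < 0):
        raise DataError(f"negative density: {arr}")
    flagged = arr == 0
    out = np.log10(arr + np.where(flagged, zero_offset, 0.0))
    if np.isscalar(d) or arr.ndim == 0:
        return float(out), bool(flagged)
    return out, flagged


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _design(predictors: Sequence[str], data: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    cols = [np.ones(n)] + [np.asarray(data[name], float) for name in predictors]
    return np.column_stack(cols)


def _finalize_linear(
    y: np.ndarray,
    included: list[str],
    data: Mapping[str, np.ndarray],
    family: str,
    response: str,
    excluded: Sequence[str] = (),
    f_enter_at_end: Mapping[str, float] | None = None,
    f_remove_at_end: Mapping[str, float] | None = None,
) -> RegressionFit:
    n = len(y)
    sst = float(((y - y.mean()) ** 2).sum())
    X = _design(included, data, n)
    beta, sse = _ols(y, X)
    p_full = X.shape[1]
    df_model = len(included)
    df_resid = n - p_full
    names = ["constant"] + list(included)
    coeffs = dict(zip(names, map(float, beta)))

    if df_model == 0 or sst == 0:
        return RegressionFit(
            family=family, response=response, predictors=list(included),
            coefficients=coeffs, std_errors={}, std_coefficients={},
            r_squared=0.0, f_stat=float("nan"), df_model=0, df_resid=df_resid,
            p_value=float("nan"), n=n, ss_model=0.0, ss_resid=sse,
            f_to_enter=dict(f_enter_at_end or {}),
        )

    mse = sse / df_resid if df_resid > 0 else float("nan")
    cov = mse * np.linalg.pinv(X.T @ X)
    ses = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    sy = float(np.std(y, ddof=1))
    std_coeffs = {
        name: coeffs[name] * float(np.std(np.asarray(data[name], float), ddof=1)) / sy
        for name in included
    }
    r2 = 1.0 - sse / sst
    ssm = sst - sse
    f_stat = (ssm / df_model) / mse if mse > 0 else float("inf")
    p_value = float(stats.f.sf(f_stat, df_model, df_resid)) if df_resid > 0 else float("nan")
    return RegressionFit(
        family=family, response=response, predictors=list(included),
        coefficients=coeffs, std_errors=ses, std_coefficients=std_coeffs,
        r_squared=r2, f_stat=f_stat, df_model=df_model, df_resid=df_resid,
        p_value=p_value, n=n, ss_model=ssm, ss_resid=sse,
        f_to_enter=dict(f_enter_at_end or {}),
        f_to_remove=dict(f_remove_at_end or {}),
    )


def fit_linear(x: Sequence[float], y: Sequence[float], name: str = "x",
               response: str = "y") -> RegressionFit:
    """Simple linear regression y = b0 + b1*x with the standard F test."""
    y = np.asarray(y, float)
    data = {name: np.asarray(x, float)}
    return _finalize_linear(y, [name], data, "simple-linear", response)


def stepwise_select(
    response: Sequence[float],
    candidates: Mapping[str, Sequence[float]],
    f_enter: float = DEFAULT_F_ENTER,
    f_remove: float = DEFAULT_F_REMOVE,
    mode: str = "f",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    response_name: str = "y",
) -> RegressionFit:
    """Forward stepwise multiple regression with backward removal.

    At each step the candidate with the largest partial F (variance
    explained beyond the current model) enters if it clears ``f_enter``;
    any included variable whose F-to-remove falls below ``f_remove`` is then
    dropped. In ``mode='p'`` the thresholds are the partial-F p-values
    ``p_enter``/``p_remove`` instead. Near-collinear candidates are skipped
    with a warning; a cycle guard ensures termination. The returned fit
    records F-to-remove for included variables and F-to-enter (at the final
    step) for excluded ones, mirroring the usual stepwise report.
    """
    y = np.asarray(response, float)
    n = len(y)
    if n < 5:
        raise DataError(f"stepwise regression needs >= 5 observations, got {n}")
    data = {k: np.asarray(v, float) for k, v in candidates.items()}
    for k, v in data.items():
        if len(v) != n:
            raise DataError(f"candidate '{k}' has length {len(v)} != {n}")
    if mode not in ("f", "p"):
        raise DataError(f"unknown stepwise mode '{mode}'")

    def partial_f(incl: list[str], cand: str) -> float | None:
        """F for adding `cand` to `incl`; None if collinear/degenerate."""
        X0 = _design(incl, data, n)
        # collinearity screen: candidate regressed on current design
        xc = data[cand]
        _, sse_c = _ols(xc, X0)
        sst_c = float(((xc - xc.mean()) ** 2).sum())
        if sst_c == 0 or sse_c / sst_c < _COLLINEAR_TOL:
            return None
        _, sse0 = _ols(y, X0)
        X1 = _design(incl + [cand], data, n)
        _, sse1 = _ols(y, X1)
        df_resid = n - X1.shape[1]
        if df_resid <= 0 or sse1 <= 0:
            return float("inf") if sse0 > sse1 else 0.0
        return (sse0 - sse1) / (sse1 / df_resid)

    def remove_f(incl: list[str]) -> dict[str, float]:
        X1 = _design(incl, data, n)
        _, sse1 = _ols(y, X1)
        df_resid = n - X1.shape[1]
        out = {}
        for v in incl:
            others = [w for w in incl if w != v]
            _, sse0 = _ols(y, _design(others, data, n))
            out[v] = (sse0 - sse1) / (sse1 / df_resid) if sse1 > 0 and df_resid > 0 else float("inf")
        return out

    def crosses_enter(f: float, df_resid: int) -> bool:
        if mode == "f":
            return f >= f_enter
        return float(stats.f.sf(f, 1, df_resid)) <= p_enter

    def crosses_remove(f: float, df_resid: int) -> bool:
        if mode == "f":
            return f < f_remove
        return float(stats.f.sf(f, 1, df_resid)) > p_remove

    included: list[str] = []
    seen: set[frozenset] = set()
    for _ in range(4 * len(data) + 4):
        # entry step
        scores: dict[str, float] = {}
        for cand in data:
            if cand in included:
                continue
            f = partial_f(included, cand)
            if f is None:
                warnings.warn(f"candidate '{cand}' near-collinear with model; skipped")
                continue
            scores[cand] = f
        entered = False
        if scores:
            best = max(scores, key=scores.get)
            df_resid_new = n - (len(included) + 2)
            if crosses_enter(scores[best], df_resid_new):
                included.append(best)
                entered = True
        # removal step
        removed = False
        if included:
            rf = remove_f(included)
            df_resid = n - (len(included) + 1)
            worst = min(rf, key=rf.get)
            if crosses_remove(rf[worst], df_resid):
                included.remove(worst)
                removed = True
        state = frozenset(included)
        if state in seen and not entered:
            break
        seen.add(state)
        if not entered and not removed:
            break

    # final bookkeeping: F-to-enter for excluded, F-to-remove for included
    f_enter_final = {}
    for cand in data:
        if cand in included:
            continue
        f = partial_f(included, cand)
        if f is not None:
            f_enter_final[cand] = f
    f_remove_final = remove_f(included) if included else {}
    return _finalize_linear(
        y, included, data, "stepwise-linear", response_name,
        f_enter_at_end=f_enter_final, f_remove_at_end=f_remove_final,
    )


def _multistart_least_squares(residual, starts, bounds=(-np.inf, np.inf)):
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = optimize.least_squares(residual, x0, bounds=bounds, xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # singular Jacobian etc.
            diagnostics.append(f"start {x0}: {exc}")
            continue
        sse = float(res.cost * 2)
        if best is None or sse < best[1] - 1e-15:
            best = (res.x, sse, res.success)
        diagnostics.append(f"start {x0}: sse={sse:.4g} success={res.success}")
    if best is None:
        raise FitError("all starts failed: " + "; ".join(diagnostics))
    return best[0], best[1]


def _nonlinear_fit_stats(y, sse, n, df_model, family, response, predictors, params):
    sst = float(((y - y.mean()) ** 2).sum())
    df_resid = n - (df_model + 1)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    mse = sse / df_resid if df_resid > 0 else float("nan")
    ssm = sst - sse
    f_stat = (ssm / df_model) / mse if mse > 0 else float("inf")
    p_value = float(stats.f.sf(f_stat, df_model, df_resid)) if df_resid > 0 else float("nan")
    return RegressionFit(
        family=family, response=response, predictors=list(predictors),
        coefficients={k: float(v) for k, v in params.items()},
        std_errors={}, std_coefficients={},
        r_squared=r2, f_stat=f_stat, df_model=df_model, df_resid=df_resid,
        p_value=p_value, n=n, ss_model=ssm, ss_resid=sse,
        negative_r2=bool(r2 < 0),
    )


def fit_gaussian3(x: Sequence[float], y: Sequence[float],
                  response: str = "y", predictor: str = "x") -> RegressionFit:
    """Fit the 3-parameter Gaussian peak y = a*exp(-0.5*((x-x0)/b)^2).

    Five deterministic starts span the x range (center at min/quartiles/
    max). Reports R^2 and the model F with 2 model df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4:
        raise DataError(f"gaussian fit needs >= 4 points, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant response: Gaussian peak is unidentifiable")

    span = max(np.ptp(x), 1e-9)
    starts = [
        np.array([y.max(), c, span / 4.0])
        for c in np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
    ]

    def residual(theta):
        a, x0, b = theta
        return a * np.exp(-0.5 * ((x - x0) / b) ** 2) - y

    bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf])
    theta, sse = _multistart_least_squares(residual, starts, bounds)
    if theta[2] > 100 * span:
        raise DegenerateFitError(
            f"fitted spread b={theta[2]:.3g} far exceeds the data range; no peak"
        )
    return _nonlinear_fit_stats(
        y, sse, n, 2, "gaussian3", response, [predictor],
        {"a": theta[0], "x0": theta[1], "b": theta[2]},
    )


def fit_hyperbola2(x: Sequence[float], y: Sequence[float],
                   response: str = "y", predictor: str = "x") -> RegressionFit:
    """Fit the saturating hyperbola y = a*(1 - exp(-b*x)) for x >= 0.

    The curve passes through the origin and plateaus at ``a``. Five
    deterministic starts cover rate constants from shallow to steep.
    Reports R^2 and the model F with 1 model df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise DataError(f"hyperbola fit needs >= 3 points, got {n}")
    if np.any(x < 0):
        raise DataError("hyperbola model requires x >= 0")
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant response: saturation level unidentifiable")

    xref = max(float(np.mean(x[x > 0])) if np.any(x > 0) else 1.0, 1e-9)
    a0 = float(np.mean(np.sort(y)[-max(2, n // 3):]))
    a0 = a0 if a0 != 0 else float(y.max()) or 1.0
    starts = [np.array([a0, b0 / xref]) for b0 in (0.2, 0.5, 1.0, 2.0, 5.0)]

    def residual(theta):
        a, b = theta
        return a * (1.0 - np.exp(-b * x)) - y

    theta, sse = _multistart_least_squares(residual, starts)
    return _nonlinear_fit_stats(
        y, sse, n, 1, "hyperbola2", response, [predictor],
        {"a": theta[0], "b": theta[1]},
    )


PHYSICAL_PARAMS = ("width_m", "slope_deg", "grain_mm", "wrack_g")


@dataclass
class GradientReport:
    """All fitted models of the gradient battery, keyed by model name."""

    fits: dict[str, RegressionFit]
    errors: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Tidy summary: one row per model x variable plus a model-level row."""
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "model": name, "family": fit.family, "variable": "<model>",
                    "coeff": np.nan, "std_coeff": np.nan, "std_error": np.nan,
                    "F": fit.f_stat, "P": fit.p_value, "R2": fit.r_squared,
                    "df": fit.df_model, "SS": fit.ss_model,
                    "MS": fit.ss_model / fit.df_model if fit.df_model else np.nan,
                    "n": fit.n,
                }
            )
            for var, coef in fit.coefficients.items():
                rows.append(
                    {
                        "model": name, "family": fit.family, "variable": var,
                        "coeff": coef,
                        "std_coeff": fit.std_coefficients.get(var, np.nan),
                        "std_error": fit.std_errors.get(var, np.nan),
                        "F": fit.f_to_remove.get(var, np.nan),
                        "P": np.nan, "R2": np.nan, "df": np.nan,
                        "SS": np.nan, "MS": np.nan, "n": fit.n,
                    }
                )
            for var, f in fit.f_to_enter.items():
                rows.append(
                    {
                        "model": name, "family": fit.family,
                        "variable": f"{var} (not in model)",
                        "coeff": np.nan, "std_coeff": np.nan, "std_error": np.nan,
                        "F": f, "P": np.nan, "R2": np.nan, "df": np.nan,
                        "SS": np.nan, "MS": np.nan, "n": fit.n,
                    }
                )
        return pd.DataFrame(rows)


def gradient_analysis(
    sites: pd.DataFrame,
    diet_site_means: pd.DataFrame,
    tp_table: pd.DataFrame,
    f_enter: float = DEFAULT_F_ENTER,
    f_remove: float = DEFAULT_F_REMOVE,
    exclude: Mapping[str, Sequence[str]] | None = None,
) -> GradientReport:
    """Run the full regression battery on the merged per-site table.

    Models fitted (names in the returned report):

    * ``diet_<taxon>~physical`` — stepwise on the arcsine-sqrt-transformed
      diet proportion vs the four physical parameters;
    * ``density~physical`` — stepwise on log10 burrow density, plus
      ``density~width_gaussian`` (Gaussian peak over width);
    * ``tp~physical`` — stepwise on trophic position;
    * ``tp~p_<taxon>`` — simple linear TP vs each diet proportion, plus
      ``tp~p_mole_crab_hyperbola`` (saturating hyperbola).

    ``exclude`` maps a model name to site codes dropped from that fit only.
    Degenerate fits are recorded under ``report.errors`` instead of raising.
    """
    exclude = exclude or {}
    merged = sites.merge(diet_site_means, on="site").merge(tp_table, on="site")
    needed = list(PHYSICAL_PARAMS) + [f"mean_p_{t}" for t in PREY_TAXA] + ["tp"]
    missing = [c for c in needed if c not in merged.columns]
    if missing:
        raise DataError(f"merged site table missing columns {missing}")

    fits: dict[str, RegressionFit] = {}
    errors: dict[str, str] = {}

    def subset(name: str) -> pd.DataFrame:
        drop = set(exclude.get(name, ()))
        return merged.loc[~merged["site"].isin(drop)]

    def try_fit(model_name: str, fn, *args, **kwargs):
        try:
            fits[model_name] = fn(*args, **kwargs)
        except (FitError, DataError) as exc:
            errors[model_name] = str(exc)
            logger.warning("model %s not fitted: %s", model_name, exc)

    for taxon in PREY_TAXA:
        name = f"diet_{taxon}~physical"
        d = subset(name)
        try_fit(
            name, stepwise_select,
            arcsine_sqrt(d[f"mean_p_{taxon}"].to_numpy()),
            {p: d[p].to_numpy() for p in PHYSICAL_PARAMS},
            f_enter, f_remove, response_name=f"asin_sqrt_p_{taxon}",
        )

    if "burrow_density" in merged.columns and merged["burrow_density"].notna().all():
        name = "density~physical"
        d = subset(name)
        logd, _ = log10_density(d["burrow_density"].to_numpy())
        try_fit(
            name, stepwise_select, logd,
            {p: d[p].to_numpy() for p in PHYSICAL_PARAMS},
            f_enter, f_remove, response_name="log10_density",
        )
        name = "density~width_gaussian"
        d = subset(name)
        logd, _ = log10_density(d["burrow_density"].to_numpy())
        try_fit(name, fit_gaussian3, d["width_m"].to_numpy(), logd,
                response="log10_density", predictor="width_m")

    name = "tp~physical"
    d = subset(name)
    try_fit(
        name, stepwise_select, d["tp"].to_numpy(),
        {p: d[p].to_numpy() for p in PHYSICAL_PARAMS},
        f_enter, f_remove, response_name="tp",
    )

    for taxon in PREY_TAXA:
        name = f"tp~p_{taxon}"
        d = subset(name)
        try_fit(name, fit_linear, d[f"mean_p_{taxon}"].to_numpy(), d["tp"].to_numpy(),
                name=f"mean_p_{taxon}", response="tp")
    name = "tp~p_mole_crab_hyperbola"
    d = subset(name)
    try_fit(name, fit_hyperbola2, d["mean_p_mole_crab"].to_numpy(), d["tp"].to_numpy(),
            response="tp", predictor="mean_p_mole_crab")

    return GradientReport(fits=fits, errors=errors)
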