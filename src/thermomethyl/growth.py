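"""Quadratic growth-response surface for weight gain rate vs temperature.

The growth experiment crosses shell diameter D (cm) with water temperature
T (deg C) and records weight gain rate WGR (%) = (Wt - W0)/W0 * 100 over
the interval. A full second-order response surface

    WGR(D, T) = b0 + b1*D + b2*T + b3*D*T + b4*D^2 + b5*T^2

is fitted by ordinary least squares. At fixed diameter the surface is a
parabola in T; when concave (b5 < 0) the per-diameter optimal temperature
is the stationary point t_opt = (b2 + b3*D) / (-2*b5), the maximum WGR is
the surface value there, and the growth-limit temperature is the larger
root of WGR(D, T) = 0 (the temperature above which the animal loses
weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: coefficients of the published sea-urchin WGR surface
#: (intercept, D, T, D*T, D^2, T^2) -- used as simulation ground truth
#: and for desk-checking the derived optima.
PUBLISHED_COEFFICIENTS = (-6.1175, 0.2177, 1.5362, 0.0054, -0.1414, -0.0511)

#: per-diameter optimal temperatures as printed in the source study's
#: results (deg C); kept for the discrepancy report only -- the D=2 and
#: D=6 values are not the stationary points of the published equation.
PUBLISHED_OPTIMA = {2.0: 16.1, 4.0: 15.4, 6.0: 13.6}

#: the growth experiment's 18-cell design
DESIGN_DIAMETERS = (2.0, 4.0, 6.0)
DESIGN_TEMPERATURES = (10.0, 14.0, 18.0, 22.0, 24.0, 26.0)


@dataclass
class QuadraticSurfaceModel:
    """Six OLS coefficients on (1, D, T, D*T, D^2, T^2) plus diagnostics."""

    beta: tuple[float, float, float, float, float, float]
    r_squared: float = float("nan")
    f_statistic: float = float("nan")
    model_p: float = float("nan")
    n_obs: int = 0
    stderr: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.beta) != 6:
            raise ValueError("expected 6 coefficients")


@dataclass
class OptimumResult:
    diameter: float
    t_opt: float
    wgr_max: float
    concave: bool


def compute_wgr(w0: float, wt: float) -> float:
    """Weight gain rate in percent: (wt - w0) / w0 * 100. Negative = loss."""
    if w0 <= 0:
        raise ValueError("initial weight must be positive")
    return (wt - w0) / w0 * 100.0


def design_matrix(D: np.ndarray, T: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    T = np.asarray(T, dtype=float)
    return np.column_stack([np.ones_like(D), D, T, D * T, D**2, T**2])


def fit_quadratic_surface(
    data: pd.DataFrame | list[tuple[float, float, float]],
    aggregate_cells: bool = False,
) -> QuadraticSurfaceModel:
    """OLS fit of the full quadratic surface to (D, T, WGR) observations.

    `data` is a DataFrame with columns diameter, temperature, wgr (or an
    iterable of (D, T, WGR) tuples). With ``aggregate_cells=True`` the
    response is first averaged within each (D, T) design cell, mirroring
    per-group mean fitting; the default fits raw observations.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(data, columns=["diameter", "temperature", "wgr"])
    if aggregate_cells:
        data = (
            data.groupby(["diameter", "temperature"], as_index=False)["wgr"]
            .mean()
        )
    if len(data) < 7:
        raise ValueError("need >= 7 observations to fit 6 coefficients")
    if data["diameter"].nunique() < 2 or data["temperature"].nunique() < 3:
        raise ValueError("design not estimable: need >=2 diameters, >=3 temperatures")
    X = design_matrix(data["diameter"].to_numpy(), data["temperature"].to_numpy())
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("design not estimable: rank-deficient design matrix")
    res = sm.OLS(data["wgr"].to_numpy(), X).fit()
    return QuadraticSurfaceModel(
        beta=tuple(float(b) for b in res.params),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        model_p=float(res.f_pvalue),
        n_obs=int(res.nobs),
        stderr=tuple(float(s) for s in res.bse),
    )


def evaluate_surface(model: QuadraticSurfaceModel, D: float, T: float) -> float:
    b0, b1, b2, b3, b4, b5 = model.beta
    return b0 + b1 * D + b2 * T + b3 * D * T + b4 * D**2 + b5 * T**2


def optimal_temperature(model: QuadraticSurfaceModel, D: float) -> OptimumResult:
    """Stationary point of the surface in T at fixed diameter.

    Only defined for surfaces concave in T (b5 < 0); the optimum is the
    closed-form root of dWGR/dT = 0.
    """
    b0, b1, b2, b3, b4, b5 = model.beta
    if b5 >= 0:
        raise ValueError("surface not concave in T: no temperature optimum")
    t_opt = (b2 + b3 * D) / (-2.0 * b5)
    return OptimumResult(
        diameter=D,
        t_opt=t_opt,
        wgr_max=evaluate_surface(model, D, t_opt),
        concave=True,
    )


def limit_temperature(model: QuadraticSurfaceModel, D: float) -> float:
    """Larger root in T of WGR(D, T) = 0: the zero-growth temperature.

    Requires a concave-in-T surface with positive WGR at the optimum;
    above the returned temperature the predicted WGR is negative.
    """
    b0, b1, b2, b3, b4, b5 = model.beta
    opt = optimal_temperature(model, D)
    if opt.wgr_max <= 0:
        raise ValueError(
            "no zero crossing: predicted WGR never positive at this diameter"
        )
    a = b5
    b = b2 + b3 * D
    c = b0 + b1 * D + b4 * D**2
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no zero crossing: discriminant negative")
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    return float(max(roots))


def validate_predictions(
    model: QuadraticSurfaceModel,
    observed: list[tuple[float, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Predicted-vs-observed WGR at each diameter's optimal temperature.

    `observed` holds (diameter, observed WGR at t_opt) pairs. Returns a
    table with predicted, observed, absolute and relative error.
    """
    if not isinstance(observed, pd.DataFrame):
        observed = pd.DataFrame(observed, columns=["diameter", "observed_wgr"])
    rows = []
    for _, rec in observed.iterrows():
        opt = optimal_temperature(model, float(rec["diameter"]))
        pred = opt.wgr_max
        obs = float(rec["observed_wgr"])
        rows.append(
            {
                "diameter": float(rec["diameter"]),
                "t_opt": opt.t_opt,
                "predicted_wgr": pred,
                "observed_wgr": obs,
                "abs_error": abs(pred - obs),
                "rel_error": abs(pred - obs) / abs(pred) if pred != 0 else np.inf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "diameter", "t_opt", "predicted_wgr", "observed_wgr",
            "abs_error", "rel_error",
        ],
    )


def published_model() -> QuadraticSurfaceModel:
    """The published WGR surface as a model object (no fit diagnostics)."""
    return QuadraticSurfaceModel(beta=PUBLISHED_COEFFICIENTS)


def printed_optimum_discrepancy(
    model: QuadraticSurfaceModel | None = None,
    printed: dict[float, float] | None = None,
    tol: float = 0.25,
) -> pd.DataFrame:
    """Compare closed-form stationary optima with the originally printed ones.

    The source study printed per-diameter optimal temperatures that, for
    the 2 cm and 6 cm classes, are not the stationary points of its own
    printed equation. This report makes that visible rather than trying to
    reproduce those values: rows carry the computed stationary point, the
    printed value, and a ``discrepant`` flag (|difference| > `tol` deg C).
    """
    model = model or published_model()
    printed = printed if printed is not None else PUBLISHED_OPTIMA
    rows = []
    for D, t_printed in sorted(printed.items()):
        opt = optimal_temperature(model, D)
        rows.append(
            {
                "diameter": D,
                "t_opt_stationary": round(opt.t_opt, 2),
                "t_opt_printed": t_printed,
                "difference": round(opt.t_opt - t_printed, 2),
                "discrepant": abs(opt.t_opt - t_printed) > tol,
            }
        )
    report = pd.DataFrame(rows)
    if report["discrepant"].any():
        warnings.warn(
            "printed per-diameter optima differ from the stationary points "
            "of the printed equation; reporting stationary points",
            stacklevel=2,
        )
    return report
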