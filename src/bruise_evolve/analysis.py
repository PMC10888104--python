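"""Growth-curve fitting and damage-rate analysis.

Fits the rescaled logistic growth law to measured damage-extent series,
derives the analytic damage-rate curve (mm/min), locates the maximum-rate
time (the fitted inflection) and the stabilization time (first crossing of
a fixed fraction of the fitted plateau, 99% by default), and compares
progression curves across scenarios via Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .phantom import growth_extent


class FitError(RuntimeError):
    """Raised when a model fit fails to converge."""


@dataclass
class FitResult:
    """Fitted growth-law (or linear) model with goodness-of-fit."""

    model: str                      # "logistic" | "linear"
    params: dict[str, float]
    r_squared: float
    p_value: float
    residual_sd: float
    n: int
    status: str = "ok"              # "ok" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.status == "degenerate"


@dataclass
class RateCurve:
    """Analytic damage-rate curve derived from a logistic fit."""

    times: np.ndarray               # evaluation grid, minutes
    rates: np.ndarray               # mm/min
    source: FitResult
    t_star: float                   # time of maximum rate, minutes
    t_stab: float                   # stabilization time, minutes


@dataclass
class ComparisonResult:
    """Pairwise Pearson correlations of time-aligned progression curves."""

    labels: list[str]
    matrix: np.ndarray

    def min_off_diagonal(self) -> float:
        m = self.matrix.copy()
        np.fill_diagonal(m, np.nan)
        return float(np.nanmin(m))


def _f_test(ss_res: float, ss_tot: float, n: int, n_params: int) -> float:
    """p-value of the regression F-test (model vs intercept-only)."""
    df1 = n_params - 1
    df2 = n - n_params
    if df2 <= 0 or ss_res <= 0 or ss_tot <= ss_res:
        return 0.0 if ss_tot > ss_res else 1.0
    f = ((ss_tot - ss_res) / df1) / (ss_res / df2)
    return float(stats.f.sf(f, df1, df2))


def fit_logistic(times: Sequence[float], extents: Sequence[float]) -> FitResult:
    """Least-squares fit of the rescaled logistic growth law.

    Initialized from the data (plateau = max, t0 = time of half-maximum,
    k = 0.1 /min).  A constant series yields a flagged degenerate result;
    optimizer failure raises :class:`FitError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(extents, dtype=float)
    if t.size < 6:
        raise FitError("need at least 6 points for a logistic fit")
    if np.any(y < 0):
        raise FitError("extents must be non-negative")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or y.max() <= 0:
        return FitResult(
            model="logistic",
            params={"plateau": float(y.max()), "t0": np.nan, "k": np.nan},
            r_squared=0.0, p_value=1.0,
            residual_sd=0.0, n=t.size, status="degenerate",
        )

    def model(tt, plateau, t0, k):
        return growth_extent(tt, plateau, t0, k)

    half = y.max() / 2.0
    above = np.flatnonzero(y >= half)
    t0_init = float(t[above[0]]) if above.size else float(np.median(t))
    p0 = (float(y.max()), max(t0_init, 1.0), 0.1)
    bounds = ([1e-9, 1e-6, 1e-4], [np.inf, 100.0 * t.max(), 50.0])
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    resid = y - model(t, *popt)
    ss_res = float(np.sum(resid**2))
    n_params = 3
    return FitResult(
        model="logistic",
        params={"plateau": float(popt[0]), "t0": float(popt[1]), "k": float(popt[2])},
        r_squared=1.0 - ss_res / ss_tot,
        p_value=_f_test(ss_res, ss_tot, t.size, n_params),
        residual_sd=float(
            np.sqrt(ss_res / max(t.size - n_params, 1))
        ),
        n=t.size,
    )


def fit_linear(times: Sequence[float], values: Sequence[float]) -> FitResult:
    """Ordinary least-squares line with R-squared and F-test p-value."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise FitError("need at least 3 points for a linear fit")
    if np.ptp(y) == 0.0:
        return FitResult(
            model="linear",
            params={"slope": 0.0, "intercept": float(y[0])},
            r_squared=0.0, p_value=1.0, residual_sd=0.0, n=t.size,
            status="degenerate",
        )
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    ss_res = float(np.sum(resid**2))
    return FitResult(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        residual_sd=float(np.sqrt(ss_res / max(t.size - 2, 1))),
        n=t.size,
    )


def _require_logistic(fit: FitResult) -> tuple[float, float, float]:
    if fit.model != "logistic":
        raise FitError("a converged logistic fit is required")
    if fit.degenerate or not np.isfinite(fit.params.get("k", np.nan)):
        raise FitError("degenerate logistic fit has no rate curve")
    return fit.params["plateau"], fit.params["t0"], fit.params["k"]


def damage_rate(
    fit: FitResult, t_max: float = 180.0, grid_step: float = 0.1
) -> RateCurve:
    """Analytic first derivative of the fitted growth curve.

    rate(t) = plateau * k * s (1 - s) / (1 - sigma(-k t0)) with
    s = sigma(k (t - t0)); the maximum sits exactly at the fitted t0.
    """
    plateau, t0, k = _require_logistic(fit)
    t = np.arange(0.0, t_max + grid_step / 2, grid_step)
    s = expit(k * (t - t0))
    rates = plateau * k * s * (1.0 - s) / (1.0 - expit(-k * t0))
    return RateCurve(
        times=t,
        rates=rates,
        source=fit,
        t_star=float(t0),
        t_stab=stabilization_time(fit),
    )


def stabilization_time(fit: FitResult, frac: float = 0.99) -> float:
    """Smallest time at which the fitted extent reaches ``frac`` of the
    fitted plateau, solved in closed form and reported to 0.1 min."""
    plateau, t0, k = _require_logistic(fit)
    if plateau <= 0:
        raise FitError("plateau must be positive")
    if not 0 < frac < 1:
        raise FitError("frac must lie in (0, 1)")
    s0 = expit(-k * t0)
    q = frac + (1.0 - frac) * s0
    t = t0 + logit(q) / k
    return round(float(t), 1)


def compare_progressions(
    traces: Sequence[pd.DataFrame],
    labels: Sequence[str] | None = None,
    column: str = "total_mm",
) -> ComparisonResult:
    """Pearson correlation matrix of progression curves on shared times."""
    if labels is None:
        labels = [f"trace_{i}" for i in range(len(traces))]
    if len(labels) != len(traces):
        raise ValueError("labels and traces must align")
    common = None
    for tr in traces:
        tset = set(np.round(tr["time_min"].to_numpy(), 9))
        common = tset if common is None else common & tset
    common = sorted(common or [])
    if len(common) < 3:
        raise ValueError("need at least 3 shared frames")
    curves = []
    for tr in traces:
        sub = tr[tr["time_min"].round(9).isin(common)].sort_values("time_min")
        y = sub[column].to_numpy()
        if np.ptp(y) == 0.0:
            warnings.warn("zero-variance curve: correlation undefined", stacklevel=2)
        curves.append(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(np.vstack(curves))
    return ComparisonResult(labels=list(labels), matrix=mat)


def proportion_band(trace: pd.DataFrame) -> tuple[float, float, float]:
    """(min, max, mean) core share over non-excluded frames of a trace."""
    ok = trace[~trace["excluded"] & trace["core_share"].notna()]
    if ok.empty:
        raise ValueError("all frames are excluded; no proportion statistics")
    shares = ok["core_share"].to_numpy()
    return float(shares.min()), float(shares.max()), float(shares.mean())
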