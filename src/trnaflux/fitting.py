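"""Rate-constant estimation from FIR time series.

Nonlinear least squares of the closed-form two-compartment FIR curve
against one series or a pooled set of series gives (k_in, k_out) and,
optionally, the composite geometry factor c = phi/w.  The relaxation
time tau and the plateau FIR_inf = k_in/k_out are derived quantities of
the fitted rates, never fitted separately, so the reported table is
internally consistent by construction.

A three-parameter saturating exponential
``FIR(t) = fir_inf + (fir_0 - fir_inf) exp(-t/tau)`` is provided as the
fallback for curves the mechanistic model cannot fit (e.g. drug-treated
cells); it coincides exactly with the closed form when c = 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    FIRSeries,
    RateConstants,
    fir_closed_form,
    steady_state_fir,
    time_constant,
)

__all__ = [
    "KineticFit",
    "ExponentialFit",
    "fit_eq1",
    "fit_exponential",
    "r_squared",
    "bootstrap_ci",
]

# Optimizer defaults: bounded trust-region reflective least squares.  The
# bounds are generous relative to any physiological envelope-transport
# rate; fits hitting them are suspect and flagged by non-convergence
# restarts rather than silently clipped.
RATE_BOUNDS = (0.0, 10.0)      # min^-1
C_BOUNDS = (0.0, 2.0)          # dimensionless phi/w
DEFAULT_INIT = (0.2, 0.2, 0.3)  # k_in, k_out, c
N_RESTARTS = 5


@dataclass
class KineticFit:
    """Result of a least-squares fit of the two-compartment FIR curve."""

    k_in: float
    k_out: float
    tau: float
    fir_inf: float
    c: float
    c_fitted: bool
    standard_errors: dict[str, float]
    r_squared: float
    n_points: int
    converged: bool
    residuals: np.ndarray = field(repr=False)

    @property
    def rates(self) -> RateConstants:
        return RateConstants(self.k_in, self.k_out)

    def to_dict(self) -> dict:
        return {
            "k_in": self.k_in,
            "k_out": self.k_out,
            "tau": self.tau,
            "fir_inf": self.fir_inf,
            "c": self.c,
            "c_fitted": self.c_fitted,
            "standard_errors": self.standard_errors,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class ExponentialFit:
    """Saturating-exponential fit (plateau, time constant, intercept)."""

    fir_inf: float
    tau: float
    fir_0: float
    standard_errors: dict[str, float]
    r_squared: float
    converged: bool


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Returns NaN (with a warning) for a constant observed series, whose
    total variance is zero.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need two equal-length series with >= 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("observed series has zero variance; R^2 undefined")
        return float("nan")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _pool(series: FIRSeries | Sequence[FIRSeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(series, FIRSeries):
        series = [series]
    t = np.concatenate([s.times for s in series])
    y = np.concatenate([s.fir for s in series])
    if all(s.sigma is not None for s in series):
        sig = np.concatenate([s.sigma for s in series])  # type: ignore[misc]
    else:
        sig = None
    return t, y, sig


def _covariance_se(res, n: int, names: Sequence[str]) -> dict[str, float]:
    """Jacobian-based standard errors scaled by residual variance."""
    p = len(names)
    dof = max(n - p, 1)
    s2 = float(2 * res.cost) / dof
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))


def _derived_ses(k_in, k_out, c, se: dict[str, float], c_fitted: bool) -> dict[str, float]:
    # delta-method propagation to fir_inf = k_in/k_out and
    # tau = 1/(k_out + c*k_in); parameter correlations ignored (upper bound
    # style reporting, matching per-parameter tables)
    s_kin, s_kout = se.get("k_in", np.nan), se.get("k_out", np.nan)
    s_c = se.get("c", 0.0) if c_fitted else 0.0
    fir_inf = k_in / k_out if k_out > 0 else np.inf
    g = k_out + c * k_in
    se_fir = abs(fir_inf) * np.hypot(s_kin / k_in if k_in else 0.0,
                                     s_kout / k_out if k_out else 0.0)
    se_tau = np.sqrt((c * s_kin) ** 2 + s_kout ** 2 + (k_in * s_c) ** 2) / g ** 2
    return {"fir_inf": float(se_fir), "tau": float(se_tau)}


def fit_eq1(
    series: FIRSeries | Sequence[FIRSeries],
    c_mode: float | Literal["free"] = "free",
    init: tuple[float, ...] | None = None,
    bounds: tuple[tuple[float, float], ...] | None = None,
    weighted: bool = False,
    seed: int = 0,
) -> KineticFit:
    """Fit the closed-form FIR curve to one or several pooled series.

    Parameters
    ----------
    series
        A single series or a list; lists are pooled by concatenating
        residuals with equal weights (one parameter set for all cells).
    c_mode
        ``"free"`` fits the composite geometry factor c = phi/w alongside
        the rates; a float fixes it at that value.
    init
        Starting point ``(k_in, k_out[, c])``.
    weighted
        If true and the series carries per-point ``sigma``, use
        1/sigma^2 weights.
    seed
        Seeds the jittered restarts attempted after a failed fit.

    Raises
    ------
    ValueError
        For fewer observations than free parameters + 1.
    """
    t, y, sig = _pool(series)
    c_fitted = c_mode == "free"
    n_free = 3 if c_fitted else 2
    if t.size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} observations, got {t.size}")
    if np.ptp(t) <= 0:
        raise ValueError("observation times must span a positive interval")

    w = 1.0 / sig if (weighted and sig is not None and np.all(sig > 0)) else None

    if c_fitted:
        names = ("k_in", "k_out", "c")
        lo = [RATE_BOUNDS[0], RATE_BOUNDS[0], C_BOUNDS[0]]
        hi = [RATE_BOUNDS[1], RATE_BOUNDS[1], C_BOUNDS[1]]
        x0 = np.asarray(init if init is not None else DEFAULT_INIT, dtype=float)
    else:
        names = ("k_in", "k_out")
        lo = [RATE_BOUNDS[0], RATE_BOUNDS[0]]
        hi = [RATE_BOUNDS[1], RATE_BOUNDS[1]]
        x0 = np.asarray(init if init is not None else DEFAULT_INIT[:2], dtype=float)
    if bounds is not None:
        lo = [b[0] for b in bounds]
        hi = [b[1] for b in bounds]
    # keep k_in away from the removable singularity at 0 during the search
    lo[0] = max(lo[0], 1e-9)

    def model(x: np.ndarray) -> np.ndarray:
        k_in, k_out = x[0], x[1]
        c = x[2] if c_fitted else float(c_mode)
        tau = 1.0 / (k_out + c * k_in)
        decay = np.exp(-t / tau)
        return (1.0 - decay) / (k_out / k_in + c * decay)

    def resid(x: np.ndarray) -> np.ndarray:
        r = model(x) - y
        return r * w if w is not None else r

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + N_RESTARTS):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.lognormal(0.0, 0.5, size=x0.size), lo, hi
        )
        try:
            res = least_squares(
                resid, np.clip(start, lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # singular model evaluation etc.
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost <= (best.cost if best else np.inf) + 1e-15:
            best = res
            if attempt == 0 and res.success:
                break

    if best is None:
        raise RuntimeError("optimizer failed on every start")

    x = best.x
    k_in, k_out = float(x[0]), float(x[1])
    c_hat = float(x[2]) if c_fitted else float(c_mode)
    converged = bool(best.success) and k_out > 0

    se = _covariance_se(best, t.size, names)
    se.update(_derived_ses(k_in, k_out, c_hat, se, c_fitted))
    resids = model(x) - y
    rates = RateConstants(k_in, k_out)
    return KineticFit(
        k_in=k_in,
        k_out=k_out,
        tau=time_constant(rates, c_hat),
        fir_inf=steady_state_fir(rates) if k_out > 0 else float("inf"),
        c=c_hat,
        c_fitted=c_fitted,
        standard_errors=se,
        r_squared=r_squared(y, model(x)),
        n_points=int(t.size),
        converged=converged,
        residuals=resids,
    )


def fit_exponential(series: FIRSeries) -> ExponentialFit:
    """Fit FIR(t) = fir_inf + (fir_0 - fir_inf) exp(-t/tau).

    Degenerate series (no dynamics, so tau is unidentifiable) return
    ``converged=False`` with the plateau set to the series mean.
    """
    t, y = series.times, series.fir
    if t.size < 4:
        raise ValueError("need at least 4 observations")
    if np.allclose(y, y[0]):
        return ExponentialFit(
            fir_inf=float(y.mean()), tau=float("nan"), fir_0=float(y[0]),
            standard_errors={}, r_squared=float("nan"), converged=False,
        )

    def resid(x: np.ndarray) -> np.ndarray:
        fir_inf, log_tau, fir_0 = x
        return fir_inf + (fir_0 - fir_inf) * np.exp(-t / np.exp(log_tau)) - y

    tau0 = max(np.ptp(t) / 3.0, 1e-3)
    x0 = np.array([y[-1], np.log(tau0), y[0]])
    res = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    fir_inf, log_tau, fir_0 = res.x
    tau = float(np.exp(log_tau))
    se_raw = _covariance_se(res, t.size, ("fir_inf", "log_tau", "fir_0"))
    se = {
        "fir_inf": se_raw["fir_inf"],
        "tau": tau * se_raw["log_tau"],  # delta method for the log parameter
        "fir_0": se_raw["fir_0"],
    }
    pred = fir_inf + (fir_0 - fir_inf) * np.exp(-t / tau)
    return ExponentialFit(
        fir_inf=float(fir_inf), tau=tau, fir_0=float(fir_0),
        standard_errors=se, r_squared=r_squared(y, pred),
        converged=bool(res.success),
    )


def bootstrap_ci(
    series: FIRSeries,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    c_mode: float | Literal["free"] = "free",
) -> dict:
    """Residual-resampling bootstrap percentile intervals for the fit.

    Fits once, then refits ``n_boot`` series built from the fitted curve
    plus resampled residuals.  Returns per-parameter ``(lo, hi)``
    intervals, the point fit, and the fraction of replicates that
    converged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentiles")
    base = fit_eq1(series, c_mode=c_mode)
    fitted_curve = series.fir - base.residuals
    rng = np.random.default_rng(seed)

    draws: dict[str, list[float]] = {"k_in": [], "k_out": [], "tau": [], "fir_inf": []}
    ok = 0
    for _ in range(n_boot):
        resampled = fitted_curve + rng.choice(base.residuals, size=len(series), replace=True)
        boot = FIRSeries(series.times, np.clip(resampled, 0, None))
        try:
            f = fit_eq1(boot, c_mode=c_mode, seed=int(rng.integers(2**31)))
        except (ValueError, RuntimeError):
            continue
        if not f.converged:
            continue
        ok += 1
        for k in draws:
            draws[k].append(getattr(f, k))

    alpha = (1 - level) / 2
    intervals = {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
        for k, v in draws.items()
        if v
    }
    return {
        "point": base,
        "intervals": intervals,
        "n_boot": n_boot,
        "success_fraction": ok / n_boot,
        "level": level,
    }
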