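"""Logistic fruit-radius growth model and real-time harvest prediction.

The radius at elapsed day ``X`` (days since April 1 of the detection
year) follows ``Y = a / (1 + b * exp(c * X))`` with ``a > 0``, ``b > 0``,
``c < 0``; the harvest-radius prediction is the curve's convergence
value, i.e. the asymptote ``a``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RadiusSeries",
    "GrowthFit",
    "growth_curve",
    "elapsed_days",
    "fit_growth_curve",
    "predict_harvest_radius",
    "realtime_predictions",
    "calibrate_to_physical",
]


@dataclass
class RadiusSeries:
    """Ordered (elapsed day, radius) observations for one fruit."""

    X: list[float]
    Y: list[float]
    fruit_id: int | str = 0

    def __post_init__(self) -> None:
        if len(self.X) != len(self.Y):
            raise ValueError("X and Y must have equal length")
        if any(x2 <= x1 for x1, x2 in zip(self.X, self.X[1:])):
            raise ValueError("X must be strictly increasing")
        if any(y <= 0 for y in self.Y):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.X)

    def prefix(self, max_day: float) -> "RadiusSeries":
        keep = [(x, y) for x, y in zip(self.X, self.Y) if x <= max_day]
        return RadiusSeries(
            X=[p[0] for p in keep], Y=[p[1] for p in keep], fruit_id=self.fruit_id
        )


@dataclass
class GrowthFit:
    a: float  # asymptotic radius
    b: float  # shape offset
    c: float  # rate (per day), negative
    rss: float = 0.0
    n_points: int = 0
    converged: bool = True
    message: str = ""
    flags: list[str] = field(default_factory=list)


def growth_curve(X, fit: GrowthFit):
    """Evaluate ``a / (1 + b * exp(c * X))``."""
    X = np.asarray(X, dtype=float)
    out = fit.a / (1.0 + fit.b * np.exp(fit.c * X))
    return float(out) if out.ndim == 0 else out


def elapsed_days(date: dt.date, reference_year: int) -> int:
    """Calendar days since April 1 of ``reference_year`` (April 1 -> 0)."""
    april1 = dt.date(reference_year, 4, 1)
    if date < april1:
        raise ValueError(f"{date} is before April 1 {reference_year}")
    return (date - april1).days


def predict_harvest_radius(fit: GrowthFit) -> float:
    """Convergence value of the growth curve (its asymptote ``a``)."""
    if fit.c >= 0:
        raise ValueError("growth curve does not converge for c >= 0")
    return fit.a


def _initial_guess(X: np.ndarray, Y: np.ndarray) -> tuple[float, float, float]:
    a0 = 1.05 * float(Y.max())
    # a0/Y - 1 = b * exp(cX)  =>  log(a0/Y - 1) = log b + c X
    z = a0 / Y - 1.0
    z = np.clip(z, 1e-12, None)
    slope, intercept = np.polyfit(X, np.log(z), 1)
    b0 = float(np.exp(intercept))
    c0 = float(slope)
    b0 = min(max(b0, 1e-5), 1e5)
    c0 = min(max(c0, -0.999), -1e-5)
    return a0, b0, c0


def fit_growth_curve(
    series: RadiusSeries,
    max_iterations: int = 500,
    rss_rel_tol: float = 1e-10,
) -> GrowthFit:
    """Bounded nonlinear least squares for (a, b, c).

    Initialization: ``a0 = 1.05 * max(Y)``; ``(log b0, c0)`` from a linear
    regression of ``log(a0/Y - 1)`` on ``X``. Non-convergence and
    degenerate data produce a flagged fit, not an exception.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points to fit the growth curve")
    X = np.asarray(series.X, dtype=float)
    Y = np.asarray(series.Y, dtype=float)
    if np.unique(X).size < 2:
        raise ValueError("need at least 2 distinct X values")

    a0, b0, c0 = _initial_guess(X, Y)
    y_max = float(Y.max())
    lower = (y_max, 1e-6, -1.0)
    upper = (50.0 * y_max, 1e6, -1e-6)
    x0 = (
        min(max(a0, lower[0] * (1 + 1e-9)), upper[0]),
        min(max(b0, lower[1]), upper[1]),
        min(max(c0, lower[2]), upper[2]),
    )

    def residuals(p):
        a, b, c = p
        return Y - a / (1.0 + b * np.exp(c * X))

    result = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        method="trf",
        ftol=rss_rel_tol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iterations * 10,
    )
    a, b, c = (float(v) for v in result.x)
    rss = float(np.sum(result.fun**2))
    flags = []
    if not result.success:
        flags.append("non_convergent")
    if np.ptp(Y) < 1e-9 * max(y_max, 1.0):
        flags.append("degenerate_flat_series")
    if a >= upper[0] * 0.999:
        flags.append("asymptote_at_bound")
    return GrowthFit(
        a=a,
        b=b,
        c=c,
        rss=rss,
        n_points=len(series),
        converged=result.success,
        message=str(result.message),
        flags=flags,
    )


def realtime_predictions(
    series: RadiusSeries,
    min_points: int = 5,
    min_span_days: float = 14.0,
) -> list[tuple[float, float | None]]:
    """Per-day harvest-radius predictions from growing prefixes.

    For each observed day ``d`` whose prefix has at least ``min_points``
    observations spanning at least ``min_span_days`` days, fit on the
    prefix and record the convergence value; days where the fit fails or
    is flagged unstable are recorded as ``None``.
    """
    out: list[tuple[float, float | None]] = []
    for d in series.X:
        prefix = series.prefix(d)
        if len(prefix) < min_points or (prefix.X[-1] - prefix.X[0]) < min_span_days:
            continue
        try:
            fit = fit_growth_curve(prefix)
        except ValueError:
            out.append((d, None))
            continue
        if not fit.converged or "asymptote_at_bound" in fit.flags:
            out.append((d, None))
        else:
            out.append((d, predict_harvest_radius(fit)))
    return out


def calibrate_to_physical(
    predictions: Sequence[tuple[float, float | None]],
    measured_radius: float,
    at_day: float,
) -> list[tuple[float, float | None]]:
    """Rescale relative predictions so the one at ``at_day`` equals a
    physically measured radius."""
    lookup = {d: p for d, p in predictions}
    ref = lookup.get(at_day)
    if ref is None:
        raise ValueError(f"no prediction available at day {at_day}")
    scale = measured_radius / ref
    return [(d, None if p is None else p * scale) for d, p in predictions]
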