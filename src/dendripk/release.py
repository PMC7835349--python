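"""First-order in vitro release kinetics and half-life estimation.

Cumulative release of drug from the conjugate in buffer (37 °C, pH 7.4)
follows single-rate first-order kinetics, ``f(t) = 1 - exp(-k_h t)`` with
complete release as the plateau.  The only free parameter is the hydrolysis
rate constant ``k_h``, reported alongside the half-life ``t_half = ln(2)/k_h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DataQualityError, InvalidParameterError, UnidentifiableError

__all__ = [
    "ReleaseCurve",
    "ReleaseFit",
    "k_from_half_life",
    "half_life_from_k",
    "cumulative_release_fraction",
    "fit_first_order_release",
]

_LN2 = math.log(2.0)


def k_from_half_life(t_half: float) -> float:
    """Convert a release half-life (h) to the first-order rate constant (h^-1)."""
    if not (t_half > 0 and math.isfinite(t_half)):
        raise InvalidParameterError(f"t_half must be strictly positive, got {t_half!r}")
    return _LN2 / t_half


def half_life_from_k(k_h: float) -> float:
    """Convert a first-order rate constant (h^-1) to the release half-life (h)."""
    if not (k_h > 0 and math.isfinite(k_h)):
        raise InvalidParameterError(f"k_h must be strictly positive, got {k_h!r}")
    return _LN2 / k_h


def cumulative_release_fraction(k_h: float, times) -> np.ndarray:
    """Fraction of drug released by time ``times`` under first-order kinetics."""
    if not (k_h > 0 and math.isfinite(k_h)):
        raise InvalidParameterError(f"k_h must be strictly positive, got {k_h!r}")
    t = np.asarray(times, dtype=float)
    return -np.expm1(-k_h * t)


@dataclass(frozen=True)
class ReleaseCurve:
    """A measured cumulative release curve: fraction released versus time (h).

    Small assay overshoot above 1 is tolerated (up to 1.05); a t=0 point, if
    present, must read essentially zero (≤ 0.05).
    """

    times: np.ndarray
    fraction_released: np.ndarray
    conjugate_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_released, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise InvalidParameterError("times and fractions must be 1-D arrays of equal length")
        if t.size == 0:
            raise InvalidParameterError("release curve is empty")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise InvalidParameterError("times must be non-negative and non-decreasing")
        if np.any(f < 0) or np.any(f > 1.05) or not np.all(np.isfinite(f)):
            raise InvalidParameterError("fractions must lie in [0, 1.05]")
        if t[0] == 0 and f[0] > 0.05:
            raise InvalidParameterError(f"fraction at t=0 is {f[0]}, expected ≤ 0.05")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_released", f)


@dataclass(frozen=True)
class ReleaseFit:
    """Least-squares estimate of the release rate constant."""

    k_h_hat: float
    t_half_hat: float
    residual_ss: float
    converged: bool
    stderr_k: float

    def __post_init__(self) -> None:
        expected = _LN2 / self.k_h_hat
        if abs(self.t_half_hat - expected) > 1e-9 * expected:
            raise InvalidParameterError("t_half_hat inconsistent with k_h_hat")


def _sum_of_squares(log_k: float, t: np.ndarray, f: np.ndarray) -> float:
    resid = f - (-np.expm1(-math.exp(log_k) * t))
    return float(resid @ resid)


def fit_first_order_release(curve: ReleaseCurve) -> ReleaseFit:
    """Fit ``f(t) = 1 - exp(-k t)`` to a cumulative release curve.

    Unweighted least squares on the fraction scale.  The one-dimensional
    objective is scanned on a wide log-spaced grid (multi-start) and the best
    bracket polished with bounded scalar minimisation, so the result is
    deterministic for given data.

    Raises
    ------
    UnidentifiableError
        if every observation sits in the flat regions (< 0.05 or > 0.95),
        where the data carry no rate information.
    DataQualityError
        if the curve drops by more than 0.2 between consecutive points,
        grossly violating cumulative-release monotonicity.
    """
    t, f = curve.times, curve.fraction_released
    informative = (f > 0.05) & (f < 0.95) & (t > 0)
    if t.size < 3 or not np.any(informative):
        raise UnidentifiableError(
            "release rate is unidentifiable: need ≥ 3 timepoints with at least "
            "one fraction strictly between 0.05 and 0.95"
        )
    drops = np.diff(f)
    if np.any(drops < -0.2):
        raise DataQualityError(
            f"cumulative release drops by {-drops.min():.2f} between consecutive "
            "timepoints; data fail monotonicity plausibility"
        )

    log_grid = np.log(np.logspace(-5, 2, 141))
    ss = np.array([_sum_of_squares(lk, t, f) for lk in log_grid])
    i = int(np.argmin(ss))
    lo = log_grid[max(i - 1, 0)]
    hi = log_grid[min(i + 1, log_grid.size - 1)]
    result = minimize_scalar(
        _sum_of_squares, bounds=(lo, hi), args=(t, f), method="bounded",
        options={"xatol": 1e-12},
    )
    k_hat = math.exp(min(result.x, log_grid[-1]))
    residual_ss = float(result.fun)

    # Gauss-Newton curvature: J_i = d model/dk = t_i exp(-k t_i)
    jac = t * np.exp(-k_hat * t)
    jtj = float(jac @ jac)
    dof = max(t.size - 1, 1)
    sigma2 = residual_ss / dof
    stderr = math.sqrt(sigma2 / jtj) if jtj > 0 else math.inf

    return ReleaseFit(
        k_h_hat=k_hat,
        t_half_hat=_LN2 / k_hat,
        residual_ss=residual_ss,
        converged=bool(result.success),
        stderr_k=stderr,
    )
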