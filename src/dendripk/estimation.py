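"""Estimation of the dendrimer disposition constants from in vivo data.

Two fitting stages, mirroring how the model is parameterised in practice:

1. ``k_res`` (RES uptake of the intact conjugate) from a total-drug plasma
   profile of a single designated conjugate whose ``k_h`` is known from the
   in vitro release fit.  Total plasma drug is treated as conjugated drug —
   released drug is a small, rapidly cleared fraction of the circulating pool.
2. ``k_ext`` (extravasation) and ``k_tu`` (tumour-to-plasma return of released
   drug) jointly, from released-drug tumour profiles of several conjugates at
   once, with ``k_res`` and each conjugate's ``k_h`` held fixed.  Pooling
   conjugates with well-separated release rates is what makes the pair
   identifiable.

Both objectives are unweighted least squares on the linear concentration
scale.  Terminal-sampling replicates (independent animals per timepoint) enter
as independent observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import InvalidParameterError, UnidentifiableError
from .model import MG_PER_ML_TO_UG_PER_ML, released_tumour_values
from .params import DispositionParams, DoseSpec, LinkerKinetics, ReleasedDrugPK
from .series import ConcentrationSeries

__all__ = [
    "FitResult",
    "ConjugateObservations",
    "MultiConjugateDataset",
    "fit_kres",
    "fit_tumour_params",
    "IdentifiabilityWarning",
]


class IdentifiabilityWarning(UserWarning):
    """The data barely constrain the parameter pair (near-degenerate fit)."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares parameter fit.

    ``estimates`` and ``stderr`` map parameter names (h^-1) to values; the
    standard errors come from the Gauss-Newton curvature at the optimum.
    """

    estimates: Dict[str, float]
    residual_ss: float
    n_obs: int
    converged: bool
    stderr: Dict[str, float]
    objective_trace: Optional[List[float]] = field(default=None)

    def __post_init__(self) -> None:
        if self.residual_ss < 0:
            raise InvalidParameterError("residual_ss must be non-negative")
        for name, value in self.estimates.items():
            if not (value > 0 and math.isfinite(value)):
                raise InvalidParameterError(f"estimate {name}={value!r} must be strictly positive")


@dataclass(frozen=True)
class ConjugateObservations:
    """One conjugate's released-drug tumour observations with its known kinetics."""

    linker: LinkerKinetics
    tumour_released: ConcentrationSeries
    dose: DoseSpec

    def __post_init__(self) -> None:
        s = self.tumour_released
        if s.tissue != "tumour" or s.species != "released":
            raise InvalidParameterError(
                f"expected a tumour released series, got {s.tissue}/{s.species}"
            )


@dataclass(frozen=True)
class MultiConjugateDataset:
    """Released-drug tumour profiles from several conjugates dosed identically.

    At least two conjugates with distinct release rates are recommended for a
    well-conditioned joint (k_ext, k_tu) fit; one is accepted.
    """

    entries: Tuple[ConjugateObservations, ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise InvalidParameterError("dataset needs at least one conjugate")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def n_obs(self) -> int:
        return sum(len(e.tumour_released) for e in self.entries)


def fit_kres(
    plasma_total: ConcentrationSeries,
    linker: LinkerKinetics,
    dose: DoseSpec,
    V_pl: float,
) -> FitResult:
    """Estimate the RES uptake constant from a total-drug plasma profile.

    Fits ``C(t) = (D/V_pl) exp(-(k_res + k_h) t)`` with ``k_h`` fixed, i.e. a
    one-parameter search over the total decay rate bracketed on a log grid,
    so the result is deterministic.  With a non-releasing conjugate
    (``k_h -> 0``) the fitted value is simply the total plasma decay constant.

    Raises
    ------
    UnidentifiableError
        if the profile is flat or increasing, leaving no decay to attribute
        to RES uptake beyond the known release rate.
    """
    if len(plasma_total) < 3:
        raise InvalidParameterError("need at least 3 plasma timepoints")
    if plasma_total.tissue != "plasma":
        raise InvalidParameterError(f"expected a plasma series, got {plasma_total.tissue!r}")
    if not (V_pl > 0):
        raise InvalidParameterError(f"V_pl must be positive, got {V_pl!r}")
    t = plasma_total.times
    y = plasma_total.values
    c0 = dose.dose_per_kg / V_pl * MG_PER_ML_TO_UG_PER_ML

    def ssr_of_log_total_rate(log_lam: float) -> float:
        resid = y - c0 * np.exp(-math.exp(log_lam) * t)
        return float(resid @ resid)

    log_grid = np.log(np.logspace(-6, 2, 161))
    ss = np.array([ssr_of_log_total_rate(v) for v in log_grid])
    i = int(np.argmin(ss))
    result = minimize_scalar(
        ssr_of_log_total_rate,
        bounds=(log_grid[max(i - 1, 0)], log_grid[min(i + 1, log_grid.size - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    lam_hat = math.exp(result.x)
    k_res_hat = lam_hat - linker.k_h
    if lam_hat < 1e-5 or k_res_hat <= 0:
        raise UnidentifiableError(
            "plasma profile is flat or decays no faster than linker release alone; "
            "k_res is unidentifiable"
        )

    pred = c0 * np.exp(-lam_hat * t)
    residual_ss = float(result.fun)
    jac = -t * pred  # d pred / d k_res
    jtj = float(jac @ jac)
    sigma2 = residual_ss / max(t.size - 1, 1)
    stderr = math.sqrt(sigma2 / jtj) if jtj > 0 else math.inf
    return FitResult(
        estimates={"k_res": k_res_hat},
        residual_ss=residual_ss,
        n_obs=t.size,
        converged=bool(result.success),
        stderr={"k_res": stderr},
    )


# multi-start grid for the joint fit: log-spaced over the plausible ranges
_KEXT_STARTS = np.logspace(-6, -1, 7)
_KTU_STARTS = np.logspace(-3, 0, 7)


def fit_tumour_params(
    data: MultiConjugateDataset,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
) -> FitResult:
    """Jointly estimate (k_ext, k_tu) from pooled released-drug tumour profiles.

    ``disp`` supplies the fixed ``k_res``, volumes and body mass (its ``k_ext``
    is ignored); ``rel`` supplies the fixed released-drug constants (its
    ``k_tu`` is ignored).  The pooled sum of squared residuals of the tumour
    released closed form is minimised over both parameters in log space, from
    a 7×7 log-spaced multi-start grid; the best local optimum is reported.
    The bi-exponential residual surface can hold local minima for a single
    late-sampled profile, which is also when the pair becomes practically
    unidentifiable — such fits trigger :class:`IdentifiabilityWarning` with
    the parameter correlation from the Gauss-Newton curvature.
    """
    prepared = [
        (e.linker.k_h, e.dose.dose_abs(disp.body_mass), e.tumour_released.times,
         e.tumour_released.values)
        for e in data.entries
    ]
    n_obs = data.n_obs

    def residuals(log_params: np.ndarray) -> np.ndarray:
        # clip keeps LM trial steps finite without affecting any plausible optimum
        k_ext, k_tu = np.exp(np.clip(log_params, -46.0, 46.0))
        chunks = [
            y - released_tumour_values(k_h, disp.k_res, k_ext, k_tu, d_abs, disp.V_tu, t)
            for (k_h, d_abs, t, y) in prepared
        ]
        return np.concatenate(chunks)

    best = None
    trace: List[float] = []
    for ke0 in _KEXT_STARTS:
        for kt0 in _KTU_STARTS:
            sol = least_squares(
                residuals,
                x0=np.log([ke0, kt0]),
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            trace.append(float(sol.cost))
            if best is None or sol.cost < best.cost:
                best = sol
    assert best is not None
    k_ext_hat, k_tu_hat = np.exp(best.x)
    residual_ss = 2.0 * float(best.cost)

    # delta-method standard errors from the log-space Jacobian, with a
    # heteroscedasticity-robust (sandwich) covariance: assay scatter is
    # multiplicative, so residual variance grows with the concentration and
    # the plain Gauss-Newton covariance would understate the uncertainty
    jac = best.jac
    resid = best.fun
    jtj = jac.T @ jac
    try:
        bread = np.linalg.inv(jtj)
        meat = jac.T @ (resid[:, None] ** 2 * jac)
        cov_log = bread @ meat @ bread * n_obs / max(n_obs - 2, 1)
        stderr = {
            "k_ext": float(k_ext_hat * math.sqrt(max(cov_log[0, 0], 0.0))),
            "k_tu": float(k_tu_hat * math.sqrt(max(cov_log[1, 1], 0.0))),
        }
        denom = math.sqrt(cov_log[0, 0] * cov_log[1, 1])
        corr = cov_log[0, 1] / denom if denom > 0 else 0.0
    except np.linalg.LinAlgError:
        stderr = {"k_ext": math.inf, "k_tu": math.inf}
        corr = 1.0
    if abs(corr) > 0.999 or np.linalg.cond(jtj) > 1e10:
        warnings.warn(
            f"(k_ext, k_tu) are practically unidentifiable from these profiles "
            f"(parameter correlation {corr:+.4f}); the confidence region is a ridge",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return FitResult(
        estimates={"k_ext": float(k_ext_hat), "k_tu": float(k_tu_hat)},
        residual_ss=residual_ss,
        n_obs=n_obs,
        converged=bool(best.success),
        stderr=stderr,
        objective_trace=trace,
    )
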