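"""Closed-form disposition model of a drug-dendrimer conjugate after bolus IV dosing.

A dendrimer-bound dose entering the circulation follows three first-order
routes: clearance of the intact conjugate by the reticuloendothelial system
(``k_res``), extravasation of intact conjugate into tumour interstitium
(``k_ext``), and hydrolytic release of free drug from the linker (``k_h``).
Extravasated conjugate is retained in the tumour (EPR effect, no backflow) and
keeps releasing drug there; released drug leaves the tumour at ``k_tu`` and, in
plasma, follows the free drug's three-compartment kinetics.

Because ``k_ext`` is orders of magnitude below ``k_res``, extravasation is
omitted from the plasma mass balance: plasma conjugated drug decays at
``k_res + k_h`` alone.  The four closed forms evaluated here are, with ``D``
the drug-equivalent dose:

* conjugated drug in plasma:   ``C = (D/V_pl) exp(-(k_res+k_h) t)``
* conjugated drug in tumour:   ``C = (D/V_tu)(k_ext/k_res) exp(-k_h t)(1-exp(-k_res t))``
* released drug in tumour:     a three-exponential cascade solution (see
  :func:`released_tumour_conc`)
* released drug in plasma:     a two-exponential short-time approximation,
  valid for t ≲ 2 h (see :func:`released_plasma_conc_approx`)

All closed forms are cross-validated against :func:`ode_reference_solution`,
a numeric integration of the same linear system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, OdeIntegrationError, SingularParameterError
from .params import ClosedFormConstants, DispositionParams, DoseSpec, LinkerKinetics, ReleasedDrugPK
from .series import ConcentrationSeries

__all__ = [
    "ApproximationDomainWarning",
    "closed_form_constants",
    "conjugated_plasma_conc",
    "conjugated_tumour_conc",
    "released_tumour_conc",
    "released_tumour_values",
    "released_plasma_conc_approx",
    "total_tumour_conc",
    "ode_reference_solution",
    "ODESolution",
]

MG_PER_ML_TO_UG_PER_ML = 1e3

#: the short-time plasma approximation is derived for t below this bound (h)
PLASMA_APPROX_T_MAX = 2.0

_SINGULAR_ATOL = 1e-12


class ApproximationDomainWarning(UserWarning):
    """Raised when the short-time plasma approximation is evaluated beyond 2 h."""


class NegativeClampWarning(UserWarning):
    """Raised when tiny negative round-off values are clamped to zero."""


def _as_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise InvalidParameterError("times must be a 1-D array")
    if t.size and (np.any(t < 0) or not np.all(np.isfinite(t))):
        raise InvalidParameterError("times must be finite and >= 0")
    return t


def exp_divided_difference(p: float, q: float, t: np.ndarray) -> np.ndarray:
    """Evaluate ``(exp(-p t) - exp(-q t)) / (q - p)`` stably.

    Written as ``exp(-p t) * t * phi((p - q) t)`` with ``phi(z) = expm1(z)/z``,
    which is exact in the removable limit ``q -> p`` (value ``t exp(-p t)``)
    and loses no precision for nearly equal rates.  This is the building block
    of every two- and three-exponential cascade solution in this module.
    """
    t = np.asarray(t, dtype=float)
    z = (p - q) * t
    safe = np.where(z == 0.0, 1.0, z)
    phi = np.where(z == 0.0, 1.0, np.expm1(safe) / safe)
    return np.exp(-p * t) * t * phi


def _clamp_negatives(values: np.ndarray, context: str) -> np.ndarray:
    """Zero out floating-point cancellation residue; reject real negatives."""
    if not np.any(values < 0):
        return values
    peak = float(np.max(values)) if values.size else 0.0
    tol = 1e-12 * max(peak, 1.0)
    worst = float(np.min(values))
    if worst < -tol:
        raise InvalidParameterError(
            f"{context}: negative concentration {worst} exceeds round-off tolerance"
        )
    warnings.warn(
        f"{context}: clamped negative round-off values (min {worst}) to zero",
        NegativeClampWarning,
        stacklevel=3,
    )
    return np.where(values < 0, 0.0, values)


def closed_form_constants(
    linker: LinkerKinetics, disp: DispositionParams, rel: ReleasedDrugPK
) -> ClosedFormConstants:
    """Compute the constants of the released-drug closed forms.

    ``alpha = k_ext k_h / k_res``; ``beta``, ``gamma``, ``delta`` are the
    exponential weights of the tumour cascade; ``omega`` prefixes the
    short-time plasma approximation.  Parameter combinations that annihilate a
    denominator are rejected — the concentration evaluators themselves handle
    those removable limits instead.
    """
    k_h, k_res, k_tu = linker.k_h, disp.k_res, rel.k_tu
    x = k_h - k_tu
    y = k_h - k_tu + k_res
    w = k_h + k_res - (rel.k_el + rel.k12 + rel.k13)
    for name, value in (("k_h - k_tu", x), ("k_h - k_tu + k_res", y),
                        ("k_h + k_res - (k_el + k12 + k13)", w)):
        if abs(value) < _SINGULAR_ATOL:
            raise SingularParameterError(f"denominator {name} vanishes ({value})")
    return ClosedFormConstants(
        alpha=disp.k_ext * k_h / k_res,
        beta=k_res / (y * x),
        gamma=1.0 / y,
        delta=1.0 / x,
        omega=k_h / w,
        k_el=rel.k_el,
    )


def conjugated_plasma_conc(
    linker: LinkerKinetics, disp: DispositionParams, dose: DoseSpec, times
) -> ConcentrationSeries:
    """Plasma concentration of still-conjugated drug (µg/mL).

    Bolus initial concentration is dose over plasma volume (both per kg body
    mass, so the mass cancels) and decays mono-exponentially at
    ``k_res + k_h``.
    """
    t = _as_times(times)
    c0 = dose.dose_per_kg / disp.V_pl * MG_PER_ML_TO_UG_PER_ML
    values = c0 * np.exp(-(disp.k_res + linker.k_h) * t)
    return ConcentrationSeries(t, values, "plasma", "conjugated",
                               linker.label, dose.dose_per_kg)


def conjugated_tumour_conc(
    linker: LinkerKinetics, disp: DispositionParams, dose: DoseSpec, times
) -> ConcentrationSeries:
    """Tumour concentration of still-conjugated drug (µg/mL).

    Extravasated conjugate accumulates at rate ``k_ext`` from the decaying
    plasma pool and is depleted only by linker hydrolysis: zero at t=0, a
    single interior maximum, decay like ``exp(-k_h t)``.
    """
    t = _as_times(times)
    d_abs = dose.dose_abs(disp.body_mass)
    prefactor = d_abs / disp.V_tu * (disp.k_ext / disp.k_res) * MG_PER_ML_TO_UG_PER_ML
    values = prefactor * np.exp(-linker.k_h * t) * (-np.expm1(-disp.k_res * t))
    return ConcentrationSeries(t, values, "tumour", "conjugated",
                               linker.label, dose.dose_per_kg)


def released_tumour_values(
    k_h: float, k_res: float, k_ext: float, k_tu: float,
    d_abs: float, v_tu: float, times: np.ndarray,
) -> np.ndarray:
    """Raw released-drug tumour profile in µg/mL (no container, no validation).

    Shared by :func:`released_tumour_conc` and the parameter-estimation
    objective, which evaluates it thousands of times.
    """
    prefactor = d_abs / v_tu * (k_h * k_ext / k_res) * MG_PER_ML_TO_UG_PER_ML
    shape = exp_divided_difference(k_h, k_tu, times) - exp_divided_difference(k_h + k_res, k_tu, times)
    return prefactor * shape


def released_tumour_conc(
    linker: LinkerKinetics,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    dose: DoseSpec,
    times,
) -> ConcentrationSeries:
    """Tumour concentration of released (free) drug (µg/mL).

    Solution of the cascade plasma-conjugate → tumour-conjugate → tumour-free,
    equal to the three-exponential form

    ``alpha (D/V_tu) [beta e^{-k_tu t} + gamma e^{-(k_h+k_res) t} - delta e^{-k_h t}]``

    but evaluated through stable exponential divided differences so the
    removable singularities at ``k_h = k_tu`` and ``k_h + k_res = k_tu`` need
    no special casing and cost no precision.
    """
    t = _as_times(times)
    d_abs = dose.dose_abs(disp.body_mass)
    raw = released_tumour_values(linker.k_h, disp.k_res, disp.k_ext, rel.k_tu,
                                 d_abs, disp.V_tu, t)
    values = _clamp_negatives(raw, "released_tumour_conc")
    return ConcentrationSeries(t, values, "tumour", "released",
                               linker.label, dose.dose_per_kg)


def released_plasma_conc_approx(
    linker: LinkerKinetics,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    dose: DoseSpec,
    times,
) -> ConcentrationSeries:
    """Short-time plasma concentration of released drug (µg/mL).

    Treats the peripheral compartments of the free drug as pure sinks, giving

    ``omega (D/V_c) [e^{-(k_el+k12+k13) t} - e^{-(k_h+k_res) t}]``.

    The neglected peripheral backflow makes this an underestimate that is only
    trustworthy for t ≲ 2 h; evaluation beyond that emits
    :class:`ApproximationDomainWarning`.  Plasma-Cmax calculations stay inside
    the window (the peak sits well below 1 h for realistic parameters).
    """
    t = _as_times(times)
    if np.any(t > PLASMA_APPROX_T_MAX):
        warnings.warn(
            f"short-time plasma approximation evaluated beyond {PLASMA_APPROX_T_MAX} h; "
            "values there underestimate the full three-compartment solution",
            ApproximationDomainWarning,
            stacklevel=2,
        )
    a = rel.k_el + rel.k12 + rel.k13
    b = linker.k_h + disp.k_res
    d_abs = dose.dose_abs(disp.body_mass)
    # d_abs in mg over V_c in L is mg/L ≡ µg/mL
    values = d_abs / rel.V_c * linker.k_h * exp_divided_difference(a, b, t)
    values = _clamp_negatives(values, "released_plasma_conc_approx")
    return ConcentrationSeries(t, values, "plasma", "released",
                               linker.label, dose.dose_per_kg)


def total_tumour_conc(
    linker: LinkerKinetics,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    dose: DoseSpec,
    times,
) -> ConcentrationSeries:
    """Total (conjugated + released) drug concentration in tumour (µg/mL)."""
    conj = conjugated_tumour_conc(linker, disp, dose, times)
    free = released_tumour_conc(linker, disp, rel, dose, times)
    return ConcentrationSeries(conj.times, conj.values + free.values,
                               "tumour", "total", linker.label, dose.dose_per_kg)


@dataclass(frozen=True)
class ODESolution:
    """Numeric reference solution of the full linear disposition system.

    ``series`` maps compartment names (``plasma_conjugated``,
    ``tumour_conjugated``, ``tumour_released``, ``plasma_released``,
    ``tumour_total``) to concentration series.  ``amounts`` holds the raw
    state trajectories in mg.  ``mass_balance`` is the conservation residual
    (total drug across compartments and elimination sinks, minus the
    extravasation ledger, minus the dose) as a fraction of the dose — zero to
    solver precision for a correct integration.
    """

    series: Dict[str, ConcentrationSeries]
    amounts: np.ndarray
    times: np.ndarray
    mass_balance: np.ndarray


def ode_reference_solution(
    linker: LinkerKinetics,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    dose: DoseSpec,
    times,
    rtol: float = 1e-11,
) -> ODESolution:
    """Integrate the full linear compartment system as a validation oracle.

    States (amounts, mg): plasma conjugated, tumour conjugated, tumour
    released, released-drug central and two peripheral compartments, plus
    bookkeeping sinks (RES uptake, central elimination, tumour return) and a
    cumulative-extravasation ledger.  The plasma conjugated balance omits the
    ``k_ext`` loss, mirroring the closed forms; the ledger state makes exact
    mass accounting possible despite that simplification.

    Independent of the closed-form evaluators by construction (generic LSODA
    integration of the rate matrix), so agreement is a genuine cross-check.
    """
    t = _as_times(times)
    k_h, k_res, k_ext, k_tu = linker.k_h, disp.k_res, disp.k_ext, rel.k_tu
    k_el, k12, k21, k13, k31 = rel.k_el, rel.k12, rel.k21, rel.k13, rel.k31
    d_abs = dose.dose_abs(disp.body_mass)

    # state: [A_cpl, A_ctu, A_rtu, A1, A2, A3, S_res, S_el, S_tu, L_ext]
    m = np.zeros((10, 10))
    m[0, 0] = -(k_res + k_h)
    m[1, 0] = k_ext
    m[1, 1] = -k_h
    m[2, 1] = k_h
    m[2, 2] = -k_tu
    m[3, 0] = k_h
    m[3, 3] = -(k_el + k12 + k13)
    m[3, 4] = k21
    m[3, 5] = k31
    m[4, 3] = k12
    m[4, 4] = -k21
    m[5, 3] = k13
    m[5, 5] = -k31
    m[6, 0] = k_res
    m[7, 3] = k_el
    m[8, 2] = k_tu
    m[9, 0] = k_ext

    x0 = np.zeros(10)
    x0[0] = d_abs

    t_span = (0.0, float(t[-1]) if t.size else 0.0)
    if t_span[1] == 0.0:
        sol_y = np.tile(x0[:, None], (1, t.size))
    else:
        result = solve_ivp(
            lambda _t, x: m @ x,
            t_span,
            x0,
            t_eval=t,
            method="LSODA",
            rtol=rtol,
            atol=max(d_abs, 1.0) * 1e-16,
            jac=lambda _t, _x: m,
        )
        if not result.success:
            raise OdeIntegrationError(
                f"reference integration failed: {result.message} "
                f"(nfev={result.nfev}, last t={result.t[-1] if result.t.size else 'n/a'})"
            )
        sol_y = result.y

    v_pl_abs = disp.V_pl * disp.body_mass  # mL
    to_ug_ml = MG_PER_ML_TO_UG_PER_ML

    def _series(values: np.ndarray, tissue: str, species: str) -> ConcentrationSeries:
        return ConcentrationSeries(t, np.clip(values, 0.0, None), tissue, species,
                                   linker.label, dose.dose_per_kg)

    series = {
        "plasma_conjugated": _series(sol_y[0] / v_pl_abs * to_ug_ml, "plasma", "conjugated"),
        "tumour_conjugated": _series(sol_y[1] / disp.V_tu * to_ug_ml, "tumour", "conjugated"),
        "tumour_released": _series(sol_y[2] / disp.V_tu * to_ug_ml, "tumour", "released"),
        # V_c is in L; mg/L ≡ µg/mL
        "plasma_released": _series(sol_y[3] / rel.V_c, "plasma", "released"),
        "tumour_total": _series((sol_y[1] + sol_y[2]) / disp.V_tu * to_ug_ml, "tumour", "total"),
    }
    balance = sol_y[:9].sum(axis=0) - sol_y[9] - d_abs
    if d_abs > 0:
        balance = balance / d_abs
    return ODESolution(series=series, amounts=sol_y, times=t, mass_balance=balance)
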