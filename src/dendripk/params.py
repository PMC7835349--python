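"""Parameter containers for the conjugate disposition model.

The model separates three groups of constants:

* linker kinetics — the first-order hydrolysis rate ``k_h`` of the cleavable
  linker, interchangeable with the release half-life via ``k_h = ln(2)/t_half``;
* dendrimer disposition — RES (reticuloendothelial system) uptake ``k_res``,
  tumour extravasation ``k_ext`` and the distribution volumes;
* released-drug pharmacokinetics — the three-compartment constants of the free
  drug after release, plus the tumour-to-plasma return rate ``k_tu``.

Canonical units throughout: hours, h^-1, mL, mg, µg/mL (≡ mg/L).  Plasma volume
is per kg body mass (the bolus plasma concentration then needs only the per-kg
dose); tumour and central-compartment volumes are absolute, so converting a
per-kg dose to an absolute drug mass requires a body mass, carried on
:class:`DispositionParams` (default 0.025 kg, a typical tumour-bearing mouse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = [
    "LinkerKinetics",
    "DispositionParams",
    "ReleasedDrugPK",
    "DoseSpec",
    "ClosedFormConstants",
]

_LN2 = math.log(2.0)
_REL_TOL = 1e-9


def _require_positive(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise InvalidParameterError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class LinkerKinetics:
    """Hydrolysis kinetics of one drug-linker chemistry.

    ``t_half`` (h) and ``k_h`` (h^-1) are redundant and must satisfy
    ``k_h = ln(2)/t_half``; use :meth:`from_half_life` or :meth:`from_rate`
    to construct one from the other.
    """

    label: str
    t_half: float
    k_h: float

    def __post_init__(self) -> None:
        _require_positive("t_half", self.t_half)
        _require_positive("k_h", self.k_h)
        expected = _LN2 / self.t_half
        if abs(self.k_h - expected) > _REL_TOL * expected:
            raise InvalidParameterError(
                f"inconsistent linker kinetics for {self.label!r}: "
                f"k_h={self.k_h} but ln(2)/t_half={expected}"
            )

    @classmethod
    def from_half_life(cls, label: str, t_half: float) -> "LinkerKinetics":
        _require_positive("t_half", t_half)
        return cls(label=label, t_half=t_half, k_h=_LN2 / t_half)

    @classmethod
    def from_rate(cls, label: str, k_h: float) -> "LinkerKinetics":
        _require_positive("k_h", k_h)
        return cls(label=label, t_half=_LN2 / k_h, k_h=k_h)


@dataclass(frozen=True)
class DispositionParams:
    """Dendrimer-level disposition constants.

    Parameters
    ----------
    k_res : float
        First-order RES uptake rate of the intact conjugate from plasma, h^-1.
    k_ext : float
        First-order extravasation rate of intact conjugate into tumour
        interstitium, h^-1.
    V_pl : float
        Plasma volume, mL per kg body mass.
    V_tu : float
        Tumour volume at dosing, mL (300 mm^3 ≡ 0.3 mL).
    body_mass : float
        Body mass, kg; converts per-kg dose to absolute drug mass.
    """

    k_res: float
    k_ext: float
    V_pl: float
    V_tu: float
    body_mass: float = 0.025

    def __post_init__(self) -> None:
        for name in ("k_res", "k_ext", "V_pl", "V_tu", "body_mass"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class ReleasedDrugPK:
    """Three-compartment PK constants of the released (free) drug.

    ``CL`` (L/h) and ``V_c`` (L) come from conventional IV dosing of the free
    drug; ``k12/k21/k13/k31`` are the micro-constants of the two peripheral
    compartments; ``k_tu`` is the first-order return of released drug from
    tumour tissue to the circulation.  The elimination constant
    ``k_el = CL/V_c`` is derived, not stored.
    """

    k_tu: float
    CL: float
    V_c: float
    k12: float
    k21: float
    k13: float
    k31: float

    def __post_init__(self) -> None:
        for name in ("k_tu", "CL", "V_c", "k12", "k21", "k13", "k31"):
            _require_positive(name, getattr(self, name))

    @property
    def k_el(self) -> float:
        """Elimination rate constant from the central compartment, h^-1."""
        return self.CL / self.V_c


@dataclass(frozen=True)
class DoseSpec:
    """A bolus IV dose expressed as drug-equivalent mass per kg body mass."""

    dose_per_kg: float  # mg/kg

    def __post_init__(self) -> None:
        if not (self.dose_per_kg >= 0 and math.isfinite(self.dose_per_kg)):
            raise InvalidParameterError(f"dose_per_kg must be non-negative, got {self.dose_per_kg!r}")

    def dose_abs(self, body_mass: float) -> float:
        """Absolute drug mass in mg for a given body mass in kg."""
        _require_positive("body_mass", body_mass)
        return self.dose_per_kg * body_mass


@dataclass(frozen=True)
class ClosedFormConstants:
    """The dimensioned constants of the released-drug closed forms.

    ``alpha = k_ext*k_h/k_res`` scales the tumour released profile;
    ``beta``, ``gamma``, ``delta`` weight its three exponentials and satisfy
    the algebraic identity ``beta + gamma - delta = 0`` (which forces the
    released tumour concentration to vanish at t=0); ``omega`` is the
    dimensionless prefactor of the short-time plasma approximation; ``k_el``
    is the central elimination constant.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    omega: float
    k_el: float
    identity_residual: float = field(default=0.0)

    def __post_init__(self) -> None:
        scale = max(abs(self.beta), abs(self.gamma), abs(self.delta))
        resid = abs(self.beta + self.gamma - self.delta)
        if scale > 0 and resid > _REL_TOL * scale:
            raise InvalidParameterError(
                f"beta + gamma - delta = {self.beta + self.gamma - self.delta} "
                "violates the zero identity"
            )
        object.__setattr__(self, "identity_residual", resid)
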