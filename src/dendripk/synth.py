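"""Synthetic study-data generator.

Emulates the two experimental data streams the analysis pipeline consumes:

* in vitro cumulative release curves in buffer (fraction released vs time),
  perturbed by additive Gaussian assay noise;
* in vivo mouse concentration-time datasets after a bolus IV dose — total
  drug in plasma (modelled as the conjugated pool) and released/total drug in
  tumour — sampled terminally, i.e. 2–3 independent animals per timepoint,
  with multiplicative lognormal assay scatter.

The noiseless truth is always the closed-form model from :mod:`.model`; the
generator contains no concentration math of its own.  Identical seeds
reproduce identical datasets bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError
from .estimation import ConjugateObservations, MultiConjugateDataset
from .model import (
    conjugated_plasma_conc,
    released_tumour_conc,
    total_tumour_conc,
)
from .params import DispositionParams, DoseSpec, LinkerKinetics, ReleasedDrugPK
from .release import ReleaseCurve, cumulative_release_fraction
from .series import ConcentrationSeries

__all__ = [
    "NoiseModel",
    "StudyDesign",
    "InVivoDataset",
    "make_table2_defaults",
    "generate_release_curve",
    "generate_in_vivo_dataset",
]

#: release half-lives (h) of the six synthesised conjugates: the initial
#: screening trio, then the second round aimed at the predicted optimum
CONJUGATE_HALF_LIVES: Dict[str, float] = {
    "SPL-8931": 201.0,
    "SPL-8932": 4.4,
    "SPL-8933": 1.7,
    "SPL-8974": 12.0,
    "SPL-8976": 7.0,
    "SPL-8977": 25.5,
}


def make_table2_defaults() -> Tuple[DispositionParams, ReleasedDrugPK, Tuple[LinkerKinetics, ...]]:
    """The reference mouse-xenograft parameter set.

    Dendrimer disposition: k_ext = 3.8e-4 h^-1, k_res = 0.21 h^-1, plasma
    volume 59.2 mL/kg, tumour volume 0.3 mL (300 mm^3).  Released drug:
    k_tu = 0.053 h^-1, CL = 0.0296 L/h, V_c = 0.0042 L, micro-constants
    k12 = 2.31, k21 = 0.108, k13 = 3.92, k31 = 4.36 h^-1.  Six conjugates
    with half-lives 201, 4.4, 1.7, 12, 7 and 25.5 h.
    """
    disp = DispositionParams(k_res=0.21, k_ext=3.8e-4, V_pl=59.2, V_tu=0.3)
    rel = ReleasedDrugPK(k_tu=0.053, CL=0.0296, V_c=0.0042,
                         k12=2.31, k21=0.108, k13=3.92, k31=4.36)
    linkers = tuple(
        LinkerKinetics.from_half_life(label, t_half)
        for label, t_half in CONJUGATE_HALF_LIVES.items()
    )
    return disp, rel, linkers


@dataclass(frozen=True)
class NoiseModel:
    """Seeded observation-noise law.

    ``lognormal_multiplicative`` scatters each value by a lognormal factor
    whose *arithmetic* mean is 1 (µ = -σ²/2, σ² = ln(1 + CV²)), so per-
    timepoint sample means converge to the model truth — matching how animal
    data are plotted as arithmetic means.  ``additive_gaussian`` adds
    homoscedastic noise with standard deviation ``cv_or_sd`` (used for
    release fractions).
    """

    kind: str = "lognormal_multiplicative"
    cv_or_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal_multiplicative", "additive_gaussian"):
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.cv_or_sd < 0:
            raise InvalidParameterError("cv_or_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        truth = np.asarray(truth, dtype=float)
        if self.cv_or_sd == 0:
            return truth.copy()
        if self.kind == "lognormal_multiplicative":
            sigma2 = np.log1p(self.cv_or_sd**2)
            factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=truth.shape)
            return truth * factors
        noisy = truth + rng.normal(0.0, self.cv_or_sd, size=truth.shape)
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of one synthetic in vivo study.

    Defaults mirror a terminal-sampling mouse study: timepoints 0.5–48 h,
    three animals killed per timepoint, 10 mg/kg drug-equivalent dose.
    """

    conjugates: Tuple[LinkerKinetics, ...]
    timepoints: Tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 24.0, 48.0)
    animals_per_timepoint: int = 3
    dose: DoseSpec = field(default_factory=lambda: DoseSpec(10.0))
    sample_plasma_total: bool = True
    sample_tumour_released: bool = True
    sample_tumour_total: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("timepoints must be strictly increasing and > 0")
        if self.animals_per_timepoint < 1:
            raise InvalidParameterError("animals_per_timepoint must be >= 1")
        if len(self.conjugates) == 0:
            raise InvalidParameterError("at least one conjugate required")
        object.__setattr__(self, "conjugates", tuple(self.conjugates))
        object.__setattr__(self, "timepoints", tuple(float(x) for x in t))


@dataclass(frozen=True)
class InVivoDataset:
    """Everything one synthetic in vivo study produced.

    ``tumour`` feeds the joint (k_ext, k_tu) fit; ``plasma_total`` (one total-
    drug series per conjugate) feeds the k_res fit; ``tumour_total`` mirrors
    the total-drug tumour assay.
    """

    tumour: Optional[MultiConjugateDataset]
    plasma_total: Dict[str, ConcentrationSeries]
    tumour_total: Dict[str, ConcentrationSeries]


def _default_release_times(linker: LinkerKinetics, n_points: int = 12) -> np.ndarray:
    """Sampling schedule covering two half-lives, truncated at 96 h.

    Mirrors a realistic dissolution-bath schedule: a t=0 blank plus
    log-spaced draws out to 2×t_half (slow releasers are cut off at 96 h,
    as a real experiment would be).
    """
    horizon = min(2.0 * linker.t_half, 96.0)
    inner = np.geomspace(horizon / 50.0, horizon, n_points - 1)
    return np.concatenate([[0.0], inner])


def generate_release_curve(
    linker: LinkerKinetics,
    noise: NoiseModel,
    times: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReleaseCurve:
    """Simulate one cumulative in vitro release curve.

    Truth is ``1 - exp(-k_h t)``; noise is applied per the noise model and the
    result clipped to the physically meaningful band [0, 1.05].  Pass ``rng``
    to draw several curves from one seeded stream.
    """
    t = _default_release_times(linker) if times is None else np.asarray(times, dtype=float)
    truth = cumulative_release_fraction(linker.k_h, t)
    gen = noise.rng() if rng is None else rng
    noisy = np.clip(noise.perturb(truth, gen), 0.0, 1.05)
    if t.size and t[0] == 0.0:
        noisy[0] = min(noisy[0], 0.05)
    return ReleaseCurve(times=t, fraction_released=noisy, conjugate_label=linker.label)


def generate_in_vivo_dataset(
    design: StudyDesign,
    disp: DispositionParams,
    rel: ReleasedDrugPK,
    noise: NoiseModel,
) -> InVivoDataset:
    """Simulate a terminal-sampling in vivo study for every conjugate.

    Each animal contributes one independent observation: the design's
    timepoints are replicated ``animals_per_timepoint`` times and each
    replicate perturbed around the closed-form truth.  Plasma total drug is
    generated from the conjugated-drug profile (released drug is a negligible
    share of the circulating total in this model).  A single seeded stream
    drives all conjugates in declaration order, so a (design, seed) pair
    fully determines the dataset.
    """
    rng = noise.rng()
    t_rep = np.repeat(np.asarray(design.timepoints, dtype=float),
                      design.animals_per_timepoint)

    entries = []
    plasma: Dict[str, ConcentrationSeries] = {}
    tumour_total: Dict[str, ConcentrationSeries] = {}
    for linker in design.conjugates:
        if design.sample_plasma_total:
            truth = conjugated_plasma_conc(linker, disp, design.dose, t_rep).values
            plasma[linker.label] = ConcentrationSeries(
                t_rep, noise.perturb(truth, rng), "plasma", "total",
                linker.label, design.dose.dose_per_kg,
            )
        if design.sample_tumour_released:
            truth = released_tumour_conc(linker, disp, rel, design.dose, t_rep).values
            obs = ConcentrationSeries(
                t_rep, noise.perturb(truth, rng), "tumour", "released",
                linker.label, design.dose.dose_per_kg,
            )
            entries.append(ConjugateObservations(linker, obs, design.dose))
        if design.sample_tumour_total:
            truth = total_tumour_conc(linker, disp, rel, design.dose, t_rep).values
            tumour_total[linker.label] = ConcentrationSeries(
                t_rep, noise.perturb(truth, rng), "tumour", "total",
                linker.label, design.dose.dose_per_kg,
            )

    tumour = MultiConjugateDataset(tuple(entries)) if entries else None
    return InVivoDataset(tumour=tumour, plasma_total=plasma, tumour_total=tumour_total)
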