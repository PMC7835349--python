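# Methods

## Model structure and assumptions

The disposition model is a linear cascade built on four assumptions: (i) the
intact conjugate stays in the vasculature and is cleared by the
reticuloendothelial system at first order (*k_res*); (ii) linker hydrolysis
in plasma and tumour proceeds at the rate measured in vitro at 37 °C, pH 7.4
(*k_h* = ln2/*t*₁/₂); (iii) free drug reaches the tumour only via
extravasation of intact conjugate (*k_ext*) followed by local release, not by
uptake of circulating free drug; (iv) extravasated conjugate is retained
(EPR), with no backflow of conjugated drug to blood. Released drug leaves the
tumour at *k_tu* and, in plasma, follows the free drug's three-compartment
kinetics (CL, V_c, k12/k21/k13/k31) as characterised from conventional IV
dosing.

Because *k_ext* (≈ 4 × 10⁻⁴ h⁻¹) is three orders of magnitude below *k_res*
(0.21 h⁻¹), extravasation is omitted from the plasma mass balance; the
numeric reference solution mirrors this so that closed forms and oracle solve
the same system. The omission creates mass at rate *k_ext·A_c,pl* in the
tumour compartment; the oracle integrates a cumulative-extravasation ledger
state so that conservation can still be asserted exactly (residual at solver
precision, ~10⁻¹⁵ of the dose).

## Units and dose handling

Canonical units: hours, h⁻¹, mL, mg, µg/mL (≡ mg/L). Plasma volume is per kg
(59.2 mL/kg), so the bolus plasma concentration needs only the per-kg dose.
Tumour (0.3 mL) and central (0.0042 L) volumes are absolute, so per-kg doses
are converted through a body mass carried on `DispositionParams` (default
0.025 kg, a typical tumour-bearing mouse; configurable). Every design
quantity is defined per unit dose and is therefore invariant to both dose
level and body mass, which the tests assert numerically.

## Numerical evaluation of the closed forms

The two- and three-exponential solutions are assembled from the scaled
divided difference `E(p,q,t) = (e^{-pt} − e^{-qt})/(q − p)`, computed as
`e^{-pt}·t·expm1(z)/z` with `z = (p−q)t`. This form is exact in the removable
limits (`k_h = k_tu`, which occurs at *t*₁/₂ ≈ 13.1 h — inside the design
scan — and `k_h + k_res = k_tu`) and loses no precision for nearly equal
rates, so no piecewise limit branches are needed. `closed_form_constants`
still rejects exactly singular configurations, naming the vanishing
denominator, because the textbook constants α…ω are undefined there.
Negative values from floating-point cancellation are clamped to zero when
below 10⁻¹² of the profile peak; anything larger raises.

The validation oracle integrates the 10-state linear system (three conjugate/
tumour states, three released-drug compartments, three elimination sinks, one
ledger) with LSODA at rtol 10⁻¹¹, and agreement is asserted to a relative
error of 10⁻⁶ of the profile peak across a swept parameter domain
(k_h ∈ [10⁻³, 1], k_res ∈ [0.01, 1], k_tu ∈ [0.01, 0.5] h⁻¹).

## The short-time plasma approximation

The released-drug plasma form treats the peripheral compartments as pure
sinks (loss k_el + k12 + k13, no returns). Since the neglected k21/k31 fluxes
only add drug back to the central compartment, the approximation is a strict
underestimate of the full three-compartment solution; with the fast
peripheral return k31 = 4.36 h⁻¹ the shortfall reaches ~20–30% near the peak.
The implementation therefore (a) asserts the one-sided bound (the
approximation never exceeds the oracle), (b) confines plasma-Cmax searches to
the stated (0, 2] h validity window, where the analytic peak
`t* = ln(a/b)/(a−b)` lies (~0.3 h for realistic parameters), and (c) warns
when evaluated beyond 2 h. The underestimate is conservative in the design
context — it inflates neither TI nor λ denominators selectively — and since
the same expression is used at every half-life, the λ argmax is unaffected by
its absolute bias.

## Estimation

All objectives are unweighted least squares on the linear concentration
scale; no transformation or weighting is applied. Terminal-sampling
replicates are independent observations; no animal-level random effects are
modelled (each animal contributes a single destructive measurement, so
within-animal correlation cannot arise).

* **Release fit** — one parameter (*k_h*), plateau fixed at complete release.
  A 141-point log-spaced scan over k ∈ [10⁻⁵, 10²] h⁻¹ brackets the optimum
  before bounded polishing, making the fit deterministic. Curves are
  unidentifiable if no fraction lies in (0.05, 0.95); drops > 0.2 between
  consecutive points are rejected as data errors.
* **k_res fit** — the total plasma decay rate λ = k_res + k_h is fitted with
  the same bracketed one-dimensional search, then k_h is subtracted. Total
  plasma drug is treated as conjugated drug: released drug is a small,
  rapidly cleared fraction of the circulating pool. k_res is estimated from
  one designated conjugate and shared across all others, since linker
  chemistry is a minor perturbation of a ~10⁵ Da carrier.
* **Joint (k_ext, k_tu) fit** — pooled residuals across all conjugates,
  minimised in log-parameter space by Levenberg–Marquardt from a 7×7
  log-spaced multi-start grid (k_ext ∈ [10⁻⁶, 10⁻¹], k_tu ∈ [10⁻³, 1] h⁻¹);
  the best local optimum is reported. k_ext enters the model as a pure scale
  factor, so rescaling the data rescales k_ext and leaves k_tu unchanged — a
  property the tests verify by refitting.

Standard errors come from the Gauss–Newton curvature with, for the joint fit,
a heteroscedasticity-robust (sandwich) covariance: assay scatter is
multiplicative, so residual variance grows with concentration and the
homoscedastic covariance understates uncertainty (measured two-sigma coverage
~70% versus ~90% with the sandwich form, over 100 seeded replicates at CV
20%). Near-degenerate fits (parameter correlation > 0.999 or curvature
condition number > 10¹⁰) emit an identifiability warning.

## Synthetic data

The generator emulates the structure of the real study, not its raw numbers:
first-order release curves with additive Gaussian assay noise (default sd
0.02 fraction units), and in vivo profiles with multiplicative lognormal
noise (default CV 20%, a typical LC-MS/MS + terminal-sampling scatter)
parameterised as µ = −σ²/2 so arithmetic per-timepoint means are unbiased,
matching how animal data are reported as means. Default in vivo schedule:
{0.5, 1, 2, 5, 24, 48} h, 3 animals per timepoint, 10 mg/kg; default release
schedule: 12 points to two half-lives, truncated at 96 h (the slowest
releaser is deliberately under-sampled, as a real 4-day bath experiment would
be, and its rate estimate correspondingly noisier). Noiseless output is
exactly the closed-form model — the generator contains no independent
concentration math.

What passing recovery tests show is internal consistency: the estimators
recover the generating truth under the assumed noise law and sampling
scheme. They do not establish robustness to model misspecification present
in real data (saturable RES uptake, tumour growth during the study,
formulation effects, assay LLOQ censoring), none of which the generator
simulates.

## Design optimisation

Tumour Cmax per unit dose is found by a 256-point geometric scan of the
unimodal released-tumour profile followed by bounded refinement (tolerance
10⁻⁶ h) on (0, 10·max(t₁/₂, 1/k_tu)]; plasma Cmax uses the analytic peak
time clipped to (0, 2] h. The half-life scan defaults to 400 log-spaced
points on [0.5, 200] h; grid argmaxes are polished by bounded scalar
optimisation inside the bracketing interval (tolerance 10⁻³ h), so reported
optima are grid-independent (doubling the density moves them < 0.1 h, as a
test asserts). Proportionality constants in TI, D_eff and λ are fixed at 1;
only ratios and argmax locations are meaningful. The effective-dose column
of the design grid is referenced to the tumour-Cmax-optimal half-life.

With the reference parameter set the tumour-Cmax curve has a very flat peak:
its refined argmax is 5.9 h, with less than a 1.5-fold variation across
5–24 h, so "the optimum is about 5–6 h" should be read as a plateau
statement. The λ curve peaks at 26.9 h.

## Problem sizes

Default test and pipeline workloads are sized for a laptop core: 400-point
design grids, 100-replicate recovery studies, 200-replicate release-bias
studies, and 10⁴-draw noise-calibration checks; the full suite runs in about
half a minute.

## Known limitations

* The plasma released-drug form is short-time only; no exact closed form for
  the full three-compartment response is provided (the ODE oracle covers it).
* No protein binding, cyclodextrin complexation, pH/temperature-dependent
  release, inter-species scaling, or dosing-schedule optimisation.
* The k_res fit treats total plasma drug as conjugated; for very fast
  releasers this biases k_res slightly high.
* Single-profile (k_ext, k_tu) fits can sit on a likelihood ridge; pooling
  conjugates with well-separated release rates is the supported design.
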