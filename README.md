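# dendripk

Disposition modelling and linker design for drug–dendrimer conjugates.

## The problem

A cytotoxic drug can be delivered as a covalent conjugate on a PEGylated
poly-L-lysine dendrimer: the intact nanocarrier circulates, extravasates into
tumour tissue (where the EPR effect retains it), and continuously releases
free drug by hydrolysis of a cleavable linker. The linker's release half-life
is a design variable. Release that is too fast reproduces the free drug's
toxicity (high plasma C<sub>max</sub>); release that is too slow starves the
tumour of free drug and forces impractically large doses. `dendripk`
implements the compartmental model, the parameter-estimation workflow, and
the optimisation index used to choose the half-life of a clinical candidate
conjugate, for pharmacokineticists and nanomedicine formulators.

## The model

After a bolus IV dose *D* (drug-equivalent mass), with first-order rate
constants (h⁻¹) for linker hydrolysis (*k<sub>h</sub>* = ln 2 / *t*₁/₂), RES
uptake of intact conjugate (*k<sub>res</sub>*), extravasation
(*k<sub>ext</sub>*) and tumour-to-plasma return of free drug
(*k<sub>tu</sub>*):

- conjugated drug in plasma
  `C_c,pl(t) = (D/V_pl) · exp(−(k_res + k_h) t)`
- conjugated drug in tumour
  `C_c,tu(t) = (D/V_tu)(k_ext/k_res) · exp(−k_h t)(1 − exp(−k_res t))`
- released drug in tumour
  `C_r,tu(t) = α(D/V_tu)[β e^(−k_tu t) + γ e^(−(k_h+k_res) t) − δ e^(−k_h t)]`
  with `α = k_ext k_h / k_res` and β, γ, δ rational in the rate constants
  (β + γ − δ = 0, so the profile starts at zero)
- released drug in plasma (short-time form, *t* ≤ 2 h)
  `C_r,pl(t) ≈ ω(D/V_c)[e^(−(k_el+k12+k13) t) − e^(−(k_h+k_res) t)]`,
  `k_el = CL/V_c`

The closed forms are evaluated through numerically stable exponential divided
differences (removable singularities such as *k<sub>h</sub>* =
*k<sub>tu</sub>* need no special casing) and validated against a numeric
integration of the full linear system, including a three-compartment model of
the released drug.

Design criteria over release half-life, all per unit dose: tumour
C<sub>max</sub> (efficacy driver), plasma C<sub>max</sub> (toxicity driver),
therapeutic index TI = C̄<sub>tu,max</sub>/C̄<sub>pl,max</sub>, effective
dose D<sub>eff</sub> ∝ 1/C̄<sub>tu,max</sub>, and the optimisation index

λ(t₁/₂) = C̄²<sub>tu,max</sub>(t₁/₂) / C̄<sub>pl,max</sub>(t₁/₂)

whose argmax identifies the optimal linker chemistry.

Estimation proceeds in stages, each by unweighted least squares:
*k<sub>h</sub>* per conjugate from in vitro cumulative release
(1 − e^(−k<sub>h</sub>t)); *k<sub>res</sub>* from a total-drug plasma profile
of one designated conjugate; (*k<sub>ext</sub>*, *k<sub>tu</sub>*) jointly
from pooled released-drug tumour profiles of several conjugates. A seeded
synthetic-data generator reproduces the study structure (terminal sampling,
2–3 animals per timepoint, multiplicative lognormal assay scatter) so the
whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
import dendripk as dp

disp, rel, linkers = dp.make_table2_defaults()      # reference mouse parameter set
dose = dp.DoseSpec(10.0)                            # 10 mg/kg drug-equivalent
slow = {l.label: l for l in linkers}["SPL-8977"]    # 25.5 h release half-life

t = np.array([0.5, 2.0, 8.0, 24.0, 48.0])
print(np.round(dp.released_tumour_conc(slow, disp, rel, dose, t).values, 4))
# [0.001  0.014  0.1261 0.3203 0.2884]   µg/mL of free drug in tumour

grid = dp.build_design_grid(disp, rel)              # scan half-lives 0.5–200 h
print(round(grid.argmax_tumour_cmax, 2), round(grid.argmax_lambda, 2))
# 5.91 26.92
```

The free-drug tumour profile rises for a day and persists — the conjugate
keeps releasing from the retained tumour reservoir. Over the half-life scan,
tumour C<sub>max</sub> per unit dose peaks near a 5.9 h half-life but is
nearly flat from 5 to 24 h, while plasma C<sub>max</sub> per unit dose falls
steeply; the optimisation index λ therefore peaks at a 26.9 h half-life,
pointing at the slow-releasing conjugate as the best trade-off of efficacy,
tolerability and dose.

The same run is available from the shell:

```bash
dendripk optimize --points 400          # JSON with both argmax half-lives
dendripk run --seed 1 --out runs/demo   # full synth → fit → optimise pipeline
```

`dendripk run` writes CSV artefacts plus a `manifest.json` recording version,
configuration and seeds; rerunning the same configuration reproduces
byte-identical outputs.

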