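# dermadyn

Quantitative models of how the mouse dermis builds and repairs itself.
During development, dermal fibroblasts proliferate, then progressively
arrest in G1 and switch to depositing extracellular matrix (ECM, chiefly
fibrillar collagen). `dermadyn` implements the hypothesis that a single
**negative feedback loop** — matrix contact drives proliferating
fibroblasts into quiescence, and quiescent fibroblasts are the efficient
matrix producers — is sufficient to explain the measured maturation time
course, the architecture of the adult dermis, and the kinetics of wound
repair.

The package is organised as an analysis project: the numbered scripts
under `analysis/` narrate the study, and every computation lives in the
importable library under `src/dermadyn/`. It is aimed at quantitative
skin biologists and modellers who want to rerun, perturb or extend the
models.

## The models

**Maturation kinetics** (`dermadyn.maturation`). Proliferating
fibroblasts *PF*, quiescent fibroblasts *QF* and matrix *ECM* obey

```
dPF/dt  = β·PF + κ₋₂·QF − κ₄·ECM·PF
dQF/dt  = κ₂·PF − κ₋₂·QF + κ₄·ECM·PF − κ₆·QF
dECM/dt = κ₃·QF − κ₇·ECM
```

where the catalytic step PF + ECM → QF + ECM (rate κ₄·ECM) is the
feedback. The system has a closed-form non-trivial steady state
(PF\*, QF\*, ECM\*) that exists only when κ₄ > 0 and whose linear
stability is decided by the Jacobian eigenvalues.

**Multi-objective fit** (`dermadyn.pareto`). The seven rate constants and
two initial conditions are fitted to two measured time courses — the
percentage of Ki67⁺ fibroblasts and the percent Picrosirius-red⁺
collagen area, embryonic day 10.5 through adulthood — by stability-
constrained Monte Carlo sampling: draws without a stable steady state are
discarded, the rest are scored by the pair (msePF, mseECM), and the
Pareto front of non-dominated pairs is extracted. Sampling is iterative
(per-parameter intervals contract around the balanced elite between
rounds), and one balanced front member is selected.

**Wound healing** (`dermadyn.wound`). The same kinetics on a 1-D circular
domain with Fickian transport of both fibroblast states (coefficient D;
matrix does not move). A wound zeroes all densities on [0.45, 0.5]; D is
calibrated so the proliferating-fibroblast content of the wound peaks
4.5 days after wounding, giving D ≈ 2×10⁻⁴ cm²/day with the unit domain
read as the ~3.2 cm trunk circumference.

**Tissue simulation** (`dermadyn.cpm`). A scaled 2-D Cellular Potts
(Glazier–Graner–Hogeweg) cross-section of the trunk: frozen lumen, closed
epidermal ring, and ten fibroblasts that grow under a decaying epidermal
signal gradient, divide, deposit matrix, quiesce at >50% matrix contact,
differentiate into adipocytes at the body wall, and — after a wound
removes a tissue slice at MCS 1,200 — re-activate, chemotax into the
clot and rebuild the matrix.

`dermadyn.datasets` ships the measured tables and the published
parameterisation; `dermadyn.synthetic` generates noisy model-based
datasets for end-to-end testing; `dermadyn.demography` holds the
cylinder-shell dermis-volume and log₂ division-count estimates.

## Worked example

```python
import numpy as np
from dermadyn import published_fit, simulate, fixed_point, pf_percentage
from dermadyn import wound

sol = published_fit()
print(round(pf_percentage(sol.pf0, sol.qf0), 2))   # 75.17  (measured: 75.1)

fp = fixed_point(sol.params)
print(round(fp.state.ecm, 2), fp.stable)           # 95.2 True

traj = simulate(sol, np.arange(10.5, 74.0, 0.5))
print(round(traj.ecm[-1], 1))                      # 89.5  (measured at day 73.5: 88.3)

field = wound.apply_wound(wound.steady_field(sol.params))
hist = wound.integrate(field, sol.params, t_end=30.0)
print(wound.peak_pf_day(wound.wound_means(hist)))  # 4.55 days postwounding
```

The first number is the model's proliferating-fibroblast percentage at
embryonic day 10.5; the second is the adult steady-state matrix level (on
the percent scale) with its stability verdict; the third is the simulated
collagen percentage at the last measured age; the last is the day the
wound's proliferating-fibroblast content peaks after wounding.

The full narrative lives in `analysis/01_maturation_dynamics.py` …
`analysis/05_division_estimate.py`; each script prints what it found and
writes its tables under `results/`. The command-line interface mirrors
the same stages (`dermadyn --help`).

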