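# Methods

This note documents the models implemented in `dermadyn`, the numerical
and design choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Maturation kinetics

The dermis is reduced to three pools: proliferating fibroblasts (PF),
quiescent fibroblasts (QF) and extracellular matrix (ECM). PF
self-replicate at net rate β (which absorbs growth-factor-driven division
and basal loss and may take either sign), interconvert with QF at rates
κ₂/κ₋₂, and are driven into quiescence catalytically by matrix contact at
rate κ₄·ECM — the negative feedback that is the core of the model. QF
deposit matrix at κ₃ and are lost at κ₆; matrix turns over at κ₇. All
rates are per day; amounts are on an arbitrary scale except ECM, whose
fitted steady state lands on the percent scale of the collagen data, so
model ECM is compared to the data directly while model PF is mapped to
the proliferating *fraction* 100·PF/(PF+QF). (The percentage formula with
an empty-compartment convention of 0, guarded at 10⁻¹², is applied
uniformly; this choice reproduces the measured day-10.5 percentage from
the fitted initial conditions to 0.1 points, but the mapping for the
maturation fit is an inference — only the wound analysis defines it
explicitly.)

The non-trivial fixed point has the closed form

PF\* = κ₇(κ₋₂(β+κ₂)+βκ₆)/(κ₃κ₄(β+κ₂)), QF\* = κ₇(κ₋₂(β+κ₂)+βκ₆)/(κ₃κ₄κ₆),
ECM\* = (κ₋₂(β+κ₂)+βκ₆)/(κ₄κ₆),

and exists only for κ₄, κ₃, κ₆ > 0 and β+κ₂ > 0 — without the feedback
the only steady state is the origin. Stability is decided by the
eigenvalues of the Jacobian of the right-hand side *evaluated at the
fixed-point state* (rather than transcribing a printed matrix, avoiding
typesetting ambiguity; agreement with central finite differences is
asserted in the tests). The stability verdict uses a tolerance of 10⁻⁸ on
the eigenvalue real parts and is insensitive to that choice over
[10⁻¹², 10⁻⁶] for the published parameters.

Integration uses an adaptive explicit Runge–Kutta scheme (scipy's RK45,
rtol 10⁻⁸, atol 10⁻¹⁰); the system is non-stiff at the published
parameter scales. Round-off-level negative excursions are clipped to
zero; larger ones abort.

## Multi-objective Monte Carlo fit

Fitting uses two objectives — the mean square deviations from the PF% and
ECM% datasets, both in percent² — under a hard admissibility filter: a
candidate whose fixed point is missing or linearly unstable is discarded
before any objective is computed (a dermis that cannot hold a steady
architecture is biologically inadmissible). The Pareto front of
non-dominated objective pairs is extracted with dominance defined as
(≤, ≤) with at least one strict; identical pairs do not dominate each
other. Because dominance is invariant to monotone rescaling of either
objective, no relative weighting of the datasets is needed.

Default search box: rates κ₂, κ₋₂, κ₃, κ₄, κ₆, κ₇ log-uniform on
[10⁻³, 3]; β uniform on [0, 1]; PF₀, QF₀ uniform on (0, 1]; ECM₀ fixed at
0 and t₀ at day 10.5 (no collagen is detectable at the first time point).
The box brackets the published parameterisation with at least a decade of
margin on every rate.

Plain uniform sampling of this nine-dimensional box is hopeless: the
jointly well-fitting region is a thin correlated valley, and in 10⁵
draws the measured joint hit rate at twice the published deviations is
zero even though each marginal is ~10⁻³. The sampler is therefore
iterative, in the spirit of interval-contraction Monte Carlo
multi-objective calibration: the draw budget (default 10 rounds) starts
on the full box; after each round the per-parameter intervals contract
around the current balanced elite — the 20 candidates with the smallest
worse-of-the-two deviations (a Chebyshev score, meaningful because both
objectives share a scale) — with an annealed margin; half of each later
round perturbs elite members with Gaussian noise (s.d. 15% of the current
interval width, annealed), which follows correlated directions an
axis-aligned box cannot express; and 10% of every round keeps sampling
the full box so the contraction cannot lock onto a secondary basin
permanently. Every evaluated candidate from every round enters the final
front. One round reduces the procedure to plain uniform sampling.
Identical (seed, n_iter, ranges, data) reproduce identical results;
because the sampling is adaptive, growing n_iter re-plans the rounds
rather than merely appending draws. Candidates whose integration
overflows at every step size are counted and skipped, never fatal.

Bulk objectives are evaluated with a vectorised fixed-step RK4 integrator
batched over candidates (base step 1/16 day; candidates that overflow are
re-integrated at 1/256 and 1/2048 before being declared failed; states
are clamped non-negative each step, which only removes round-off
excursions and stops the sign-flip blow-up of diverging steps). The
scalar `mse_pair` uses the adaptive solver and serves as the reference
the batch path is validated against in the tests (relative agreement
~10⁻⁴ for the published parameters, limited by the fixed step).

Selection from the front defaults to the *balanced* member, the minimiser
of max(msePF, mseECM). A min-max-normalised knee is also available but is
hostage to extreme trade-off members (fronts legitimately contain
candidates with one deviation in the thousands, which crush the
normalised scale of the other objective); with same-unit objectives the
Chebyshev summary is the robust choice. `min_pf` and `min_ecm` select the
extremes. Ties break by smaller msePF, then smaller κ₄.

## Wound healing PDE

The kinetics are extended to a 1-D domain of unit length with Fickian
transport of PF and QF (equal coefficient D); matrix does not diffuse —
it is deposited where quiescent fibroblasts sit. The intact dermis is the
uniform stable fixed point; a wound zeroes all three densities on the
closed interval [0.45, 0.5]. The default boundary condition is periodic
(the domain is a circular dermal cross-section); a no-flux option is
provided, and for the default interior wound the two differ by <0.5%.

Discretisation: second-order central differences, explicit Euler, default
201 grid points, time step min(0.4·dx²/(2D), 0.01) days; a user-supplied
step violating the diffusion stability bound is rejected before stepping.
Wound-interval summaries are trapezoidal integrals of each density,
plus the proliferating percentage 100·PF̄/(PF̄+QF̄) with the empty-wound
convention of 0.

**Units and the calibrated observable.** The proliferating *fraction*
inside the wound peaks on an intrinsic kinetic timescale (the matrix-free
wound bed re-expands PF at a rate set by β and κ₋₂, and local matrix
rebuild at κ₃, κ₇ shuts it down); its peak day saturates below ~2 days
however small D is, so it cannot be the quantity a motility calibration
targets. The D-sensitive observable is the proliferating-fibroblast
*content* of the wound, PF̄(t): it peaks when diffusive reseeding and
local re-proliferation balance, and `calibrate_D` (golden-section search
on log₁₀D, tolerance 2%, bracket endpoints checked for achievability)
places that peak at day 4.5 for D = 2×10⁻⁵ (domain length)²/day.
Identifying this with a physical motility of 2×10⁻⁴ cm²/day fixes the
unit domain at √10 ≈ 3.16 cm — the dermal circumference of a ~1 cm
diameter mouse trunk — under which the 0.05-wide wound is ≈1.6 mm,
consistent with a 2 mm punch biopsy. `peak_pf_day` therefore defaults to
the content observable (the percentage observable remains available),
and all diffusion coefficients are stated in both unit systems.

**Wound representation and convergence.** Zeroing the closed interval
removes an extra O(dx) strip beyond the nominal wound (the trapezoidal
mass deficit includes half a cell outside each edge), which shifts
summaries between resolutions by more than the truncation error. For
grid-convergence studies the package offers a resolution-consistent
variant that zeroes the open interior and halves nodes coinciding exactly
with an endpoint, making the interpolated initial condition the true step
at every resolution; with it the scheme converges at first order, and at
a 1601-point base grid a 2× refinement moves the wound summaries by
<0.5% of their steady-state scale. At the default solver-unit
D = 2×10⁻⁴ the wound means return to within 2% of the steady state by
day 60 and tissue farther than 4√(2Dt) from the wound never deviates by
more than 1%; at the physical mapping (domain D = 2×10⁻⁵) the day-60
recovery is slightly slower, ~2.5%.

## Cellular Potts tissue model

A 2-D (x, y) cross-section on a default 200×200 lattice stands in for the
3-D trunk segment: a frozen central disc is the body cavity (lumen), a
closed ring of epidermal cells encloses the dermal annulus, and the ten
initial proliferating fibroblasts are radial spokes spanning the annulus,
touching both the epidermis and the body wall — the natural reading of
cells "disposed radially" in an embryonic dermis only a cell-width thick.
One Monte Carlo step (MCS) is 200² = 40,000 Metropolis pixel-copy
attempts under a Hamiltonian with type-pair contact energies, a quadratic
volume constraint, and (post-wounding) chemotaxis up the wound signal;
matrix is a single shared immobile domain excluded from source selection
and never overwritten, and the per-MCS update order is fixed: Metropolis
sweep → growth/division → quiescence transition → matrix
deposition/maturation/compaction → adipocyte differentiation → field
relaxation.

Rules, in the package's terms:

* **Growth/division.** PF (and activated) cells gain target volume in
  proportion to the local epidermal signal — a short-range field relaxed
  by damped Jacobi sweeps from epidermis sources whose amplitude halves
  every 90 MCS (the signal "ages out"). A cell reaching the division
  volume splits along a random axis through its centroid; children
  inherit type and lineage label and each takes half the parent's target.
  The growth drive saturates at a cap and relaxes toward the baseline
  size, so a cell that cannot realise its growth does not accumulate
  unbounded drive.
* **Quiescence.** A proliferating (or wound-activated) cell whose
  4-neighbourhood boundary is more than 50% in contact with matrix
  (strict inequality) becomes quiescent, and then condenses gradually
  toward a smaller resting size — the lattice analogue of matrix
  replacing cellular volume as the tissue matures. Quiescence never
  reverts except through wound activation.
* **Matrix.** Free pixels (medium or clot) bordering a quiescent cell
  convert to matrix at 0.055 per MCS, bordering only proliferating/
  activated cells at 0.005 (quiescent cells are the efficient
  depositors). Two scaled-2-D extensions make a matrix-dominated adult
  composition reachable on a fixed lattice: deposited fibrils extend into
  adjacent free space at 0.009 per MCS (matrix maturation — collagen
  bundles grow through the tissue), and matrix encroaches on cells that
  exceed their target volume at 0.05 per boundary pixel per MCS, never
  squeezing below target (compaction). Without these, cells jam the
  dermis, deposition stalls at the jam surface and the quiescence rule
  can never fire tissue-wide.
* **Adipocytes.** After MCS 300, fibroblasts in direct contact with the
  body wall differentiate terminally into adipocytes.
* **Wounding.** At MCS 1,200 a radial slice (half-angle 0.13 rad) is
  cleared of cells, matrix and gradients; its dermal part is filled with
  a blood clot seeded with immune cells that source a short-range wound
  signal with its own decay clock. Fibroblasts within 14 px of the slice
  re-activate (proliferating-like rates, wound-field chemotaxis); the
  epidermis — frozen during unwounded maturation so the ring is integral
  by construction — is unfrozen, grows on the wound signal and chemotaxes
  to close the gap. Activated cells re-quiesce by the same >50%
  matrix-contact rule once the bed is rebuilt.
* **Lineage tracing.** Labelling a dermal band (upper/middle/lower third
  by normalised depth, 0 at the epidermis, 1 at the body wall) marks all
  fibroblasts whose centroid lies there; descendants inherit the label,
  and per-label depth distributions are recorded each MCS. The default
  labelling time used in the analysis is MCS 150, the stage at which the
  fibroblast lineages regionalise (MCS ≈ 200 corresponds to E17.5 on the
  model's time anchors).

All numeric defaults (contact energies, temperature 14, λ_volume 4,
growth and deposition rates, decay constants) were adjusted once so that
the simulated proliferating fraction is anchored to the measured course —
MCS 300 (birth on the model's clock) matches the birth-time measurement —
and are recorded in full in `data/cpm_defaults.toml`; no sensitivity
analysis is implied, mirroring the manually-adjusted character of such
tissue models. Time anchors (MCS 300 ≈ P0, MCS > 450 ≈ P5, MCS 1,200 ≈
P50) are configuration, not a formula. Per-cell volume bookkeeping is
revalidated against a full pixel recount every 100 MCS, and identical
configuration plus seed reproduces identical metrics (all randomness
flows from one seeded generator; the Metropolis kernel consumes
pre-drawn random arrays).

## Synthetic data

`synth_maturation` and `synth_wound` sample the respective model at
requested times and add per-time-point Gaussian noise — per-point
standard deviations copied from the measured tables where times coincide
(`table_sd`), a fixed value, or proportional to the mean — then truncate
to [0, 100]; the recorded sd column is always the generating sd, so
synthetic datasets are drop-in replacements for the measured ones. The
noise is unbiased before truncation; the truncation bias is accepted
because the measured sds are small relative to the range. The generator
emulates the *statistical shape* of the data (model-generated means,
independent Gaussian errors at the printed sds) and not biological
replicate structure, batch effects or measurement-specific artefacts —
passing recovery tests therefore demonstrates that the fitting machinery
works, not that the model is identifiable from real data.
`recovery_experiment` fits noiseless synthetic data from the published
parameterisation and scores *trajectory* recovery (RMS deviation of the
selected solution's curves from the generating curves on a dense grid);
parameter-level recovery is deliberately not scored, because distinct
parameter vectors produce near-identical curves.

## Problem sizes

The default analysis and acceptance runs use 100,000 Monte Carlo draws
for the fit and the recovery experiment, a 201-point PDE grid (1601/3201
for the convergence study), and a 200×200 lattice for 1,500 MCS — sizes
chosen so the whole analysis reruns on a desk machine in minutes.

## Known limitations

* The maturation fit's PF→percentage mapping is an inference (see above).
* The physical length of the PDE domain is fixed by requiring the
  printed motility to reproduce the day-4.5 peak; an independent
  anatomical measurement of the modelled circumference would pin it
  without that argument.
* The lattice model is 2-D with a fixed domain: dermal volume growth is
  represented by matrix replacing free space and cellular volume, not by
  tissue expansion; hair follicles, dermal white adipose maturation, and
  immune/endothelial biology beyond the clot construct are out of scope.
* The cell-level rules (spread, compaction, condensation) are scaling
  devices with biological motivation, not measured processes; their rates
  are anchored jointly to the proliferation time course and have no
  independent calibration.
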