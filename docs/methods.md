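# Methods

## Model structure and assumptions

The model couples the Lemaire osteoblast/osteoclast regulatory core to
explicit bone, tumor and drug variables.  State is kept internally in pM
(bone in generic "bone units", drug as a dimensionless ratio of the
0.1 mg/mouse reference dose); the data interface converts cell
concentrations to fM (×1000) and bone to percent of its day-0 value.

Assumptions worth making explicit:

* **TGF-β and PTH/PTHrP are implicit.**  π_C — the occupancy fraction of
  TGF-β receptors on osteoblast progenitors, `(C + f_O·C_s)/(C + C_s)` —
  stands in for free TGF-β, on the grounds that resorbing osteoclasts are
  its dominant source.  Likewise PTH/PTHrP acts through the quasi-steady
  occupancy π_P with hormone level `(I_P + S_P)/k_P`.  Tumor-derived PTHrP
  is assumed equipotent with PTH and enters as
  `I_P = Ī_P + k_Tpthrp·T·π_C`; the π_C factor encodes TGF-β-enhanced
  PTHrP secretion and closes the vicious cycle.
* **Hill-compensated bone fluxes.**  Per-cell formation/resorption rates
  `r_X = k1(k2ⁿ + Xⁿ)/Xⁿ` are bounded below by `k1`, double at `X = k2`,
  and grow as the population shrinks — tissue-scale homeostatic
  compensation.  Total fluxes are used in the algebraically simplified
  form `F(X) = k1(Xⁿ + k2ⁿ)/X^(n−1)`, finite at `X = 0` for the default
  Hill coefficients `n = 1` (a 1e-12 pM floor guards `n > 1`).  Note the
  consequence: formation never falls below `k1B·k2B` even with no
  osteoblasts, and resorption has the analogous floor — with raw reference
  parameters an aggressive tumor can therefore *raise* net bone by
  suppressing osteoblasts, whose loss collapses RANKL and hence
  osteoclasts.  Producing the osteolytic phenotype requires
  calibrated-scale tumor parameters (see the generator presets below).
* **Tumor growth** is logistic: the summed basal and TGF-β-enhanced
  division rate is multiplied by `(1 − T/M)` while death is unmodified,
  which keeps `T ≤ M` for `T(0) ≤ M`.  The alternative reading (a separate
  crowding-death term) is not distinguishable from the data used here.
* **Tumor–osteoblast interaction** is mass-action loss `k_T−B·T·B` from
  the active pool only; whether the cells die or transdifferentiate is
  immaterial at this resolution.
* **Drug action** is pure active-osteoclast killing `k_Z−C·Z·C` with no
  clearance (`dZ/dt = 0`): the enumerated reaction set contains no
  elimination step, so a bolus acts as a persistent dose.  No direct drug
  effect on tumor or osteoblasts is assumed.

## Parameters

All 36 constants, with units and defaults, are documented on
`tibd.params.ModelParameters`.  Six are structural and never calibrated
(`fO`, `IL`, `IO`, `IP`, `nB`, `nC`); five (`kTdiv`, `kTtgfb`, `kTdth`,
`kTpthrp`, `kTB`) are duplicated per tumor type.  Two defaults deserve
comment:

* `kB = 0.013/day` (active-osteoblast death) implies a slow ~77-day
  osteoblast turnover mode.  The tumor-free steady state that follows has
  π_C ≈ 0.78 and B ≈ 0.042 pM, and a 500-day settling run leaves a small
  residual drift (~2×10⁻⁶ pM/day).  `pre_equilibrate` therefore extends
  the settling window in 500-day blocks (default cap 2000 days) until the
  (R, B, C) derivatives fall below 10⁻⁶ pM/day, warning — not failing —
  when a sampled parameter set never settles.
* The "initial value" column is a calibration starting point, not a fitted
  set: with `kTpthrp = 500`, `kTB = 2` the simulated tumor *protects* bone
  (see above).  Downstream defaults that need a realistic phenotype use
  the generator presets instead.

## Simulation protocols

Every experiment starts from the tumor-free steady state (settling run
from `R = B = C = T = 0`, `N = 100`, `Z = 0`).  Three protocols mirror the
in-vivo designs: (i) 1 fM tumor injected at day 0; (ii) tumor at day 0
plus a unit ZA dose at day 6; (iii) ZA only.  Injections are additive
state jumps applied stop-inject-restart (the right-hand side stays
smooth); simultaneous events apply in listed order.  Relative bone density
is normalized to bone at protocol day 0 — the post-settling value, not the
nominal 100 the settling run starts from — so plots and likelihoods begin
at exactly 100%.

Integration uses LSODA with defaults rtol 1e-8 / atol 1e-10 pM and a
configurable internal step cap so pathological parameter sets fail fast.
Calibration uses rtol 1e-6 / atol 1e-8, which perturbs day-21 observables
by far less than any measurement error.

## Data processing

Histology counts convert to concentrations via `X/(N_A·A·h)` (slide
thickness 5 μm); osteoblast/osteoclast concentrations are rescaled by
mean-to-slide bone perimeter to remove sampling bias, with the mean
perimeter pooled per cell type across the study's slides.  BV/TV is
normalized to the mean of the no-tumor pool (all control mice plus day-7
tumor mice, where no tumor is histologically detectable).  Tumor
fluorescence is fit log-linearly over the untreated days-14/21/28 points;
the treated arm shares the pre-exponential (same inoculum) and is anchored
by its day-28 point alone, earlier points being flagged
`excluded_from_fit` as near the detection floor; concentrations are
fluorescence ratios to the fitted day-0 value, anchored at the injected
1 fM.  Figure-extracted datasets get the published error-bar policy: bone
density SE = 5 percentage points, tumor SE = 5% of each mean.  In-house
style datasets keep σ/√n.

## Synthetic data

The generator emulates the three raw input kinds from known ground truth:
Poisson slide counts (log-normal areas and perimeters, perimeter-correlated
OB/OC counts, log-normal overdispersion sd 0.25), per-mouse BV/TV
(log-normal, cv 0.20 around a 0.30 reference), and fluorescence
(gain-scaled latent tumor concentration, cv 0.30, detection floor).  Noise
magnitudes are set once to values typical of the respective assays —
murine trabecular BV/TV varies by ~15–25% across animals, and slide-level
histology scatter well exceeds counting statistics.  The design defaults
(three cohorts of eight mice, two slides per mouse, days 7/14/21 for the
bone-adapted study and 7–28 for the parental one) mirror the in-vivo
designs.

The ground-truth presets are chosen for the observed biology rather than
the reference column: bone-adapted `kTdiv = 1.0`, `kTtgfb = 0.1`,
`kTpthrp = 1500`, `kTB = 0.15`; parental `kTdiv = 0.55`, `kTtgfb = 0.3`,
`kTpthrp = 3000`, `kTB = 0.08`; shared truth `kZC = 0.3`.  These give the
qualitative in-vivo picture — severe osteolysis with osteoclast expansion
for the fast-growing bone-adapted line, slower loss for the
TGF-β-dependent parental line, treated bone stabilizing near 120–130%,
and per-cell PTHrP higher for the parental line even though the
bone-adapted line produces more PTHrP in total.

`make_recovery_benchmark` packages a seeded nine-dataset study (four
bone-adapted, five parental datasets).  Its parental tumor series are
drawn directly from the latent trajectories with noise matching the
claimed 5% errors, *not* through the fluorescence-extrapolation step: that
step's exponential extrapolation of the treated arm from a single anchor
point is systematically ~20–25% off the latent curve — an accepted
distortion when processing real data, but one that would confound a
parameter-recovery assessment, which must feed the calibrator data
statistically consistent with the claimed error model.  The extrapolation
pipeline is exercised by its own round-trip tests.

What passing the synthetic tests does *not* show: the generator has no
inter-animal correlation, no censoring by death or failed engraftment, no
section-location structure beyond random perimeters, and its noise
magnitudes are generic; recovery on this benchmark demonstrates the
correctness of the machinery, not the identifiability of real data.

## Calibration

35 sampled dimensions (25 shared + 2 × 5 tumor-specific), log10 scale.
Priors: log-normal, sd 2.0 decades (configurable) centered on the
reference values; log-uniform of total width 0.3 decades for `M`.  The
likelihood is independent-Gaussian per data point with the dataset SEs;
one ODE solve per (tumor type, protocol) pair per evaluation, with the
tumor-free pre-equilibration shared across types.  Solver failures reject
the sample with −∞.

The sampler is a DREAM-style multi-chain differential-evolution MCMC:
subspace-crossover proposals (CR ∈ {⅓, ⅔, 1}, γ = 2.38/√(2d′) with 10%
γ = 1 moves, ±10% jitter) built from difference vectors of an archive of
thinned past states, Metropolis acceptance, optional snooker moves.
Chains extend in blocks until the classic per-dimension Gelman-Rubin
factor (second-half-of-chain form) drops below 1.2 or a block cap is hit.
Post-processing discards the first half of each chain and filters samples
with log-likelihood below mean − 2·sd.

Initialization matters at desk scale: the Gaussian likelihood spans ~10⁵
log-units between the prior bulk and the posterior, and chains started
from the prior need far more iterations than a reduced run affords to
descend the narrow curved valley.  `run_mcmc` therefore defaults to a
descent initialization: each chain independently runs a windowed-archive
Metropolis descent (sliding 400-state window over its own history, 0.01-
decade jitter floor) from the default-parameter point, and the endpoint
clouds are merged into the initial archive.  Because the chains land on
diverse points of the high-likelihood region, the sampling phase starts
with cross-chain difference vectors spanning it — the geometry DE moves
need to traverse ridges.  Descent states are initialization only and never
reported as posterior samples.  `init="center"`/`"prior"` disable this.
One master seed drives everything; per-chain streams are spawned
deterministically, and runs are bit-reproducible.

Known limitation: at reduced scale (thousands rather than hundreds of
thousands of iterations per chain) the Gelman-Rubin factor typically stays
above threshold and marginals for weakly identified parameters — notably
the parental osteoblast-suppression rate `kTB`, unconstrained by any
parental osteoblast data — remain unreliable.  The recovery tests
therefore check credible-interval coverage over a focal set, not full
convergence.

## Posterior analysis

Marginals are smoothed with a Gaussian KDE at 3× the Scott reference
bandwidth and discretized on a uniform grid of ≥1000 segments (default
1024, padded by 3 bandwidths).  The histogram distance and expected
self-distance are computed as discrete sums on a shared grid; both depend
mildly on the segment count, so reports carry it.  `N_s` for the
self-distance is the smaller filtered-ensemble size, a conservative
choice.  Significance means `D > E[D_self]`, the self-distance averaged
over the two densities.  Distances are computed in log10 parameter space,
matching how the marginals are sampled and displayed.  Credible envelopes
are per-time 5th/50th/95th percentiles over simulated trajectories of (a
seeded subsample of) filtered ensemble members; solver failures are
excluded and counted.

## Numerical choices and degenerate inputs

* State components are floored at zero inside the right-hand side;
  tolerance-level solver undershoots are the only negatives that occur.
* π_P is floored at 1e-12 to guard underflow at extreme sampled rate
  ratios; π_L's OPG term raises a singularity error if evaluated directly
  with π_P = 0 and R > 0.
* Zero-variance samples are rejected by the KDE; zero within-chain
  variance reports a Gelman-Rubin factor of +∞ with a warning.
* Groups with a single observation have undefined SE and are dropped from
  assembled datasets with a logged warning; a tumor mean of zero under the
  5%-of-mean error policy is rejected (the likelihood needs finite
  weights).
* Events must be sorted, non-negative and within the horizon; an event at
  a recorded grid time is recorded post-injection, while the
  pre-equilibration endpoint is preserved separately as the protocol's
  day-0 state.

## Limitations

The drug has no pharmacokinetics (no clearance, no repeat dosing), the
model has no spatial or intracellular resolution, and the bone variable is
a single scalar density.  The reduced-scale calibration shipped in the
tests demonstrates machinery correctness on synthetic data; conclusions
about real tumor biology require full-scale runs and the original data.
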