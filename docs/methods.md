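# Methods

This note documents the models, estimators, defaults and numerical choices
behind `crossfeed`, and what the synthetic-data tests do and do not show
about real data.

## Community model

The community ODEs track live-cell densities of the two complementary
strains (`n_lh` consumes lysine L and releases hypoxanthine H; `n_hl` the
reverse) and the two free metabolite pools:

```
dn_lh/dt = (b_L(L) − d_L − c_L)·n_lh
dn_hl/dt = (b_H(H) − d_H − c_H)·n_hl
dL/dt    = r_L·n_hl − u_L·b_L(L)·n_lh
dH/dt    = r_H·n_lh − u_H·b_H(H)·n_hl
```

Assumptions: well-mixed culture; one genotype per strain; release is a
zero-order per-live-cell process; consumption is proportional to the birth
rate (utilization is "per birth", so dead or arrested cells consume
nothing); death `d` and overproduction cost `c` subtract from the birth
rate.  Growth assays measure *net* rates g = b − d − c; the documented
converter `birth_law_from_net_fit` shifts only `gmax`, since a subtractive
loss moves the whole curve uniformly.

At balanced growth both strains grow at the community rate, which gives the
closed-form `steady_state_growth_rate` (quadratic in the sum of losses and
the geometric mean of the exchange ratios `r_H/u_L` and `r_L/u_H`).  The
form with a single square root has no catastrophic cancellation for
non-negative parameters and is used as-is.  The central invariance —
`(r_H, u_L) → (κ·r_H, κ·u_L)` leaves `g_comm` unchanged for any κ > 0 — is
exact in floating point for κ that are powers of two and holds to rounding
error otherwise.

Birth kinetics are Moser: `b(m) = gmax·mⁿ/(Kⁿ + mⁿ)`.  The functional form
is assumed for both strains even though growth-vs-concentration data
typically exist for only one; with n = 1 it reduces to Monod, so this
assumption is a superset of the usual one.

**Units.** Hours, cells/ml, fmole/ml everywhere inside the library
(1 µM = 10⁶ fmole/ml).  Release rate r: fmole·cell⁻¹·hr⁻¹; utilization per
birth u: fmole·cell⁻¹.  Unit conversion happens only at assay-table
boundaries via per-column unit tags.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
rtol 1e-8, atol 1e-12.  Negative excursions smaller than the solver's own
error scale (max of atol and rtol times the component's magnitude) are
clipped to zero; anything larger raises, because it indicates a genuine
model or tolerance problem rather than integrator noise.

**Steady-state checks on trajectories** use the least-squares slope of
ln(total density) over the last 25% of the time grid, accepted as
stationary when it agrees with the preceding 25% window within 1%.

## Chemostat

```
dn/dt = (g(L) − dil)·n,   g = b(L) − d − c
dL/dt = L0·dil − L·dil − u·b(L)·n
dH/dt = r·n − dil·H
```

The same `StrainParams` object serves batch and chemostat; the single net
rate that appears in the classical chemostat balance is composed as
g = b − d − c.  Consumption is tied to the birth rate b (per-birth
utilization); when d = c = 0 — the default for the synthetic chemostat
generator — b = g and the printed steady-state estimators are exact:

- `u = (L0·dil − L_ss·dil)/(g_ss·n_ss)`, with the reservoir approximation
  `u ≈ L0/n_ss` valid when `L_ss ≪ L0`;
- `r = dil·H_ss/n_ss`;
- exchange ratio `r/u = (H_ss/L0)·dil`, which involves no cell density —
  the reason two strains with proportionally scaled (r, u) are
  experimentally indistinguishable by supernatant H alone.

At any simulated steady state the identity
`exchange_ratio = (r/u)·(1 − L_ss/L0)` holds; the estimator converges to
r/u as the residual concentration vanishes.

Steady state is declared when n, L and H each change by < 0.1% over one
dilution time.  The inoculation helper mirrors the protocol: inoculate at
one third of the expected density `L0/u`, vessel topped up with reservoir
medium; the starting metabolite concentration is not pinned by the
protocol, so it defaults to 0.4·L0 and is configurable.  Default operating
point: 19 ml vessel, 20 µM reservoir metabolite, 6-hr doubling time
(dil = ln2/6 ≈ 0.1155 hr⁻¹).

## Phenotyping estimators

All estimators are exact on noiseless data from their own generating model
class (verified in the test suite); the notes below cover the choices that
were genuinely open.

- **max_growth_rate**: maximum over consecutive 3–4-point windows of the
  least-squares slope of ln(fluorescence) vs time.  Flagged when the
  maximum lands in the final window (assay too short) or no positive slope
  exists.  An `exclude_before` argument (default 0 hr) drops the initial
  residual-growth phase: cells emerging from starvation grow for ~3 hr on
  vacuolar metabolite stores at a rate unrelated to the external
  concentration, and including that phase corrupts the concentration
  dependence.  Invariant to rescaling fluorescence by any positive
  constant.
- **fit_moser**: `lmfit` Levenberg–Marquardt with gmax initialized at the
  largest observed rate, K at the concentration nearest half-max, n = 1;
  n bounded to (0, 10]; uniform weights.  Non-convergence is reported,
  never silently coerced into parameters.
- **release_rate_batch**: concentration regressed on cumulative
  ∫n_live dt computed by the trapezoid rule (exact for piecewise-linear
  density; for an exponentially decaying culture sampled every 6 hr at a
  1%/hr death rate the quadrature bias is ~3·10⁻⁴ relative, far below
  assay noise).  The intercept is left free because washed cultures can
  carry a nonzero time-zero supernatant concentration; the slope is the
  estimate.
- **utilization_per_birth**: through-origin least-squares slope of final
  density vs input concentration, restricted to an explicit linear range
  (default 25 µM, per the assay's validated range) rather than automatic
  breakpoint detection; u = 1/slope with the slope's standard error
  propagated through the reciprocal.  An optional inoculum density is
  subtracted so only metabolite-supported births are counted.
- **propagate_ratio_error**: `σ_f = |A/B|·sqrt((σ_A/A)² + (σ_B/B)²)` for
  independent errors — first-order (delta-method) propagation, checked
  against a 10⁶-draw Monte-Carlo oracle to 3%.  A = 0 with σ_A > 0 is
  rejected (the relative-error form is undefined there).
- **calibrate_bioassay**: replicate-averaged standards must be monotone;
  inversion is piecewise-linear; out-of-range queries are flagged, never
  extrapolated.
- **steady_state_rate**: ln(density) slope after lag exclusion and below a
  density cap (default 10⁸ cells/ml, above which growth leaves the
  exchange-limited regime).  The lag rule in the source protocol is
  visual; the `"auto"` policy (drop leading points until the local 3-point
  slope is within 20% of the trailing-quarter slope) is a documented
  stand-in, and an explicit time cutoff is also supported.  Reported
  uncertainty convention is ±2 standard errors.

## Aneuploidy calling

**Depth route.** Per-base depth → mean per successive non-overlapping
1000-bp window → divide by the genome-wide median window mean → log2.
Coordinates are 0-based half-open; trailing partial windows are dropped
(short windows are high-variance and contribute nothing at chromosome
scale).  Zero-depth windows get the profile's minimum finite log2 minus 1
and a flag, never ±inf.  A chromosome is called duplicated when its mean
window log2 ≥ 0.6 — between euploid (≈0) and duplicated-in-haploid (≈1);
the source analysis inspects these plots visually, so the threshold is
explicit, configurable and reported in the output.

**RAD route.** Marker filters (independent predicates, order-free):
median per-sample coverage ≥ 2; cross-strain CV (sd/mean of the normalized
proportion across all analyzed samples) < 0.6, with CV = 0.6 discarded;
expected fragment length strictly between 125 and 400 bp (gel-cut bounds,
exclusive); observed alignment length equal to expected.  Proportions are
renormalized over retained markers per sample and compared marker-by-marker
to the euploid panel's median proportion; a supercontig's score is the
*mean of per-marker ratios* (the alternative — ratio of mean proportions —
weights high-proportion markers more; the per-marker mean is used and
users should be aware of the choice).  Supercontigs with < 5 retained
markers are reported as no-call, not euploid.

The fold threshold defaults to 1.6 rather than a literal 2.0: per-sample
renormalization depresses the on-target ratio of a duplication covering
weight fraction f of the markers to 2/(1+f) (≈1.89 at f = 6%) and the
off-target ratio to 1/(1+f), so a strict ≥ 2 rule fails even on noiseless
data.  1.6 sits midway between the renormalized on- and off-target values
with wide margins at realistic f; it is configurable and recorded in every
call set.

**Tetrads.** A disomic × euploid cross gives a zygote trisomic for the
target chromosome; meiosis I segregates three homologs 2:1, so the four
spores carry copy numbers [2,2,1,1] — the 2:2 expectation the segregation
check tests.  Any no-call spore makes the verdict indeterminate rather
than false.

## Synthetic data

Generators emulate the statistical structure each estimator assumes, with
one noise knob: multiplicative lognormal measurement noise (positive data)
scaled to mean exactly 1 at a given CV.  Defaults follow the study
conditions where stated: 20 µM reservoir lysine and 6-hr doubling chemostat;
u = 2 fmole/cell and r = 0.4 fmole/cell/hr scale phenotypes (u matches the
reservoir-over-density arithmetic of the chemostat protocol); release
assays sampled every 6 hr for 24 hr; yield assays linear to 25 µM;
microscopy inocula ~5·10³ cells/ml; 30× base coverage Poisson depth; 3000
RAD markers over 16 supercontigs with the target carrying ~6% of marker
weight, 10⁶ reads per spore, a 10-sample euploid panel.  Where the source
protocol states no value (noise model, marker-weight dispersion, residual
growth duration) a single realistic choice is documented here and not
tuned: lognormal noise, lognormal marker weights (σ = 0.5), 3-hr residual
phase at gmax.

Depth tracks use 16 chromosomes of 20–65 kb rather than megabase
chromosomes: the windowed statistics depend on chromosome length only
through the window count, and ≥ 20 windows per chromosome already puts the
caller's error probability far below any practical threshold, so the
compact genome is the package's chosen problem size.

Meiotic nondisjunction is not modeled (rate 0); the 2:2 tetrad outcome is
the modeled ideal.  Marker-proportion overdispersion beyond multinomial is
not modeled by default.

**What passing tests show — and don't.** The generators share their model
class with the estimators, so recovery tests demonstrate correctness of
the estimation machinery and its noise robustness, not robustness to real
data's unmodeled structure: pipetting drift, non-lognormal outliers,
mapping bias along chromosomes, GC-dependent coverage, restriction-site
polymorphism, or partial aneuploidy.  The depth and RAD callers are tested
against planted whole-chromosome duplications only.

## Classification workflow

`classify_mutation` compares two strains' exchange ratios with a two-sided
z-test on the propagated sigmas (α = 0.05 default) to label the
partner-serving axis increased/unchanged/decreased.  A z-test at the
summary-statistic level mirrors comparisons performed on replicate means
when raw replicates are unavailable.  The self-serving axis compares
Moser-fit growth at a limiting concentration (the ancestor's K/2) with a
5% relative-change deadband.  When a partner phenotype is supplied, the
closed-form community growth rate is recomputed with the mutant
substituted in, quantifying the predicted long-term effect on the partner.

## Known limitations

- No spatially structured or agent-based community model; the ODEs assume
  a well-mixed environment (the steady-state rate regression applies to
  spatial data as input, but the dynamics are not modeled).
- No inoculum-threshold (Allee) analysis beyond what the ODEs produce, and
  no within-run evolution of parameters.
- The chemostat estimators assume the culture reached steady state;
  `SteadyStateSummary.attained` must be checked.
- Ploidy baselines above haploid-vs-disomic (e.g. diploid gaining a third
  copy) are out of scope for the callers' thresholds.
- Alignment, variant calling and read-level quality filtering are upstream
  of this package; marker tables and depth tracks are taken as given.
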