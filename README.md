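# crossfeed

Tools for quantifying metabolite exchange in obligate cross-feeding
microbial mutualisms — for microbial ecologists and experimental-evolution
labs who need to decide whether a mutation arising in one partner of a
mutualism actually serves the other partner.

## The problem

Consider a two-strain community in which each strain overproduces and
releases an essential metabolite the other cannot make (the canonical
example: two engineered *S. cerevisiae* strains exchanging lysine and
hypoxanthine).  A mutant that releases *more* metabolite per cell looks
partner-serving.  But if the same mutation also makes each cell *cost more*
of the partner's metabolite to build — e.g. a chromosome duplication that
enlarges cells — the partner gains nothing over the long run: a fixed
metabolite budget buys fewer, more-generous cells.  The quantity that
actually matters to the partner is the **exchange ratio**

> r / u — metabolite release rate per cell (fmole · cell⁻¹ · hr⁻¹) divided
> by partner-metabolite utilization per cell birth (fmole · cell⁻¹),

because the steady-state community growth rate depends on the strain
phenotypes only through the geometric mean of the two exchange ratios:

```
g_comm = −(d_H + c_H + d_L + c_L)/2
         + sqrt( r_H·r_L/(u_L·u_H) + (d_H + c_H − d_L − c_L)²/4 )
       ≈ sqrt( r_H·r_L / (u_L·u_H) )          (small losses d, c)
```

with `d` the death rates, `c` the growth-rate costs of overproduction, and
strain birth rates following Moser (sigmoidal Monod) kinetics
`b(L) = gmax·Lⁿ/(Kⁿ + Lⁿ)`.  Scaling one strain's `(r, u)` by a common
factor leaves `g_comm` exactly unchanged — the mathematical statement of
"bigger cells that release more but cost more are not partner-serving".

## What the package provides

- **`crossfeed.model_core`** — the four-variable community ODE model
  (two strain densities, two free metabolite pools), its closed-form
  steady-state growth rate, approximation, and strain ratio.
- **`crossfeed.chemostat`** — single-strain chemostat model and the
  steady-state estimators `u = (L0 − L_ss)·dil/(g_ss·n_ss)`,
  `r = dil·H_ss/n_ss`, and the density-free exchange ratio
  `r/u = (H_ss/L0)·dil`.
- **`crossfeed.phenotyping`** — regression estimators for batch assays:
  maximal ln-slope growth rates, Moser-law fits, release rate from
  concentration vs integrated live density, utilization from through-origin
  yield slopes, flow-cytometry bead calibration, bioassay standard curves,
  post-lag steady-state rates, and uncorrelated-error ratio propagation.
- **`crossfeed.ploidy`** — aneuploidy callers: 1000-bp windowed
  median-normalized log2 read-depth profiles, and a RAD-marker route with
  quality filters (median coverage ≥ 2, cross-strain CV < 0.6, fragment
  length strictly inside 125–400 bp), euploid-panel fold-change calls, and
  a 2:2 tetrad segregation check.
- **`crossfeed.synthetic`** — seeded generators for every assay type with
  ground-truth records, so every estimator is testable end to end.
- **`crossfeed.cli`** — `crossfeed` command with subcommands
  (`simulate-community`, `simulate-chemostat`, `chemostat-estimate`,
  `fit-growth`, `fit-moser`, `release-rate`, `utilization`,
  `exchange-ratio`, `call-ploidy`, `rad-call`, `tetrad-check`, `generate`,
  `classify`) and the `classify_mutation` workflow.

## Worked example: classifying a cell-size duplication

An ancestor releases 0.30 fmole/cell/hr and utilizes 2.0 fmole/birth; a
candidate mutant measures 0.61 fmole/cell/hr and 4.1 fmole/birth (both from
independent assays with standard errors), and its growth-vs-lysine Moser
fit shows much better affinity (K drops from 2.0 to 0.6 µM-equivalent):

```python
from crossfeed import MoserParams, RatioWithError, StrainParams
from crossfeed.cli import PhenotypeEstimate, classify_mutation, format_report

partner = StrainParams(r=1.0, u=5.0, d=0.01, c=0.01,
                       birth_law=MoserParams(0.5, 2e6, 1.0))
anc = PhenotypeEstimate(release=RatioWithError(0.30, 0.015),
                        utilization=RatioWithError(2.0, 0.08),
                        moser=MoserParams(0.45, 2.0e6, 2.0))
mut = PhenotypeEstimate(release=RatioWithError(0.61, 0.03),
                        utilization=RatioWithError(4.1, 0.17),
                        moser=MoserParams(0.42, 0.6e6, 2.0))
print(format_report(classify_mutation(anc, mut, partner=partner)))
```

prints

```
Mutation classification
-----------------------
exchange ratio: ancestor 0.15 ± 0.0096, mutant 0.1488 ± 0.0096 (fmole/fmole/hr)
two-sided z-test: z = -0.090, p = 0.9283
partner-serving axis: exchange ratio unchanged
predicted community growth rate: 0.1635 -> 0.1628 /hr (-0.43%)
self-serving axis (growth at limiting concentration): 0.09 -> 0.3088 /hr, improved
```

Despite doubling its per-cell release rate, the mutant's exchange ratio is
statistically indistinguishable from the ancestor's (p = 0.93) and the
predicted community growth rate is unchanged — the mutation is strictly
self-serving (better growth under metabolite limitation), not win-win.

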