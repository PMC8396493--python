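# Methods

## The model

`cohortlife` implements classic female-based cohort life-table demography.
A cohort of eggs is followed individually; the analysis reduces it to two
schedules on a whole-day age grid with origin at egg deposition:

* `l_x` — probability that a newborn (egg) is alive at age `x`.  Immature
  mortality affects both sexes; after the final molt only females are
  tracked, under the assumption that immature survival is sex-independent
  (immatures cannot be sexed, so this is also the only identifiable
  convention).  Formally `l_x = S_imm(x) · S_F(x)` where `S_imm` is the
  fraction of all individuals not dead as immatures by `x` and `S_F` the
  fraction of adult-reaching females still alive at `x`.
* `m_x` — female eggs per living female per day: the mean daily egg count
  over adult females alive at `x`, multiplied by the progeny female
  fraction.  Females that never oviposit stay in the denominator
  (excluding them would bias `R0` upward).

Birch's parameters follow: `R0 = Σ l_x m_x`, `r_m` the unique real root of
`Σ e^{-r_m x} l_x m_x = 1` (the left side is strictly decreasing in `r_m`,
and `m_0 = 0` guarantees a sign change), `T = ln(R0)/r_m`, `λ = e^{r_m}`.
Ages enter the sums exactly as the grid values; a mid-interval
"pivotal-age" variant (`x + 0.5`) is available but off by default, because
the plain sums are the variant under which printed `(R0, r_m, T, λ)`
quadruples of studies in this literature satisfy `T = ln(R0)/r_m` and
`λ = e^{r_m}` exactly.

### Numerical choices

* Root solve: bracket from `[-1, 2]` per day, doubled up to `|r_m| = 10`
  (growth rates outside that range are biologically impossible for
  arthropods on a daily scale), then Brent's method at machine precision;
  the returned root must leave a renewal residual below `tol` (default
  1e-10).  Roots within 1e-13 of zero are snapped to exactly zero so a
  stationary cohort reports `r_m = 0`, `λ = 1`, and — when reproduction is a
  single pulse — `T` equal to the pulse age (the limit of `ln(R0)/r_m`).
* Immature deaths carry no observed death age (the record schema stops at
  the first failed transition), so survivorship uses a drop-out convention:
  an individual dying in stage `s` counts as alive at whole-day ages
  `x ≤` its entry age into `s` (0 for egg deaths) and dead after.  With
  immature stages lasting ~0.6–2 days this displaces `l_x` by at most one
  day for a small minority of the cohort.
* Adult ages: a female molting at half-day age `A` is first observed as an
  adult at day `⌈A⌉`; her daily egg vector is indexed from that day.

## Jackknife inference

Demographic parameters are nonlinear functionals of the whole cohort, so
SEs come from leave-one-out pseudovalues `φ_i = n·θ − (n−1)·θ_(−i)`, the
life table being rebuilt and the renewal equation re-solved for every
removal.  The leave-one-out unit is the individual entering the cohort as
an egg.  If removing an individual leaves a cohort with no reproducing
female, that replicate is excluded with a warning and logged; the point
estimate and SE then use the reduced effective n (pseudovalues still use
the full n).  Pairwise diet comparisons are pooled-variance two-sample t
tests on the pseudovalue sets with `df = n_a + n_b − 2` (Welch available as
an option), two-sided, deliberately without multiplicity adjustment; the
compact letter display assigns the maximal cliques of the
non-significance graph as letters, ordered by ascending estimate, so
intransitive patterns yield multi-letter labels.

For a linear statistic (a mean) the pseudovalues equal the observations and
the jackknife SE reduces exactly to `sd/√n`; this identity is a test.

## The synthetic experiment

The generator emulates the rearing protocol of diet-assessment studies on
phytoseiid mites: single eggs in arenas, twice-daily immature checks,
daily adult checks.  Per individual:

* four stage durations drawn from gamma laws (positive, flexible CV) with
  the configured means, shared CV 0.25 by default, rounded **up** to the
  0.5-day grid — an event is detected at the first check after it occurs;
* Bernoulli survival per stage; sex assigned at adulthood
  (`proportion_female`, default 0.67, the typical phytoseiid female bias);
* for females, gamma pre-oviposition / oviposition / post-oviposition
  periods (CV 0.25, rounded up to whole days, oviposition at least one
  day) and Poisson daily egg counts with mean `daily_egg_mean` inside the
  oviposition window.  A deterministic egg law replaces the Poisson for
  degenerate-case testing.  An optional tray-level additive offset on
  fecundity exists but defaults to off: trays are bookkeeping (round-robin
  assignment), not a simulated effect.

Rounding up makes the realized mean of a recorded duration exceed the
underlying continuous mean by up to half a grid step; since the
configuration means are themselves means of *recorded* (grid-valued) data,
tests compare realized moments against the analytic mean of the rounded
law, not the raw configuration value.

The default three-cohort experiment is parameterized from the published
descriptive tables of the motivating study (stage means, stage survivals,
adult periods, total fecundity): cohorts of 47, 55 and 53 eggs on spruce
spider mite, false spider mite and pine pollen respectively — the unique
small denominators consistent with the printed egg-survival percentages
(45/47 = 95.74%, 53/55 = 96.36%, 52/53 = 98.11%); the study's remaining
replicates were progeny-sexing units.  `daily_egg_mean` is total fecundity
divided by the oviposition period.  The progeny sex ratio was measured but
not published; 0.67 is the configurable default.

### The expected (noiseless) schedule

`expected_life_table` integrates out all individual variation analytically:
the pmf of each grid-rounded gamma duration follows from the gamma CDF,
stage-entry and adult-age distributions are convolutions of those pmfs, and
`l_x`, `m_x` come from the resulting exact mixture (Poisson noise is
mean-neutral).  Applying the same Euler–Lotka solver to this schedule gives
the population value that cohort estimates converge to; parameter-recovery
tests require the simulated estimate at 500 eggs to sit within 3 jackknife
SEs of it.  At 40 000 eggs the simulated `r_m` agrees with the analytic
value to ~3·10⁻⁴.

### What the simulator does not capture

Real rearing data contain features the generator omits: censoring
(escapes, handling losses), tray- or observer-level heterogeneity beyond
the optional fecundity offset, age-dependent daily fecundity (the Poisson
mean is flat across the window), correlated durations within individuals,
and male adult life history.  Passing tests therefore demonstrate the
correctness of the estimators on data satisfying the stated protocol, not
robustness to those field realities.

## Descriptive summaries

Stage survival is stage-entry counting: `100 × (entered next)/(entered
this)`; the percentage reaching maturity is `100 × adults/initial eggs` and
equals the product of stage survivals exactly when nothing is censored.
Adult female conventions, with `A` the first adult day, `F`/`L` the
first/last oviposition days and `D` the death day: preoviposition `F − A`,
oviposition `L − F + 1`, postoviposition `D − L`, longevity `D − A`
(the adult lifespan — the definition under which published longevity means
in this literature equal the sum of the printed period means), oviposition
rate = total eggs / longevity, averaged per female.  Females dying before
their first egg are included in longevity but excluded from the period and
fecundity means, which would otherwise be undefined.  SEs are classical
(`sd/√n` over individuals).

## Problem sizes

Default test and acceptance runs use the study-scale cohorts (47–55 eggs),
200 seed pairs for the null-rejection calibration of the pairwise test at
50 eggs per cohort, 500 eggs per diet for parameter recovery, and 2000-egg
cohorts for moment-convergence checks; the full suite completes in well
under a minute on one core.

## Known limitations

* The drop-out convention for unobserved immature death ages is a choice;
  alternatives (e.g. mid-stage death) would shift `l_x` slightly at
  immature ages and `R0`/`r_m` negligibly.
* Jackknife t tests on pseudovalues are approximate; the calibration test
  only verifies the type-I error at study-scale n within a binomial band.
* The letter display is exact for the share-iff-nonsignificant relation
  but, like every compact letter display, is not a substitute for the
  underlying p-values.
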