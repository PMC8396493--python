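# cohortlife

Cohort life-table demography for arthropod rearing experiments.

Laboratory assessments of biocontrol candidates — here the motivating system
is a predatory mite (*Amblyseius andersoni*, Phytoseiidae) reared on two
coniferous-plant pests (the spruce spider mite *Oligonychus ununguis* and the
false spider mite *Pentamerismus taxi*) or on pine pollen as an alternative
food — follow single individuals from egg deposition to death and summarize
each diet cohort by its demographic growth potential.  `cohortlife` implements
that entire analysis chain for anyone running such cohort studies:

* **Life tables.** From individual records (stage-transition ages on a
  half-day observation grid, immature fate, sex at the final molt, daily egg
  counts) it builds the age-specific survival rate `l_x` (proportion of the
  initial egg cohort alive at age *x*, females only after adulthood) and the
  age-specific fecundity rate `m_x` (female eggs per living female per day).
* **Birch's demographic parameters.** The net reproductive rate
  `R0 = Σ_x l_x m_x`, the intrinsic rate of increase `r_m` solving the
  discrete Euler–Lotka renewal equation `Σ_x e^{-r_m x} l_x m_x = 1`
  (bracketed and solved to a 1e-10 residual), the mean generation time
  `T = ln(R0)/r_m`, and the finite rate of increase `λ = e^{r_m}`.
* **Jackknife inference.** Leave-one-out pseudovalues
  `φ_i = n·θ − (n−1)·θ_(−i)` give standard errors for these nonlinear cohort
  statistics; unadjusted pooled-variance t tests compare diets pairwise, with
  compact letter displays over all pairs.
* **Descriptive summaries.** Stage durations and stage-entry survival,
  percentage reaching maturity, pre-/post-/oviposition periods, fecundity,
  oviposition rate, adult longevity (mean ± SE).
* **A synthetic-cohort generator.** An individual-based simulator of the
  rearing protocol (gamma-distributed durations rounded up to the
  observation grid, Bernoulli stage survival, Poisson daily fecundity) plus
  the exact analytic `l_x`/`m_x` schedule a configuration implies, so the
  whole pipeline is testable and calibratable with no external data.

## Worked example

```python
from cohortlife import (default_configs, generate_cohort, build_life_table,
                        demographic_params)

cfg = default_configs(seed=1)[0]               # spruce-spider-mite diet cohort
records = generate_cohort(cfg)                 # 47 individually reared eggs
lt = build_life_table(records, cfg.progeny_female_fraction)
p = demographic_params(lt)
print(f"R0 = {p.r0:.2f}  T = {p.t:.1f} d  rm = {p.rm:.4f}/d  lambda = {p.lam:.3f}/d")
```

prints

```
R0 = 14.99  T = 16.6 d  rm = 0.1630/d  lambda = 1.177/d
```

i.e. each female leaves ~15 daughters per generation of ~17 days, so the
cohort grows about 17.7% per day (λ ≈ 1.18).  The full three-diet report
(`examples/04_full_report.py`, or `cohortlife report --seed 1 --out-dir report`)
adds jackknife SEs and letter groups:

```
          Oligonychus ununguis Pentamerismus taxi       pine pollen
R0            14.989 ± 1.378 a   20.746 ± 1.266 b  12.240 ± 1.130 a
T             16.616 ± 0.479 a   16.471 ± 0.337 a  19.405 ± 0.412 b
rm             0.163 ± 0.006 b    0.184 ± 0.005 c   0.129 ± 0.005 a
lambda         1.177 ± 0.007 b    1.202 ± 0.006 c   1.138 ± 0.006 a
```

Diets sharing a letter within a row do not differ at p ≤ 0.05.  The ordering
reproduces the qualitative finding of such assessments: both prey diets
support faster population growth than pine pollen, which nevertheless
sustains a growing population (λ > 1).

The `examples/` directory holds one short script per capability; the
`cohortlife` command exposes the same pipeline from the shell
(`simulate`, `analyze`, `compare`, `report`).

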