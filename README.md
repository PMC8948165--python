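# ltfhpp

Family-history and age-of-onset aware phenotypes for genome-wide
association studies (GWAS), implementing the LT-FH++ method: each genotyped
individual's **posterior mean genetic liability** is estimated under an
age-dependent liability threshold model, conditional on their own and their
family members' disease status, sex, birth year, and age (of onset for
cases, at censoring for controls).  The resulting continuous phenotype
replaces case-control status as the GWAS outcome and increases power to
detect associated variants, because it distils family history and timing
information that a 0/1 status throws away.

The package is aimed at statistical geneticists working with cohorts linked
to health registers or other sources of per-person timing information,
together with population cumulative incidence curves.

## Model

Under the liability threshold model every person carries a latent liability
`ℓ = ℓg + ℓe` with genetic component `ℓg ~ N(0, h²)` and independent
environment `ℓe ~ N(0, 1−h²)`; a person is a case when `ℓ ≥ T` where
`P(ℓ ≥ T) = K` for prevalence `K`.  For an index individual and
first-degree relatives, `(ℓg, ℓo, ℓ_rel…)` is jointly Gaussian with
covariances `r·h²` determined by the coefficients of relationship
(`r = 0.5` for parents and full siblings).

The age-dependent extension makes the threshold a decreasing function of
age through the sex- and birth-year-specific cumulative incidence `K(age)`:
`T(age) = Φ⁻¹(1 − K(age))`.  Consequently

* a **case with a known age of onset** has its full liability *fixed* at
  `T(onset)` — earlier onset means higher liability;
* a **control of age a** is truncated to `ℓ < T(a)`;
* a **case without onset** is truncated to `ℓ ≥ T(a)`;
* unknown status integrates over the whole axis.

The estimand is `E[ℓg | all family constraints]`.  Fixed coordinates are
handled by exact Gaussian conditioning; the interval-truncated coordinates
are sampled with a Gibbs sampler for the truncated multivariate normal, and
`E[ℓg]` is Rao-Blackwellized from the chain.  Cumulative incidence curves
can be estimated from register-style event data with the Aalen-Johansen
estimator under competing risks (death, emigration).

The comparison outcomes from the literature are included: plain
case-control status, GWAX (proxy cases: anyone with an affected relative),
and LT-FH (family history with group-level thresholds, no ages), plus a
family-based cohort simulator, linear/trend association tests, and
power/χ²-slope comparison metrics.

## Worked example

```python
import numpy as np
from ltfhpp import (
    SamplerConfig, SimulationConfig, ascertain, build_incidence_surface,
    cohort_to_records, incidence_table_from_config, simulate_cohort,
)
from ltfhpp.posterior import estimate_from_records
from ltfhpp.assoc import linear_gwas, power

cfg = SimulationConfig(n_families=20_000, n_snps=50, n_causal=50,
                       prevalence=0.05, downsample=True, seed=1)
cohort = simulate_cohort(cfg)                      # families + liabilities
keep = ascertain(cohort)                           # 50/50 case-control
surface = build_incidence_surface(
    incidence_table_from_config(cfg), interpolation="linear")
records = [r for r in cohort_to_records(cohort)
           if r.family_id in set(cohort.index_records.iloc[keep]["family_id"])]
est = estimate_from_records(records, surface, cfg.h2,
                            SamplerConfig(seed=1)).set_index("person_id")
ids = cohort.index_records.iloc[keep]["person_id"]
y = est.loc[ids, "post_mean_liab"].to_numpy()
res = linear_gwas(cohort.genotypes[keep].astype(float), y)
print(round(power(res, [f"snp{j}" for j in range(50)]), 2))
```

This prints `0.34`: 34% of the causal variants reach genome-wide
significance (p < 5×10⁻⁸) with the liability phenotype on this downsampled
cohort of 2,000 individuals, versus `0.28` if you rerun the last two lines
with the raw case-control status — the power gain from conditioning on
family history and onset timing.

A command-line interface mirrors the library:

```bash
ltfhpp simulate --seed 1 --n-families 2000 --out sim/
ltfhpp estimate --pedigree sim/pedigree.csv --incidence cif.csv \
                --h2 0.5 --mode ltfhpp --out est/
ltfhpp gwas --genotypes sim/genotypes.npy --phenotype est/phenotype.txt --out gwas/
ltfhpp compare --sumstats-a gwas/sumstats.tsv --sumstats-b other/sumstats.tsv --out cmp/
```

`estimate` writes a PLINK-compatible `FID IID ltfhpp` phenotype file, so
the outcome can be fed to external mixed-model GWAS tools.  Genotyped
individuals should be unrelated (no two sharing family members); the
package does not filter relatedness itself.

## Layout

- `src/ltfhpp/pedigree.py` — pedigree types, liability covariance, thresholds
- `src/ltfhpp/incidence.py` — cumulative incidence surfaces, Aalen-Johansen,
  personalized liability constraints
- `src/ltfhpp/posterior.py` — conditioning + Gibbs machinery, LT-FH mode,
  rejection-sampling oracle
- `src/ltfhpp/simulate.py` — generative model for family cohorts
- `src/ltfhpp/assoc.py` — association tests, GWAX, power and χ² comparisons
- `src/ltfhpp/cli.py` — `ltfhpp` command-line interface
- `docs/methods.md` — modeling and implementation notes
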