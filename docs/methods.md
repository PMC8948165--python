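# Methods notes

## Model and estimand

Each person's latent liability decomposes as `ℓ = ℓg + ℓe`, `ℓg ~ N(0, h²)`,
`ℓe ~ N(0, 1−h²)`, independent, with no environmental covariance between
family members (fixed, not configurable).  For an index individual with
relatives the joint vector `(ℓg, ℓo, ℓ_rel_1, …)` is multivariate normal;
`Cov(ℓg, ℓo) = h²`, `Cov(·, ℓ_rel) = r·h²` with coefficient of relationship
`r`, spouses are uncorrelated, sibling-sibling and parent-sibling pairs
share `0.5·h²`.  Only parents and full siblings (`r = 0.5`) are exposed in
the public pedigree API; other `r` values are accepted internally.  The
estimand is the posterior mean genetic liability `E[ℓg | Z]` given each
family member's constraint on their full liability.

Thresholds are personalized: a person's sex, birth year and age (of onset
for cases, at censoring otherwise) select a cumulative incidence proportion
`p`, and `T = Φ⁻¹(1−p)`.  Cases with a known onset are *fixed* at `T`
(exact Gaussian conditioning via the Schur complement, rather than
zero-width truncation intervals, for exactness and sampler stability);
everyone else contributes a truncation interval.  Unknown-status relatives
are excluded, which is mathematically identical to integrating their
coordinate over the whole axis — the implementation exploits this by
marginalizing any unconstrained coordinate out of the sampling problem.

## Sampler

The interval-constrained full liabilities form a truncated multivariate
normal.  A coordinate-wise Gibbs sampler updates them in fixed input order;
since `ℓg` itself is unconstrained, its posterior mean is obtained by
Rao-Blackwellization: each sweep records the exact conditional mean
`E[ℓg | current full liabilities]` (a fixed linear map), and the estimate is
the average of these.  This is both lower-variance than averaging raw `ℓg`
draws and removes one coordinate from the chain; for families whose only
free coordinate after conditioning is `ℓg` the answer is analytic
(`n_samples = 0`).

Stopping rule: batches of 1,000 retained sweeps after 200 burn-in sweeps;
stop when the batch-means Monte Carlo standard error of the mean drops to
`sem_tol` (default 0.01 liability units, small relative to the
between-person spread of ~0.3) or at 100,000 retained sweeps.  At least 4
batches are required before the batch-means SE is trusted, and the SE is
floored by the independent-draw estimate `sd/√n`; with fewer batches the
batch-means estimator is far too noisy and can stop the chain prematurely.

Truncated normal draws use the inverse-CDF on the constrained interval,
computed through the survival function whenever the interval sits above
zero so that bounds out to ~±38 standard deviations keep full relative
precision (the naive CDF route rounds `Φ(a)` to 1 beyond ~8; old mortality
strata produce thresholds well into the tail).

Families sharing a covariance structure and fixed/free pattern are sampled
as one vectorized batch, but every family consumes its own random stream
seeded from `(master seed, SHA-256 of family id)`, so results are
bit-for-bit independent of grouping, input order, and scheduling.  Families
are statistically independent; nothing is shared across them.  Relatedness
among *genotyped* individuals is the user's obligation: apply the method
only to individuals unrelated enough that no two share family members,
otherwise the phenotypes are more correlated than the genotypes imply.

The LT-FH comparison mode runs the same machinery with two group
thresholds (children vs parents) and interval constraints only.  It
requires per-sibling statuses; the original "at least one sibling affected"
union constraint is not implemented, since per-person statuses are always
available from the simulator and from register-style data.

## Incidence surfaces

Cumulative incidence by (sex, birth year) is stored as a step function of
age (last observation carried forward — registers report yearly counts;
linear interpolation is available behind a flag).  Birth years missing from
the table clamp to the nearest tabulated year with a logged warning;
unknown sex averages the male and female curves; a person with known
status but no age at all falls back to the stratum's lifetime (maximum-age)
incidence, the group-prevalence threshold of family-history-only models.
Proportions are clamped to `[1e−12, 1−1e−12]` before the quantile
transform so thresholds stay finite when incidence approaches 1 (late-age
mortality).  The Aalen-Johansen estimator handles competing events (death,
emigration); at tied times, events of interest are processed before
competing events before censorings — fixed for reproducibility.

## Simulator

The generator reproduces the reference study design: `N` families
(default 100,000), each with two parents and 0–2 siblings; allele
frequencies Uniform(0.01, 0.49); parents Binomial(2, AF); children the
parental average with half-integers rounded up or down with equal
probability; effects `N(0, h²/C)` on standardized genotypes with `C`
causal SNPs (default 1,000, `h² = 0.5`); lifetime prevalence 5% (or 10%)
split 4:1 male:female (8%/2%, doubling to 16%/4%); logistic cumulative
incidence with growth rate 1/8 per year and median onset 60 years; case
counts fixed exactly to the per-sex prevalence; control children aged
Uniform(10, 60), parents child age + Uniform(20, 35), cases aged at their
onset (high-liability individuals are never reassigned to controls);
optional 50/50 ascertainment by downsampling controls.  Only causal SNPs
are materialized; null SNPs for calibration are generated in blocks on
demand.

Numerical/design choices worth knowing:

* **Per-role genotype standardization.**  Under the parental-averaging
  scheme a child's genotype variance is `pq(1+p²+q²)`, not the binomial
  `2pq`.  Children are standardized by their exact variance so that
  `Var(ℓg) = h²` holds for every role and full liabilities are standard
  normal (which the onset assignment requires).  A side effect of the
  scheme itself: the standardized parent-child genetic correlation is
  `1/√(2(1+p²+q²))` ≈ 0.55 rather than the Mendelian 0.5, and the
  sibling-sibling correlation ≈ 0.6.  The analysis model keeps `r = 0.5`;
  this deliberate, small misspecification is consistent with the method's
  demonstrated robustness to misspecified hyper-parameters.
* **Rank-based onset quantiles.**  Case onsets invert the logistic curve
  at the liability's empirical per-sex rank `(rank+0.5)/n` rather than at
  `1−Φ(ℓ)`.  This makes the onset distribution exactly uniform over
  incidence levels — matching the exact-count status assignment, which
  guarantees every case's level lies below the lifetime prevalence `L` —
  and removes extreme sensitivity of the upper onset percentile to the
  realized liability variance (a 2% variance fluctuation otherwise moves
  the 95th percentile by years).  Onsets are floored at age 0; the
  logistic curve formally extends below birth for the most extreme ranks.
* **Balanced sexes.**  Exactly half the individuals in each generation are
  male (random permutation), so per-sex case counts and the ascertained
  sample size (10,000 at 5% prevalence for N=100,000; 20,000 at 10%) are
  exact rather than binomially noisy.
* Sexes of index and siblings are independent 50/50; relatives' statuses
  and onsets follow the same exact-count rules as the index within each
  (role, sex) group, with independent environmental terms.

What the simulator does **not** emulate: linkage disequilibrium,
assortative mating, birth-cohort effects (incidence curves are
birth-year-flat), environmental covariance between relatives, genotyping
error or missingness.  Passing tests therefore demonstrate correctness of
the estimator under its own generative assumptions, not performance on
real register data, where these features all exist.

One population-level consequence of the design: the average posterior mean
liability sits slightly above zero (~+0.06 at 5% prevalence), because
cases' liabilities are pinned at their onset thresholds while young
controls — who by the never-reassign rule are known never to onset — are
only weakly bounded by their current-age threshold.  Relatedly, the
whole-population variance of LT-FH++ estimates can fall below LT-FH's
(the case-control gap narrows more than onset information widens it), but
within each status stratum LT-FH++ estimates are strictly more variable,
which is the behavior that matters for association power.

## Association testing and power

Continuous phenotypes are tested per SNP by ordinary least squares with
covariates projected out (`χ² = (β̂/SE)²`, exact residual degrees of
freedom).  Binary status uses the 1-df Cochran-Armitage trend test on
additive coding, `χ² = n·corr(x,z)²` — the score test of genotype-only
logistic regression, asymptotically equivalent to the linear-regression χ²
under the null; with covariates it falls back to the residualized score
statistic.  Power is the fraction of causal SNPs with `p` strictly below
the threshold (default 5×10⁻⁸).  Relative power / effective-sample-size
gain between two methods is the through-origin regression slope of one
method's χ² on the other's minus one, over a common variant selection
(default: `p < 5×10⁻⁶` for at least one method).  Mixed-model association
and LD clumping are out of scope; phenotypes are exported in PLINK format
for external tools, and `compare` accepts pre-selected variant lists.

## Problem sizes in the test suite

The simulation-backed checks run at reduced scale chosen so Monte Carlo
noise stays well below the effects being asserted: power-ordering uses six
replicates of 20,000 families with 50 causal SNPs downsampled to 2,000
individuals; calibration uses 10,000 null SNPs; misspecification uses
three replicates of 10,000 families; sampler-oracle agreement uses twenty
random family configurations against 3×10⁶ rejection-sampling proposals.
The onset-interval and ascertainment checks run at the full reference
sizes (2×10⁶ individuals / 100,000 families), which are cheap because they
need no genotypes.

## Known limitations

* Only the posterior mean (with its Monte Carlo SE) is reported — no
  credible intervals.
* Half-siblings, grandparents and environmental correlation models are not
  supported; `h²` is an input, never estimated.
* Extra stratification beyond sex/birth year (e.g. a categorical risk
  factor) can be emulated by pre-stratifying the incidence table, but this
  path is untested against any reference result.
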