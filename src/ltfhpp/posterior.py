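"""Posterior mean genetic liabilities via exact conditioning + Gibbs sampling.

Each family defines a truncated multivariate normal: cases with a known age
of onset pin their full liability to the personalized threshold (handled by
exact Gaussian conditioning), everyone else contributes a truncation
interval.  The index's genetic liability ``l_g`` is itself unconstrained, so
its posterior mean is obtained by Rao-Blackwellization: the Gibbs chain runs
over the interval-constrained full liabilities only, and ``E[l_g | data]``
is the average of the exact conditional means ``E[l_g | full liabilities]``
along the chain.  Families sharing a covariance structure and
fixed/free pattern are sampled together as one vectorized batch; each family
consumes its own seeded random stream, so results do not depend on how
families are grouped or ordered.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .incidence import IncidenceSurface, LiabilityConstraint, personalized_constraint
from .pedigree import (
    CovarianceModel,
    FamilyPedigree,
    PersonRecord,
    build_covariance,
    threshold_from_cip,
)

__all__ = [
    "SamplerConfig",
    "PosteriorEstimate",
    "ConditionalGaussian",
    "condition_on_fixed",
    "truncated_normal_ppf",
    "sample_truncated_normal",
    "gibbs_truncated_mvn",
    "estimate_genetic_liability",
    "estimate_genetic_liabilities",
    "estimate_from_records",
    "ltfh_estimate",
    "rejection_oracle",
    "write_plink_phenotype",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Stopping rule and seeding for the Gibbs sampler.

    Sampling proceeds in batches of ``batch_size`` retained sweeps after
    ``burn_in`` discarded sweeps; it stops once the batch-means Monte Carlo
    standard error of the posterior-mean estimate drops to ``sem_tol`` or
    ``max_samples`` retained sweeps are reached.
    """

    burn_in: int = 200
    batch_size: int = 1000
    max_samples: int = 100_000
    sem_tol: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.burn_in, self.batch_size, self.max_samples) <= 0:
            raise ValueError("burn_in, batch_size and max_samples must be positive")
        if self.sem_tol <= 0:
            raise ValueError("sem_tol must be positive")


@dataclass(frozen=True)
class PosteriorEstimate:
    person_id: str
    mean_genetic_liability: float
    mc_standard_error: float
    n_samples: int
    converged: bool


@dataclass(frozen=True)
class ConditionalGaussian:
    """Mean and covariance of the free coordinates after conditioning."""

    order: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray


def _solve_psd(block: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``block @ x = rhs`` with a tiny ridge fallback for singular blocks."""
    try:
        return np.linalg.solve(block, rhs)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.eye(block.shape[0])
        return np.linalg.solve(block + jitter, rhs)


def condition_on_fixed(
    model: CovarianceModel, fixed: Mapping[str, float]
) -> ConditionalGaussian:
    """Condition the liability Gaussian on fixed full-liability coordinates.

    ``fixed`` maps coordinate names (entries of ``model.order``, never the
    ``"genetic"`` coordinate) to their pinned values.  Standard Schur
    complement conditioning; with no fixed coordinates the input is returned
    unchanged (zero mean).
    """
    if "genetic" in fixed:
        raise ValueError("the genetic liability coordinate cannot be fixed")
    unknown = set(fixed) - set(model.order)
    if unknown:
        raise KeyError(f"fixed coordinates not in model: {sorted(unknown)}")
    if not fixed:
        return ConditionalGaussian(
            order=model.order,
            mean=np.zeros(model.dim),
            cov=model.sigma.copy(),
        )
    names = list(model.order)
    fixed_idx = [names.index(k) for k in fixed]
    free_idx = [i for i in range(model.dim) if i not in fixed_idx]
    t = np.array([fixed[names[i]] for i in fixed_idx])
    s = model.sigma
    s_ff = s[np.ix_(fixed_idx, fixed_idx)]
    s_vf = s[np.ix_(free_idx, fixed_idx)]
    s_vv = s[np.ix_(free_idx, free_idx)]
    gain = _solve_psd(s_ff, s_vf.T).T  # free x fixed regression coefficients
    mean = gain @ t
    cov = s_vv - gain @ s_vf.T
    cov = 0.5 * (cov + cov.T)
    return ConditionalGaussian(
        order=tuple(names[i] for i in free_idx), mean=mean, cov=cov
    )


# ---------------------------------------------------------------------------
# truncated normal draws


def truncated_normal_ppf(u, a, b):
    """Quantile function of the standard normal truncated to ``(a, b)``.

    Stable far into either tail: intervals lying mostly above zero are
    mapped through the survival function so that e.g. ``a = 10`` (or any
    bound up to ~|38| standard deviations) keeps full relative precision,
    where the naive CDF route would round ``Phi(a)`` to 1.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    # decide per element which tail representation keeps precision
    with np.errstate(invalid="ignore"):
        mid = np.where(
            np.isinf(a) & np.isinf(b),
            0.0,
            np.where(np.isinf(a), b, np.where(np.isinf(b), a, a + b)),
        )
    with np.errstate(invalid="ignore"):
        fa, fb = ndtr(a), ndtr(b)
        x_cdf = ndtri(fa + u * (fb - fa))
        sa, sb = ndtr(-a), ndtr(-b)  # survival, decreasing
        x_sf = -ndtri(sa + u * (sb - sa))
    x = np.where(mid > 0, x_sf, x_cdf)
    # degenerate mass (bounds beyond double range): collapse to nearest bound
    x = np.clip(x, a, b)
    bad = ~np.isfinite(x)
    if np.any(bad):
        lo = np.broadcast_to(a, x.shape)[bad]
        hi = np.broadcast_to(b, x.shape)[bad]
        repl = np.where(np.isfinite(lo), lo, np.where(np.isfinite(hi), hi, 0.0))
        x = x.copy()
        x[bad] = repl
    return x if x.ndim else float(x)


def sample_truncated_normal(mu, sd, lower, upper, rng, size=None):
    """Draw from N(mu, sd^2) truncated to the open interval (lower, upper)."""
    mu, sd = np.asarray(mu, dtype=float), np.asarray(sd, dtype=float)
    lower, upper = np.asarray(lower, dtype=float), np.asarray(upper, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    if np.any(~(lower < upper)):
        raise ValueError("need lower < upper")
    if size is None:
        size = np.broadcast_shapes(mu.shape, sd.shape, lower.shape, upper.shape)
    u = rng.random(size)
    a = (lower - mu) / sd
    b = (upper - mu) / sd
    return mu + sd * truncated_normal_ppf(u, a, b)


# ---------------------------------------------------------------------------
# Gibbs machinery

#: minimum number of retained batches before the batch-means standard error
#: is trusted for the stopping rule
_MIN_BATCHES = 4


def _gibbs_coefs(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate conditional update coefficients from a covariance.

    Returns ``(B, csd)`` where the full conditional of coordinate ``i``
    given the rest is N(mu_i + B[i] @ (x - mu), csd[i]^2) (B has zero
    diagonal).
    """
    q = np.linalg.inv(cov)
    d = np.diag(q)
    if np.any(d <= 0):
        raise ValueError("covariance is not positive definite")
    b = -q / d[:, None]
    np.fill_diagonal(b, 0.0)
    csd = 1.0 / np.sqrt(d)
    return b, csd


def _initial_state(mean: np.ndarray, lower: np.ndarray, upper: np.ndarray):
    with np.errstate(invalid="ignore"):
        x = np.minimum(np.maximum(mean, lower + 1e-3), upper - 1e-3)
        both = np.isfinite(lower) & np.isfinite(upper)
        narrow = both & (upper - lower < 2e-3)
        x = np.where(
            narrow, 0.5 * (np.where(both, lower, 0.0) + np.where(both, upper, 0.0)), x
        )
    return x


def gibbs_truncated_mvn(
    mean: np.ndarray,
    cov: np.ndarray,
    constraints: Sequence[LiabilityConstraint],
    config: SamplerConfig,
    rng: Optional[np.random.Generator] = None,
    return_all: bool = False,
):
    """Sample a truncated multivariate normal by coordinate-wise Gibbs.

    ``constraints`` must be interval-kind (fixed coordinates are removed by
    :func:`condition_on_fixed` beforehand).  Coordinates are updated in
    fixed input order; after ``config.burn_in`` sweeps, up to
    ``config.max_samples`` states are retained.  Returns the retained draws
    of coordinate 0 (the genetic liability by convention), or the full
    states when ``return_all`` is set.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = mean.size
    if len(constraints) != k:
        raise ValueError("one constraint per coordinate required")
    if any(c.kind != "interval" for c in constraints):
        raise ValueError("fixed constraints must be conditioned out first")
    lower = np.array([c.lower for c in constraints])
    upper = np.array([c.upper for c in constraints])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b, csd = _gibbs_coefs(cov)
    x = _initial_state(mean, lower, upper)
    n = int(config.max_samples)
    out = np.empty((n, k)) if return_all else np.empty(n)
    for s in range(config.burn_in + n):
        u = rng.random(k)
        for i in range(k):
            m = mean[i] + b[i] @ (x - mean)
            ai = (lower[i] - m) / csd[i]
            bi = (upper[i] - m) / csd[i]
            x[i] = m + csd[i] * truncated_normal_ppf(u[i], ai, bi)
        if s >= config.burn_in:
            if return_all:
                out[s - config.burn_in] = x
            else:
                out[s - config.burn_in] = x[0]
    if not np.all(np.isfinite(out)):
        raise RuntimeError(
            "constraint set has numerically zero probability mass "
            "(non-finite Gibbs states)"
        )
    return out


def _family_seed(master_seed: int, family_id: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(str(family_id).encode()).digest()
    fid_entropy = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence(entropy=(int(master_seed), fid_entropy))


@dataclass
class _GibbsTask:
    family_id: str
    person_id: str
    m_g: float  # conditional mean of l_g given fixed coordinates
    m_v: np.ndarray  # conditional mean of the free full liabilities
    lower: np.ndarray
    upper: np.ndarray
    rng: np.random.Generator


def _prepare_family(
    pedigree: FamilyPedigree,
    constraints: Mapping[str, LiabilityConstraint],
    h2: float,
):
    """Reduce one family to an analytic answer or a Gibbs task.

    Relatives whose constraint is absent or unconstrained are marginalized
    out (integrating a Gaussian coordinate over its full range is the same
    as excluding it).  Fixed coordinates are conditioned out exactly.
    Returns ``(signature, task_or_mean)`` where a ``float`` means the
    posterior is exact.
    """
    idx_con = constraints.get(pedigree.index.person_id)
    if idx_con is None:
        idx_con = LiabilityConstraint.interval()
    keep, cons = [], []
    for p in pedigree.relatives:
        c = constraints.get(p.person_id)
        if c is None or c.unconstrained:
            continue
        keep.append(p)
        cons.append(c)
    ped = FamilyPedigree(
        index=pedigree.index,
        relatives=tuple(keep),
        relatedness={p.person_id: pedigree.r_of(p.person_id) for p in keep},
    )
    model = build_covariance(h2, ped)
    all_cons = [idx_con, *cons]  # aligned with model.order[1:]
    fixed = {
        name: c.value
        for name, c in zip(model.order[1:], all_cons)
        if c.kind == "fixed"
    }
    cond = condition_on_fixed(model, fixed)
    free_names = list(cond.order)
    g_pos = free_names.index("genetic")
    # interval-constrained free coordinates (excluding l_g and unconstrained)
    name_to_con = dict(zip(model.order[1:], all_cons))
    v_pos, v_lower, v_upper = [], [], []
    for j, name in enumerate(free_names):
        if name == "genetic":
            continue
        c = name_to_con[name]
        if c.unconstrained:
            continue
        v_pos.append(j)
        v_lower.append(c.lower)
        v_upper.append(c.upper)
    m_g = float(cond.mean[g_pos])
    if not v_pos:
        return None, m_g
    c_vv = cond.cov[np.ix_(v_pos, v_pos)]
    c_vg = cond.cov[v_pos, g_pos]
    # group signature: families with identical structure share C_VV and the
    # l_g projection weights
    sig_coords = []
    for pos, c in enumerate(all_cons):
        tag = (
            "fixed"
            if c.kind == "fixed"
            else ("free" if not c.unconstrained else "drop")
        )
        if pos == 0:
            role, r = "index", 1.0
        else:
            p = keep[pos - 1]
            role, r = p.role, ped.r_of(p.person_id)
        sig_coords.append((role, r, tag))
    signature = (round(h2, 12), tuple(sig_coords))
    task = _GibbsTask(
        family_id=pedigree.index.family_id,
        person_id=pedigree.index.person_id,
        m_g=m_g,
        m_v=cond.mean[v_pos],
        lower=np.array(v_lower),
        upper=np.array(v_upper),
        rng=None,  # filled in by the caller once the master seed is known
    )
    return (signature, (c_vv, c_vg)), task


def _run_group(
    tasks: list[_GibbsTask],
    c_vv: np.ndarray,
    c_vg: np.ndarray,
    config: SamplerConfig,
) -> list[PosteriorEstimate]:
    """Vectorized Gibbs over families sharing one conditional covariance."""
    f = len(tasks)
    k = c_vv.shape[0]
    b, csd = _gibbs_coefs(c_vv)
    w = _solve_psd(c_vv, c_vg)  # E[l_g | x] = m_g + w @ (x - m_v)
    m_v = np.stack([t.m_v for t in tasks])
    lower = np.stack([t.lower for t in tasks])
    upper = np.stack([t.upper for t in tasks])
    m_g = np.array([t.m_g for t in tasks])
    x = _initial_state(m_v, lower, upper)
    active = np.ones(f, dtype=bool)
    batch_means: list[list[float]] = [[] for _ in range(f)]
    total_sum = np.zeros(f)
    total_sq = np.zeros(f)
    total_n = np.zeros(f, dtype=int)
    sem = np.full(f, np.inf)
    first = True
    while np.any(active):
        ai = np.flatnonzero(active)
        sweeps = config.batch_size + (config.burn_in if first else 0)
        u = np.stack([tasks[j].rng.random((sweeps, k)) for j in ai])
        xa = x[ai]
        ma = m_v[ai]
        la, ua = lower[ai], upper[ai]
        ysum = np.zeros(len(ai))
        ysq = np.zeros(len(ai))
        start = config.burn_in if first else 0
        for s in range(sweeps):
            for i in range(k):
                cm = ma[:, i] + (xa - ma) @ b[i]
                a_std = (la[:, i] - cm) / csd[i]
                b_std = (ua[:, i] - cm) / csd[i]
                xa[:, i] = cm + csd[i] * truncated_normal_ppf(u[:, s, i], a_std, b_std)
            if s >= start:
                y = (xa - ma) @ w
                ysum += y
                ysq += y * y
        x[ai] = xa
        if not np.all(np.isfinite(ysum)):
            raise RuntimeError(
                "constraint set has numerically zero probability mass"
            )
        bm = ysum / config.batch_size + m_g[ai]
        total_sum[ai] += ysum + m_g[ai] * config.batch_size
        total_sq[ai] += ysq
        total_n[ai] += config.batch_size
        for j, fam in enumerate(ai):
            batch_means[fam].append(float(bm[j]))
            bms = batch_means[fam]
            # the batch-means SE estimate is unreliable with very few
            # batches, so convergence needs at least _MIN_BATCHES of them
            # and the SE is floored by the independent-draw estimate
            if len(bms) >= _MIN_BATCHES:
                n_f = total_n[fam]
                mean_y = total_sum[fam] / n_f - m_g[fam]
                var_y = max(total_sq[fam] / n_f - mean_y**2, 0.0)
                se_iid = math.sqrt(var_y / n_f)
                se_bm = float(np.std(bms, ddof=1) / math.sqrt(len(bms)))
                sem[fam] = max(se_bm, se_iid)
                if sem[fam] <= config.sem_tol or n_f >= config.max_samples:
                    active[fam] = False
        first = False
    return [
        PosteriorEstimate(
            person_id=t.person_id,
            mean_genetic_liability=float(total_sum[j] / total_n[j]),
            mc_standard_error=float(sem[j]),
            n_samples=int(total_n[j]),
            converged=bool(sem[j] <= config.sem_tol),
        )
        for j, t in enumerate(tasks)
    ]


def estimate_genetic_liabilities(
    items: Iterable[tuple[FamilyPedigree, Mapping[str, LiabilityConstraint]]],
    h2: float,
    config: SamplerConfig,
) -> pd.DataFrame:
    """Posterior mean genetic liability for every family.

    Families are independent; each draws from its own random stream seeded
    by ``(config.seed, family_id)``, so results do not depend on input
    order.  Returns a DataFrame with one row per index individual.
    """
    analytic: list[PosteriorEstimate] = []
    groups: dict = {}
    group_tasks: dict = {}
    for pedigree, constraints in items:
        key, task = _prepare_family(pedigree, constraints, h2)
        if key is None:
            analytic.append(
                PosteriorEstimate(
                    person_id=pedigree.index.person_id,
                    mean_genetic_liability=task,
                    mc_standard_error=0.0,
                    n_samples=0,
                    converged=True,
                )
            )
            continue
        signature, mats = key
        task.rng = np.random.default_rng(
            _family_seed(config.seed, task.family_id)
        )
        groups.setdefault(signature, mats)
        group_tasks.setdefault(signature, []).append(task)
    results = list(analytic)
    for signature, tasks in group_tasks.items():
        c_vv, c_vg = groups[signature]
        results.extend(_run_group(tasks, c_vv, c_vg, config))
    df = pd.DataFrame(
        [
            (
                r.person_id,
                r.mean_genetic_liability,
                r.mc_standard_error,
                r.n_samples,
                r.converged,
            )
            for r in results
        ],
        columns=["person_id", "post_mean_liab", "mc_se", "n_samples", "converged"],
    )
    return df


def estimate_genetic_liability(
    pedigree: FamilyPedigree,
    constraints: Mapping[str, LiabilityConstraint],
    h2: float,
    config: SamplerConfig,
) -> PosteriorEstimate:
    """Single-family convenience wrapper around the batched estimator."""
    df = estimate_genetic_liabilities([(pedigree, constraints)], h2, config)
    row = df.iloc[0]
    return PosteriorEstimate(
        person_id=row["person_id"],
        mean_genetic_liability=float(row["post_mean_liab"]),
        mc_standard_error=float(row["mc_se"]),
        n_samples=int(row["n_samples"]),
        converged=bool(row["converged"]),
    )


def ltfh_estimate(
    pedigree: FamilyPedigree,
    statuses: Mapping[str, str],
    prev_child: float,
    prev_parent: float,
    h2: float,
    config: SamplerConfig,
) -> PosteriorEstimate:
    """Family-history-only posterior mean with two group thresholds.

    The index and any siblings share the threshold from ``prev_child``;
    parents share the one from ``prev_parent``.  All constraints are
    intervals (no liability is ever fixed): case -> (T, +inf),
    control -> (-inf, T).  Statuses must be known per person.
    """
    t_child = threshold_from_cip(prev_child)
    t_parent = threshold_from_cip(prev_parent)
    constraints = {}
    for p in pedigree.members:
        status = statuses.get(p.person_id, p.status)
        if status == "unknown":
            if p.role == "index":
                constraints[p.person_id] = LiabilityConstraint.interval()
            continue  # unknown relatives are excluded
        t = t_parent if p.role in ("father", "mother") else t_child
        if status == "case":
            constraints[p.person_id] = LiabilityConstraint.interval(lower=t)
        else:
            constraints[p.person_id] = LiabilityConstraint.interval(upper=t)
    return estimate_genetic_liability(pedigree, constraints, h2, config)


def ltfh_from_records(
    records: Sequence[PersonRecord],
    prev_child: float,
    prev_parent: float,
    h2: float,
    config: SamplerConfig,
) -> pd.DataFrame:
    """Batched family-history-only (LT-FH) phenotypes for a population.

    Same grouping machinery as :func:`estimate_from_records`, but with the
    two group thresholds (children vs parents) and interval constraints
    only; relatives with unknown status are excluded.
    """
    t_child = threshold_from_cip(prev_child)
    t_parent = threshold_from_cip(prev_parent)
    by_family: dict[str, list[PersonRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family_id, []).append(rec)
    items = []
    for fid, members in by_family.items():
        index = next(p for p in members if p.role == "index")
        rels = tuple(
            p for p in members if p.role != "index" and p.status != "unknown"
        )
        ped = FamilyPedigree(index=index, relatives=rels)
        cons = {}
        for p in ped.members:
            if p.status == "unknown":
                cons[p.person_id] = LiabilityConstraint.interval()
                continue
            t = t_parent if p.role in ("father", "mother") else t_child
            if p.status == "case":
                cons[p.person_id] = LiabilityConstraint.interval(lower=t)
            else:
                cons[p.person_id] = LiabilityConstraint.interval(upper=t)
        items.append((ped, cons))
    return estimate_genetic_liabilities(items, h2, config)


def rejection_oracle(
    model: CovarianceModel,
    constraints: Mapping[str, LiabilityConstraint],
    n_draws: int,
    seed: int,
) -> tuple[float, float]:
    """Posterior mean of ``l_g`` by naive MVN sampling + filtering.

    Test oracle only: draws from the (conditioned) multivariate normal and
    keeps draws satisfying every interval constraint.  Returns
    ``(mean, mc_se)``.  Aborts when the empirical acceptance rate falls
    below 1e-6.
    """
    fixed = {
        name: c.value
        for name, c in constraints.items()
        if c.kind == "fixed"
    }
    cond = condition_on_fixed(model, fixed)
    g_pos = cond.order.index("genetic")
    lower = np.full(len(cond.order), -np.inf)
    upper = np.full(len(cond.order), np.inf)
    for j, name in enumerate(cond.order):
        if name == "genetic":
            continue
        c = constraints.get(name)
        if c is None:
            continue
        lower[j], upper[j] = c.lower, c.upper
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        cond.cov + 1e-12 * np.eye(cond.cov.shape[0])
    )
    accepted: list[np.ndarray] = []
    proposed = 0
    block = 100_000
    while proposed < n_draws:
        m = min(block, n_draws - proposed)
        z = rng.standard_normal((m, cond.cov.shape[0]))
        draws = cond.mean + z @ chol.T
        ok = np.all((draws > lower) & (draws < upper), axis=1)
        accepted.append(draws[ok, g_pos])
        proposed += m
        n_acc = sum(a.size for a in accepted)
        if proposed >= 1_000_000 and n_acc / proposed < 1e-6:
            raise RuntimeError(
                f"acceptance rate {n_acc / proposed:.2e} below 1e-6; "
                "constraints too restrictive for rejection sampling"
            )
    g = np.concatenate(accepted)
    if g.size < 2:
        raise RuntimeError("rejection oracle accepted fewer than 2 draws")
    return float(g.mean()), float(g.std(ddof=1) / math.sqrt(g.size))


def estimate_from_records(
    records: Sequence[PersonRecord],
    surface: IncidenceSurface,
    h2: float,
    config: SamplerConfig,
) -> pd.DataFrame:
    """LT-FH++ phenotypes for a long-format population of person records.

    Groups records into families, derives each person's liability
    constraint from their own sex/birth-year/age stratum of ``surface``,
    excludes relatives with unknown status, and runs the batched estimator.
    """
    from .pedigree import PedigreeError  # local to avoid cycle noise

    by_family: dict[str, list[PersonRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family_id, []).append(rec)
    items = []
    for fid, members in by_family.items():
        idx = [p for p in members if p.role == "index"]
        if len(idx) != 1:
            raise PedigreeError(
                f"family {fid}: expected exactly one index record, got {len(idx)}"
            )
        relatives = tuple(
            p for p in members if p.role != "index" and p.status != "unknown"
        )
        ped = FamilyPedigree(index=idx[0], relatives=relatives)
        cons = {
            p.person_id: personalized_constraint(p, surface)
            for p in (idx[0], *relatives)
        }
        items.append((ped, cons))
    return estimate_genetic_liabilities(items, h2, config)


def write_plink_phenotype(
    estimates: pd.DataFrame, path, column: str = "ltfhpp"
) -> None:
    """Write `FID IID <column>` whitespace-delimited phenotype file."""
    out = pd.DataFrame(
        {
            "FID": estimates["person_id"],
            "IID": estimates["person_id"],
            column: estimates["post_mean_liab"],
        }
    )
    out.to_csv(path, sep=" ", index=False)
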