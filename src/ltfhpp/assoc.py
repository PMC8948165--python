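"""Association testing, GWAX phenotype construction and power metrics.

Continuous liability phenotypes are tested per SNP with ordinary least
squares (covariates projected out); binary case-control status with the
1-df Cochran-Armitage trend test on additive genotype coding.  Power is the
fraction of causal SNPs below a significance threshold; relative gains
between phenotype constructions are summarized by the through-origin
regression slope of one method's chi-squared statistics on another's.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gwax_phenotype",
    "linear_gwas",
    "case_control_test",
    "power",
    "compare_chisq",
    "write_sumstats",
    "read_sumstats",
]

SUMSTATS_COLUMNS = ["snp_id", "beta", "se", "chisq", "p", "phenotype"]


def gwax_phenotype(records: pd.DataFrame) -> pd.Series:
    """Proxy-case status: 1 if the person or any family member is a case.

    ``records`` is the long-format table (columns ``family_id``, ``role``,
    ``status``); returns one 0/1 value per index individual, indexed by
    ``person_id``.  Families where every status is unknown yield NA.
    """
    fam = records.groupby("family_id").agg(
        any_case=("status", lambda s: bool((s == "case").any())),
        any_known=("status", lambda s: bool(s.isin(["case", "control"]).any())),
    )
    idx = records[records["role"] == "index"]
    out = pd.Series(
        np.where(
            fam.loc[idx["family_id"], "any_known"].to_numpy(),
            fam.loc[idx["family_id"], "any_case"].to_numpy().astype(float),
            np.nan,
        ),
        index=pd.Index(idx["person_id"], name="person_id"),
        name="gwax",
    )
    return out


def _residualize(y: np.ndarray, covariates: Optional[np.ndarray]) -> tuple[np.ndarray, int]:
    """Project out covariates (plus intercept); return residuals and df used."""
    n = y.shape[0]
    if covariates is None:
        x = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        x = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, x.shape[1]


def linear_gwas(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    snp_ids: Optional[Sequence[str]] = None,
    phenotype: str = "linear",
) -> pd.DataFrame:
    """Per-SNP ordinary least squares of a continuous phenotype.

    Covariates (with an intercept) are projected out of both the phenotype
    and each genotype; the per-SNP statistic is ``chisq = (beta/se)^2``
    with the exact OLS residual degrees of freedom.  Monomorphic SNPs are
    flagged with missing statistics.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("phenotype contains missing values")
    n, m = g.shape
    yr, k = _residualize(y, covariates)
    gr, _ = _residualize(g, covariates)
    gss = np.einsum("ij,ij->j", gr, gr)
    poly = gss > 0
    gxy = yr @ gr
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[poly] = gxy[poly] / gss[poly]
    dof = n - k - 1
    yss = float(yr @ yr)
    rss = np.maximum(yss - beta**2 * gss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se[poly] = np.sqrt(rss[poly] / dof / gss[poly])
    chisq = (beta / se) ** 2
    p = stats.chi2.sf(chisq, df=1)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta": beta,
            "se": se,
            "chisq": chisq,
            "p": p,
            "phenotype": phenotype,
        }
    )


def case_control_test(
    genotypes: np.ndarray,
    z: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    snp_ids: Optional[Sequence[str]] = None,
    phenotype: str = "case_control",
) -> pd.DataFrame:
    """1-df genotype trend test of a binary status.

    Without covariates this is the Cochran-Armitage trend statistic on
    additive coding, ``chisq = n * corr(x, z)^2`` (the score test of
    logistic regression on genotype alone); it is invariant to swapping the
    case/control labels.  With covariates the test falls back to the
    linear-model score statistic on residualized genotype and status, which
    is asymptotically equivalent.
    """
    z = np.asarray(z, dtype=float)
    classes = np.unique(z[np.isfinite(z)])
    if classes.size < 2:
        raise ValueError("case_control_test needs both classes present")
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if covariates is None:
        zc = z - z.mean()
        gc = g - g.mean(axis=0)
    else:
        zc, _ = _residualize(z, covariates)
        gc, _ = _residualize(g, covariates)
    gss = np.einsum("ij,ij->j", gc, gc)
    zss = float(zc @ zc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (zc @ gc) ** 2 / (gss * zss)
    chisq = np.where(gss > 0, n * r2, np.nan)
    # report the score-scale effect and a consistent SE so chisq=(beta/se)^2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gss > 0, (zc @ gc) / gss, np.nan)
        se = np.abs(beta) / np.sqrt(np.where(chisq > 0, chisq, np.nan))
    p = stats.chi2.sf(chisq, df=1)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "beta": beta,
            "se": se,
            "chisq": chisq,
            "p": p,
            "phenotype": phenotype,
        }
    )


def power(
    results: pd.DataFrame, causal: Sequence[str], alpha: float = 5e-8
) -> float:
    """Fraction of causal SNPs with p value strictly below ``alpha``."""
    causal = set(causal)
    if not causal:
        raise ValueError("empty causal set")
    tested = set(results["snp_id"])
    if not causal <= tested:
        raise ValueError("causal set contains untested variants")
    sub = results[results["snp_id"].isin(causal)]
    return float((sub["p"] < alpha).sum() / len(causal))


def compare_chisq(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    selection: Optional[Sequence[str]] = None,
    p_threshold: Optional[float] = None,
) -> dict:
    """Relative power gain of method a over method b from chi-squared slopes.

    Restricted to ``selection`` (or, when ``p_threshold`` is given, to
    variants below the threshold for at least one method), the
    through-origin regression slope of ``chisq_a`` on ``chisq_b``
    approximates the ratio of effective sample sizes; ``gain = slope - 1``.
    """
    a = results_a.set_index("snp_id")["chisq"]
    b = results_b.set_index("snp_id")["chisq"]
    common = a.index.intersection(b.index)
    if selection is not None:
        common = common.intersection(pd.Index(selection))
    if p_threshold is not None:
        pa = results_a.set_index("snp_id")["p"]
        pb = results_b.set_index("snp_id")["p"]
        hits = common[(pa[common] < p_threshold) | (pb[common] < p_threshold)]
        common = hits
    if len(common) == 0:
        raise ValueError("empty variant selection for chi-squared comparison")
    x = b[common].to_numpy()
    ya = a[common].to_numpy()
    ok = np.isfinite(x) & np.isfinite(ya)
    if not np.any(ok):
        raise ValueError("no finite chi-squared pairs in selection")
    slope = float(ya[ok] @ x[ok] / (x[ok] @ x[ok]))
    return {
        "slope": slope,
        "relative_gain": slope - 1.0,
        "n_variants": int(ok.sum()),
    }


def write_sumstats(results: pd.DataFrame, path) -> None:
    """Write the summary-statistics TSV."""
    results.reindex(columns=SUMSTATS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    return df
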