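"""Generative model for family-based case-control cohorts with age of onset.

Families (two parents, 0-2 siblings, one genotyped offspring) are simulated
under the liability threshold model: parental genotypes are binomial in the
allele frequency, offspring genotypes are the parental average with random
rounding of half-integers, genetic liabilities are sums of standardized
causal genotypes times N(0, h2/C) effects, and case status is assigned by
ranking full liabilities so the per-sex prevalence holds exactly.  Age of
onset follows a logistic cumulative incidence curve (growth rate k, median
onset x0, sex-specific lifetime prevalence L), inverted at each case's full
liability quantile, so earlier onset corresponds to higher liability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .incidence import LogisticCIF, invert_logistic_cif
from .pedigree import PersonRecord

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "sex_specific_prevalence",
    "simulate_genotypes",
    "simulate_liabilities",
    "assign_status_and_onset",
    "ascertain",
    "simulate_cohort",
    "cohort_to_records",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_plink_triplet",
]

PARENT_ROLES = ("father", "mother")


def sex_specific_prevalence(prevalence: float, male_multiplier: float) -> tuple[float, float]:
    """Split an overall lifetime prevalence into (male, female) values.

    With a male:female prevalence ratio ``m`` and a balanced sex split,
    ``L_f = 2K / (1 + m)`` and ``L_m = m * L_f``; e.g. K=5%, m=4 gives
    8% / 2%.
    """
    l_f = 2.0 * prevalence / (1.0 + male_multiplier)
    l_m = male_multiplier * l_f
    if not (0.0 < l_f and l_m < 1.0):
        raise ValueError("sex-specific prevalences must lie in (0, 1)")
    return l_m, l_f


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Defaults follow the reference simulation design: 100,000 families with
    100,000 SNPs of which C = 1,000 are causal, liability heritability 0.5,
    5% lifetime prevalence with males four times as likely to be cases as
    females, logistic onset curve with growth rate 1/8 per year and median
    onset at 60 years.
    """

    n_families: int = 100_000
    n_snps: int = 100_000
    n_causal: int = 1_000
    h2: float = 0.5
    maf_range: tuple[float, float] = (0.01, 0.49)
    prevalence: float = 0.05
    male_multiplier: float = 4.0
    k: float = 1.0 / 8.0
    x0: float = 60.0
    n_siblings: int = 0
    downsample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 <= self.n_siblings <= 2:
            raise ValueError("n_siblings must be 0, 1 or 2")
        sex_specific_prevalence(self.prevalence, self.male_multiplier)

    def logistic(self, sex: str) -> LogisticCIF:
        """Sex-specific logistic cumulative incidence parameters."""
        l_m, l_f = sex_specific_prevalence(self.prevalence, self.male_multiplier)
        return LogisticCIF(L=l_m if sex == "male" else l_f, k=self.k, x0=self.x0)


@dataclass
class SimulatedCohort:
    """In-memory result of a simulation run.

    ``genotypes`` holds the index individuals' causal-SNP genotypes
    (families x n_causal, additive 0/1/2 coding); ``family_genotypes`` maps
    role -> matrix for relatives.  ``records`` is the long-format phenotype
    table (one row per person).  ``beta`` are the true standardized effects
    of the causal SNPs, ``afs`` their allele frequencies,
    ``causal_indices`` their positions within the full SNP panel.
    """

    config: SimulationConfig
    genotypes: np.ndarray
    family_genotypes: dict[str, np.ndarray]
    afs: np.ndarray
    beta: np.ndarray
    causal_indices: np.ndarray
    genetic_liability: np.ndarray
    full_liability: np.ndarray
    records: pd.DataFrame

    @property
    def index_records(self) -> pd.DataFrame:
        return self.records[self.records["role"] == "index"].reset_index(drop=True)


def _round_half_genotypes(avg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Round parental-average genotypes; .5 values go up or down 50/50."""
    frac = avg % 1.0
    half = frac == 0.5
    out = np.floor(avg)
    out[half] += rng.integers(0, 2, size=int(half.sum()))
    return out.astype(np.int8)


def simulate_genotypes(
    n_families: int,
    n_snps: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.01, 0.49),
    n_siblings: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw allele frequencies, parental and offspring genotypes.

    Allele frequencies are Uniform(maf_range); each parent's genotype is
    Binomial(2, AF); every child (index and siblings) is the average of the
    two parental genotypes with half-integers rounded up or down with equal
    probability.  Returns ``(afs, genotypes_by_role)``.
    """
    afs = rng.uniform(*maf_range, size=n_snps)
    geno = {}
    for role in PARENT_ROLES:
        geno[role] = rng.binomial(2, afs, size=(n_families, n_snps)).astype(np.int8)
    parent_avg = (geno["father"].astype(np.float32) + geno["mother"]) / 2.0
    geno["index"] = _round_half_genotypes(parent_avg, rng)
    for s in range(n_siblings):
        geno[f"sibling{s + 1}"] = _round_half_genotypes(parent_avg, rng)
    return afs, geno


def simulate_liabilities(
    genotypes: dict[str, np.ndarray],
    afs: np.ndarray,
    h2: float,
    n_causal: int,
    n_snps_total: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Genetic and full liabilities for every family member.

    Causal positions are chosen uniformly at random among ``n_snps_total``
    panel slots; effect sizes are N(0, h2/C) on genotypes standardized by
    the true allele frequency, so Var(l_g) = h2 by construction.  Each
    person receives an independent N(0, 1-h2) environmental term.
    """
    c = afs.size  # simulated (causal) SNPs
    causal_indices = np.sort(rng.choice(n_snps_total, size=n_causal, replace=False))
    beta = rng.normal(0.0, math.sqrt(h2 / n_causal) if n_causal else 0.0, size=c)
    pq = afs * (1.0 - afs)
    # exact genotype variances under this transmission scheme: parents are
    # Binomial(2, p) with variance 2pq; a child is the parental average plus
    # a fair half-integer rounding term, giving pq * (1 + p^2 + q^2).
    # Standardizing each role by its own variance makes Var(l_g) = h2 hold
    # for everyone, so full liabilities are standard normal as the
    # age-of-onset assignment requires.
    scale_parent = np.sqrt(2.0 * pq)
    scale_child = np.sqrt(pq * (1.0 + afs**2 + (1.0 - afs) ** 2))
    gen_liab, full_liab = {}, {}
    for role, g in genotypes.items():
        scale = scale_parent if role in PARENT_ROLES else scale_child
        std = (g - 2.0 * afs) / scale
        lg = std @ beta
        gen_liab[role] = lg
        full_liab[role] = lg + rng.normal(
            0.0, math.sqrt(1.0 - h2), size=lg.shape
        )
    return causal_indices, beta, gen_liab, full_liab


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly-balanced male/female assignment via a random permutation."""
    sexes = np.array(["male"] * (n // 2) + ["female"] * (n - n // 2))
    rng.shuffle(sexes)
    return sexes


def assign_status_and_onset(
    full_liability: np.ndarray,
    sexes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    child_generation: bool = True,
    child_ages: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assign case status, onset and censoring ages from full liabilities.

    Within each sex, the top ``round(L_sex * n)`` liabilities are cases, so
    the realized prevalence equals the target exactly.  Case onset inverts
    the sex-specific logistic cumulative incidence at the full liability's
    upper-tail quantile; the quantile is the empirical rank
    ``(rank + 0.5) / n_sex`` (descending), which is the same ordering that
    fixes case status and guarantees every case's quantile lies strictly
    below L.  The case's age is its onset.  Control children draw age ~
    Uniform(10, 60); control parents get ``child age + Uniform(20, 35)``
    (pass ``child_ages`` and ``child_generation=False``).
    """
    n = full_liability.size
    status = np.zeros(n, dtype=bool)
    onset = np.full(n, np.nan)
    age = np.full(n, np.nan)
    for sex in ("male", "female"):
        m = sexes == sex
        n_sex = int(m.sum())
        if n_sex == 0:
            continue
        params = config.logistic(sex)
        n_cases = int(round(params.L * n_sex))
        liab = full_liability[m]
        order = np.argsort(liab)[::-1]
        case_local = np.zeros(n_sex, dtype=bool)
        case_local[order[:n_cases]] = True
        idx = np.flatnonzero(m)
        status[idx[case_local]] = True
        # onset from the liability's empirical upper-tail quantile; ranking
        # descending means case i's quantile is (rank + 0.5)/n_sex, always
        # strictly below the case cutoff L by construction
        rank = np.empty(n_sex, dtype=float)
        rank[order] = np.arange(n_sex)
        q = (rank[case_local] + 0.5) / n_sex
        # equality can occur when round(L*n) rounds up in tiny strata; the
        # clamp below keeps the inversion finite
        assert np.all(q <= params.L), "case quantile exceeded the lifetime prevalence"
        q = np.minimum(q, params.L * (1.0 - 1e-9))
        # the logistic curve extends below age 0 for extreme quantiles;
        # onsets are floored at birth
        onset[idx[case_local]] = np.maximum(invert_logistic_cif(q, params), 0.0)
    age[status] = onset[status]
    ctrl = ~status
    if child_generation:
        age[ctrl] = rng.uniform(10.0, 60.0, size=int(ctrl.sum()))
    else:
        if child_ages is None:
            raise ValueError("parent generation needs child_ages")
        age[ctrl] = child_ages[ctrl] + rng.uniform(20.0, 35.0, size=int(ctrl.sum()))
    return pd.DataFrame(
        {
            "sex": sexes,
            "status": np.where(status, "case", "control"),
            "age_of_onset": onset,
            "age": age,
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative model.

    Only causal SNPs are materialized as genotypes (null SNPs carry no
    liability and can be generated lazily with
    :func:`simulate_null_genotypes` when calibration experiments need
    them).  Returns a :class:`SimulatedCohort` with a long-format record
    table for index individuals and relatives.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_families
    afs, geno = simulate_genotypes(
        n, config.n_causal, rng, config.maf_range, config.n_siblings
    )
    causal_indices, beta, gen_liab, full_liab = simulate_liabilities(
        geno, afs, config.h2, config.n_causal, config.n_snps, rng
    )
    roles = list(geno)
    frames = []
    sexes = {}
    for role in roles:
        if role == "father":
            sexes[role] = np.array(["male"] * n)
        elif role == "mother":
            sexes[role] = np.array(["female"] * n)
        else:
            sexes[role] = _balanced_sexes(n, rng)
    # children first: parents' control ages depend on the index child's age
    child_frames = {}
    for role in roles:
        if role in PARENT_ROLES:
            continue
        child_frames[role] = assign_status_and_onset(
            full_liab[role], sexes[role], config, rng, child_generation=True
        )
    index_age = child_frames["index"]["age"].to_numpy()
    for role in PARENT_ROLES:
        child_frames[role] = assign_status_and_onset(
            full_liab[role],
            sexes[role],
            config,
            rng,
            child_generation=False,
            child_ages=index_age,
        )
    for role in roles:
        f = child_frames[role].copy()
        f.insert(0, "family_id", [f"F{i}" for i in range(n)])
        f.insert(1, "person_id", [f"F{i}_{role}" for i in range(n)])
        f.insert(2, "role", "sibling" if role.startswith("sibling") else role)
        frames.append(f)
    records = pd.concat(frames, ignore_index=True)
    records["birth_year"] = np.nan  # birth cohort effects are not modeled
    return SimulatedCohort(
        config=config,
        genotypes=geno["index"],
        family_genotypes={r: geno[r] for r in roles if r != "index"},
        afs=afs,
        beta=beta,
        causal_indices=causal_indices,
        genetic_liability=gen_liab["index"],
        full_liability=full_liab["index"],
        records=records,
    )


def simulate_null_genotypes(
    n_individuals: int,
    n_snps: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.01, 0.49),
) -> np.ndarray:
    """Genotypes for SNPs with no liability effect (calibration blocks)."""
    afs = rng.uniform(*maf_range, size=n_snps)
    return rng.binomial(2, afs, size=(n_individuals, n_snps)).astype(np.int8)


def ascertain(
    cohort: SimulatedCohort, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Indices of retained index individuals after control downsampling.

    All cases are kept; controls are sampled uniformly without replacement
    to match the case count (50/50 case-control design).  With the
    ``downsample`` flag off the whole cohort is retained.
    """
    idx = cohort.index_records
    if not cohort.config.downsample:
        return np.arange(len(idx))
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    cases = np.flatnonzero((idx["status"] == "case").to_numpy())
    controls = np.flatnonzero((idx["status"] == "control").to_numpy())
    if cases.size > controls.size:
        raise ValueError("more cases than controls; cannot downsample controls")
    keep_controls = rng.choice(controls, size=cases.size, replace=False)
    return np.sort(np.concatenate([cases, keep_controls]))


def incidence_table_from_config(
    config: SimulationConfig, ages: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """The simulator's true cumulative incidence as a long-format table.

    Tabulates the sex-specific logistic curves on an age grid (default
    0..110 by 0.5 years) in the incidence-surface CSV dialect; birth year
    is left blank because cohort effects are not simulated.
    """
    from .incidence import logistic_cif

    if ages is None:
        ages = np.arange(0.0, 110.5, 0.5)
    rows = []
    for sex in ("male", "female"):
        params = config.logistic(sex)
        for a in ages:
            rows.append((sex, np.nan, float(a), float(logistic_cif(a, params))))
    return pd.DataFrame(rows, columns=["sex", "birth_year", "age", "cum_inc"])


def cohort_to_records(cohort: SimulatedCohort) -> list[PersonRecord]:
    """Convert the cohort's long-format table into PersonRecord objects."""
    out = []
    for row in cohort.records.itertuples(index=False):
        is_case = row.status == "case"
        out.append(
            PersonRecord(
                person_id=row.person_id,
                family_id=row.family_id,
                role=row.role,
                sex=row.sex,
                birth_year=None,
                status=row.status,
                age_at_censoring=None if is_case else float(row.age),
                age_of_onset=float(row.age_of_onset) if is_case else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file interop


PEDIGREE_COLUMNS = [
    "family_id",
    "person_id",
    "role",
    "sex",
    "birth_year",
    "status",
    "age",
    "age_of_onset",
]


def write_pedigree_csv(records: pd.DataFrame, path) -> None:
    """Write the long-format pedigree CSV (status coded 1/0/NA)."""
    df = records.copy()
    df["status"] = df["status"].map({"case": 1, "control": 0}).astype("Int64")
    df = df.reindex(columns=PEDIGREE_COLUMNS)
    df.to_csv(path, index=False)


def read_pedigree_csv(path) -> list[PersonRecord]:
    """Read the long-format pedigree CSV into PersonRecord objects."""
    df = pd.read_csv(path)
    missing = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree CSV missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        status = row.status
        if pd.isna(status):
            status = "unknown"
        else:
            status = "case" if int(status) == 1 else "control"
        sex = row.sex if isinstance(row.sex, str) and row.sex else "unknown"
        try:
            records.append(
                PersonRecord(
                    person_id=str(row.person_id),
                    family_id=str(row.family_id),
                    role=str(row.role),
                    sex=sex,
                    birth_year=None if pd.isna(row.birth_year) else int(row.birth_year),
                    status=status,
                    age_at_censoring=None if pd.isna(row.age) else float(row.age),
                    age_of_onset=(
                        None if pd.isna(row.age_of_onset) else float(row.age_of_onset)
                    ),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def write_plink_triplet(
    genotypes: np.ndarray, ids: list[str], prefix: str
) -> None:
    """Write a PLINK1 .bed/.bim/.fam triplet (chromosome 1, bp = SNP index).

    Genotypes are individuals x SNPs in additive 0/1/2 coding with no
    missingness; alleles are labeled A (counted) and B.
    """
    n, m = genotypes.shape
    with open(f"{prefix}.fam", "w") as fh:
        for i in ids:
            fh.write(f"{i} {i} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for j in range(m):
            fh.write(f"1 snp{j} 0 {j + 1} A B\n")
    # PLINK bed codes (SNP-major): 00=hom alt(2 copies of A here), 01=missing,
    # 10=het, 11=hom ref.  Counting allele A: 2 -> 00, 1 -> 10, 0 -> 11.
    code = np.array([3, 2, 0], dtype=np.uint8)  # genotype value -> 2-bit code
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        n_bytes = (n + 3) // 4
        for j in range(m):
            codes = code[genotypes[:, j]]
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for off in range(4):
                chunk = codes[off::4]
                packed[: chunk.size] |= chunk << (2 * off)
            fh.write(packed.tobytes())


def read_plink_bed(prefix: str) -> tuple[np.ndarray, list[str]]:
    """Minimal reader for triplets written by :func:`write_plink_triplet`.

    Used for round-trip verification only; assumes no missing genotypes.
    """
    ids = [line.split()[1] for line in open(f"{prefix}.fam")]
    m = sum(1 for _ in open(f"{prefix}.bim"))
    n = len(ids)
    decode = {3: 0, 2: 1, 0: 2}
    data = open(f"{prefix}.bed", "rb").read()
    if data[:3] != bytes([0x6C, 0x1B, 0x01]):
        raise ValueError("not a SNP-major PLINK1 .bed file")
    n_bytes = (n + 3) // 4
    geno = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        block = np.frombuffer(
            data, dtype=np.uint8, count=n_bytes, offset=3 + j * n_bytes
        )
        for off in range(4):
            codes = (block >> (2 * off)) & 0b11
            take = codes[: len(codes)]
            rows = np.arange(off, n, 4)
            geno[rows, j] = [decode[int(c)] for c in take[: rows.size]]
    return geno, ids
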