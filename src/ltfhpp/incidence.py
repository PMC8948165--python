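"""Cumulative incidence surfaces and personalized liability constraints.

Cumulative incidence (CIF) by sex, birth year and age is the bridge between
register data and the age-dependent liability threshold model: the
proportion of a (sex, birth-year) stratum diagnosed before a given age maps,
through the upper-tail normal quantile, to a personalized liability
threshold.  Cases with a known age of onset pin their full liability to the
threshold at onset; everyone else contributes a truncation interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import PersonRecord, threshold_from_cip

__all__ = [
    "LogisticCIF",
    "IncidenceSurface",
    "LiabilityConstraint",
    "logistic_cif",
    "invert_logistic_cif",
    "aalen_johansen_cif",
    "build_incidence_surface",
    "personalized_constraint",
    "read_incidence_csv",
    "write_incidence_csv",
]

logger = logging.getLogger(__name__)

EVENT_INTEREST = 1
EVENT_COMPETING = 2
EVENT_CENSORED = 0


@dataclass(frozen=True)
class LogisticCIF:
    """Logistic cumulative incidence curve.

    ``L`` is the maximal attainable (lifetime) prevalence, ``k`` the growth
    rate per year, ``x0`` the median age of onset in years.
    """

    L: float
    k: float = 1.0 / 8.0
    x0: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.L < 1.0):
            raise ValueError(f"L must lie in (0, 1), got {self.L}")
        if self.k <= 0 or self.x0 <= 0:
            raise ValueError("k and x0 must be positive")


def logistic_cif(age, params: LogisticCIF):
    """Cumulative incidence ``L / (1 + exp(-k (age - x0)))`` at ``age``."""
    age = np.asarray(age, dtype=float)
    out = params.L / (1.0 + np.exp(-params.k * (age - params.x0)))
    return float(out) if out.ndim == 0 else out


def invert_logistic_cif(p, params: LogisticCIF):
    """Age at which the logistic CIF reaches proportion ``p``.

    Closed form ``x0 - (1/k) * log(L/p - 1)``; requires ``0 < p < L``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= params.L):
        raise ValueError("p must lie strictly between 0 and L")
    out = params.x0 - np.log(params.L / p - 1.0) / params.k
    return float(out) if out.ndim == 0 else out


def aalen_johansen_cif(
    times: Sequence[float], kinds: Sequence[int]
) -> pd.DataFrame:
    """Aalen-Johansen cumulative incidence under competing risks.

    Parameters
    ----------
    times
        Event or censoring ages, one per subject.
    kinds
        Aligned codes: 1 = event of interest, 2 = competing event (death,
        emigration), 0 = censored.

    Returns
    -------
    DataFrame with columns ``time``, ``cif`` (event of interest),
    ``cif_competing`` and ``surv`` (overall survival), one row per distinct
    time; step-function (right-continuous) semantics.  At tied times events
    of interest are processed before competing events before censorings.

    With no competing events and no censoring the estimate reduces to the
    empirical CDF of the event times.
    """
    times = np.asarray(times, dtype=float)
    kinds = np.asarray(kinds, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if times.shape != kinds.shape:
        raise ValueError("times and kinds must align")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(kinds, [EVENT_CENSORED, EVENT_INTEREST, EVENT_COMPETING])):
        raise ValueError("kinds must be 0 (censored), 1 (interest) or 2 (competing)")

    # tie order: interest < competing < censored
    tie_rank = np.select(
        [kinds == EVENT_INTEREST, kinds == EVENT_COMPETING], [0, 1], default=2
    )
    order = np.lexsort((tie_rank, times))
    times, kinds = times[order], kinds[order]

    n = times.size
    at_risk = n
    surv = 1.0
    cif1 = 0.0
    cif2 = 0.0
    rows = []
    i = 0
    while i < n:
        t = times[i]
        j = i
        d1 = d2 = c = 0
        while j < n and times[j] == t:
            if kinds[j] == EVENT_INTEREST:
                d1 += 1
            elif kinds[j] == EVENT_COMPETING:
                d2 += 1
            else:
                c += 1
            j += 1
        if d1 or d2:
            # product-limit increments use survival just before t
            cif1 += surv * d1 / at_risk
            cif2 += surv * d2 / at_risk
            surv *= 1.0 - (d1 + d2) / at_risk
            rows.append((t, cif1, cif2, surv))
        at_risk -= d1 + d2 + c
        i = j
    if not rows:
        rows.append((float(times[-1]), 0.0, 0.0, 1.0))
    return pd.DataFrame(rows, columns=["time", "cif", "cif_competing", "surv"])


def _stratum_key(sex: str, birth_year) -> tuple:
    by = None if birth_year is None or (isinstance(birth_year, float) and math.isnan(birth_year)) else int(birth_year)
    return (sex, by)


class IncidenceSurface:
    """Queryable cumulative incidence by (sex, birth year, age).

    Each stratum holds a non-decreasing step function of age (last
    observation carried forward, matching yearly register counts); linear
    interpolation is available via ``interpolation='linear'``.  Birth years
    outside the table clamp to the nearest available year (with a logged
    warning); missing sex averages the male and female curves.
    """

    def __init__(
        self,
        strata: dict[tuple, tuple[np.ndarray, np.ndarray]],
        interpolation: str = "step",
    ) -> None:
        if interpolation not in ("step", "linear"):
            raise ValueError("interpolation must be 'step' or 'linear'")
        self._strata = strata
        self.interpolation = interpolation
        self._warned: set[tuple] = set()

    @property
    def strata(self) -> tuple:
        return tuple(self._strata)

    def _eval(self, ages: np.ndarray, cifs: np.ndarray, age: float) -> float:
        if self.interpolation == "linear":
            return float(np.interp(age, ages, cifs))
        idx = np.searchsorted(ages, age, side="right") - 1
        if idx < 0:
            return 0.0
        return float(cifs[idx])

    def _resolve_birth_year(self, sex: str, birth_year) -> list[tuple]:
        years = sorted(
            by for (s, by) in self._strata if s == sex and by is not None
        )
        has_none = (sex, None) in self._strata
        if birth_year is None:
            if has_none:
                return [(sex, None)]
            if not years:
                raise KeyError(f"no strata for sex={sex!r}")
            # no birth-year information: average across all available cohorts
            return [(sex, by) for by in years]
        birth_year = int(birth_year)
        if (sex, birth_year) in self._strata:
            return [(sex, birth_year)]
        if not years:
            if has_none:
                return [(sex, None)]
            raise KeyError(f"no strata for sex={sex!r}")
        nearest = min(years, key=lambda y: (abs(y - birth_year), y))
        key = (sex, birth_year)
        if key not in self._warned:
            self._warned.add(key)
            logger.warning(
                "birth year %s not in incidence table for sex=%s; using nearest "
                "available year %s",
                birth_year,
                sex,
                nearest,
            )
        return [(sex, nearest)]

    def query(self, sex: str, birth_year, age: float) -> float:
        """Cumulative incidence proportion for one person-age."""
        if sex in ("male", "female"):
            keys = self._resolve_birth_year(sex, birth_year)
        else:
            # unknown sex: unweighted average of the sex-specific curves
            vals = [
                self.query(s, birth_year, age)
                for s in ("male", "female")
                if any(k[0] == s for k in self._strata)
            ]
            if not vals:
                raise KeyError("no male/female strata to average for unknown sex")
            return float(np.mean(vals))
        vals = [self._eval(*self._strata[k], age) for k in keys]
        return float(np.mean(vals))

    def lifetime(self, sex: str, birth_year) -> float:
        """Cumulative incidence at the stratum's maximum tabulated age."""
        max_age = max(float(ages[-1]) for ages, _ in self._strata.values())
        return self.query(sex, birth_year, max_age)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, by), (ages, cifs) in self._strata.items():
            for a, c in zip(ages, cifs):
                rows.append((sex, by, a, c))
        return pd.DataFrame(rows, columns=["sex", "birth_year", "age", "cum_inc"])


def build_incidence_surface(
    table: pd.DataFrame, interpolation: str = "step"
) -> IncidenceSurface:
    """Build an :class:`IncidenceSurface` from a long-format table.

    ``table`` needs columns ``sex``, ``birth_year``, ``age``, ``cum_inc``;
    within each (sex, birth_year) stratum ``cum_inc`` must be non-decreasing
    in age (offending rows are reported).
    """
    required = {"sex", "birth_year", "age", "cum_inc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    if np.any(table["cum_inc"] < 0) or np.any(table["cum_inc"] > 1):
        raise ValueError("cum_inc values must lie in [0, 1]")
    strata: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for (sex, by), grp in table.groupby(
        ["sex", "birth_year"], dropna=False, sort=False
    ):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=float)
        cifs = grp["cum_inc"].to_numpy(dtype=float)
        bad = np.where(np.diff(cifs) < 0)[0]
        if bad.size:
            offending = grp.iloc[bad + 1]
            raise ValueError(
                f"stratum (sex={sex}, birth_year={by}): cumulative incidence "
                f"decreases at rows\n{offending.to_string()}"
            )
        strata[_stratum_key(sex, by)] = (ages, cifs)
    return IncidenceSurface(strata, interpolation=interpolation)


def read_incidence_csv(path) -> IncidenceSurface:
    """Read a `sex,birth_year,age,cum_inc` CSV into a surface."""
    return build_incidence_surface(pd.read_csv(path))


def write_incidence_csv(surface: IncidenceSurface, path) -> None:
    surface.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LiabilityConstraint:
    """A per-person restriction on the full liability scale.

    Either ``fixed`` at a known value (cases with an age of onset) or an
    ``interval`` truncation ``(lower, upper)`` with infinite bounds allowed.
    """

    kind: str
    value: float = math.nan
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if not math.isfinite(self.value):
                raise ValueError("fixed constraint needs a finite value")
        elif self.kind == "interval":
            if not self.lower < self.upper:
                raise ValueError("interval constraint needs lower < upper")
        else:
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    @classmethod
    def fixed_at(cls, value: float) -> "LiabilityConstraint":
        return cls(kind="fixed", value=float(value))

    @classmethod
    def interval(cls, lower=-math.inf, upper=math.inf) -> "LiabilityConstraint":
        return cls(kind="interval", lower=float(lower), upper=float(upper))

    @property
    def unconstrained(self) -> bool:
        return (
            self.kind == "interval"
            and math.isinf(self.lower)
            and math.isinf(self.upper)
        )


def personalized_constraint(
    person: PersonRecord, surface: IncidenceSurface
) -> LiabilityConstraint:
    """Translate a person's record into a liability constraint.

    * case with age of onset: liability fixed at the threshold from the
      cumulative incidence at onset age;
    * case without onset: interval [T(age at censoring), +inf);
    * control: interval (-inf, T(age at censoring));
    * unknown status: unconstrained;
    * known status, no age at all: the threshold falls back to the stratum's
      lifetime cumulative incidence (the group-prevalence threshold used by
      family-history-only models).
    """
    if person.status == "unknown":
        return LiabilityConstraint.interval()
    if person.status == "case" and person.age_of_onset is not None:
        p = surface.query(person.sex, person.birth_year, person.age_of_onset)
        return LiabilityConstraint.fixed_at(threshold_from_cip(p))
    age = person.age_at_censoring
    if age is None:
        p = surface.lifetime(person.sex, person.birth_year)
    else:
        p = surface.query(person.sex, person.birth_year, age)
    t = threshold_from_cip(p)
    if person.status == "case":
        return LiabilityConstraint.interval(lower=t)
    return LiabilityConstraint.interval(upper=t)
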