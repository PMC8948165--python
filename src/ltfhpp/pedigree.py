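"""Pedigree domain types and the multivariate liability covariance model.

The liability threshold model assigns each person a latent liability
``l = l_g + l_e`` with genetic component ``l_g ~ N(0, h2)`` and independent
environmental component ``l_e ~ N(0, 1 - h2)``.  A person is a case when
their full liability exceeds a threshold ``T`` chosen so that
``P(l >= T) = K`` for prevalence ``K``.  For a genotyped index individual
and their first-degree relatives the joint vector
``(l_g, l_o, l_rel_1, ..., l_rel_m)`` is multivariate normal with a
covariance determined entirely by the heritability ``h2`` and the
coefficients of relationship ``r`` between family members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "PersonRecord",
    "FamilyPedigree",
    "CovarianceModel",
    "build_covariance",
    "threshold_from_cip",
    "hazard_probability",
    "cox_hazard_probability",
    "CIP_CLAMP",
]

ROLES = ("index", "father", "mother", "sibling")
SEXES = ("male", "female", "unknown")
STATUSES = ("case", "control", "unknown")

#: Cumulative incidence proportions are clamped into this open interval before
#: quantile transformation so thresholds stay finite (mortality incidence
#: approaches 1 at high ages).
CIP_CLAMP = (1e-12, 1.0 - 1e-12)


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (e.g. duplicate parents)."""


@dataclass(frozen=True)
class PersonRecord:
    """One person's disease status and timing information.

    Parameters
    ----------
    person_id, family_id
        Opaque identifiers.
    role
        One of ``index``, ``father``, ``mother``, ``sibling``.
    sex
        ``male``, ``female`` or ``unknown``.
    birth_year
        Calendar year of birth, or ``None`` when unknown.
    status
        ``case``, ``control`` or ``unknown``.
    age_at_censoring
        Age in years at last follow-up (current age, or age at
        death/emigration).  Used for controls and for cases lacking an
        age of onset.
    age_of_onset
        Age at first diagnosis, cases only.
    """

    person_id: str
    family_id: str
    role: str
    sex: str = "unknown"
    birth_year: Optional[int] = None
    status: str = "unknown"
    age_at_censoring: Optional[float] = None
    age_of_onset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PedigreeError(f"unknown role {self.role!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "case" and self.age_of_onset is not None:
            raise ValueError(
                f"person {self.person_id}: age_of_onset is only valid for cases"
            )
        for name in ("birth_year", "age_at_censoring", "age_of_onset"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"person {self.person_id}: {name}={v!r} invalid")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class FamilyPedigree:
    """An index individual together with their first-degree relatives.

    ``relatedness`` maps each relative's ``person_id`` to the coefficient of
    relationship r with the index; parents and full siblings have r = 0.5.
    When omitted, r = 0.5 is filled in for the supported roles.
    """

    index: PersonRecord
    relatives: Sequence[PersonRecord] = ()
    relatedness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.index.role != "index":
            raise PedigreeError("index record must have role='index'")
        n_father = sum(1 for p in self.relatives if p.role == "father")
        n_mother = sum(1 for p in self.relatives if p.role == "mother")
        if n_father > 1 or n_mother > 1:
            raise PedigreeError("at most one father and one mother allowed")
        if any(p.role == "index" for p in self.relatives):
            raise PedigreeError("exactly one index record per family")
        rel = dict(self.relatedness)
        for p in self.relatives:
            r = rel.get(p.person_id, 0.5)
            if not (0.0 < r <= 1.0):
                raise PedigreeError(
                    f"relatedness for {p.person_id} must lie in (0, 1], got {r}"
                )
            rel[p.person_id] = r
        object.__setattr__(self, "relatedness", rel)

    @property
    def members(self) -> tuple[PersonRecord, ...]:
        return (self.index, *self.relatives)

    def r_of(self, person_id: str) -> float:
        return self.relatedness[person_id]


@dataclass(frozen=True)
class CovarianceModel:
    """Joint covariance of ``(l_g, l_o, l_rel_1, ..., l_rel_m)``.

    ``order`` names the coordinates: the index's genetic liability, the
    index's full liability, then one full liability per relative (input
    order preserved).
    """

    h2: float
    order: tuple[str, ...]
    sigma: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.order)


def build_covariance(h2: float, pedigree: FamilyPedigree) -> CovarianceModel:
    """Build the liability covariance matrix for a family.

    Entries follow the r-scaled rule: ``Var(l_g) = h2``, all full liabilities
    have unit variance, ``Cov(l_g, l_o) = h2``, ``Cov(l_g, l_rel) =
    Cov(l_o, l_rel) = r * h2``, spouses (father, mother) are uncorrelated,
    any two siblings and any parent-sibling pair share ``0.5 * h2``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    rels = list(pedigree.relatives)
    order = ("genetic", "index", *(p.person_id for p in rels))
    n = 2 + len(rels)
    sigma = np.zeros((n, n))
    sigma[0, 0] = h2
    sigma[1, 1] = 1.0
    sigma[0, 1] = sigma[1, 0] = h2
    for i, p in enumerate(rels, start=2):
        r = pedigree.r_of(p.person_id)
        sigma[i, i] = 1.0
        sigma[0, i] = sigma[i, 0] = r * h2
        sigma[1, i] = sigma[i, 1] = r * h2
    for i, p in enumerate(rels, start=2):
        for j, q in enumerate(rels, start=2):
            if j <= i:
                continue
            pr, qr = p.role, q.role
            if {pr, qr} == {"father", "mother"}:
                cov = 0.0
            else:
                # parent-sibling and sibling-sibling pairs share half the
                # additive genetic variance
                cov = 0.5 * h2
            sigma[i, j] = sigma[j, i] = cov
    return CovarianceModel(h2=h2, order=order, sigma=sigma)


def threshold_from_cip(p: float) -> float:
    """Liability threshold for a cumulative incidence proportion ``p``.

    Returns the upper-tail standard normal quantile ``T`` with
    ``P(l >= T) = p``; strictly decreasing in ``p``.  ``p`` is clamped into
    an open interval just inside (0, 1) so the result stays finite.
    """
    if not (0.0 < p < 1.0):
        p = float(np.clip(p, *CIP_CLAMP))
        if not (0.0 < p < 1.0):
            raise ValueError(f"cumulative incidence must lie in (0, 1), got {p}")
    return float(-ndtri(p))


def hazard_probability(T_t: float, T_tdt: float, g: float, h2: float) -> float:
    """Probability of onset in an age interval under the threshold model.

    With age-dependent threshold ``T(t)`` and genetic liability ``g``, the
    probability of being diagnosed between ages ``t`` and ``t + dt`` given no
    prior diagnosis is::

        1 - Phi((T(t+dt) - g) / sqrt(1 - h2)) / Phi((T(t) - g) / sqrt(1 - h2))

    since the full liability given ``g`` is N(g, 1 - h2).  Requires
    ``T(t+dt) <= T(t)`` (thresholds never increase with age).
    """
    if T_tdt > T_t:
        raise ValueError("threshold must be non-increasing in age (T_tdt <= T_t)")
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1); h2=1 has no environmental noise")
    s = math.sqrt(1.0 - h2)
    denom = ndtr((T_t - g) / s)
    if denom == 0.0:
        # already diagnosed almost surely; interval probability degenerate
        return 1.0
    val = 1.0 - ndtr((T_tdt - g) / s) / denom
    return float(min(max(val, 0.0), 1.0))


def cox_hazard_probability(dt: float, alpha: float, g: float) -> float:
    """Cox-model analogue: onset probability ``dt * alpha * exp(g)``.

    Assumes a constant baseline hazard ``alpha`` with log-hazard shifted by
    the genetic liability, for side-by-side comparison with
    :func:`hazard_probability`.
    """
    if dt <= 0 or alpha <= 0:
        raise ValueError("dt and alpha must be positive")
    return dt * alpha * math.exp(g)
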