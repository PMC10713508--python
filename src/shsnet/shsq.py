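"""SHSQ-25 data model, scoring, median-split stratification and group comparisons.

The SHSQ-25 instrument asks respondents to rate 25 symptom items on a
five-point scale (0 = never/almost never … 4 = always).  Items belong to five
health domains: cardiovascular (CS, 3 items), digestive (DS, 3), fatigue
(FT, 9), immune (IS, 3) and mental health (MH, 7).  The total score is the
plain sum of the 25 ratings; the sample median of the total splits the cohort
into an "optimal" (low score) and a "suboptimal" (high score) population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_ITEMS",
    "CANONICAL_DOMAIN_MAP",
    "DOMAIN_SIZES",
    "LikertResponseMatrix",
    "ScoreTable",
    "GroupComparison",
    "SchemaError",
    "RatingValidationError",
    "DegenerateSplitWarning",
    "load_responses",
    "shs_scores",
    "median_split",
    "cohens_d",
    "effect_size_label",
    "compare_groups",
]

DOMAIN_SIZES = {"CS": 3, "DS": 3, "FT": 9, "IS": 3, "MH": 7}

CANONICAL_ITEMS: tuple[str, ...] = tuple(
    f"{dom}{i}" for dom, k in DOMAIN_SIZES.items() for i in range(1, k + 1)
)

CANONICAL_DOMAIN_MAP: dict[str, str] = {item: item[:2] for item in CANONICAL_ITEMS}

RATING_MIN, RATING_MAX = 0, 4


class SchemaError(ValueError):
    """An expected item or covariate column is absent from the input."""


class RatingValidationError(ValueError):
    """A rating falls outside {0,...,4} or is not an integer.

    Attributes
    ----------
    offending : list of (respondent_id, item) pairs locating the bad cells.
    """

    def __init__(self, message: str, offending: list[tuple[object, str]]):
        super().__init__(message)
        self.offending = offending


class DegenerateSplitWarning(UserWarning):
    """All total scores are identical; the median split is degenerate."""


@dataclass
class LikertResponseMatrix:
    """Respondents × items integer rating matrix with an item→domain mapping.

    ``ratings`` is stored as float so missing entries can be carried as NaN;
    every observed entry must be an integer in {0,…,4}.  Missingness is never
    silently imputed.
    """

    respondent_ids: list
    items: list[str]
    ratings: np.ndarray
    domain_map: dict[str, str] = field(default_factory=lambda: dict(CANONICAL_DOMAIN_MAP))
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.ratings.shape != (len(self.respondent_ids), len(self.items)):
            raise ValueError(
                f"ratings shape {self.ratings.shape} does not match "
                f"{len(self.respondent_ids)} respondents x {len(self.items)} items"
            )
        obs = self.ratings[~np.isnan(self.ratings)]
        bad = (obs < RATING_MIN) | (obs > RATING_MAX) | (obs != np.round(obs))
        if bad.any():
            cells = self._locate_bad_cells()
            raise RatingValidationError(
                "ratings outside {0,...,4} or non-integer at: "
                + ", ".join(f"(respondent {r}, item {c})" for r, c in cells[:20]),
                cells,
            )
        missing_items = [i for i in self.items if i not in self.domain_map]
        if missing_items:
            raise SchemaError(f"items without a domain assignment: {missing_items}")

    def _locate_bad_cells(self) -> list[tuple[object, str]]:
        cells = []
        for i, rid in enumerate(self.respondent_ids):
            for j, item in enumerate(self.items):
                v = self.ratings[i, j]
                if not np.isnan(v) and (v < RATING_MIN or v > RATING_MAX or v != round(v)):
                    cells.append((rid, item))
        return cells

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.ratings)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratings, index=self.respondent_ids, columns=self.items)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        if self.covariates is not None:
            df = pd.concat([df, self.covariates], axis=1)
        df.to_csv(path, index_label="respondent_id")


@dataclass
class ScoreTable:
    """Per-respondent total and domain scores, plus the split once applied."""

    respondent_ids: list
    total_score: np.ndarray
    domain_scores: pd.DataFrame  # columns = domains, index = respondent_ids
    status_label: pd.Series | None = None  # "optimal" / "suboptimal"
    median_cutoff: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.domain_scores.copy()
        df.insert(0, "total", self.total_score)
        if self.status_label is not None:
            df["status"] = self.status_label
        return df


@dataclass
class GroupComparison:
    variable: str
    kind: str  # "numeric" | "categorical"
    group_means: dict | None
    group_sds: dict | None
    group_ns: dict
    pooled_sd: float | None
    cohens_d: float | None
    effect_label: str | None
    statistic: float
    df: float
    p_value: float
    test: str


def load_responses(
    path,
    items: Sequence[str] = CANONICAL_ITEMS,
    domain_map: Mapping[str, str] | None = None,
    covariate_columns: Sequence[str] = (),
    id_column: str | None = "respondent_id",
) -> LikertResponseMatrix:
    """Read a respondents × items CSV into a validated :class:`LikertResponseMatrix`.

    The CSV must carry one respondent per row and one column per item code
    (``CS1`` … ``MH7`` for the canonical instrument).  Out-of-range or
    non-integer ratings raise :class:`RatingValidationError` naming the cells;
    a missing item column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    if id_column is not None and id_column in df.columns:
        df = df.set_index(id_column)
    missing = [c for c in items if c not in df.columns]
    if missing:
        raise SchemaError(f"missing item columns: {missing}")
    absent_cov = [c for c in covariate_columns if c not in df.columns]
    if absent_cov:
        raise SchemaError(f"missing covariate columns: {absent_cov}")
    ratings = df[list(items)].to_numpy(dtype=float)
    cov = df[list(covariate_columns)].copy() if covariate_columns else None
    dm = dict(domain_map) if domain_map is not None else {i: i[:2] for i in items}
    return LikertResponseMatrix(
        respondent_ids=list(df.index),
        items=list(items),
        ratings=ratings,
        domain_map=dm,
        covariates=cov,
    )


def shs_scores(m: LikertResponseMatrix, missing: str = "strict") -> ScoreTable:
    """Total and per-domain SHS scores obtained by summing item ratings.

    ``missing='strict'`` (default) refuses to score respondents with missing
    ratings; ``missing='drop'`` removes them with a warning.  No imputation.
    """
    mask = m.missing_mask.any(axis=1)
    ids = list(m.respondent_ids)
    ratings = m.ratings
    if mask.any():
        offenders = [ids[i] for i in np.flatnonzero(mask)]
        if missing == "strict":
            raise ValueError(
                f"missing ratings for respondents {offenders}; "
                "use missing='drop' to exclude them"
            )
        if missing == "drop":
            warnings.warn(f"dropping {len(offenders)} incomplete respondents: {offenders}")
            keep = ~mask
            ids = [ids[i] for i in np.flatnonzero(keep)]
            ratings = ratings[keep]
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    domains = sorted(set(m.domain_map[i] for i in m.items))
    dom_scores = {}
    for dom in domains:
        cols = [j for j, item in enumerate(m.items) if m.domain_map[item] == dom]
        dom_scores[dom] = ratings[:, cols].sum(axis=1).astype(int)
    domain_df = pd.DataFrame(dom_scores, index=ids)
    total = ratings.sum(axis=1).astype(int)
    return ScoreTable(respondent_ids=ids, total_score=total, domain_scores=domain_df)


def median_split(scores: ScoreTable, ties: str = "optimal") -> ScoreTable:
    """Label respondents optimal/suboptimal by the sample median of the total.

    Scores strictly above the median are "suboptimal", strictly below
    "optimal".  Scores equal to the median go to the group named by ``ties``
    (default "optimal", i.e. suboptimal means strictly greater than the
    cutoff).  If all totals are identical the split is degenerate: everyone
    is labelled optimal and a :class:`DegenerateSplitWarning` is emitted.
    """
    if len(scores.respondent_ids) < 2:
        raise ValueError("median split requires at least 2 respondents")
    if ties not in ("optimal", "suboptimal"):
        raise ValueError("ties must be 'optimal' or 'suboptimal'")
    total = np.asarray(scores.total_score, dtype=float)
    cutoff = float(np.median(total))
    if np.all(total == total[0]):
        warnings.warn(
            "all total scores identical; degenerate split, labelling everyone optimal",
            DegenerateSplitWarning,
        )
        labels = np.full(total.shape, "optimal", dtype=object)
    elif ties == "optimal":
        labels = np.where(total > cutoff, "suboptimal", "optimal")
    else:
        labels = np.where(total >= cutoff, "suboptimal", "optimal")
    return ScoreTable(
        respondent_ids=scores.respondent_ids,
        total_score=scores.total_score,
        domain_scores=scores.domain_scores,
        status_label=pd.Series(labels, index=scores.respondent_ids, name="status"),
        median_cutoff=cutoff,
    )


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Pooled-SD Cohen's d from group summary statistics.

    d = |m2 − m1| / s_p with s_p² = ((n1−1)s1² + (n2−1)s2²) / (n1+n2−2).
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = abs(m2 - m1)
    if sp == 0:
        if diff == 0:
            return 0.0
        raise ZeroDivisionError("zero pooled SD with unequal means: effect size undefined")
    return float(diff / sp)


def effect_size_label(d: float) -> str:
    """Standard magnitude bands: <0.2 negligible, 0.2–0.5 small, 0.5–0.8 medium, ≥0.8 large."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def pooled_t_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from group summaries.

    Returns (t, df, two-sided p).  The pooled form shares its SD with
    :func:`cohens_d`, so d and t are mutually consistent.
    """
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    if sp == 0:
        if m1 == m2:
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled SD with unequal means")
    t = (m2 - m1) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def compare_groups(
    m: LikertResponseMatrix,
    variable: str,
    status: pd.Series | None = None,
) -> GroupComparison:
    """Compare a covariate between the optimal and suboptimal populations.

    Numeric covariates get a pooled two-sample t-test plus Cohen's d;
    categorical covariates get a chi-square test on the group × category
    contingency table.  If ``status`` is not supplied it is derived by
    scoring and median-splitting ``m``.
    """
    if m.covariates is None or variable not in m.covariates.columns:
        raise SchemaError(f"covariate {variable!r} not present")
    if status is None:
        status = median_split(shs_scores(m)).status_label
    status = pd.Series(np.asarray(status), index=m.covariates.index, name="status")
    values = m.covariates[variable]
    groups = {g: values[status == g] for g in ("optimal", "suboptimal")}
    ns = {g: int(v.notna().sum()) for g, v in groups.items()}
    if min(ns.values()) < 2:
        raise ValueError(f"insufficient data: group sizes {ns}")

    if pd.api.types.is_numeric_dtype(values):
        stats_ = {g: (float(v.mean()), float(v.std(ddof=1))) for g, v in groups.items()}
        (m1, s1), (m2, s2) = stats_["optimal"], stats_["suboptimal"]
        n1, n2 = ns["optimal"], ns["suboptimal"]
        t, df, p = pooled_t_from_summaries(m1, s1, n1, m2, s2, n2)
        d = cohens_d(m1, s1, n1, m2, s2, n2)
        sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        return GroupComparison(
            variable=variable,
            kind="numeric",
            group_means={"optimal": m1, "suboptimal": m2},
            group_sds={"optimal": s1, "suboptimal": s2},
            group_ns=ns,
            pooled_sd=float(sp),
            cohens_d=d,
            effect_label=effect_size_label(d),
            statistic=t,
            df=df,
            p_value=p,
            test="pooled t-test",
        )

    table = pd.crosstab(status, values)
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return GroupComparison(
        variable=variable,
        kind="categorical",
        group_means=None,
        group_sds=None,
        group_ns=ns,
        pooled_sd=None,
        cohens_d=None,
        effect_label=None,
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        test="chi-square",
    )
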