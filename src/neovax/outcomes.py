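"""Recurrence-free survival and propensity-matched controls.

Recurrence-free survival (RFS) runs from an origin (radical surgery or
first vaccination) to radiographic relapse, with administrative censoring
otherwise.  Group comparisons (responsive vs non-responsive/prime-only vs
matched controls) use Kaplan-Meier medians and the log-rank test.

Untreated control patients are drawn from a clinical pool by propensity-
score matching: a logistic model of treatment on baseline covariates,
then 1:2 greedy nearest-neighbor matching without replacement on the
logit of the propensity score, within a caliper of 0.2 standard
deviations of that logit (the standard reading of "caliper of 0.2"; a
raw-probability caliper is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.linear_model import LogisticRegression

DAYS_PER_MONTH = 30.4375  # 365.25 / 12

GROUPS = ("responsive", "non-responsive", "matched-control")


@dataclass
class PatientOutcome:
    """One patient's clinical timeline and response-group label."""

    patient: str
    surgery: date
    first_vaccination: date | None
    endpoint: date            # recurrence date if event, else censor date
    event: bool               # True = radiographic relapse observed
    group: str = "responsive"
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.endpoint < self.surgery:
            raise ValueError(f"{self.patient}: endpoint precedes surgery")
        if (
            self.first_vaccination is not None
            and self.first_vaccination < self.surgery
        ):
            raise ValueError(f"{self.patient}: vaccination precedes surgery")


def rfs_months(
    origin: Literal["surgery", "first_vaccination"],
    outcome: PatientOutcome,
) -> tuple[float, bool]:
    """RFS in months from the chosen origin, with the event flag.

    Months use the mean Gregorian month of 30.4375 days.
    """
    start = outcome.surgery if origin == "surgery" else outcome.first_vaccination
    if start is None:
        raise ValueError(f"{outcome.patient}: no {origin} date")
    delta = (outcome.endpoint - start).days
    if delta < 0:
        raise ValueError(f"{outcome.patient}: origin after endpoint")
    return delta / DAYS_PER_MONTH, outcome.event


def km_median(times: Sequence[float], events: Sequence[bool]) -> float | None:
    """Kaplan-Meier median: smallest time with survivor estimate <= 0.5.

    Returns None when the product-limit curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival sample")
    if times.size != events.size:
        raise ValueError("times and events length mismatch")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    # tolerance so an exact 0.5 plateau counts despite float rounding
    hit = sf[sf <= 0.5 + 1e-9]
    return float(hit.index[0]) if len(hit) else None


def logrank_compare(
    samples: dict[str, tuple[Sequence[float], Sequence[bool]]],
) -> tuple[float, float]:
    """Log-rank chi-square test across two or more labeled survival samples.

    Returns (test statistic, p-value).
    """
    if len(samples) < 2:
        raise ValueError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for label, (t, e) in samples.items():
        if len(t) == 0:
            raise ValueError(f"group {label!r} is empty")
        times.extend(t)
        events.extend(e)
        labels.extend([label] * len(t))
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float),
        np.asarray(labels),
        np.asarray(events, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Propensity-score matching


@dataclass
class MatchResult:
    """Outcome of 1:ratio caliper matching."""

    matches: dict[int, list[int]]      # treated row index -> control row indices
    unmatched_treated: list[int]
    propensity_treated: np.ndarray     # logit scale
    propensity_control: np.ndarray
    caliper_logit: float
    dropped_covariates: list[str]

    @property
    def matched_control_indices(self) -> list[int]:
        return [c for cs in self.matches.values() for c in cs]


def _fit_propensity(
    treated: pd.DataFrame, pool: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = list(treated.columns)
    dropped = [
        c for c in cols
        if pd.concat([treated[c], pool[c]]).nunique() < 2
    ]
    keep = [c for c in cols if c not in dropped]
    if not keep:
        raise ValueError("all covariates are degenerate (constant)")
    X = pd.concat([treated[keep], pool[keep]], ignore_index=True).to_numpy(float)
    y = np.r_[np.ones(len(treated)), np.zeros(len(pool))]
    # standardize for a well-conditioned, near-unpenalized fit
    mu, sd = X.mean(axis=0), X.std(axis=0)
    model = LogisticRegression(C=1e6, max_iter=2000)
    model.fit((X - mu) / sd, y)
    p = np.clip(model.predict_proba((X - mu) / sd)[:, 1], 1e-12, 1 - 1e-12)
    logit = np.log(p / (1 - p))
    return logit[: len(treated)], logit[len(treated):], dropped


def propensity_match(
    treated: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 2,
    caliper: float = 0.2,
    caliper_scale: Literal["logit-sd", "probability"] = "logit-sd",
    seed: int = 0,
) -> MatchResult:
    """1:ratio greedy nearest-neighbor matching within a caliper.

    Both frames hold one row per patient and share a numeric covariate
    schema.  Constant covariates are dropped with a warning entry in the
    result.  Treated patients are visited in a seeded random order; each
    claims its ``ratio`` nearest unused controls on the logit scale, but
    only within the caliper (0.2 x SD of the logit by default).  Treated
    patients with no in-caliper control left are reported unmatched.
    """
    if list(treated.columns) != list(pool.columns):
        raise ValueError("treated and pool covariate schemas differ")
    lt, lc, dropped = _fit_propensity(treated, pool)
    if caliper_scale == "logit-sd":
        width = caliper * float(np.std(np.r_[lt, lc]))
    else:
        pt, pc = 1 / (1 + np.exp(-lt)), 1 / (1 + np.exp(-lc))
        width = caliper
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lt))
    available = set(range(len(lc)))
    matches: dict[int, list[int]] = {}
    unmatched: list[int] = []
    for i in order:
        if caliper_scale == "logit-sd":
            dists = {j: abs(lt[i] - lc[j]) for j in available}
        else:
            dists = {j: abs(pt[i] - pc[j]) for j in available}
        near = sorted(
            (j for j, d in dists.items() if d <= width), key=dists.__getitem__
        )[:ratio]
        if near:
            matches[int(i)] = [int(j) for j in near]
            available -= set(near)
        else:
            unmatched.append(int(i))
    return MatchResult(
        matches=matches,
        unmatched_treated=sorted(unmatched),
        propensity_treated=lt,
        propensity_control=lc,
        caliper_logit=width,
        dropped_covariates=dropped,
    )


def standardized_mean_differences(
    treated: pd.DataFrame, control: pd.DataFrame
) -> pd.Series:
    """Absolute standardized mean difference per covariate (balance metric).

    SMD = |mean_t - mean_c| / sqrt((var_t + var_c) / 2); 0 when both
    variances vanish.
    """
    out = {}
    for col in treated.columns:
        t = treated[col].to_numpy(float)
        c = control[col].to_numpy(float)
        denom = np.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2)
        out[col] = abs(t.mean() - c.mean()) / denom if denom > 0 else 0.0
    return pd.Series(out)
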