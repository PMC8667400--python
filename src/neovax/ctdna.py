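"""Longitudinal ctDNA panel monitoring.

Each patient's plasma samples are sequenced over a personalized panel of
their somatic mutation sites, split into vaccine-targeted neoantigen sites
and other somatic sites.  Per timepoint we compute detection (>= 2 mutant
reads by default; plasma positivity has no community-standard rule, so the
threshold is exposed), panel positive rates, and mean VAF per subset;
across timepoints the two mean-VAF series form a trajectory whose shape is
classified as:

- ``untrackable`` — too few timepoints with any detected site to follow
  tumor burden at all;
- ``concordant``  — targeted and other mutations rise and fall together
  (rank correlation >= 0.7 by default), i.e. ctDNA tracks bulk tumor
  burden;
- ``divergent``   — the treated-neoantigen series decouples from the rest
  of the panel, the signature expected when vaccine-driven selection
  preferentially clears neoantigen-bearing clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_ALT_READS = 2
DEFAULT_MIN_TIMEPOINTS = 3
DEFAULT_RHO_THRESHOLD = 0.7

Pattern = Literal["concordant", "divergent", "untrackable"]
UndetectedPolicy = Literal["zero", "exclude"]


@dataclass(frozen=True)
class PlasmaObservation:
    """Read counts for one panel site in one plasma sample."""

    patient: str
    day: int          # days from first vaccination; negative = pre-vaccination
    site: str         # locus key "chrom:pos:ref>alt"
    alt_reads: int
    total_reads: int
    is_target: bool   # vaccine-targeted neoantigen site vs other somatic site

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.total_reads:
            raise ValueError(
                f"{self.site} day {self.day}: alt_reads > total_reads"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else 0.0


@dataclass
class PanelTrajectory:
    """Mean-VAF time series of a patient's panel, split target vs other."""

    patient: str
    days: list[int]
    mean_vaf_target: list[float]
    mean_vaf_other: list[float]
    n_sites_target: int
    n_sites_other: int
    n_detected_by_day: list[int]  # sites (either subset) detected per timepoint


def site_detected(
    obs: PlasmaObservation, min_alt_reads: int = DEFAULT_MIN_ALT_READS
) -> bool:
    """Plasma positivity for one site: at least ``min_alt_reads`` mutant reads."""
    return obs.alt_reads >= min_alt_reads


def positive_rate(
    sample: Iterable[PlasmaObservation],
    subset: Literal["target", "other"],
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float:
    """Fraction of panel sites in the subset detected in one plasma sample."""
    wanted = [o for o in sample if o.is_target == (subset == "target")]
    if not wanted:
        raise ValueError(f"no {subset!r} sites in sample")
    detected = sum(site_detected(o, min_alt_reads) for o in wanted)
    return detected / len(wanted)


def mean_vaf(
    sample: Iterable[PlasmaObservation],
    subset: Literal["target", "other"],
    undetected_policy: UndetectedPolicy = "zero",
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> float:
    """Mean per-site VAF over the subset at one timepoint.

    Under the default ``zero`` policy undetected sites contribute VAF 0,
    keeping means comparable across timepoints with different detection;
    ``exclude`` averages detected sites only (0 if none detected).
    """
    wanted = [o for o in sample if o.is_target == (subset == "target")]
    if not wanted:
        raise ValueError(f"no {subset!r} sites in sample")
    if undetected_policy == "zero":
        return float(np.mean([o.vaf if site_detected(o, min_alt_reads) else 0.0
                              for o in wanted]))
    detected = [o.vaf for o in wanted if site_detected(o, min_alt_reads)]
    return float(np.mean(detected)) if detected else 0.0


def percent_decline(v_before: float, v_after: float) -> float:
    """Percent change from before to after: 100 x (before - after) / before.

    Negative values denote an increase.  Undefined when the baseline is 0.
    """
    if v_before <= 0:
        raise ValueError("percent decline undefined for zero/negative baseline")
    return 100.0 * (v_before - v_after) / v_before


def build_trajectory(
    observations: Sequence[PlasmaObservation],
    undetected_policy: UndetectedPolicy = "zero",
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> PanelTrajectory:
    """Collapse a patient's plasma observations into mean-VAF time series."""
    patients = {o.patient for o in observations}
    if len(patients) != 1:
        raise ValueError(f"observations span {len(patients)} patients, expected 1")
    days = sorted({o.day for o in observations})
    by_day: dict[int, list[PlasmaObservation]] = {d: [] for d in days}
    for o in observations:
        by_day[o.day].append(o)
    mv_t, mv_o, ndet = [], [], []
    for d in days:
        sample = by_day[d]
        mv_t.append(mean_vaf(sample, "target", undetected_policy, min_alt_reads))
        mv_o.append(mean_vaf(sample, "other", undetected_policy, min_alt_reads))
        ndet.append(sum(site_detected(o, min_alt_reads) for o in sample))
    return PanelTrajectory(
        patient=patients.pop(),
        days=days,
        mean_vaf_target=mv_t,
        mean_vaf_other=mv_o,
        n_sites_target=len({o.site for o in observations if o.is_target}),
        n_sites_other=len({o.site for o in observations if not o.is_target}),
        n_detected_by_day=ndet,
    )


def classify_pattern(
    traj: PanelTrajectory,
    min_timepoints: int = DEFAULT_MIN_TIMEPOINTS,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> Pattern:
    """Classify the joint dynamics of targeted vs other mean-VAF series.

    Fewer than ``min_timepoints`` timepoints with any detected site →
    ``untrackable``.  Otherwise Spearman rank correlation between the two
    series decides: >= ``rho_threshold`` → ``concordant``, else
    ``divergent``.  A series that is constant has no rank ordering: both
    constant counts as concordant (nothing moved apart), exactly one
    constant as divergent.
    """
    trackable = sum(n > 0 for n in traj.n_detected_by_day)
    if trackable < min_timepoints:
        return "untrackable"
    t = np.asarray(traj.mean_vaf_target)
    o = np.asarray(traj.mean_vaf_other)
    t_const = np.ptp(t) == 0
    o_const = np.ptp(o) == 0
    if t_const and o_const:
        return "concordant"
    if t_const or o_const:
        return "divergent"
    rho = stats.spearmanr(t, o).statistic
    return "concordant" if rho >= rho_threshold else "divergent"


# ---------------------------------------------------------------------------
# Table I/O

PLASMA_COLUMNS = ["patient", "day", "site", "alt_reads", "total_reads", "is_target"]


def observations_from_frame(df: pd.DataFrame) -> list[PlasmaObservation]:
    return [
        PlasmaObservation(
            patient=str(r.patient), day=int(r.day), site=str(r.site),
            alt_reads=int(r.alt_reads), total_reads=int(r.total_reads),
            is_target=bool(r.is_target),
        )
        for r in df.itertuples()
    ]


def read_plasma_table(path) -> list[PlasmaObservation]:
    """Plasma TSV with columns patient, day, site, alt_reads, total_reads, is_target."""
    return observations_from_frame(pd.read_csv(path, sep="\t"))


def trajectory_frame(traj: PanelTrajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": traj.patient,
            "day": traj.days,
            "mean_vaf_target": traj.mean_vaf_target,
            "mean_vaf_other": traj.mean_vaf_other,
            "n_detected": traj.n_detected_by_day,
        }
    )
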