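"""IFN-gamma ELISpot response calling and durability summaries.

PBMCs sampled before vaccination, after the prime phase, after the boost
phase and at follow-up are stimulated with each neoantigen peptide pool
(or single peptide), alongside a negative control (unpulsed) and positive
control well set.  A stimulus is called positive against its matched
negative control with a conventional empirical criterion: mean spots at
least ``fold`` times the NC mean *and* exceeding it by at least
``min_excess`` spots (defaults 2x and 10 spots; both configurable — the
underlying assay has no single standard rule).

A patient counts as having responsive neoantigens only when at least one
pool or peptide is positive at a post-boost timepoint: pre-existing
reactivity that decays before the boost phase does not qualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FOLD = 2.0
DEFAULT_MIN_EXCESS = 10.0

#: canonical timepoint labels in assay order
TIMEPOINTS = ("pre-vaccination", "post-prime", "post-boost", "follow-up")
POST_BOOST_TIMEPOINTS = ("post-boost", "follow-up")


@dataclass(frozen=True)
class ElispotMeasurement:
    """Replicate spot counts for one stimulus in one patient sample."""

    patient: str
    timepoint: str       # "pre-vaccination" | "post-prime" | "post-boost" | "follow-up"
    stimulus: str        # pool id, peptide id, "NC" or "PC"
    spot_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.spot_counts) == 0:
            raise ValueError("need at least one replicate well")
        if any(c < 0 for c in self.spot_counts):
            raise ValueError("spot counts must be non-negative")

    @property
    def mean_spots(self) -> float:
        return float(np.mean(self.spot_counts))


def response_positive(
    stim: ElispotMeasurement,
    nc: ElispotMeasurement,
    fold: float = DEFAULT_FOLD,
    min_excess: float = DEFAULT_MIN_EXCESS,
) -> bool:
    """Call a stimulus positive against its matched negative control.

    Positive iff mean(stim) >= fold x mean(NC) and
    mean(stim) - mean(NC) >= min_excess.
    """
    if stim.patient != nc.patient or stim.timepoint != nc.timepoint:
        raise ValueError(
            "stimulus and negative control must share patient and timepoint"
        )
    return (
        stim.mean_spots >= fold * nc.mean_spots
        and stim.mean_spots - nc.mean_spots >= min_excess
    )


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of one stimulus-vs-NC comparison."""

    patient: str
    timepoint: str
    stimulus: str
    positive: bool


def patient_responsive(
    calls: Iterable[ResponseCall], completed_boost: bool = True
) -> bool:
    """Whether a fully vaccinated patient shows vaccine-associated responses.

    True iff any pool/peptide is positive at a post-boost timepoint
    (post-boost or follow-up).  Patients who only received the prime phase
    are a separate clinical group and cannot be scored here.
    """
    if not completed_boost:
        raise ValueError(
            "patient did not complete the boost phase; responsiveness is "
            "only defined for fully vaccinated patients"
        )
    return any(
        c.positive and c.timepoint in POST_BOOST_TIMEPOINTS for c in calls
    )


def peptide_response_rate(n_positive: int, n_tested: int) -> float:
    """Percent of tested individual peptides that induced a response, 1 d.p."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if n_positive > n_tested or n_positive < 0:
        raise ValueError("n_positive must lie in [0, n_tested]")
    return round(100.0 * n_positive / n_tested, 1)


def call_responses(
    measurements: Sequence[ElispotMeasurement],
    fold: float = DEFAULT_FOLD,
    min_excess: float = DEFAULT_MIN_EXCESS,
) -> list[ResponseCall]:
    """Call every non-control stimulus against the matched NC well set."""
    ncs = {
        (m.patient, m.timepoint): m for m in measurements if m.stimulus == "NC"
    }
    calls = []
    for m in measurements:
        if m.stimulus in ("NC", "PC"):
            continue
        nc = ncs.get((m.patient, m.timepoint))
        if nc is None:
            raise ValueError(
                f"no negative control for {m.patient} at {m.timepoint}"
            )
        calls.append(
            ResponseCall(
                patient=m.patient,
                timepoint=m.timepoint,
                stimulus=m.stimulus,
                positive=response_positive(m, nc, fold, min_excess),
            )
        )
    return calls


def durability_summary(measurements: Sequence[ElispotMeasurement]) -> pd.DataFrame:
    """Mean spots per pool at each timepoint — the durability readout."""
    rows = [
        {
            "patient": m.patient,
            "timepoint": m.timepoint,
            "stimulus": m.stimulus,
            "mean_spots": m.mean_spots,
        }
        for m in measurements
        if m.stimulus not in ("NC", "PC")
    ]
    return pd.DataFrame(rows)


def read_elispot_csv(path) -> list[ElispotMeasurement]:
    """ELISpot CSV: patient, timepoint, stimulus, then one spot count per replicate row."""
    df = pd.read_csv(path)
    out = []
    for (patient, timepoint, stimulus), grp in df.groupby(
        ["patient", "timepoint", "stimulus"], sort=False
    ):
        out.append(
            ElispotMeasurement(
                patient=str(patient),
                timepoint=str(timepoint),
                stimulus=str(stimulus),
                spot_counts=tuple(int(s) for s in grp["spots"]),
            )
        )
    return out


def elispot_frame(measurements: Sequence[ElispotMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for i, s in enumerate(m.spot_counts, start=1):
            rows.append(
                {
                    "patient": m.patient,
                    "timepoint": m.timepoint,
                    "stimulus": m.stimulus,
                    "replicate": i,
                    "spots": s,
                }
            )
    return pd.DataFrame(rows)
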