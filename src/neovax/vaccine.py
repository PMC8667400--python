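"""Long-peptide vaccine design: 27-mers, dose pools, prime-boost schedule.

Each selected mutation yields one synthetic long peptide of up to 27
amino acids with the mutant residue centered (offset 14 of 27) whenever at
least 13 residues flank it on both sides; near a protein terminus the
window slides to stay inside the protein at full length, and proteins
shorter than 27 residues are used whole.  Peptides are grouped into up to
four dose pools of 3-5 peptides each (0.3 mg/peptide, adjuvanted with
0.5 mg poly-IC), filled round-robin by priority rank so high-priority
peptides spread across pools.  Vaccination follows a prime phase on days
1, 4, 8, 15 and 22 and a boost phase on days 90 and 140, with boost doses
allowed up to 15 days late.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

DEFAULT_WINDOW = 27
PRIME_DAYS = (1, 4, 8, 15, 22)
BOOST_DAYS = (90, 140)
BOOST_WINDOW_DAYS = 15
DOSE_PER_PEPTIDE_MG = 0.3
ADJUVANT_DOSE_MG = 0.5

MIN_POOL_SIZE = 3
MAX_POOL_SIZE = 5
MAX_POOLS = 4


@dataclass(frozen=True)
class ProteinContext:
    """The protein carrying a mutation: full sequence plus mutant residue site."""

    mutation_key: str
    sequence: str
    mutant_position: int  # 1-based residue index
    mutant_residue: str

    def __post_init__(self) -> None:
        if not 1 <= self.mutant_position <= len(self.sequence):
            raise ValueError(
                f"{self.mutation_key}: mutant_position {self.mutant_position} "
                f"outside protein of length {len(self.sequence)}"
            )
        if self.sequence[self.mutant_position - 1] != self.mutant_residue:
            raise ValueError(
                f"{self.mutation_key}: residue at position {self.mutant_position} "
                f"is {self.sequence[self.mutant_position - 1]}, "
                f"expected {self.mutant_residue}"
            )


@dataclass(frozen=True)
class LongPeptide:
    mutation_key: str
    sequence: str
    mutant_offset: int  # 1-based index within the peptide

    def __post_init__(self) -> None:
        if len(self.sequence) > DEFAULT_WINDOW:
            raise ValueError(f"peptide longer than {DEFAULT_WINDOW} aa")
        if not 1 <= self.mutant_offset <= len(self.sequence):
            raise ValueError("mutant_offset outside peptide")


@dataclass
class VaccinePool:
    pool_id: int  # 1-4
    peptides: list[LongPeptide] = field(default_factory=list)
    dose_per_peptide_mg: float = DOSE_PER_PEPTIDE_MG
    adjuvant_dose_mg: float = ADJUVANT_DOSE_MG


def design_long_peptide(
    context: ProteinContext, window: int = DEFAULT_WINDOW
) -> LongPeptide:
    """Cut the mutant-centered long peptide out of the protein context.

    The mutant residue sits at the center of the window (position 14 of a
    27-mer) when the protein allows; otherwise the window slides toward
    the interior so the peptide keeps full length, and a protein shorter
    than the window is returned whole.
    """
    seq = context.sequence
    n = len(seq)
    pos = context.mutant_position  # 1-based
    if n <= window:
        return LongPeptide(context.mutation_key, seq, pos)
    flank = (window - 1) // 2
    start = pos - flank  # 1-based start of ideal centered window
    start = max(1, min(start, n - window + 1))
    peptide = seq[start - 1 : start - 1 + window]
    return LongPeptide(context.mutation_key, peptide, pos - start + 1)


def partition_pools(peptides: Sequence[LongPeptide]) -> list[VaccinePool]:
    """Split a ranked peptide list into balanced dose pools.

    Pool count is ceil(n/5) clamped to [1, 4]; peptides are dealt
    round-robin in rank order, so pool sizes differ by at most one and
    every pool draws from the whole priority range.  Valid for 3-20
    peptides (a manufacturable batch); outside that range no pool layout
    satisfies the 3-5 peptides/pool rule.
    """
    n = len(peptides)
    if n < MIN_POOL_SIZE:
        raise ValueError(f"cannot pool {n} peptides: minimum pool size is {MIN_POOL_SIZE}")
    if n > MAX_POOLS * MAX_POOL_SIZE:
        raise ValueError(
            f"cannot pool {n} peptides: at most {MAX_POOLS} pools of {MAX_POOL_SIZE}"
        )
    k = min(max(math.ceil(n / MAX_POOL_SIZE), 1), MAX_POOLS)
    pools = [VaccinePool(pool_id=i + 1) for i in range(k)]
    for i, pep in enumerate(peptides):
        pools[i % k].peptides.append(pep)
    return pools


@dataclass(frozen=True)
class ScheduledDose:
    dose_number: int
    phase: str            # "prime" | "boost"
    nominal_day: int      # protocol day offset from day_zero
    nominal_date: date
    window_days: int      # allowed lateness


def schedule_vaccinations(day_zero: date) -> list[ScheduledDose]:
    """Dated prime-boost schedule anchored at ``day_zero`` (protocol day 0)."""
    doses = []
    for i, day in enumerate(PRIME_DAYS + BOOST_DAYS, start=1):
        phase = "prime" if day in PRIME_DAYS else "boost"
        doses.append(
            ScheduledDose(
                dose_number=i,
                phase=phase,
                nominal_day=day,
                nominal_date=day_zero + timedelta(days=day),
                window_days=BOOST_WINDOW_DAYS if phase == "boost" else 0,
            )
        )
    return doses


def dose_within_window(dose: ScheduledDose, administered_day: int) -> bool:
    """Whether an administration day falls inside the dose's allowed window."""
    return dose.nominal_day <= administered_day <= dose.nominal_day + dose.window_days
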