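"""Neoantigen calling and four-criterion candidate prioritization.

Binding affinities (IC50, nM) for every mutant peptide x HLA-allele pair
are predicted by external tools and consumed here as a table.  For class I,
8-11-mer mutant peptides are scored by several predictors and the decision
statistic per (peptide, allele) pair is the *median* IC50 across predictors;
for class II a single predictor scores the 15-mer.  A mutation's best class
I (class II) affinity is the minimum over all its class I (class II) pairs
of that per-pair median.

A mutation is a predicted neoantigen when its best class I *or* best class
II median IC50 is strictly below 500 nM.  When more than 30 neoantigens are
predicted, candidates are ranked by:

1. strong binding (IC50 < 150 nM) to *both* HLA class I and class II;
2. strong binding to exactly one class;
3. higher RNA-level VAF (used as the ordering key within tiers);
4. modest binding (150 < IC50 <= 500 nM) to both classes;

remaining predicted neoantigens follow, and the list is capped at 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NEOANTIGEN_IC50_NM = 500.0
STRONG_IC50_NM = 150.0
DEFAULT_CAP = 30

_CLASS_I_LENGTHS = range(8, 12)
_CLASS_II_LENGTH = 15


@dataclass(frozen=True)
class AffinityRecord:
    """One predictor's IC50 for one mutant peptide on one HLA allele."""

    mutation_key: str
    peptide: str
    allele: str       # e.g. "HLA-A*02:01" (class I) or "DRB1*15:01" (class II)
    hla_class: int    # 1 or 2
    predictor: str
    ic50: float       # nM

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be > 0 nM, got {self.ic50}")
        if self.hla_class not in (1, 2):
            raise ValueError(f"hla_class must be 1 or 2, got {self.hla_class}")
        n = len(self.peptide)
        if self.hla_class == 1 and n not in _CLASS_I_LENGTHS:
            raise ValueError(f"class I peptide must be 8-11 aa, got {n}")
        if self.hla_class == 2 and n != _CLASS_II_LENGTH:
            raise ValueError(f"class II peptide must be 15 aa, got {n}")


@dataclass
class MutationEpitopeSummary:
    """Per-mutation best class I/II binding with RNA expression and tier."""

    mutation_key: str
    best_classI_ic50: float | None
    best_classII_ic50: float | None
    rna_vaf: float
    tier: int | None = None  # 1..4, or None when not a predicted neoantigen


def median_ic50(ic50s: Sequence[float]) -> float:
    """Sample median IC50 for one peptide-allele pair across predictors."""
    if len(ic50s) == 0:
        raise ValueError("median of empty IC50 set")
    return float(np.median(ic50s))


def summarize_mutation(
    records: Iterable[AffinityRecord],
    genotype: Iterable[str],
    rna_vaf: float,
) -> MutationEpitopeSummary:
    """Aggregate one mutation's affinity records into best class I/II IC50s.

    best class I = min over class-I (peptide, allele) pairs of the per-pair
    median IC50; likewise class II.  Records for an allele not in the
    patient's genotype raise.
    """
    records = list(records)
    if not records:
        raise ValueError("no affinity records for mutation")
    keys = {r.mutation_key for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple mutations: {sorted(keys)}")
    alleles = set(genotype)
    best: dict[int, float] = {}
    pairs: dict[tuple[int, str, str], list[float]] = {}
    for r in records:
        if r.allele not in alleles:
            raise ValueError(f"allele {r.allele} not in patient genotype")
        pairs.setdefault((r.hla_class, r.peptide, r.allele), []).append(r.ic50)
    for (cls, _pep, _al), values in pairs.items():
        med = median_ic50(values)
        if cls not in best or med < best[cls]:
            best[cls] = med
    return MutationEpitopeSummary(
        mutation_key=keys.pop(),
        best_classI_ic50=best.get(1),
        best_classII_ic50=best.get(2),
        rna_vaf=rna_vaf,
    )


def is_predicted_neoantigen(
    summary: MutationEpitopeSummary,
    threshold: float = NEOANTIGEN_IC50_NM,
) -> bool:
    """True iff best class I or best class II median IC50 < threshold (strict)."""
    ci = summary.best_classI_ic50
    cii = summary.best_classII_ic50
    return (ci is not None and ci < threshold) or (cii is not None and cii < threshold)


def assign_tier(
    summary: MutationEpitopeSummary,
    threshold: float = NEOANTIGEN_IC50_NM,
    strong: float = STRONG_IC50_NM,
) -> int:
    """Priority tier for a predicted neoantigen.

    tier 1: strong (< 150 nM) on both classes; tier 2: strong on exactly
    one class; tier 3: modest (150 < IC50 <= 500) on both classes; tier 4:
    every other predicted neoantigen.  IC50 exactly 150 is neither strong
    nor modest, so a class at 150 can only contribute to tier 4.
    """
    if not is_predicted_neoantigen(summary, threshold):
        raise ValueError(f"{summary.mutation_key}: not a predicted neoantigen")
    ci = summary.best_classI_ic50
    cii = summary.best_classII_ic50
    strong_i = ci is not None and ci < strong
    strong_ii = cii is not None and cii < strong
    modest_i = ci is not None and strong < ci <= threshold
    modest_ii = cii is not None and strong < cii <= threshold
    if strong_i and strong_ii:
        return 1
    if strong_i != strong_ii:
        return 2
    if modest_i and modest_ii:
        return 3
    return 4


def _rank_key(s: MutationEpitopeSummary) -> tuple:
    ci = s.best_classI_ic50 if s.best_classI_ic50 is not None else math.inf
    return (s.tier, -s.rna_vaf, ci, s.mutation_key)


def prioritize(
    summaries: Sequence[MutationEpitopeSummary],
    cap: int = DEFAULT_CAP,
) -> list[MutationEpitopeSummary]:
    """Rank predicted neoantigens and cap the candidate list.

    Total order: tier ascending, then RNA VAF descending, then best class I
    IC50 ascending, then mutation key (determinism).  All candidates are
    retained when there are at most ``cap``; otherwise the top ``cap``.
    """
    for s in summaries:
        if s.tier is None:
            raise ValueError(f"{s.mutation_key}: tier not assigned")
    ranked = sorted(summaries, key=_rank_key)
    return ranked[:cap]


def summarize_affinity_table(
    table: pd.DataFrame,
    genotypes: dict[str, list[str]] | None = None,
    rna_vafs: dict[str, float] | None = None,
) -> list[MutationEpitopeSummary]:
    """Build per-mutation summaries from a long-format affinity table.

    Expected columns: mutation_key, peptide, hla_allele, hla_class,
    predictor, ic50_nM.  ``genotypes`` maps patient-independent mutation
    keys to allowed alleles (skipped when None); ``rna_vafs`` supplies each
    mutation's RNA VAF (default 0).
    """
    out = []
    for key, grp in table.groupby("mutation_key", sort=True):
        records = [
            AffinityRecord(
                mutation_key=str(key),
                peptide=r.peptide,
                allele=r.hla_allele,
                hla_class=int(r.hla_class),
                predictor=r.predictor,
                ic50=float(r.ic50_nM),
            )
            for r in grp.itertuples()
        ]
        alleles = (
            genotypes[str(key)] if genotypes is not None
            else {r.allele for r in records}
        )
        vaf = rna_vafs.get(str(key), 0.0) if rna_vafs else 0.0
        out.append(summarize_mutation(records, alleles, vaf))
    return out


def read_affinity_table(path: str | Path) -> pd.DataFrame:
    """Affinity TSV: mutation_key, peptide, length, hla_allele, hla_class, predictor, ic50_nM."""
    return pd.read_csv(path, sep="\t")
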