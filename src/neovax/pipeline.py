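"""End-to-end per-patient pipeline: call-sets to vaccine pools.

Thin composition layer over the analysis modules, used by the CLI and the
cohort-level summaries: consensus filtering → RNA validation → affinity
summarization → neoantigen calling and prioritization → long-peptide and
pool design.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from neovax.filtering import (
    ConsensusVariant,
    VariantCall,
    attach_rna_evidence,
    consensus_somatic_calls,
    rna_validate,
)
from neovax.prioritization import (
    MutationEpitopeSummary,
    assign_tier,
    is_predicted_neoantigen,
    prioritize,
    summarize_affinity_table,
)
from neovax.vaccine import (
    LongPeptide,
    ProteinContext,
    VaccinePool,
    design_long_peptide,
    partition_pools,
)


@dataclass
class PatientResult:
    patient: str
    consensus: list[ConsensusVariant]
    validated: list[ConsensusVariant]
    neoantigens: list[MutationEpitopeSummary]
    candidates: list[MutationEpitopeSummary]   # prioritized, capped
    peptides: list[LongPeptide]
    pools: list[VaccinePool]

    @property
    def neoantigen_fraction(self) -> float:
        """Predicted neoantigens as a fraction of all consensus mutations."""
        return len(self.neoantigens) / len(self.consensus) if self.consensus else 0.0


def run_patient(
    patient: str,
    callsets: dict[str, list[VariantCall]],
    rna_table: pd.DataFrame,
    affinity_table: pd.DataFrame,
    contexts: dict[str, ProteinContext],
    ic50_threshold: float = 500.0,
    cap: int = 30,
    min_depth: int = 20,
    min_vaf: float = 0.05,
) -> PatientResult:
    """Run the full candidate-selection pipeline for one patient."""
    consensus = consensus_somatic_calls(callsets)
    consensus = attach_rna_evidence(consensus, rna_table)
    validated = [v for v in consensus if rna_validate(v, min_depth, min_vaf)]
    rna_vafs = {v.mutation_key: float(v.rna_vaf or 0.0) for v in validated}
    usable = affinity_table[
        affinity_table["mutation_key"].isin(rna_vafs)
    ] if len(affinity_table) else affinity_table
    summaries = summarize_affinity_table(usable, rna_vafs=rna_vafs)
    neoantigens = []
    for s in summaries:
        if is_predicted_neoantigen(s, ic50_threshold):
            s.tier = assign_tier(s, ic50_threshold)
            neoantigens.append(s)
    candidates = prioritize(neoantigens, cap=cap)
    peptides = [
        design_long_peptide(contexts[s.mutation_key])
        for s in candidates
        if s.mutation_key in contexts
    ]
    # at most 20 peptides make it into a manufactured vaccine (synthesis cap)
    pools = partition_pools(peptides[:20]) if len(peptides) >= 3 else []
    return PatientResult(
        patient=patient,
        consensus=consensus,
        validated=validated,
        neoantigens=neoantigens,
        candidates=candidates,
        peptides=peptides,
        pools=pools,
    )
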