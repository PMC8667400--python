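"""Consensus somatic-variant filtering and RNA-expression validation.

Somatic SNVs are called on tumor/normal exomes by two primary callers and
a confirmatory caller; only loci reported by both primary callers *and*
confirmed by the third are retained.  Surviving variants must additionally
be expressed: tumor RNA-seq coverage >= 20x with variant allele frequency
>= 0.05 at the site (both boundaries inclusive).

Neoantigen candidates arising from RNA editing rather than DNA mutation do
not go through the DNA consensus step — they enter directly as confirmed
records flagged ``origin="RNA-editing"`` — but are subject to the same RNA
depth/VAF validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

PRIMARY_CALLERS = ("callerA", "callerB")
CONFIRMER = "confirmer"

#: (chrom, pos, ref, alt)
LocusKey = tuple[str, int, str, str]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide somatic call from one caller on one tumor/normal pair."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    caller: str = ""
    tumor_alt_reads: int = 0
    tumor_ref_reads: int = 0
    normal_alt_reads: int = 0
    normal_ref_reads: int = 0
    origin: str = "DNA"  # "DNA" | "RNA-editing"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only SNVs are supported; got {self.ref}>{self.alt} at "
                f"{self.chrom}:{self.pos} (indels are rejected)"
            )
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        for name in ("tumor_alt_reads", "tumor_ref_reads",
                     "normal_alt_reads", "normal_ref_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def locus(self) -> LocusKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """A consensus somatic SNV with DNA support and RNA validation data."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    dna_vaf: float = 0.0
    caller_support: frozenset[str] = field(default_factory=frozenset)
    rna_depth: int | None = None
    rna_vaf: float | None = None
    origin: str = "DNA"

    def __post_init__(self) -> None:
        if not self.caller_support:
            raise ValueError("caller_support may not be empty")
        if not 0.0 <= self.dna_vaf <= 1.0:
            raise ValueError(f"dna_vaf out of [0,1]: {self.dna_vaf}")
        if self.rna_vaf is not None and not 0.0 <= self.rna_vaf <= 1.0:
            raise ValueError(f"rna_vaf out of [0,1]: {self.rna_vaf}")

    @property
    def locus(self) -> LocusKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def mutation_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def compute_vaf(alt_reads: int, ref_reads: int) -> float:
    """Variant allele frequency: alt / (alt + ref).

    Raises
    ------
    ValueError
        If the site has zero total reads (VAF undefined).
    """
    total = alt_reads + ref_reads
    if total <= 0:
        raise ValueError("VAF undefined at zero total reads")
    return alt_reads / total


def consensus_somatic_calls(
    callsets: Mapping[str, Sequence[VariantCall]],
) -> list[ConsensusVariant]:
    """Intersect per-caller call-sets into confirmed consensus variants.

    A locus is retained iff it appears in both primary call-sets and in the
    confirmer's set.  Read counts (hence DNA VAF) are taken from the first
    primary caller's record.  Output is sorted by (chrom, pos, ref, alt).

    Parameters
    ----------
    callsets
        Mapping with exactly the keys ``callerA``, ``callerB`` and
        ``confirmer``, each a list of :class:`VariantCall`.
    """
    required = set(PRIMARY_CALLERS) | {CONFIRMER}
    missing = required - set(callsets)
    if missing:
        raise ValueError(f"missing call-set(s): {sorted(missing)}")

    by_caller: dict[str, dict[LocusKey, VariantCall]] = {}
    for caller in required:
        index: dict[LocusKey, VariantCall] = {}
        for call in callsets[caller]:
            if call.locus in index:
                raise ValueError(
                    f"duplicate locus {call.locus} in call-set {caller!r}"
                )
            index[call.locus] = call
        by_caller[caller] = index

    shared = (
        set(by_caller[PRIMARY_CALLERS[0]])
        & set(by_caller[PRIMARY_CALLERS[1]])
        & set(by_caller[CONFIRMER])
    )

    out: list[ConsensusVariant] = []
    for locus in sorted(shared):
        primary = by_caller[PRIMARY_CALLERS[0]][locus]
        out.append(
            ConsensusVariant(
                chrom=primary.chrom,
                pos=primary.pos,
                ref=primary.ref,
                alt=primary.alt,
                gene=primary.gene,
                protein_change=primary.protein_change,
                dna_vaf=compute_vaf(primary.tumor_alt_reads, primary.tumor_ref_reads)
                if primary.tumor_alt_reads + primary.tumor_ref_reads > 0
                else 0.0,
                caller_support=frozenset(required),
                origin="DNA",
            )
        )
    return out


def rna_editing_candidates(calls: Iterable[VariantCall]) -> list[ConsensusVariant]:
    """Wrap RNA-editing-derived candidates as confirmed variants.

    These bypass the DNA consensus (there is no DNA mutation to intersect)
    and carry ``caller_support={confirmer}``; they still face the same RNA
    depth/VAF validation as DNA variants.
    """
    out = []
    for call in sorted(calls, key=lambda c: c.locus):
        if call.origin != "RNA-editing":
            raise ValueError(f"{call.locus}: origin must be 'RNA-editing'")
        out.append(
            ConsensusVariant(
                chrom=call.chrom,
                pos=call.pos,
                ref=call.ref,
                alt=call.alt,
                gene=call.gene,
                protein_change=call.protein_change,
                dna_vaf=0.0,
                caller_support=frozenset({CONFIRMER}),
                origin="RNA-editing",
            )
        )
    return out


def rna_validate(
    variant: ConsensusVariant,
    min_depth: int = 20,
    min_vaf: float = 0.05,
) -> bool:
    """Expression check: RNA depth >= ``min_depth`` and RNA VAF >= ``min_vaf``.

    Both boundaries are inclusive.  Variants with missing RNA data fail.
    """
    if variant.rna_depth is None or variant.rna_vaf is None:
        return False
    return variant.rna_depth >= min_depth and variant.rna_vaf >= min_vaf


def attach_rna_evidence(
    variants: Sequence[ConsensusVariant],
    rna_table: pd.DataFrame,
) -> list[ConsensusVariant]:
    """Fill ``rna_depth`` / ``rna_vaf`` from an RNA validation table.

    The table needs columns chrom, pos, ref, alt, rna_depth, rna_vaf; loci
    absent from it keep missing RNA evidence (and will fail validation).
    """
    index = {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): (int(r.rna_depth), float(r.rna_vaf))
        for r in rna_table.itertuples()
    }
    out = []
    for v in variants:
        depth_vaf = index.get(v.locus)
        if depth_vaf is None:
            out.append(v)
        else:
            out.append(
                ConsensusVariant(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    gene=v.gene, protein_change=v.protein_change,
                    dna_vaf=v.dna_vaf, caller_support=v.caller_support,
                    rna_depth=depth_vaf[0], rna_vaf=depth_vaf[1],
                    origin=v.origin,
                )
            )
    return out


# ---------------------------------------------------------------------------
# File I/O


def read_caller_vcf(path: str | Path, caller: str) -> list[VariantCall]:
    """Read one caller's somatic VCF (TUMOR/NORMAL sample columns, AD format).

    Multi-allelic records are split into one call per alternate allele;
    non-SNV alleles raise, matching the SNV-only scope of the pipeline.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = str(rec.info.get("GENE", "")) if "GENE" in rec.info else ""
            pchange = str(rec.info.get("PCHANGE", "")) if "PCHANGE" in rec.info else ""
            for i, alt in enumerate(rec.alts or ()):
                tumor = rec.samples["TUMOR"]
                normal = rec.samples["NORMAL"]
                t_ad = tumor.get("AD") or (0, 0)
                n_ad = normal.get("AD") or (0, 0)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        protein_change=pchange,
                        caller=caller,
                        tumor_alt_reads=int(t_ad[i + 1]) if len(t_ad) > i + 1 else 0,
                        tumor_ref_reads=int(t_ad[0]),
                        normal_alt_reads=int(n_ad[i + 1]) if len(n_ad) > i + 1 else 0,
                        normal_ref_reads=int(n_ad[0]),
                    )
                )
    return calls


def write_caller_vcf(path: str | Path, calls: Sequence[VariantCall]) -> None:
    """Write a caller's calls as an uncompressed VCF with TUMOR/NORMAL columns."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">')
    for chrom in sorted({c.chrom for c in calls}, key=_chrom_sort_key):
        header.contigs.add(chrom)
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.ref, c.alt)):
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos,
                alleles=(call.ref, call.alt),
            )
            if call.gene:
                rec.info["GENE"] = call.gene
            if call.protein_change:
                rec.info["PCHANGE"] = call.protein_change
            rec.samples["TUMOR"]["AD"] = (call.tumor_ref_reads, call.tumor_alt_reads)
            rec.samples["NORMAL"]["AD"] = (call.normal_ref_reads, call.normal_alt_reads)
            vcf.write(rec)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    name = chrom.removeprefix("chr")
    return (int(name), "") if name.isdigit() else (10**6, name)


def read_rna_table(path: str | Path) -> pd.DataFrame:
    """RNA validation TSV: chrom, pos, ref, alt, rna_depth, rna_vaf."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
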