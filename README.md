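# neovax

Analysis toolkit for personalized neoantigen-vaccine studies in resected
hepatocellular carcinoma — from tumor/normal somatic calls to vaccine
design and the three response readouts: ELISpot immunogenicity, ctDNA
tumor-burden tracking, and recurrence-free survival.

Personalized cancer vaccines target the mutant peptides (neoantigens) of a
patient's own tumor. Turning sequencing into a vaccine, and then judging
whether the vaccine worked, takes a chain of small, well-defined decisions
that are easy to get subtly wrong; `neovax` implements that chain as a
tested library:

- **Somatic filtering** — consensus of two primary callers confirmed by a
  third (a locus survives iff in A ∩ B ∩ C), then RNA-expression
  validation: tumor RNA-seq depth ≥ 20× and VAF ≥ 0.05.
- **Neoantigen prioritization** — consumes externally predicted MHC
  binding tables (it never computes IC50s). Per (peptide, allele) pair the
  median IC50 across predictors; per mutation the minimum over pairs; a
  predicted neoantigen iff best class I *or* class II median IC50
  < 500 nM. Ranking: strong (< 150 nM) on both classes → strong on one →
  (within tiers) higher RNA VAF → modest (150–500 nM) on both; capped
  at 30 candidates.
- **Vaccine design** — 27-aa long peptides with the mutant residue
  centered, 1–4 dose pools of 3–5 peptides (0.3 mg/peptide + 0.5 mg
  poly-IC), prime doses on days 1/4/8/15/22 and boosts on days 90/140.
- **ctDNA monitoring** — per-timepoint positive rates and mean VAF over a
  personal mutation panel, split into vaccine-targeted vs other somatic
  sites; trajectory classification into concordant / divergent /
  untrackable, where divergence (targeted sites decoupling from the rest)
  is the signature of vaccine-driven clonal selection.
- **Immune response** — ELISpot positivity (≥ 2× negative control and
  ≥ +10 spots), patient-level responsiveness (positive post-boost), and
  response durability summaries.
- **Clinical outcomes** — Kaplan–Meier RFS medians, log-rank group
  comparison, and 1:2 propensity-score matching of untreated controls
  within a 0.2-logit-SD caliper.
- **Synthetic cohorts** — a generator producing complete, bit-reproducible
  input bundles (per-caller VCFs, RNA/affinity/plasma TSVs, FASTA contexts,
  ELISpot and outcome CSVs) with clone-structured plasma dynamics, so the
  whole pipeline is testable without access-controlled patient data.

## Worked example

Simulate a small cohort and run candidate selection for one patient:

```bash
neovax simulate --out-dir demo --seed 1 --n-patients 2
neovax filter --caller-a demo/S01/callerA.vcf --caller-b demo/S01/callerB.vcf \
    --confirmer demo/S01/confirmer.vcf --rna demo/S01/rna_validation.tsv \
    --out filtered.tsv
neovax prioritize --affinities demo/S01/affinities.tsv --rna filtered.tsv \
    --out ranked.tsv
neovax design --fasta demo/S01/proteins.fasta --sidecar demo/S01/proteins.tsv \
    --ranked ranked.tsv --out pools.tsv --day-zero 2019-01-01
```

which prints:

```
80 consensus variants, 49 RNA-validated → filtered.tsv
25 predicted neoantigens, 25 selected → ranked.tsv
25 peptides in 4 pools → pools.tsv
dose 1 (prime): day 1 = 2019-01-02
...
dose 7 (boost): day 140 = 2019-05-21
```

Read: of patient S01's 80 consensus somatic SNVs, 49 are expressed in
tumor RNA; 25 of those bind an HLA allele under 500 nM and all fit under
the 30-candidate cap; the top 20 become 27-mer peptides in four dose pools
(the synthesis batch limit), injected on the printed prime–boost dates.
The same operations are available as a library
(`from neovax import consensus_somatic_calls, prioritize, ...`), and
`neovax monitor`, `neovax elispot` and `neovax outcomes` cover the
post-vaccination readouts.

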