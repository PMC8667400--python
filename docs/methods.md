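# Methods

`neovax` implements the desk-side analysis around a personalized long-peptide
neoantigen vaccine given after radical surgery for hepatocellular carcinoma
(HCC): candidate selection from tumor/normal sequencing, vaccine design,
and the three response readouts (ELISpot, ctDNA, recurrence-free survival).
This note records the models, the defaults and why, and what the synthetic
cohort does and does not emulate.

## Candidate selection

**Consensus filtering.** Somatic SNVs enter as three per-caller call-sets
(two primary callers plus a confirmatory caller). A locus is retained iff it
is present in both primary sets *and* in the confirmer's set — plain
three-way set intersection on (chrom, pos, ref, alt). Multi-allelic records
are split before intersection; indels are rejected (the vaccine targets are
missense products of point mutations). Candidates derived from RNA editing
have no DNA mutation to intersect; they bypass consensus with
`caller_support={confirmer}` but face the same expression filter.

**RNA validation.** A variant is expressed iff tumor RNA-seq shows depth
≥ 20× and VAF ≥ 0.05 at the site, both boundaries inclusive. Variants
missing RNA evidence fail closed.

**Neoantigen calling.** Binding affinities are *inputs*: a long table of
IC50 (nM) per (mutation, peptide, HLA allele, predictor). For class I,
8–11-mer mutant peptides are scored by five predictors and the decision
statistic per (peptide, allele) pair is the median IC50 across predictors;
class II uses one predictor on the 15-mer (a single value is its own
median). A mutation's best class I (II) affinity is the minimum of these
pair medians, and the mutation is a predicted neoantigen iff either best
value is strictly below 500 nM. Where several peptide lengths exist for one
mutation we take the minimum over all pairs; the alternative (median over
lengths) has no support in standard epitope-selection practice, which ranks
by the best binder.

**Prioritization.** When more than 30 neoantigens are predicted the list is
capped at 30 under a total order built from four criteria: (1) strong
binding (IC50 < 150 nM) on both HLA classes; (2) strong on exactly one
class; (3) higher RNA VAF; (4) modest binding (150 < IC50 ≤ 500) on both
classes. Criteria 1, 2 and 4 define affinity categories while 3 is
comparative, so 3 is read as the ordering key *within* tiers (and the
global tie-break): tier ascending, then RNA VAF descending, then best class
I IC50 ascending, then locus key for determinism. Mutations modest on only
one class fall into tier 4 (the criteria list "modest on both" explicitly
and are silent on "modest on one"). IC50 exactly 150 is neither strong
(< 150) nor modest (> 150): a class sitting on the boundary can only
contribute to tier 4. These readings are this package's design choices,
documented here, and exposed via `--ic50-threshold` / `--strong-threshold`.

## Vaccine design

Each selected mutation yields one ≤ 27-aa long peptide. The mutant residue
is centered (offset 14 of 27) whenever ≥ 13 residues flank both sides —
standard synthetic-long-peptide practice; near a terminus the window slides
inward to keep full length, and proteins shorter than 27 aa are used whole.
With multiple transcripts, the canonical (longest) protein is the context.

Peptides are partitioned into `clamp(ceil(n/5), 1, 4)` dose pools of 3–5
peptides (0.3 mg each, adjuvanted with 0.5 mg poly-IC), dealt round-robin in
priority order so pool sizes differ by at most one and every pool spans the
priority range; the grouping rule itself is a package choice since only the
pool-count and pool-size constraints are fixed. Valid for 3–20 peptides — a
manufacturable batch — with clear errors outside that range. The schedule
is prime doses on protocol days 1, 4, 8, 15, 22 and boost doses on days 90
and 140, boosts allowed up to 15 days late.

## ctDNA monitoring

Each patient's plasma samples are sequenced over their personal mutation
panel, split into vaccine-targeted neoantigen sites and other somatic
sites. Defaults, all exposed as flags:

- **Detection**: ≥ 2 mutant reads at a site. Plasma positivity has no
  community-standard rule; two non-reference reads is a conventional floor
  against sequencing error.
- **Mean VAF**: undetected sites count as VAF 0 (`zero` policy) so means
  stay comparable across timepoints with different detection; an `exclude`
  policy (detected sites only) is provided. `zero` ≤ `exclude` always.
- **Positive rate**: detected sites / all panel sites in the subset (the
  all-sites denominator; sites-with-coverage is the other reading).

Trajectories are classified from the two mean-VAF series: `untrackable`
when fewer than 3 timepoints have any detected site; otherwise `concordant`
when the Spearman rank correlation between the targeted and other series is
≥ 0.7, else `divergent`. Divergence — the targeted series decoupling from
the rest of the panel — is the readout expected when vaccination
preferentially clears neoantigen-bearing clones. Degenerate flat series
have no rank ordering: both flat → concordant, exactly one flat →
divergent. The 0.7 cut is a conventional "strong correlation" default.

## ELISpot

A stimulus well set is positive against its matched negative control iff
mean spots ≥ 2× the NC mean **and** exceed it by ≥ 10 spots — a standard
empirical dual-margin criterion (the assay has no single canonical rule);
both margins are configurable. Under a Poisson null (stimulus rate = NC
rate = 5, 3 replicates) this fires < 5% of the time, and detects a 3×+20
effect > 90% of the time (both verified by simulation in the test suite).
A patient has responsive neoantigens iff ≥ 1 pool or peptide is positive at
a post-boost timepoint; pre-existing reactivity that decays before the
boost does not qualify, and prime-only patients are a separate group, not
scorable. Durability is summarized as mean spots per pool per follow-up
timepoint; no decay model is fitted.

## Survival and matching

RFS runs from surgery or first vaccination to relapse/censoring; a month is
30.4375 days (365.25/12 — no convention is universal, this one is stated).
The KM median is the smallest time with survivor estimate ≤ 0.5, read from
the lifelines product-limit curve with a 1e-9 boundary tolerance so exact
0.5 plateaus are not missed to float rounding; group comparison is the
standard log-rank chi-square.

Propensity matching fits a logistic model of treatment on baseline
covariates (constant columns dropped with a warning), then matches each
treated patient greedily to its 2 nearest unused controls on the logit
scale within a caliper of 0.2 × SD of the logit — the standard reading of
"caliper of 0.2"; a raw-probability caliper is available by flag. Greedy
order is a seeded random permutation; optimal matching is out of scope.
Treated patients with no in-caliper control left are reported unmatched.

## Synthetic cohort

The generator produces complete input bundles with the statistical
structure the pipeline assumes. Defaults (all in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| mutation count | NB(mean 78, size 3) clamped to [7, 148] | matches the observed per-patient mean and range without asserting an unstated distribution |
| expressed fraction | 0.60 | with the IC50 mixture below, yields ≈ 33.5% of all mutations as predicted neoantigens |
| class I IC50 mixture | strong/modest/non = 0.20/0.30/0.50; log-normal centers 50/280/4000 nM | straddles the 150/500 nM cut points on the log scale |
| class II strong prob. | 0.12 | class II binders are rarer with a single predictor |
| clones | 3, Dirichlet(1.5) CCFs × 0.95 | CCFs sum to ≤ 1; sorted so clone 1 is dominant |
| plasma tumor fraction | 0.12 preop → 0.015 nadir → 0.10 at relapse | surgical debulking followed by regrowth; drives the shared burden signal |
| plasma depth | 1000× mean (Poisson) | typical targeted ctDNA panel scale; the source assays' depth is not public, so this is a package default, not a claimed value |
| vaccine kill rate | 0 (null) | per-30-day multiplicative CCF decay of clones carrying ≥ 1 targeted mutation |
| ELISpot | Poisson; NC 5, responsive 60, PC 150; 3 wells | spot-count scale of typical IFN-γ assays |
| recurrence | exponential; medians 19.3 / 6.7 / 4.8 months per group; censor at 32 months | group-dependent hazards at the reported median scale |

Sites are diploid and copy-neutral: expected plasma VAF is
`tumor_fraction(t) × CCF_clone(t) / 2`, with Poisson total reads and
binomial mutant reads. Vaccine-targeted mutations are placed in the leading
clones and other mutations in the remaining clones, so preferential killing
produces the clone-structured divergence the classifier looks for; with
`vaccine_kill_rate = 0` the two series share the tumor-fraction signal and
classify concordant. Primary caller call-sets carry ~10% private false
positives that consensus must remove. Identical configs (same seed) give
bit-identical bundles.

**What it does not emulate** — and hence what passing tests do not show
about real data: read-level error and GC/coverage structure (no FASTQ/BAM),
copy-number variation and its effect on VAF, subclonal phylogenies beyond a
flat clone mixture, cfDNA fragment-length signal, HLA typing error,
predictor disagreement structure beyond log-normal noise, and non-Poisson
ELISpot overdispersion. Tests on this cohort validate the *logic and
calibration* of the pipeline, not its field performance.

## Numerical choices and edge cases

- VAF at zero total reads is an error, not 0; percent decline from a zero
  baseline is an error (the statistic is undefined).
- Medians of even-count IC50 sets are the mean of the central pair.
- `prioritize` is idempotent and permutation-invariant; ties broken by
  locus key.
- Degenerate covariates in matching are dropped, not imputed.
- Problem sizes in the acceptance script (10-patient pipeline cohort,
  100 patients per ctDNA condition, 1,000 ELISpot replicates, 500 log-rank
  simulations at 200/arm, n = 300 matching cohort) were chosen to bound
  Monte-Carlo error on each reported rate below ~1–3 percentage points.

## Known limitations

- The consensus rule assumes exactly two primary callers plus one
  confirmer; other caller topologies need the general intersection oracle.
- Pattern classification needs ≥ 3 usable timepoints and treats rank
  correlation as the whole story; amplitude-only divergence with preserved
  ordering is classified concordant.
- The propensity model is a main-effects logistic fit; no interactions or
  splines.
- Peptide manufacturability (hydrophobicity, cysteine content) is not
  scored; a selected candidate may be unsynthesizable in practice.
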