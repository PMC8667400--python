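"""Synthetic patient-cohort generator.

The study's sequencing and clinical data are controlled-access, so this
module generates complete synthetic cohorts with the statistical structure
the downstream analysis assumes:

- per-patient somatic SNV counts from a clamped negative binomial
  (mean ~78, range 7-148), emitted as three per-caller call-sets whose
  three-way intersection recovers the true mutation set;
- RNA validation outcomes such that a configurable fraction of mutations
  is expressed, and log-scale IC50 mixtures (strong / modest / non-binder)
  straddling the 150 / 500 nM cut points so that roughly a third of all
  mutations end up predicted neoantigens;
- a clone structure per patient (Dirichlet cancer-cell fractions, summing
  to <= 1) with vaccine-targeted mutations concentrated in the leading
  clones, plasma VAF time courses following
  ``expected VAF = tumor_fraction(t) x CCF_clone(t) / 2`` with binomial
  read sampling at a configurable mean depth, and an optional
  multiplicative per-30-day CCF decay (``vaccine_kill_rate``) applied only
  to clones carrying vaccine-targeted mutations;
- Poisson ELISpot replicate counts with baseline and responsive means;
- exponential per-group recurrence times with administrative censoring.

Sites are diploid and copy-neutral throughout (hence the /2); read-level
artifacts and sequencing-error models beyond binomial sampling are out of
scope.  Identical configs (same seed) produce bit-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from neovax.ctdna import PlasmaObservation
from neovax.elispot import ElispotMeasurement
from neovax.filtering import PRIMARY_CALLERS, CONFIRMER, VariantCall
from neovax.outcomes import DAYS_PER_MONTH, PatientOutcome
from neovax.vaccine import ProteinContext

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

CLASS_I_ALLELES = [
    "HLA-A*02:01", "HLA-A*11:01", "HLA-A*24:02", "HLA-A*33:03",
    "HLA-B*40:01", "HLA-B*46:01", "HLA-B*58:01", "HLA-B*15:01",
    "HLA-C*01:02", "HLA-C*07:02", "HLA-C*08:01", "HLA-C*03:04",
]
CLASS_II_ALLELES = ["DRB1*09:01", "DRB1*15:01", "DRB1*12:02", "DRB1*08:03"]
CLASS_I_PREDICTORS = ["NetMHCpan", "NetMHC", "NetMHCcons", "PickPocket", "MHCflurry"]
CLASS_II_PREDICTOR = "NetMHCpanII"


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class MutationCountLaw:
    """Clamped negative binomial for per-patient somatic SNV counts."""

    mean: float = 78.0
    dispersion: float = 3.0       # NB size parameter; larger = closer to Poisson
    clamp_low: int = 7
    clamp_high: int = 148


@dataclass
class IC50Law:
    """Log-normal mixture of binding categories for class I medians.

    Weights (strong, modest, non-binder) place peptide-MHC affinities on
    either side of the 150 and 500 nM decision boundaries; predictors see
    the category value under multiplicative log-normal noise.
    """

    weights: tuple[float, float, float] = (0.20, 0.30, 0.50)
    strong_log_mean: float = math.log(50.0)
    modest_log_mean: float = math.log(280.0)
    nonbinder_log_mean: float = math.log(4000.0)
    log_sd: float = 0.35
    predictor_log_sd: float = 0.25
    classII_strong_prob: float = 0.12
    classII_strong_log_mean: float = math.log(80.0)
    classII_weak_log_mean: float = math.log(3000.0)


@dataclass
class ElispotLaw:
    """Poisson spot-count rates per well class."""

    baseline_mean: float = 5.0
    responsive_mean: float = 60.0
    pc_mean: float = 150.0
    replicates: int = 3


@dataclass
class SimulationConfig:
    """All tunables of the synthetic cohort; identical configs are reproducible."""

    n_patients: int = 10
    mutation_count_law: MutationCountLaw = field(default_factory=MutationCountLaw)
    expressed_fraction: float = 0.60
    neoantigen_fraction_target: float = 0.335
    ic50_law: IC50Law = field(default_factory=IC50Law)
    n_clones: int = 3
    clone_ccf_concentration: float = 1.5
    ccf_total: float = 0.95
    #: (day offset from first vaccination, plasma tumor fraction)
    tumor_fraction_curve: tuple[tuple[int, float], ...] = (
        (-30, 0.12), (0, 0.05), (30, 0.015), (90, 0.02), (150, 0.045), (240, 0.10),
    )
    vaccine_kill_rate: float = 0.0   # per-30-day CCF decay of targeted clones
    plasma_depth: float = 1000.0     # mean total reads per site per sample
    elispot_law: ElispotLaw = field(default_factory=ElispotLaw)
    responsive_fraction: float = 0.5
    #: exponential recurrence hazards per month, per response group
    recurrence_hazard: dict = field(
        default_factory=lambda: {
            "responsive": math.log(2) / 19.3,
            "non-responsive": math.log(2) / 6.7,
            "matched-control": math.log(2) / 4.8,
        }
    )
    censor_horizon_months: float = 32.0
    n_control_pool: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        law = self.mutation_count_law
        if law.clamp_low < 1 or law.clamp_high < law.clamp_low:
            raise ValueError("mutation_count_law clamp range invalid (low >= 1)")
        if law.mean <= 0 or law.dispersion <= 0:
            raise ValueError("mutation_count_law mean/dispersion must be > 0")
        for name in ("expressed_fraction", "neoantigen_fraction_target",
                     "responsive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.ic50_law.weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.ic50_law.weights
        ):
            raise ValueError("ic50_law weights must be a probability vector")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0.0 < self.ccf_total <= 1.0:
            raise ValueError("ccf_total must be in (0, 1]")
        if self.clone_ccf_concentration <= 0:
            raise ValueError("clone_ccf_concentration must be > 0")
        for day, tf in self.tumor_fraction_curve:
            if not 0.0 <= tf <= 1.0:
                raise ValueError(f"tumor_fraction_curve value {tf} outside [0, 1]")
        if not 0.0 <= self.vaccine_kill_rate < 1.0:
            raise ValueError("vaccine_kill_rate must be in [0, 1)")
        if self.plasma_depth <= 0:
            raise ValueError("plasma_depth must be > 0")
        if self.elispot_law.replicates < 1:
            raise ValueError("elispot_law replicates must be >= 1")
        for g, h in self.recurrence_hazard.items():
            if h <= 0:
                raise ValueError(f"recurrence_hazard[{g!r}] must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tumor_fraction_curve"] = [list(p) for p in self.tumor_fraction_curve]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["mutation_count_law"] = MutationCountLaw(**d["mutation_count_law"])
        ic = d["ic50_law"]
        ic["weights"] = tuple(ic["weights"])
        d["ic50_law"] = IC50Law(**ic)
        d["elispot_law"] = ElispotLaw(**d["elispot_law"])
        d["tumor_fraction_curve"] = tuple(tuple(p) for p in d["tumor_fraction_curve"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Bundle container


@dataclass
class PatientData:
    patient: str
    callsets: dict[str, list[VariantCall]]
    rna_table: pd.DataFrame
    hla_classI: list[str]
    hla_classII: list[str]
    affinity_table: pd.DataFrame           # only expressed mutations are scored
    contexts: list[ProteinContext]
    mutation_keys: list[str]               # the true consensus mutation set
    expressed_keys: list[str]
    neoantigen_keys: list[str]
    target_keys: list[str]                 # vaccine-targeted mutations
    clone_ccf: np.ndarray                  # base CCF per clone
    site_to_clone: dict[str, int]
    plasma: list[PlasmaObservation]
    elispot: list[ElispotMeasurement]
    responsive: bool


@dataclass
class CohortBundle:
    config: SimulationConfig
    patients: list[PatientData]
    outcomes: list[PatientOutcome]         # enrolled patients + matched-control pool

    def patient(self, name: str) -> PatientData:
        for p in self.patients:
            if p.patient == name:
                return p
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Generation


def _window(seq: str, pos: int, k: int) -> tuple[str, int]:
    """k-mer of ``seq`` containing 1-based ``pos``, centered when feasible."""
    n = len(seq)
    if n <= k:
        return seq, pos
    start = max(1, min(pos - (k - 1) // 2, n - k + 1))
    return seq[start - 1 : start - 1 + k], pos - start + 1


def _draw_mutation_count(rng: np.random.Generator, law: MutationCountLaw) -> int:
    p = law.dispersion / (law.dispersion + law.mean)
    n = int(rng.negative_binomial(law.dispersion, p))
    return int(np.clip(n, law.clamp_low, law.clamp_high))


def _make_sites(rng: np.random.Generator, n: int) -> list[dict]:
    sites = []
    seen = set()
    while len(sites) < n:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(10_000, 50_000_000))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        sites.append(
            {
                "chrom": chrom, "pos": pos, "ref": str(ref), "alt": str(alt),
                "gene": f"GENE{rng.integers(1, 20000):05d}",
                "key": f"{chrom}:{pos}:{ref}>{alt}",
            }
        )
    return sites


def _make_callsets(
    rng: np.random.Generator, sites: list[dict]
) -> dict[str, list[VariantCall]]:
    """Three call-sets whose (A ∩ B) ∩ confirmer equals the true site set.

    Each primary caller additionally reports private false positives (about
    10% extra), which the consensus rule must remove.
    """

    def call(site: dict, caller: str) -> VariantCall:
        depth = max(int(rng.poisson(120)), 30)
        vaf = float(rng.uniform(0.05, 0.5))
        alt = int(rng.binomial(depth, vaf))
        return VariantCall(
            chrom=site["chrom"], pos=site["pos"], ref=site["ref"], alt=site["alt"],
            gene=site["gene"], protein_change=site.get("protein_change", ""),
            caller=caller,
            tumor_alt_reads=alt, tumor_ref_reads=depth - alt,
            normal_alt_reads=0, normal_ref_reads=max(int(rng.poisson(100)), 20),
        )

    n_extra = max(1, int(0.1 * len(sites)))
    callsets: dict[str, list[VariantCall]] = {}
    for caller in PRIMARY_CALLERS:
        extras = _make_sites(rng, n_extra)
        callsets[caller] = [call(s, caller) for s in sites + extras]
    callsets[CONFIRMER] = [call(s, CONFIRMER) for s in sites]
    return callsets


def _ic50_tables(
    rng: np.random.Generator,
    sites: list[dict],
    expressed: list[bool],
    hla_I: list[str],
    hla_II: list[str],
    law: IC50Law,
    contexts: dict[str, tuple[str, int]],
) -> tuple[pd.DataFrame, list[str]]:
    """Affinity table for expressed mutations; returns table + neoantigen keys."""
    rows = []
    neo_keys = []
    for site, expr in zip(sites, expressed):
        if not expr:
            continue
        key = site["key"]
        protein, mpos = contexts[key]
        category = rng.choice(3, p=law.weights)
        log_center = (
            law.strong_log_mean, law.modest_log_mean, law.nonbinder_log_mean
        )[category]
        pair_alleles = rng.choice(hla_I, size=2, replace=False)
        classI_pair_medians = []
        for length in (9, 10):
            pep, _ = _window(protein, mpos, length)
            for allele in pair_alleles:
                pair_log = log_center + rng.normal(0, law.log_sd)
                preds = np.exp(pair_log + rng.normal(0, law.predictor_log_sd, size=5))
                if category == 1:
                    # keep modest binders inside (150, 500]
                    preds = np.clip(preds, 151.0, 500.0)
                for predictor, ic50 in zip(CLASS_I_PREDICTORS, preds):
                    rows.append(
                        {
                            "mutation_key": key, "peptide": pep, "length": length,
                            "hla_allele": str(allele), "hla_class": 1,
                            "predictor": predictor, "ic50_nM": float(ic50),
                        }
                    )
                classI_pair_medians.append(float(np.median(preds)))
        pep2, _ = _window(protein, mpos, 15)
        strong_II = rng.random() < law.classII_strong_prob
        log_c2 = law.classII_strong_log_mean if strong_II else law.classII_weak_log_mean
        ic50_2 = float(np.exp(log_c2 + rng.normal(0, law.log_sd)))
        rows.append(
            {
                "mutation_key": key, "peptide": pep2, "length": 15,
                "hla_allele": str(rng.choice(hla_II)), "hla_class": 2,
                "predictor": CLASS_II_PREDICTOR, "ic50_nM": ic50_2,
            }
        )
        if min(classI_pair_medians) < 500.0 or ic50_2 < 500.0:
            neo_keys.append(key)
    table = pd.DataFrame(
        rows,
        columns=["mutation_key", "peptide", "length", "hla_allele",
                 "hla_class", "predictor", "ic50_nM"],
    )
    return table, neo_keys


def simulate_plasma_series(
    clone_ccf_curves: np.ndarray,
    site_to_clone: dict[str, int],
    tumor_fraction_curve: Sequence[tuple[int, float]],
    plasma_depth: float,
    rng: np.random.Generator,
    patient: str = "P",
    target_sites: frozenset[str] | set[str] = frozenset(),
) -> list[PlasmaObservation]:
    """Binomial plasma read counts over a mutation panel and timepoints.

    ``clone_ccf_curves`` has shape (n_timepoints, n_clones) giving each
    clone's cancer-cell fraction at each timepoint; the expected VAF of a
    site in clone c at time t is ``tumor_fraction(t) x CCF_c(t) / 2``
    (diploid, copy-neutral).  Total reads per site are Poisson around
    ``plasma_depth``; mutant reads are binomial at the expected VAF.
    """
    curves = np.asarray(clone_ccf_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] != len(tumor_fraction_curve):
        raise ValueError("clone_ccf_curves must be (n_timepoints, n_clones)")
    if np.any((curves < 0) | (curves > 1)):
        raise ValueError("CCF values must lie in [0, 1]")
    if plasma_depth <= 0:
        raise ValueError("plasma_depth must be > 0")
    n_clones = curves.shape[1]
    for site, clone in site_to_clone.items():
        if not 0 <= clone < n_clones:
            raise ValueError(f"site {site} mapped to unknown clone {clone}")
    obs = []
    for t, (day, tf) in enumerate(tumor_fraction_curve):
        for site, clone in sorted(site_to_clone.items()):
            expected_vaf = tf * curves[t, clone] / 2.0
            total = int(rng.poisson(plasma_depth))
            alt = int(rng.binomial(total, min(expected_vaf, 1.0))) if total else 0
            obs.append(
                PlasmaObservation(
                    patient=patient, day=int(day), site=site,
                    alt_reads=alt, total_reads=total,
                    is_target=site in target_sites,
                )
            )
    return obs


def clone_ccf_curves(
    base_ccf: np.ndarray,
    days: Sequence[int],
    kill_rate: float,
    targeted_clones: set[int],
) -> np.ndarray:
    """Per-clone CCF over time: targeted clones decay (1-kill)^(t/30) for t > 0."""
    base = np.asarray(base_ccf, dtype=float)
    out = np.tile(base, (len(days), 1))
    if kill_rate > 0:
        for t, day in enumerate(days):
            if day > 0:
                decay = (1.0 - kill_rate) ** (day / 30.0)
                for c in targeted_clones:
                    out[t, c] = base[c] * decay
    return out


def _simulate_elispot(
    rng: np.random.Generator,
    patient: str,
    n_pools: int,
    responsive: bool,
    law: ElispotLaw,
) -> list[ElispotMeasurement]:
    from neovax.elispot import TIMEPOINTS

    def wells(mean: float) -> tuple[int, ...]:
        return tuple(int(x) for x in rng.poisson(mean, size=law.replicates))

    out = []
    for tp in TIMEPOINTS:
        out.append(ElispotMeasurement(patient, tp, "NC", wells(law.baseline_mean)))
        out.append(ElispotMeasurement(patient, tp, "PC", wells(law.pc_mean)))
        post = tp in ("post-boost", "follow-up")
        for pool in range(1, n_pools + 1):
            mean = law.responsive_mean if (responsive and post) else law.baseline_mean
            out.append(ElispotMeasurement(patient, tp, f"pool{pool}", wells(mean)))
    return out


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort bundle from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = [d for d, _ in config.tumor_fraction_curve]
    patients: list[PatientData] = []
    outcomes: list[PatientOutcome] = []
    base_surgery = date(2019, 1, 1)

    for i in range(config.n_patients):
        name = f"S{i + 1:02d}"
        n_mut = _draw_mutation_count(rng, config.mutation_count_law)
        sites = _make_sites(rng, n_mut)

        # protein contexts (one canonical protein per mutated gene)
        contexts: dict[str, tuple[str, int]] = {}
        context_objs = []
        for s in sites:
            length = int(rng.integers(60, 600))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            mpos = int(rng.integers(1, length + 1))
            contexts[s["key"]] = (seq, mpos)
            s["protein_change"] = f"p.X{mpos}{seq[mpos - 1]}"
            context_objs.append(
                ProteinContext(
                    mutation_key=s["key"], sequence=seq,
                    mutant_position=mpos, mutant_residue=seq[mpos - 1],
                )
            )

        callsets = _make_callsets(rng, sites)

        # RNA validation: expressed sites pass the depth/VAF rule, others fail
        expressed = [bool(rng.random() < config.expressed_fraction) for _ in sites]
        rna_rows = []
        for s, expr in zip(sites, expressed):
            if expr:
                depth = max(int(rng.poisson(100)), 20)
                vaf = float(rng.uniform(0.05, 0.6))
            elif rng.random() < 0.5:
                depth = int(rng.poisson(8))
                vaf = float(rng.uniform(0.0, 0.6))
            else:
                depth = max(int(rng.poisson(100)), 20)
                vaf = float(rng.uniform(0.0, 0.049))
            rna_rows.append(
                {
                    "chrom": s["chrom"], "pos": s["pos"], "ref": s["ref"],
                    "alt": s["alt"], "rna_depth": depth, "rna_vaf": round(vaf, 4),
                }
            )
        rna_table = pd.DataFrame(rna_rows)

        hla_I = [str(a) for a in rng.choice(CLASS_I_ALLELES, size=6, replace=False)]
        hla_II = [str(a) for a in rng.choice(CLASS_II_ALLELES, size=2, replace=False)]

        affinity, neo_keys = _ic50_tables(
            rng, sites, expressed, hla_I, hla_II, config.ic50_law, contexts
        )

        # vaccine targets: up to 20 of the predicted neoantigens (synthesis cap)
        n_target = min(len(neo_keys), 20)
        target_keys = sorted(neo_keys)[:n_target] if n_target >= 3 else []

        # clone structure: targeted mutations sit in the leading clones,
        # untargeted mutations in the remainder (clone-structured panels)
        ccf = rng.dirichlet(np.full(config.n_clones, config.clone_ccf_concentration))
        ccf = np.sort(ccf)[::-1] * config.ccf_total
        n_lead = max(1, config.n_clones // 2)
        target_set = set(target_keys)
        site_to_clone = {}
        for s in sites:
            if s["key"] in target_set:
                site_to_clone[s["key"]] = int(rng.integers(0, n_lead))
            else:
                lo = n_lead if config.n_clones > n_lead else 0
                site_to_clone[s["key"]] = int(rng.integers(lo, config.n_clones))
        targeted_clones = {c for k, c in site_to_clone.items() if k in target_set}
        curves = clone_ccf_curves(ccf, days, config.vaccine_kill_rate, targeted_clones)
        plasma = simulate_plasma_series(
            curves, site_to_clone, config.tumor_fraction_curve,
            config.plasma_depth, rng, patient=name, target_sites=target_set,
        )

        responsive = bool(rng.random() < config.responsive_fraction)
        n_pools = max(1, min(4, math.ceil(max(n_target, 3) / 5)))
        elispot = _simulate_elispot(
            rng, name, n_pools, responsive, config.elispot_law
        )

        group = "responsive" if responsive else "non-responsive"
        surgery = base_surgery + timedelta(days=int(rng.integers(0, 365)))
        first_vacc = surgery + timedelta(days=int(rng.integers(60, 120)))
        t_rec = float(rng.exponential(1.0 / config.recurrence_hazard[group]))
        event = t_rec <= config.censor_horizon_months
        months = min(t_rec, config.censor_horizon_months)
        outcomes.append(
            PatientOutcome(
                patient=name,
                surgery=surgery,
                first_vaccination=first_vacc,
                endpoint=surgery + timedelta(days=round(months * DAYS_PER_MONTH)),
                event=event,
                group=group,
                covariates=_draw_covariates(rng, treated=True),
            )
        )

        patients.append(
            PatientData(
                patient=name, callsets=callsets, rna_table=rna_table,
                hla_classI=hla_I, hla_classII=hla_II,
                affinity_table=affinity, contexts=context_objs,
                mutation_keys=[s["key"] for s in sites],
                expressed_keys=[s["key"] for s, e in zip(sites, expressed) if e],
                neoantigen_keys=neo_keys, target_keys=target_keys,
                clone_ccf=ccf, site_to_clone=site_to_clone,
                plasma=plasma, elispot=elispot, responsive=responsive,
            )
        )

    # untreated control pool for propensity matching
    for j in range(config.n_control_pool):
        name = f"C{j + 1:02d}"
        surgery = base_surgery + timedelta(days=int(rng.integers(0, 365)))
        t_rec = float(rng.exponential(1.0 / config.recurrence_hazard["matched-control"]))
        event = t_rec <= config.censor_horizon_months
        months = min(t_rec, config.censor_horizon_months)
        outcomes.append(
            PatientOutcome(
                patient=name,
                surgery=surgery,
                first_vaccination=None,
                endpoint=surgery + timedelta(days=round(months * DAYS_PER_MONTH)),
                event=event,
                group="matched-control",
                covariates=_draw_covariates(rng, treated=False),
            )
        )

    return CohortBundle(config=config, patients=patients, outcomes=outcomes)


def _draw_covariates(rng: np.random.Generator, treated: bool) -> dict[str, float]:
    """Baseline covariates with a mild treated/control shift (confounding)."""
    shift = 0.4 if treated else 0.0
    return {
        "sex": float(rng.random() < 0.8),
        "age": float(np.clip(rng.normal(52 + 3 * shift, 9), 18, 75)),
        "vascular_invasion": float(rng.random() < (0.9 if treated else 0.7)),
        "hemoglobin": float(np.clip(rng.normal(135 + 5 * shift, 12), 100, 175)),
        "platelet": float(np.clip(rng.normal(180 + 15 * shift, 45), 80, 400)),
        "tace": float(rng.random() < (0.95 if treated else 0.8)),
    }


# ---------------------------------------------------------------------------
# File bundle I/O (the formats the downstream modules read)


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write the cohort as the on-disk formats every downstream reader accepts."""
    from neovax.ctdna import PLASMA_COLUMNS
    from neovax.elispot import elispot_frame
    from neovax.filtering import write_caller_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.config.to_yaml(out / "config.yaml")
    for p in bundle.patients:
        pdir = out / p.patient
        pdir.mkdir(exist_ok=True)
        for caller, calls in p.callsets.items():
            write_caller_vcf(pdir / f"{caller}.vcf", calls)
        p.rna_table.to_csv(pdir / "rna_validation.tsv", sep="\t", index=False)
        (pdir / "hla.txt").write_text(
            "\n".join(["# class I"] + p.hla_classI + ["# class II"] + p.hla_classII)
            + "\n"
        )
        p.affinity_table.to_csv(pdir / "affinities.tsv", sep="\t", index=False)
        records = [
            SeqRecord(Seq(c.sequence), id=c.mutation_key, description="")
            for c in p.contexts
        ]
        SeqIO.write(records, pdir / "proteins.fasta", "fasta")
        pd.DataFrame(
            {
                "mutation_key": [c.mutation_key for c in p.contexts],
                "position": [c.mutant_position for c in p.contexts],
                "residue": [c.mutant_residue for c in p.contexts],
            }
        ).to_csv(pdir / "proteins.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "patient": o.patient, "day": o.day, "site": o.site,
                    "alt_reads": o.alt_reads, "total_reads": o.total_reads,
                    "is_target": o.is_target,
                }
                for o in p.plasma
            ],
            columns=PLASMA_COLUMNS,
        ).to_csv(pdir / "plasma.tsv", sep="\t", index=False)
        elispot_frame(p.elispot).to_csv(pdir / "elispot.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient": o.patient,
                "surgery": o.surgery.isoformat(),
                "first_vaccination": (
                    o.first_vaccination.isoformat() if o.first_vaccination else ""
                ),
                "endpoint": o.endpoint.isoformat(),
                "event": int(o.event),
                "group": o.group,
                **o.covariates,
            }
            for o in bundle.outcomes
        ]
    ).to_csv(out / "outcomes.csv", index=False)


def read_outcomes_csv(path: str | Path) -> list[PatientOutcome]:
    df = pd.read_csv(path, dtype={"first_vaccination": str})
    covariate_cols = [
        c for c in df.columns
        if c not in ("patient", "surgery", "first_vaccination", "endpoint",
                     "event", "group")
    ]
    out = []
    for r in df.itertuples():
        fv = getattr(r, "first_vaccination")
        out.append(
            PatientOutcome(
                patient=str(r.patient),
                surgery=date.fromisoformat(r.surgery),
                first_vaccination=(
                    date.fromisoformat(fv) if isinstance(fv, str) and fv else None
                ),
                endpoint=date.fromisoformat(r.endpoint),
                event=bool(r.event),
                group=str(r.group),
                covariates={c: float(getattr(r, c)) for c in covariate_cols},
            )
        )
    return out
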