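"""Synthetic-cohort generator: determinism, distributions, and round-trips."""

import numpy as np
import pandas as pd
import pytest

from neovax.ctdna import build_trajectory, classify_pattern, mean_vaf
from neovax.filtering import read_caller_vcf, read_rna_table
from neovax.pipeline import run_patient
from neovax.simulate import (
    SimulationConfig,
    clone_ccf_curves,
    generate_cohort,
    read_outcomes_csv,
    simulate_plasma_series,
    write_bundle,
)


def _bundle_fingerprint(bundle):
    parts = []
    for p in bundle.patients:
        parts.append(p.patient)
        parts.append(",".join(p.mutation_keys))
        parts.append(p.rna_table.to_csv())
        parts.append(p.affinity_table.to_csv())
        parts.append(",".join(f"{o.site}:{o.day}:{o.alt_reads}:{o.total_reads}"
                              for o in p.plasma))
        parts.append(",".join(f"{m.stimulus}:{m.spot_counts}" for m in p.elispot))
    for o in bundle.outcomes:
        parts.append(f"{o.patient}:{o.endpoint}:{o.event}:{o.group}:{o.covariates}")
    return "|".join(parts)


class TestConfigValidation:
    def test_bad_fields_named_in_error(self):
        cfg = SimulationConfig(expressed_fraction=1.5)
        with pytest.raises(ValueError, match="expressed_fraction"):
            cfg.validate()
        cfg = SimulationConfig(vaccine_kill_rate=1.0)
        with pytest.raises(ValueError, match="vaccine_kill_rate"):
            cfg.validate()
        cfg = SimulationConfig(plasma_depth=0)
        with pytest.raises(ValueError, match="plasma_depth"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_patients=3, seed=9, vaccine_kill_rate=0.3)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestDeterminism:
    def test_identical_seed_identical_bundle(self):
        a = generate_cohort(SimulationConfig(n_patients=3, seed=1))
        b = generate_cohort(SimulationConfig(n_patients=3, seed=1))
        assert _bundle_fingerprint(a) == _bundle_fingerprint(b)

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(n_patients=3, seed=1))
        b = generate_cohort(SimulationConfig(n_patients=3, seed=2))
        assert _bundle_fingerprint(a) != _bundle_fingerprint(b)


class TestDistributions:
    def test_mutation_counts_within_clamp(self, small_cohort):
        for p in small_cohort.patients:
            assert 7 <= len(p.mutation_keys) <= 148

    def test_mutation_count_mean_within_three_se(self):
        cohort = generate_cohort(SimulationConfig(n_patients=50, seed=3))
        counts = np.array([len(p.mutation_keys) for p in cohort.patients])
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 78.0) <= 3 * se

    def test_ccf_sums_below_one(self, small_cohort):
        for p in small_cohort.patients:
            assert p.clone_ccf.sum() <= 1.0 + 1e-12
            assert np.all(p.clone_ccf >= 0)

    def test_neoantigen_fraction_near_target(self):
        cohort = generate_cohort(SimulationConfig(n_patients=30, seed=4))
        fracs = [
            len(p.neoantigen_keys) / len(p.mutation_keys)
            for p in cohort.patients
        ]
        assert np.mean(fracs) == pytest.approx(0.335, abs=0.1)


class TestPlasmaSimulation:
    def test_zero_tumor_fraction_zero_alt_reads(self, rng):
        curves = np.full((3, 2), 0.5)
        obs = simulate_plasma_series(
            curves, {"s1": 0, "s2": 1}, [(0, 0.0), (30, 0.0), (60, 0.0)],
            1000.0, rng,
        )
        assert all(o.alt_reads == 0 for o in obs)

    def test_expected_vaf_formula_at_high_depth(self, rng):
        # single clone, CCF 1, tumor fraction 0.2 -> VAF ~ 0.10
        curves = np.ones((1, 1))
        obs = simulate_plasma_series(
            curves, {"s1": 0}, [(0, 0.2)], 2_000_000.0, rng,
        )
        assert obs[0].vaf == pytest.approx(0.10, rel=0.02)

    def test_unknown_clone_raises(self, rng):
        with pytest.raises(ValueError, match="unknown clone"):
            simulate_plasma_series(
                np.ones((1, 1)), {"s1": 3}, [(0, 0.1)], 100.0, rng
            )

    def test_alt_never_exceeds_total(self, rng):
        curves = rng.uniform(0, 1, size=(4, 3))
        obs = simulate_plasma_series(
            curves, {f"s{i}": i % 3 for i in range(20)},
            [(0, 0.5), (30, 0.2), (60, 0.1), (90, 0.4)], 200.0, rng,
        )
        assert all(o.alt_reads <= o.total_reads for o in obs)

    def test_kill_rate_drives_targeted_decline(self):
        """Targeted-site mean VAF ends below its start in >=95% of replicates."""
        declines = 0
        n = 100
        days = [0, 60, 120, 180]
        for s in range(n):
            rng = np.random.default_rng(10_000 + s)
            curves = clone_ccf_curves(
                np.array([0.6, 0.3]), days, kill_rate=0.5, targeted_clones={0}
            )
            obs = simulate_plasma_series(
                curves, {f"t{i}": 0 for i in range(10)},
                [(d, 0.05) for d in days], 1000.0, rng,
                target_sites={f"t{i}" for i in range(10)},
            )
            first = mean_vaf([o for o in obs if o.day == days[0]], "target")
            last = mean_vaf([o for o in obs if o.day == days[-1]], "target")
            declines += last < first
        assert declines / n >= 0.95

    def test_null_decline_symmetric_between_subsets(self):
        """With kill_rate 0, targeted and other sites decline identically
        in relative terms (clone CCFs differ, so absolute VAFs may not)."""
        from neovax.ctdna import percent_decline

        diffs = []
        cohort = generate_cohort(
            SimulationConfig(n_patients=100, seed=5, vaccine_kill_rate=0.0)
        )
        for p in cohort.patients:
            if not p.target_keys:
                continue
            traj = build_trajectory(p.plasma)
            if traj.mean_vaf_target[0] <= 0 or traj.mean_vaf_other[0] <= 0:
                continue
            dt = percent_decline(traj.mean_vaf_target[0], traj.mean_vaf_target[-1])
            do = percent_decline(traj.mean_vaf_other[0], traj.mean_vaf_other[-1])
            diffs.append(dt - do)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se


class TestSelectionPressure:
    def test_kill_rate_produces_divergent_patterns(self):
        cohort = generate_cohort(
            SimulationConfig(n_patients=40, seed=6, vaccine_kill_rate=0.5)
        )
        patterns = [
            classify_pattern(build_trajectory(p.plasma))
            for p in cohort.patients
            if p.target_keys
        ]
        assert patterns.count("divergent") / len(patterns) >= 0.9

    def test_null_produces_concordant_patterns(self):
        cohort = generate_cohort(
            SimulationConfig(n_patients=40, seed=6, vaccine_kill_rate=0.0)
        )
        patterns = [
            classify_pattern(build_trajectory(p.plasma))
            for p in cohort.patients
            if p.target_keys
        ]
        assert patterns.count("concordant") / len(patterns) >= 0.9


class TestBundleRoundTrip:
    def test_files_round_trip_through_readers(self, tmp_path, small_cohort):
        write_bundle(small_cohort, tmp_path)
        p = small_cohort.patients[0]
        pdir = tmp_path / p.patient
        for caller in ("callerA", "callerB", "confirmer"):
            calls = read_caller_vcf(pdir / f"{caller}.vcf", caller)
            assert {c.locus for c in calls} == {
                c.locus for c in p.callsets[caller]
            }
        rna = read_rna_table(pdir / "rna_validation.tsv")
        pd.testing.assert_frame_equal(
            rna.astype({"chrom": str}), p.rna_table.astype({"chrom": str})
        )
        aff = pd.read_csv(pdir / "affinities.tsv", sep="\t")
        assert len(aff) == len(p.affinity_table)
        outcomes = read_outcomes_csv(tmp_path / "outcomes.csv")
        assert len(outcomes) == len(small_cohort.outcomes)
        assert outcomes[0].covariates == small_cohort.outcomes[0].covariates

    def test_bundle_accepted_by_downstream_pipeline(self, small_cohort):
        for p in small_cohort.patients:
            ctx = {c.mutation_key: c for c in p.contexts}
            res = run_patient(
                p.patient, p.callsets, p.rna_table, p.affinity_table, ctx
            )
            assert {v.mutation_key for v in res.consensus} == set(p.mutation_keys)
            assert {v.mutation_key for v in res.validated} == set(p.expressed_keys)
            assert {s.mutation_key for s in res.neoantigens} == set(
                p.neoantigen_keys
            )
            assert len(res.candidates) <= 30
            for pep in res.peptides:
                assert len(pep.sequence) <= 27
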