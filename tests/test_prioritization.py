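"""Neoantigen calling, tiering, and capped prioritization."""

import math

import numpy as np
import pytest

from neovax.prioritization import (
    AffinityRecord,
    MutationEpitopeSummary,
    assign_tier,
    is_predicted_neoantigen,
    median_ic50,
    prioritize,
    summarize_mutation,
)


def _summary(ci=None, cii=None, vaf=0.0, key="m1", tier=None):
    return MutationEpitopeSummary(
        mutation_key=key, best_classI_ic50=ci, best_classII_ic50=cii,
        rna_vaf=vaf, tier=tier,
    )


@pytest.mark.parametrize(
    "values,expected",
    [
        ([100, 200, 300, 400, 500], 300),
        ([320], 320),             # single class-II predictor
        ([100, 400], 250),        # even count: mean of central pair
    ],
)
def test_median_ic50(values, expected):
    assert median_ic50(values) == pytest.approx(expected)


def test_median_ic50_empty_raises():
    with pytest.raises(ValueError):
        median_ic50([])


class TestSummarize:
    def test_best_is_min_over_pair_medians(self):
        # three class-I pairs with medians 600, 450, 900
        records = []
        for pep, allele, meds in [
            ("AAAAAAAAA", "HLA-A*02:01", [500, 600, 700]),
            ("CCCCCCCCC", "HLA-A*02:01", [450, 400, 500]),
            ("AAAAAAAAA", "HLA-B*40:01", [900, 900, 900]),
        ]:
            for m in meds:
                records.append(
                    AffinityRecord("m1", pep, allele, 1, "pred", float(m))
                )
        s = summarize_mutation(records, ["HLA-A*02:01", "HLA-B*40:01"], 0.2)
        assert s.best_classI_ic50 == pytest.approx(450)
        assert s.best_classII_ic50 is None

    def test_allele_outside_genotype_raises(self):
        rec = AffinityRecord("m1", "AAAAAAAAA", "HLA-A*02:01", 1, "p", 100.0)
        with pytest.raises(ValueError, match="genotype"):
            summarize_mutation([rec], ["HLA-B*40:01"], 0.0)

    def test_random_table_matches_exhaustive_oracle(self, rng):
        """best class I/II equal brute-force enumeration over all pairs."""
        alleles = ["HLA-A*02:01", "HLA-B*40:01", "DRB1*09:01"]
        records = []
        for _ in range(20):
            cls = int(rng.integers(1, 3))
            pep = "".join(rng.choice(list("ACDEFGHIK"), 9 if cls == 1 else 15))
            allele = alleles[int(rng.integers(0, 2))] if cls == 1 else alleles[2]
            records.append(
                AffinityRecord(
                    "m1", pep, allele, cls, f"p{rng.integers(5)}",
                    float(rng.uniform(10, 5000)),
                )
            )
        s = summarize_mutation(records, alleles, 0.1)
        for cls, attr in [(1, "best_classI_ic50"), (2, "best_classII_ic50")]:
            pairs = {}
            for r in records:
                if r.hla_class == cls:
                    pairs.setdefault((r.peptide, r.allele), []).append(r.ic50)
            expected = (
                min(float(np.median(v)) for v in pairs.values()) if pairs else None
            )
            got = getattr(s, attr)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)


class TestNeoantigenCall:
    @pytest.mark.parametrize(
        "ci,cii,expected",
        [
            (499.0, 600.0, True),    # class I just under the cut
            (500.0, 500.0, False),   # strict inequality at 500
            (None, 450.0, True),     # class II alone suffices
            (None, None, False),
        ],
    )
    def test_500nM_boundary(self, ci, cii, expected):
        assert is_predicted_neoantigen(_summary(ci, cii)) is expected

    def test_threshold_monotonicity(self, rng):
        summaries = [
            _summary(float(rng.uniform(10, 2000)), float(rng.uniform(10, 2000)))
            for _ in range(200)
        ]
        at_500 = {i for i, s in enumerate(summaries) if is_predicted_neoantigen(s, 500)}
        at_800 = {i for i, s in enumerate(summaries) if is_predicted_neoantigen(s, 800)}
        assert at_500 <= at_800


class TestTiers:
    @pytest.mark.parametrize(
        "ci,cii,tier",
        [
            (100.0, 120.0, 1),   # strong on both classes
            (100.0, 900.0, 2),   # strong on exactly one
            (300.0, 400.0, 3),   # modest on both
            (300.0, 900.0, 4),   # modest on one only
            (150.0, 100.0, 2),   # 150 itself is not strong
            (150.0, 160.0, 4),   # 150 is not modest either
            (100.0, None, 2),
            (None, 450.0, 4),
        ],
    )
    def test_tier_assignment(self, ci, cii, tier):
        assert assign_tier(_summary(ci, cii)) == tier

    def test_non_neoantigen_raises(self):
        with pytest.raises(ValueError, match="not a predicted neoantigen"):
            assign_tier(_summary(900.0, 900.0))


def _random_candidates(rng, n):
    out = []
    for i in range(n):
        ci = float(rng.uniform(10, 600)) if rng.random() < 0.9 else None
        cii = float(rng.uniform(10, 600)) if rng.random() < 0.6 else None
        s = _summary(ci, cii, vaf=round(float(rng.uniform(0, 0.6)), 3), key=f"m{i:03d}")
        if is_predicted_neoantigen(s):
            s.tier = assign_tier(s)
            out.append(s)
    return out


def _oracle_sort(cands):
    def key(s):
        ci = s.best_classI_ic50 if s.best_classI_ic50 is not None else math.inf
        return (s.tier, -s.rna_vaf, ci, s.mutation_key)

    return sorted(cands, key=key)


class TestPrioritize:
    def test_under_cap_all_retained(self, rng):
        cands = _random_candidates(rng, 10)[:7]
        out = prioritize(cands)
        assert len(out) == len(cands)
        assert [s.mutation_key for s in out] == [
            s.mutation_key for s in _oracle_sort(cands)
        ]

    def test_over_cap_truncates_to_30(self, rng):
        cands = []
        while len(cands) < 44:
            cands.extend(_random_candidates(rng, 60))
        cands = cands[:44]
        assert len(prioritize(cands)) == 30

    def test_matches_comparator_sort_oracle(self, rng):
        for _ in range(50):
            cands = _random_candidates(rng, 50)
            got = [s.mutation_key for s in prioritize(cands)]
            expected = [s.mutation_key for s in _oracle_sort(cands)[:30]]
            assert got == expected

    def test_idempotent_and_permutation_invariant(self, rng):
        cands = _random_candidates(rng, 50)
        once = prioritize(cands)
        assert prioritize(once) == once
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        assert [s.mutation_key for s in prioritize(shuffled)] == [
            s.mutation_key for s in once
        ]

    def test_tier_blocks_ordered(self, rng):
        out = prioritize(_random_candidates(rng, 40), cap=40)
        tiers = [s.tier for s in out]
        assert tiers == sorted(tiers)

    def test_unassigned_tier_raises(self):
        with pytest.raises(ValueError, match="tier"):
            prioritize([_summary(100.0, 100.0)])
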