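"""Boundary behaviour and invariants of the variant-filtering cascade."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rareburden.models import MutationTasterCall, Zygosity
from rareburden.prioritize import (
    AlleleRatioBounds,
    PrioritizationCriteria,
    compute_allele_ratio,
    passes_allele_ratio,
    passes_functional_consensus,
    passes_indel_filter,
    passes_variant_filter,
    prioritize,
    recurrence_filter,
)
from rareburden.simulate import (
    CohortSimSpec,
    null_gene_catalogue,
    simulate_cohort,
)

from conftest import make_call, make_cohort, make_variant

D = MutationTasterCall.DELETERIOUS
N = MutationTasterCall.BENIGN


class TestAlleleRatio:
    @pytest.mark.parametrize("alt,depth,expected", [(10, 20, 0.5), (0, 30, 0.0), (18, 20, 0.9)])
    def test_exact_quotient(self, alt, depth, expected):
        assert compute_allele_ratio(alt, depth) == expected

    def test_zero_depth_is_undefined(self):
        with pytest.raises(ValueError, match="zero depth"):
            compute_allele_ratio(0, 0)

    @pytest.mark.parametrize("alt,depth,zyg,keep", [
        (35, 100, Zygosity.HET, True),    # lower bound inclusive
        (34, 100, Zygosity.HET, False),   # just below
        (65, 100, Zygosity.HET, True),    # upper bound inclusive
        (66, 100, Zygosity.HET, False),   # just above
        (90, 100, Zygosity.HOM_ALT, True),   # hom bound inclusive
        (89, 100, Zygosity.HOM_ALT, False),
        (100, 100, Zygosity.HOM_ALT, True),
        (50, 100, Zygosity.HOM_ALT, False),  # balanced reads are not a hom call
    ])
    def test_qc_window_boundaries(self, alt, depth, zyg, keep):
        call = make_call(zygosity=zyg, alt_reads=alt, depth=depth)
        assert passes_allele_ratio(call, AlleleRatioBounds()) is keep


class TestFunctionalConsensus:
    def test_full_consensus_passes(self):
        assert passes_functional_consensus(make_variant(maf=0.0)) is True

    @pytest.mark.parametrize("override,expected", [
        ({"predictsnp2_benign_count": 1}, True),   # < 2 benign calls tolerated
        ({"predictsnp2_benign_count": 2}, False),
        ({"sift": None}, False),                   # missing required score fails
        ({"polyphen": None}, False),
        ({"mutation_taster": None}, False),
        ({"mutation_taster": N}, False),
        ({"predictsnp2_benign_count": None}, False),
        ({"sift": 0.05}, True),                    # SIFT "D" encoding boundary
        ({"sift": 0.051}, False),
        ({"polyphen": 0.909}, True),               # PolyPhen2 "D" encoding boundary
        ({"polyphen": 0.908}, False),
        ({"maf": 0.0009}, True),                   # strict MAF < 0.001
        ({"maf": 0.001}, False),
        ({"maf": None}, True),                     # missing MAF treated as 0
    ])
    def test_consensus_components(self, override, expected):
        v = make_variant(**override)
        assert passes_functional_consensus(v) is expected

    def test_indel_is_a_contract_violation(self):
        indel = make_variant(ref="A", alt="AT")
        with pytest.raises(ValueError, match="SNV-only"):
            passes_functional_consensus(indel)


@pytest.mark.parametrize("maf,expected", [(0.0005, True), (0.001, False), (None, True)])
def test_indel_filter_is_maf_only(maf, expected):
    indel = make_variant(ref="A", alt="AT", sift=None, polyphen=None,
                         mutation_taster=None, predictsnp2_benign_count=None, maf=maf)
    assert passes_indel_filter(indel) is expected


class TestRecurrence:
    def _cohort(self, n_carriers):
        samples = [f"case{i:03d}" for i in range(1, 11)]
        v = make_variant()
        calls = [make_call(sample=s) for s in samples[:n_carriers]]
        return make_cohort([(v, calls)], samples)

    @pytest.mark.parametrize("n_carriers,kept", [(6, False), (5, True), (1, True)])
    def test_carrier_count_bound_inclusive(self, n_carriers, kept):
        filtered = recurrence_filter(self._cohort(n_carriers), max_samples=5)
        assert (len(filtered.variants) == 1) is kept
        if not kept:  # removed entirely, all carriers
            assert filtered.genotypes == {}


class TestPrioritize:
    def test_survivors_match_generator_truth(self):
        spec = CohortSimSpec(
            seed=11,
            genes=null_gene_catalogue(n_genes=40, site_allele_freq=0.01),
            artifact_fraction=0.3,
            deleterious_prob=0.6,
            n_recurrent_artifact_sites=4,
            indel_fraction=0.15,
        )
        cohort, truth = simulate_cohort(spec)
        result = prioritize(cohort)

        # independent expectation from truth labels: annotation-passing,
        # non-artifact calls at sites whose surviving carrier count <= 5
        post_qc: dict[tuple, list[str]] = {}
        for key, calls in cohort.genotypes.items():
            if not truth.variant_pass[key]:
                continue
            for sample in calls:
                if (key, sample) not in truth.artifact_calls:
                    post_qc.setdefault(key, []).append(sample)
        expected = {
            (key, s)
            for key, samples in post_qc.items()
            if len(samples) <= 5 and key not in truth.recurrent_sites
            for s in samples
        }
        assert set(result.surviving) == expected
        assert set(result.gene_list) == {cohort.variant(k).gene for k, _ in expected}

    def test_attrition_ledger_conserves_input(self):
        spec = CohortSimSpec(seed=12, genes=null_gene_catalogue(n_genes=30,
                                                                site_allele_freq=0.02),
                             artifact_fraction=0.25, deleterious_prob=0.5)
        cohort, _ = simulate_cohort(spec)
        result = prioritize(cohort)
        n_calls = sum(len(c) for c in cohort.genotypes.values())
        assert result.n_input == n_calls
        assert len(result.surviving) + sum(result.attrition.values()) == n_calls

    def test_all_fail_maf_gives_empty_gene_list(self):
        v = make_variant(maf=0.1)
        cohort = make_cohort([(v, [make_call()])], ["case001"])
        result = prioritize(cohort)
        assert result.gene_list == []
        assert result.attrition["functional_maf"] == 1

    def test_idempotent_on_survivors(self):
        spec = CohortSimSpec(seed=13, genes=null_gene_catalogue(n_genes=30,
                                                                site_allele_freq=0.02),
                             artifact_fraction=0.2)
        cohort, _ = simulate_cohort(spec)
        first = prioritize(cohort)
        keep = set(first.surviving)
        surviving_cohort = make_cohort(
            [(cohort.variant(k), [c for s, c in cohort.calls(k).items() if (k, s) in keep])
             for k in {k for k, _ in keep}],
            cohort.samples,
        )
        again = prioritize(surviving_cohort)
        assert set(again.surviving) == set(first.surviving)
        assert sum(again.attrition.values()) == 0

    def test_empty_cohort_is_empty_result(self):
        result = prioritize(make_cohort([], ["case001"]))
        assert result.surviving == [] and result.gene_list == []

    def test_gene_list_deduplicated(self):
        v1 = make_variant(pos=100, maf=0.0)
        v2 = make_variant(pos=200, ref="C", alt="T", maf=0.0)
        cohort = make_cohort([(v1, [make_call()]), (v2, [make_call()])], ["case001"])
        assert prioritize(cohort).gene_list == ["GENE1"]


snv_strategy = st.builds(
    make_variant,
    pos=st.integers(1, 10**6),
    sift=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    polyphen=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    mutation_taster=st.sampled_from([D, N, None]),
    predictsnp2_benign_count=st.one_of(st.none(), st.integers(0, 8)),
    maf=st.one_of(st.none(), st.floats(0, 0.5, allow_nan=False)),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(v=snv_strategy, alt=st.integers(0, 60), depth=st.integers(1, 60),
       zyg=st.sampled_from([Zygosity.HET, Zygosity.HOM_ALT]))
def test_variant_and_call_predicates_commute(v, alt, depth, zyg):
    """Conjunction of the pure predicates equals cascade survival in any order."""
    alt = min(alt, depth)
    call = make_call(zygosity=zyg, alt_reads=alt, depth=depth)
    a = passes_variant_filter(v)
    b = passes_allele_ratio(call)
    assert (a and b) == (b and a)
    cohort = make_cohort([(v, [call])], ["case001"])
    result = prioritize(cohort)
    assert (len(result.surviving) == 1) == (a and b)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(maf=st.floats(0, 0.5, allow_nan=False, exclude_min=True),
       looser=st.floats(0, 0.5, allow_nan=False, exclude_min=True))
def test_loosening_maf_threshold_never_shrinks_survivors(maf, looser):
    lo, hi = sorted([maf, looser])
    v = make_variant(maf=0.25)
    cohort = make_cohort([(v, [make_call()])], ["case001"])
    tight = prioritize(cohort, PrioritizationCriteria(maf_max_snv=lo, maf_max_indel=lo))
    loose = prioritize(cohort, PrioritizationCriteria(maf_max_snv=hi, maf_max_indel=hi))
    assert set(tight.surviving) <= set(loose.surviving)
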