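"""Qualifying-variant rules, carrier counting, contingency construction and
the one-sided Fisher test of the per-gene burden scan."""

from __future__ import annotations

import numpy as np
import pytest

from rareburden.burden import (
    GeneCaseCounts,
    GeneControlCounts,
    QualifyingCriteria,
    count_case_models,
    dominant_contingency,
    expected_biallelic_controls,
    fisher_one_sided_greater,
    implied_bh_m,
    recessive_contingency,
    run_burden_scan,
    select_qualifying,
    variant_qualifies,
)
from rareburden.enrichment import bh_adjust
from rareburden.models import Zygosity
from rareburden.simulate import (
    CohortSimSpec,
    simulate_cohort,
    simulate_control_summary,
    spiked_gene_catalogue,
)

from conftest import make_call, make_cohort, make_variant
from test_enrichment import fisher_oracle


class TestQualifyingRules:
    def test_all_boundaries_as_printed(self):
        v = make_variant(sift=0.05, polyphen=0.8, maf=0.009)
        assert variant_qualifies(v, QualifyingCriteria()) is True

    @pytest.mark.parametrize("override", [
        {"sift": 0.06}, {"sift": None},
        {"polyphen": 0.79}, {"polyphen": None},
        {"maf": 0.01}, {"maf": 0.2},
    ])
    def test_failing_each_rule_excludes(self, override):
        v = make_variant(**{"sift": 0.05, "polyphen": 0.8, "maf": 0.009, **override})
        assert variant_qualifies(v, QualifyingCriteria()) is False

    def test_indel_excluded_even_with_perfect_scores(self):
        indel = make_variant(ref="A", alt="AT", sift=0.0, polyphen=1.0, maf=0.0)
        assert variant_qualifies(indel, QualifyingCriteria()) is False

    def test_depth_rule_is_per_carrier_call(self):
        """depth > 10 strictly; a variant may qualify in one sample only."""
        v = make_variant()
        cohort = make_cohort(
            [(v, [make_call(sample="case001", alt_reads=5, depth=10),
                  make_call(sample="case002", alt_reads=6, depth=11)])],
            ["case001", "case002"],
        )
        qset = select_qualifying(cohort)
        assert qset.by_gene["GENE1"][v.key] == ["case002"]

    def test_carrierless_qualifying_site_kept_but_gene_untested(self):
        v = make_variant()
        cohort = make_cohort([(v, [])], ["case001"])
        qset = select_qualifying(cohort)
        assert qset.by_gene["GENE1"][v.key] == []
        assert qset.genes == []


class TestCaseCounting:
    def _counts(self, calls_by_site):
        samples = ["case001", "case002", "case003"]
        pairs = []
        for i, calls in enumerate(calls_by_site):
            pairs.append((make_variant(pos=100 + i, ref="A", alt="G"), calls))
        cohort = make_cohort(pairs, samples)
        qualifying = {v.key: sorted(c.sample_id for c in calls) for v, calls in pairs}
        return count_case_models("GENE1", qualifying, cohort)

    def test_two_het_sites_is_both_het_and_compound_het(self):
        counts = self._counts([
            [make_call("case001", Zygosity.HET)],
            [make_call("case001", Zygosity.HET)],
        ])
        assert (counts.het_carriers, counts.ch_carriers, counts.hom_carriers) == (1, 1, 0)
        assert counts.dominant_carriers == 1 and counts.recessive_carriers == 1

    def test_single_hom_counts_under_both_models(self):
        counts = self._counts([[make_call("case001", Zygosity.HOM_ALT)]])
        assert (counts.het_carriers, counts.ch_carriers, counts.hom_carriers) == (0, 0, 1)
        assert counts.dominant_carriers == 1 and counts.recessive_carriers == 1
        assert counts.total_ac == 2

    def test_no_qualifying_variants_all_zero(self):
        counts = self._counts([])
        assert (counts.het_carriers, counts.hom_carriers,
                counts.ch_carriers, counts.total_ac) == (0, 0, 0, 0)

    def test_invariants_hold_on_mixed_cohort(self):
        counts = self._counts([
            [make_call("case001", Zygosity.HET), make_call("case002", Zygosity.HOM_ALT)],
            [make_call("case001", Zygosity.HET), make_call("case003", Zygosity.HET)],
        ])
        assert counts.ch_carriers <= counts.het_carriers
        assert counts.het_carriers + counts.hom_carriers <= 3
        assert counts.total_ac >= counts.het_carriers + 2 * counts.hom_carriers


class TestContingency:
    def test_dominant_construction_from_published_counts(self):
        """18 het carriers of 50 cases vs summed control AC 7943 of 125,748."""
        case = GeneCaseCounts("CNTN4", het_carriers=18, hom_carriers=0,
                              ch_carriers=5, total_ac=24)
        ctrl = GeneControlCounts("CNTN4", control_ac_sum=7943, control_nhom_sum=0)
        assert dominant_contingency(case, ctrl, 50) == ((18, 32), (7943, 117805))

    def test_zero_carriers_and_cap_rule(self):
        case = GeneCaseCounts("G", 0, 0, 0, 0)
        ctrl = GeneControlCounts("G", control_ac_sum=10, control_nhom_sum=0, control_n=100)
        assert dominant_contingency(case, ctrl, 50) == ((0, 50), (10, 90))
        ctrl_over = GeneControlCounts("G", control_ac_sum=500, control_nhom_sum=0,
                                      control_n=100)
        assert dominant_contingency(case, ctrl_over, 50) == ((0, 50), (100, 0))

    def test_recessive_reported_hom_strategy(self):
        case = GeneCaseCounts("ARVCF", het_carriers=16, hom_carriers=1,
                              ch_carriers=6, total_ac=35)
        ctrl = GeneControlCounts("ARVCF", control_ac_sum=7463, control_nhom_sum=0)
        table = recessive_contingency(case, ctrl, 50, strategy="reported_hom")
        assert table == ((7, 43), (0, 125748))

    def test_recessive_strategies_ordered(self):
        """Independence estimate >= reported homozygotes at positive freqs."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            freqs = tuple(rng.uniform(0, 0.01, size=rng.integers(1, 12)))
            n = 125_748
            nhom = sum(round(n * f * f) for f in freqs)
            ctrl = GeneControlCounts("G", control_ac_sum=int(sum(2 * n * f for f in freqs)),
                                     control_nhom_sum=nhom, allele_frequencies=freqs)
            assert expected_biallelic_controls(ctrl) >= nhom or nhom == 0
            case = GeneCaseCounts("G", 0, 0, 0, 0)
            rep = recessive_contingency(case, ctrl, 50, "reported_hom")[1][0]
            exp = recessive_contingency(case, ctrl, 50, "expected_biallelic")[1][0]
            assert exp >= rep

    def test_unknown_strategy_is_configuration_error(self):
        case = GeneCaseCounts("G", 0, 0, 0, 0)
        ctrl = GeneControlCounts("G", 0, 0)
        with pytest.raises(ValueError, match="strategy"):
            recessive_contingency(case, ctrl, 50, strategy="bogus")

    def test_zero_recessive_carriers_give_p_one(self):
        case = GeneCaseCounts("G", 5, 0, 0, 5)
        ctrl = GeneControlCounts("G", 100, 0)
        for strategy in ("reported_hom", "expected_biallelic"):
            assert fisher_one_sided_greater(
                recessive_contingency(case, ctrl, 50, strategy)) == 1.0


class TestFisherOneSided:
    def test_exact_small_table(self):
        # P(X>=2) = [C(3,2)C(3,1) + C(3,3)C(3,0)] / C(6,3) = 10/20
        assert fisher_one_sided_greater(((2, 1), (1, 2))) == pytest.approx(0.5)

    def test_all_zero_and_empty_margins(self):
        assert fisher_one_sided_greater(((0, 0), (0, 0))) == 1.0
        assert fisher_one_sided_greater(((0, 50), (0, 125748))) == 1.0

    def test_sweep_against_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            total = int(rng.integers(4, 201))
            cuts = np.sort(rng.integers(0, total + 1, size=3))
            a, b, c = int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1])
            d = total - a - b - c
            got = fisher_one_sided_greater(((a, b), (c, d)))
            assert got == pytest.approx(fisher_oracle(a, b, c, d, "greater"),
                                        rel=1e-9, abs=1e-300)

    def test_monotone_in_case_carriers(self):
        """p_dom non-increasing as carriers move from control to case row
        with both margins' totals fixed."""
        ps = [fisher_one_sided_greater(((a, 50 - a), (200 - a, 125548 + a)))
              for a in range(0, 21)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestBurdenScan:
    def test_spiked_gene_attains_smallest_dominant_p(self, spiked_sim):
        spec, cohort, truth, controls = spiked_sim
        results = run_burden_scan(cohort, controls)
        assert results[0].gene in truth.spiked_genes
        spiked = set(truth.spiked_genes)
        assert {r.gene for r in results[:5]} >= spiked

    def test_gene_subset_restricts_results_and_family(self, spiked_sim):
        spec, cohort, truth, controls = spiked_sim
        full = run_burden_scan(cohort, controls)
        keep = {r.gene for r in full[:10]}
        sub = run_burden_scan(cohort, controls, gene_subset=keep)
        assert {r.gene for r in sub} == keep
        sub_m = {r.gene: r for r in sub}
        for r in full[:10]:
            # same raw p, FDR re-adjusted within the smaller family
            assert sub_m[r.gene].p_dom == pytest.approx(r.p_dom)
        assert all(sub_m[r.gene].fdr_dom <= r.fdr_dom + 1e-12 for r in full[:10])

    def test_missing_control_site_contributes_zero(self, spiked_sim):
        spec, cohort, truth, controls = spiked_sim
        gene = next(iter(truth.spiked_genes))
        pruned = {k: v for k, v in controls.items()
                  if cohort.variant(k).gene != gene if k in controls}
        results = run_burden_scan(cohort, pruned)
        row = next(r for r in results if r.gene == gene)
        assert row.control.control_ac_sum == 0
        assert row.p_dom < 1e-6  # zero-control gene becomes extreme, not an error

    def test_fdr_not_below_p(self, spiked_sim):
        spec, cohort, truth, controls = spiked_sim
        for r in run_burden_scan(cohort, controls):
            assert r.fdr_dom >= r.p_dom - 1e-15
            assert r.fdr_rec >= r.p_rec - 1e-15


def test_implied_family_size_recovers_known_m():
    rng = np.random.default_rng(5)
    p = rng.uniform(1e-8, 0.2, size=30)
    q = bh_adjust(p, m_total=263)
    m = implied_bh_m(p, q)
    assert m == pytest.approx(263, rel=0.02)
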