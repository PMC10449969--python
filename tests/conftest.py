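"""Shared fixtures: tiny hand-built cohorts and simulated ones."""

from __future__ import annotations

import pytest

from rareburden.models import (
    AnnotatedVariant,
    CohortTable,
    GenotypeCall,
    MutationTasterCall,
    Zygosity,
)
from rareburden.simulate import (
    CohortSimSpec,
    simulate_cohort,
    simulate_control_summary,
    spiked_gene_catalogue,
)


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gene="GENE1",
    sift=0.01,
    polyphen=0.95,
    mutation_taster=MutationTasterCall.DELETERIOUS,
    predictsnp2_benign_count=0,
    maf=0.0001,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, sift=sift,
        polyphen=polyphen, mutation_taster=mutation_taster,
        predictsnp2_benign_count=predictsnp2_benign_count, maf=maf,
    )


def make_call(sample="case001", zygosity=Zygosity.HET, alt_reads=10, depth=20) -> GenotypeCall:
    return GenotypeCall(sample, zygosity, alt_reads, depth)


def make_cohort(variant_calls: list[tuple[AnnotatedVariant, list[GenotypeCall]]],
                samples: list[str]) -> CohortTable:
    return CohortTable(
        variants=[v for v, _ in variant_calls],
        genotypes={v.key: {c.sample_id: c for c in calls}
                   for v, calls in variant_calls if calls},
        samples=samples,
    )


@pytest.fixture(scope="session")
def spiked_sim():
    """One simulated 50-case cohort with three dominant spiked genes."""
    spec = CohortSimSpec(seed=7, genes=spiked_gene_catalogue())
    cohort, truth = simulate_cohort(spec)
    controls = simulate_control_summary(spec)
    return spec, cohort, truth, controls
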