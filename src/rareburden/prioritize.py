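"""Variant-level filtering cascade producing the prioritized variant list.

The cascade removes, in order: SNVs failing the functional consensus
(SIFT, PolyPhen2 and MutationTaster all deleterious, fewer than two
PredictSNP2 component tools benign, MAF < 0.001) and indels failing the
MAF rule; calls failing allele-ratio QC (het kept in [0.35, 0.65], hom at
>= 0.9 — read-support evidence against artifactual genotypes); and variants
recurring in more than 5 unrelated carriers (systematic platform artifacts).
Surviving variants collapse to a deduplicated gene list for
overrepresentation analysis.

The three variant/call-level predicates are pure and commute; the cascade
order only fixes how attrition is attributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import AnnotatedVariant, CohortTable, GenotypeCall, VariantKey, Zygosity

MAF_RARE_THRESHOLD = 0.001


@dataclass(frozen=True)
class AlleleRatioBounds:
    """Inclusive allele-ratio acceptance windows, as fractions of reads."""

    het_low: float = 0.35
    het_high: float = 0.65
    hom_min: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.het_low < self.het_high < self.hom_min <= 1:
            raise ValueError(
                f"require 0 < het_low < het_high < hom_min <= 1, got "
                f"({self.het_low}, {self.het_high}, {self.hom_min})"
            )


@dataclass(frozen=True)
class PrioritizationCriteria:
    maf_max_snv: float = MAF_RARE_THRESHOLD  # exclusive
    maf_max_indel: float = MAF_RARE_THRESHOLD  # exclusive
    recurrence_max_samples: int = 5  # inclusive
    predictsnp2_benign_max: int = 1  # inclusive: keep if benign count < 2
    apply_ar_to_indels: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.maf_max_snv <= 0.5 or not 0 < self.maf_max_indel <= 0.5:
            raise ValueError("MAF thresholds must lie in (0, 0.5]")
        if self.recurrence_max_samples < 1:
            raise ValueError("recurrence_max_samples must be >= 1")


@dataclass
class PrioritizedSet:
    """Surviving (variant, sample) pairs with a per-filter attrition ledger.

    ``attrition`` attributes each removed pair to the first failing filter in
    cascade order; counts plus survivors always sum to the input pair count.
    """

    surviving: list[tuple[VariantKey, str]]
    attrition: dict[str, int] = field(default_factory=dict)
    gene_list: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.surviving) + sum(self.attrition.values())


def compute_allele_ratio(alt_read_count: int, depth: int) -> float:
    """AR = AC / CD: alternate reads over total coverage at the site."""
    if depth <= 0:
        raise ValueError("allele ratio undefined at zero depth; discard the call")
    if not 0 <= alt_read_count <= depth:
        raise ValueError(f"alt_read_count {alt_read_count} outside [0, {depth}]")
    return alt_read_count / depth


def passes_allele_ratio(call: GenotypeCall, bounds: AlleleRatioBounds | None = None) -> bool:
    """Allele-balance QC: het calls kept in [het_low, het_high], hom-alt
    calls kept at >= hom_min (all bounds inclusive)."""
    bounds = bounds or AlleleRatioBounds()
    ar = compute_allele_ratio(call.alt_read_count, call.depth)
    if call.zygosity is Zygosity.HET:
        return bounds.het_low <= ar <= bounds.het_high
    return ar >= bounds.hom_min


def passes_functional_consensus(
    v: AnnotatedVariant, criteria: PrioritizationCriteria | None = None
) -> bool:
    """Deleteriousness consensus for SNVs.

    True iff SIFT, PolyPhen2 and MutationTaster all call deleterious, fewer
    than two PredictSNP2 component tools call benign/tolerated, and
    MAF < 0.001 (strict). A missing required score fails (conservative:
    unannotated noise must not flood the gene list). Missing MAF counts as 0.
    """
    criteria = criteria or PrioritizationCriteria()
    if not v.is_snv:
        raise ValueError(f"consensus filter is SNV-only; got {v.variant_class.value} at "
                         f"{v.chrom}:{v.pos} (indels use passes_indel_filter)")
    from .models import MutationTasterCall

    if v.sift is None or not sift_is_deleterious(v.sift):
        return False
    if v.polyphen is None or not polyphen_is_deleterious(v.polyphen):
        return False
    if v.mutation_taster is not MutationTasterCall.DELETERIOUS:
        return False
    if v.predictsnp2_benign_count is None or (
        v.predictsnp2_benign_count > criteria.predictsnp2_benign_max
    ):
        return False
    return v.maf_or_zero < criteria.maf_max_snv


# Standard numeric encodings of the categorical "D" calls: SIFT deleterious at
# <= 0.05; PolyPhen2 "probably damaging" at >= 0.909 (HumDiv category cutoff).
SIFT_DELETERIOUS_MAX = 0.05
POLYPHEN_DELETERIOUS_MIN = 0.909


def sift_is_deleterious(score: float) -> bool:
    return score <= SIFT_DELETERIOUS_MAX


def polyphen_is_deleterious(score: float) -> bool:
    return score >= POLYPHEN_DELETERIOUS_MIN


def passes_indel_filter(
    v: AnnotatedVariant, criteria: PrioritizationCriteria | None = None
) -> bool:
    """Indels are kept on rarity alone: MAF < 0.001 (strict; missing = 0)."""
    criteria = criteria or PrioritizationCriteria()
    return v.maf_or_zero < criteria.maf_max_indel


def passes_variant_filter(
    v: AnnotatedVariant, criteria: PrioritizationCriteria | None = None
) -> bool:
    """Dispatch: SNVs through the consensus, indels/MNVs through the MAF rule."""
    if v.is_snv:
        return passes_functional_consensus(v, criteria)
    return passes_indel_filter(v, criteria)


def recurrence_filter(cohort: CohortTable, max_samples: int = 5) -> CohortTable:
    """Drop variants carried by more than ``max_samples`` distinct samples.

    In an unrelated cohort a rare pathogenic variant should not recur widely;
    recurrent sites are treated as platform artifacts and removed entirely
    (all carriers). Carrier counting is by individual, not allele.
    """
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    keep = [
        v.key for v in cohort.variants if len(cohort.carrier_samples(v.key)) <= max_samples
    ]
    return cohort.subset(keep)


def prioritize(
    cohort: CohortTable,
    criteria: PrioritizationCriteria | None = None,
    bounds: AlleleRatioBounds | None = None,
) -> PrioritizedSet:
    """Run the full cascade over every (variant, carrier) pair.

    Attrition attribution follows cascade order: functional/MAF filter, then
    allele-ratio QC, then recurrence. The collapsed gene list is the
    deduplicated set of gene symbols over surviving pairs, sorted.
    """
    criteria = criteria or PrioritizationCriteria()
    bounds = bounds or AlleleRatioBounds()
    attrition = {"functional_maf": 0, "allele_ratio": 0, "recurrence": 0}

    # variant+call level predicates
    stage1: dict[VariantKey, list[str]] = {}
    for v in cohort.variants:
        calls = cohort.calls(v.key)
        variant_ok = passes_variant_filter(v, criteria)
        skip_ar = not v.is_snv and not criteria.apply_ar_to_indels
        for sample, call in calls.items():
            if not variant_ok:
                attrition["functional_maf"] += 1
            elif not skip_ar and not passes_allele_ratio(call, bounds):
                attrition["allele_ratio"] += 1
            else:
                stage1.setdefault(v.key, []).append(sample)

    # recurrence on post-QC carrier counts
    surviving: list[tuple[VariantKey, str]] = []
    genes: set[str] = set()
    for key, samples in stage1.items():
        if len(samples) > criteria.recurrence_max_samples:
            attrition["recurrence"] += len(samples)
            continue
        gene = cohort.variant(key).gene
        for sample in samples:
            surviving.append((key, sample))
        genes.add(gene)

    surviving.sort()
    return PrioritizedSet(
        surviving=surviving, attrition=attrition, gene_list=sorted(genes)
    )
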