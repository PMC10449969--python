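"""Per-gene collapsing (burden) test against summary-level population controls.

Qualifying variants (SNV, carrier depth > 10, SIFT <= 0.05, PolyPhen >= 0.8,
MAF < 0.01) are collected per gene; case carriers are counted under a
dominant model (any het or hom-alt qualifying call) and a recessive model
(hom-alt, or >= 2 distinct het sites in the gene — a phase-unaware putative
compound heterozygote). Controls are known only through per-site allele
counts, so the dominant control carrier count is the summed allele count,
each allele assumed to sit in a distinct individual (capped at the cohort
size; conservative). Case vs control carrier counts are compared by the
one-sided Fisher exact test (enrichment in cases), with BH FDR per model
across the tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .enrichment import bh_adjust
from .models import (
    AnnotatedVariant,
    CohortTable,
    ControlSiteSummary,
    VariantKey,
    Zygosity,
)

Table2x2 = tuple[tuple[int, int], tuple[int, int]]

GNOMAD_EXOME_N = 125_748  # gnomAD v2.1.1 exome individuals


@dataclass(frozen=True)
class QualifyingCriteria:
    """Inclusion rules for burden-test qualifying variants.

    ``min_depth`` is an exclusive bound (depth > 10) applied per carrier
    call, so a variant may qualify in one sample and not another.
    """

    snv_only: bool = True
    min_depth: int = 10  # exclusive
    sift_max: float = 0.05  # inclusive
    polyphen_min: float = 0.8  # inclusive
    maf_max: float = 0.01  # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.sift_max <= 1 or not 0 <= self.polyphen_min <= 1:
            raise ValueError("score thresholds must lie in [0, 1]")
        if not 0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must lie in (0, 0.5]")


@dataclass(frozen=True)
class GeneCaseCounts:
    gene: str
    het_carriers: int  # samples with >=1 het qualifying call and no hom
    hom_carriers: int  # samples with >=1 hom-alt qualifying call
    ch_carriers: int  # samples with >=2 distinct het qualifying sites, no hom
    total_ac: int  # summed alternate alleles over qualifying case calls

    @property
    def dominant_carriers(self) -> int:
        return self.het_carriers + self.hom_carriers

    @property
    def recessive_carriers(self) -> int:
        return self.ch_carriers + self.hom_carriers


@dataclass(frozen=True)
class GeneControlCounts:
    gene: str
    control_ac_sum: int
    control_nhom_sum: int
    control_n: int = GNOMAD_EXOME_N
    allele_frequencies: tuple[float, ...] = ()  # per qualifying site, for estimates


@dataclass
class GeneBurdenResult:
    gene: str
    case: GeneCaseCounts
    control: GeneControlCounts
    dominant_table: Table2x2
    recessive_table: Table2x2
    p_dom: float
    p_rec: float
    fdr_dom: float = float("nan")
    fdr_rec: float = float("nan")


@dataclass
class QualifyingSet:
    """Per-gene qualifying variants with their depth-passing carriers.

    ``by_gene[gene][variant]`` lists the case samples whose call at that
    variant passes the depth rule (possibly empty: a qualifying site stays
    in the gene's 'SNP file' — and contributes its control allele count —
    even when no case carrier survives the depth cut). A gene is *tested*
    only if at least one carrier remains.
    """

    by_gene: dict[str, dict[VariantKey, list[str]]] = field(default_factory=dict)
    missing_control: list[VariantKey] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        """Genes with at least one depth-passing qualifying case carrier."""
        return sorted(
            g for g, sites in self.by_gene.items() if any(sites.values())
        )


def variant_qualifies(v: AnnotatedVariant, criteria: QualifyingCriteria) -> bool:
    """Variant-level part of the qualifying rule (scores and rarity)."""
    if criteria.snv_only and not v.is_snv:
        return False
    if v.sift is None or v.sift > criteria.sift_max:
        return False
    if v.polyphen is None or v.polyphen < criteria.polyphen_min:
        return False
    return v.maf_or_zero < criteria.maf_max


def select_qualifying(
    cohort: CohortTable,
    criteria: QualifyingCriteria | None = None,
) -> QualifyingSet:
    """Build the per-gene qualifying call sets from the case cohort.

    The depth criterion is evaluated per carrier call (depth strictly
    greater than ``min_depth``).
    """
    criteria = criteria or QualifyingCriteria()
    out = QualifyingSet()
    for v in cohort.variants:
        if not variant_qualifies(v, criteria):
            continue
        carriers = [
            s for s, call in cohort.calls(v.key).items() if call.depth > criteria.min_depth
        ]
        out.by_gene.setdefault(v.gene, {})[v.key] = sorted(carriers)
    return out


def count_case_models(
    gene: str,
    qualifying_calls: dict[VariantKey, list[str]],
    cohort: CohortTable,
) -> GeneCaseCounts:
    """Classify each case sample over the gene's qualifying sites.

    hom if any hom-alt call; else compound-het (ch) if het at >= 2 distinct
    sites; else het if het at >= 1 site. Phase is unknown, so ch is a
    putative biallelic state only.
    """
    per_sample: dict[str, list[Zygosity]] = {}
    total_ac = 0
    for key in qualifying_calls:
        for sample in qualifying_calls[key]:
            call = cohort.calls(key)[sample]
            per_sample.setdefault(sample, []).append(call.zygosity)
            total_ac += 2 if call.zygosity is Zygosity.HOM_ALT else 1
    het = hom = ch = 0
    for zygs in per_sample.values():
        if any(z is Zygosity.HOM_ALT for z in zygs):
            hom += 1
        else:
            het += 1
            if sum(z is Zygosity.HET for z in zygs) >= 2:
                ch += 1
    return GeneCaseCounts(gene=gene, het_carriers=het, hom_carriers=hom,
                          ch_carriers=ch, total_ac=total_ac)


def control_counts_for_gene(
    gene: str,
    qualifying_keys: list[VariantKey],
    control_summary: dict[VariantKey, ControlSiteSummary],
    control_n: int = GNOMAD_EXOME_N,
) -> tuple[GeneControlCounts, list[VariantKey]]:
    """Sum control AC and nhom over the gene's qualifying sites.

    A site absent from the control summary contributes zero (returned in the
    missing list for logging), matching the treatment of case-only variants.
    """
    ac = nhom = 0
    freqs: list[float] = []
    missing: list[VariantKey] = []
    for key in qualifying_keys:
        site = control_summary.get(key)
        if site is None:
            missing.append(key)
            freqs.append(0.0)
            continue
        ac += site.control_ac
        nhom += site.control_nhom
        freqs.append(site.control_ac / site.control_an if site.control_an else 0.0)
    return (
        GeneControlCounts(gene=gene, control_ac_sum=ac, control_nhom_sum=nhom,
                          control_n=control_n, allele_frequencies=tuple(freqs)),
        missing,
    )


def dominant_contingency(
    case: GeneCaseCounts, ctrl: GeneControlCounts, n_cases: int
) -> Table2x2:
    """2x2 of carrier vs non-carrier individuals under the dominant model.

    Control carriers are approximated by the summed allele count, capped at
    the control cohort size (each allele in a distinct individual).
    """
    carriers = case.dominant_carriers
    if carriers > n_cases:
        raise ValueError(f"{case.gene}: dominant carriers ({carriers}) exceed n_cases")
    ctrl_carriers = min(ctrl.control_ac_sum, ctrl.control_n)
    return ((carriers, n_cases - carriers), (ctrl_carriers, ctrl.control_n - ctrl_carriers))


def expected_biallelic_controls(ctrl: GeneControlCounts) -> int:
    """Estimated biallelic control carriers under site independence.

    Each haplotype carries >= 1 qualifying allele with probability
    1 - prod_i(1 - f_i); squaring gives the probability both haplotypes do,
    i.e. a (phase-free) biallelic genotype. Includes homozygotes, so it is
    never below the reported-homozygote count when frequencies are positive.
    """
    prod = 1.0
    for f in ctrl.allele_frequencies:
        prod *= 1.0 - f
    p_hap = 1.0 - prod
    return round(ctrl.control_n * p_hap * p_hap)


def recessive_contingency(
    case: GeneCaseCounts,
    ctrl: GeneControlCounts,
    n_cases: int,
    strategy: str = "reported_hom",
) -> Table2x2:
    """2x2 under the recessive model.

    Case carriers are putative biallelic individuals (compound het + hom).
    The control side is under-determined by summary statistics; two
    strategies:

    - ``reported_hom``: homozygote counts as reported (undercounts compound
      hets in controls — anti-conservative).
    - ``expected_biallelic``: independence estimate of biallelic carriers
      from per-site allele frequencies (see
      :func:`expected_biallelic_controls`).
    """
    carriers = case.recessive_carriers
    if carriers > n_cases:
        raise ValueError(f"{case.gene}: recessive carriers ({carriers}) exceed n_cases")
    if strategy == "reported_hom":
        ctrl_carriers = min(ctrl.control_nhom_sum, ctrl.control_n)
    elif strategy == "expected_biallelic":
        ctrl_carriers = min(
            max(expected_biallelic_controls(ctrl), ctrl.control_nhom_sum), ctrl.control_n
        )
    else:
        raise ValueError(f"unknown recessive control strategy {strategy!r}")
    return ((carriers, n_cases - carriers), (ctrl_carriers, ctrl.control_n - ctrl_carriers))


def fisher_one_sided_greater(table: Table2x2) -> float:
    """Upper-tail Fisher exact p: P(X >= a) for the top-left cell, with the
    margins of the 2x2 fixed (hypergeometric)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def implied_bh_m(p_values, fdrs) -> float:
    """Diagnose the BH family size implied by paired (p, FDR) columns.

    For step-up BH without clipping, fdr_i = min_{j >= rank_i} p_(j) * m / j,
    so fdr_i * rank_i / p_i <= m, with equality at every row that realises
    its own running minimum; the maximum of the per-row ratio over unclipped
    rows (fdr < 1) therefore recovers m.
    """
    import numpy as np

    p = np.asarray(p_values, dtype=float)
    q = np.asarray(fdrs, dtype=float)
    order = np.argsort(p, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, p.size + 1)
    mask = (q < 1) & (p > 0)
    if not mask.any():
        return float("nan")
    return float(np.max(q[mask] * ranks[mask] / p[mask]))


def run_burden_scan(
    cohort: CohortTable,
    control_summary: dict[VariantKey, ControlSiteSummary],
    criteria: QualifyingCriteria | None = None,
    gene_subset: set[str] | None = None,
    control_n: int = GNOMAD_EXOME_N,
    recessive_strategy: str = "reported_hom",
) -> list[GeneBurdenResult]:
    """Scan all genes with >= 1 qualifying case variant; both models; BH FDR.

    ``gene_subset`` restricts the scan (and the BH family size) to the given
    genes, e.g. those of a significant enrichment term. Genes without
    qualifying case variants are excluded from testing and from the BH m.
    Results are sorted by dominant p.
    """
    criteria = criteria or QualifyingCriteria()
    qualifying = select_qualifying(cohort, criteria)
    n_cases = cohort.n_cases

    results: list[GeneBurdenResult] = []
    for gene in qualifying.genes:
        if gene_subset is not None and gene not in gene_subset:
            continue
        sites = qualifying.by_gene[gene]
        case = count_case_models(gene, sites, cohort)
        ctrl, missing = control_counts_for_gene(
            gene, list(sites), control_summary, control_n=control_n
        )
        qualifying.missing_control.extend(missing)
        dom = dominant_contingency(case, ctrl, n_cases)
        rec = recessive_contingency(case, ctrl, n_cases, strategy=recessive_strategy)
        results.append(
            GeneBurdenResult(
                gene=gene, case=case, control=ctrl,
                dominant_table=dom, recessive_table=rec,
                p_dom=fisher_one_sided_greater(dom),
                p_rec=fisher_one_sided_greater(rec),
            )
        )
    if results:
        fdr_dom = bh_adjust([r.p_dom for r in results])
        fdr_rec = bh_adjust([r.p_rec for r in results])
        for r, qd, qr in zip(results, fdr_dom, fdr_rec):
            r.fdr_dom = float(qd)
            r.fdr_rec = float(qr)
    results.sort(key=lambda r: (r.p_dom, r.gene))
    return results
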