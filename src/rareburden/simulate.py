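"""Synthetic case cohorts, control summaries and gene sets with ground truth.

The generator emulates the data regime the pipeline targets: a small,
deeply-genotyped case cohort (default 50 samples) against a large population
control known only through summary allele counts (default 125,748
individuals), with per-gene qualifying-variant carrier structure, a
configurable fraction of artifact calls with skewed allele balance,
recurrent artifact sites planted across many samples, and an annotation
model controlling how often a site carries fully deleterious in-silico
scores. Ground-truth labels for every variant, call, gene and term make
each pipeline stage testable without external data.

Control summaries are derived deterministically from the site allele
frequencies (AC = round(2*N*f), AN = 2*N, nhom = round(N*f^2)) so that any
case-vs-control discrepancy is attributable to case sampling alone; a
sampled-control mode exists behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    AnnotatedVariant,
    CohortTable,
    ControlSiteSummary,
    GeneSetCollection,
    GenotypeCall,
    MutationTasterCall,
    VariantKey,
    Zygosity,
)

CONTROL_N_DEFAULT = 125_748


@dataclass(frozen=True)
class GeneSimSpec:
    """Simulation parameters for one gene."""

    name: str
    n_sites: int = 10
    site_allele_freq: float = 0.0005  # control allele frequency per site
    dominant_multiplier: float = 1.0  # case carrier prob = mult * control carrier prob
    recessive_spike: bool = False
    recessive_carrier_prob: float = 0.1  # case biallelic prob when spiked

    def __post_init__(self) -> None:
        if not 0 <= self.site_allele_freq <= 0.5:
            raise ValueError("site_allele_freq must lie in [0, 0.5]")
        if self.dominant_multiplier < 1:
            raise ValueError("dominant_multiplier must be >= 1 (1 = null)")


@dataclass
class CohortSimSpec:
    """Study conditions for one simulated cohort; the seed is mandatory."""

    seed: int
    genes: list[GeneSimSpec]
    n_cases: int = 50
    control_n: int = CONTROL_N_DEFAULT
    artifact_fraction: float = 0.0  # calls drawn with out-of-window allele balance
    n_recurrent_artifact_sites: int = 0
    recurrent_artifact_carriers: int = 8  # planted carriers per recurrent site
    deleterious_prob: float = 1.0  # prob a site gets fully deleterious annotations
    indel_fraction: float = 0.0
    low_depth_fraction: float = 0.0  # calls drawn with depth <= 10
    sampled_controls: bool = False

    def __post_init__(self) -> None:
        for name in ("artifact_fraction", "indel_fraction", "low_depth_fraction",
                     "deleterious_prob"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside each simulated cohort."""

    variant_pass: dict[VariantKey, bool]  # passes annotation+MAF prioritization rules
    artifact_calls: set[tuple[VariantKey, str]]  # calls with skewed allele balance
    recurrent_sites: set[VariantKey]  # planted recurrent-artifact sites
    spiked_genes: dict[str, str]  # gene -> "dom" | "rec"
    spiked_terms: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variant_pass": {"|".join(map(str, k)): v for k, v in self.variant_pass.items()},
            "artifact_calls": sorted("|".join(map(str, k)) + "@" + s
                                     for k, s in self.artifact_calls),
            "recurrent_sites": sorted("|".join(map(str, k)) for k in self.recurrent_sites),
            "spiked_genes": self.spiked_genes,
            "spiked_terms": sorted(self.spiked_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def null_gene_catalogue(
    n_genes: int = 200, n_sites: int = 10, site_allele_freq: float = 0.0005
) -> list[GeneSimSpec]:
    """A catalogue of null genes (case carrier rate equals control)."""
    width = len(str(n_genes))
    return [
        GeneSimSpec(name=f"G{i:0{width}d}", n_sites=n_sites,
                    site_allele_freq=site_allele_freq)
        for i in range(1, n_genes + 1)
    ]


def spiked_gene_catalogue(
    n_genes: int = 200,
    n_sites: int = 10,
    site_allele_freq: float = 0.0005,
    n_spiked_dom: int = 3,
    dominant_multiplier: float = 20.0,
    n_spiked_rec: int = 0,
    recessive_carrier_prob: float = 0.1,
) -> list[GeneSimSpec]:
    """Null catalogue with the first genes replaced by spiked ones."""
    genes = null_gene_catalogue(n_genes, n_sites, site_allele_freq)
    out: list[GeneSimSpec] = []
    for i, g in enumerate(genes):
        if i < n_spiked_dom:
            out.append(GeneSimSpec(name=f"DOM{i + 1}", n_sites=n_sites,
                                   site_allele_freq=site_allele_freq,
                                   dominant_multiplier=dominant_multiplier))
        elif i < n_spiked_dom + n_spiked_rec:
            out.append(GeneSimSpec(name=f"REC{i - n_spiked_dom + 1}", n_sites=n_sites,
                                   site_allele_freq=site_allele_freq,
                                   recessive_spike=True,
                                   recessive_carrier_prob=recessive_carrier_prob))
        else:
            out.append(g)
    return out


def _site_layout(spec: CohortSimSpec) -> list[tuple[VariantKey, str, float, bool]]:
    """Deterministic (key, gene, allele_freq, is_recurrent_artifact) layout.

    Positions are synthetic but valid: genes tile chromosomes 1-22, sites
    spaced 100 bp apart. Shared by the cohort and control generators so the
    two tables stay keyed identically.
    """
    layout: list[tuple[VariantKey, str, float, bool]] = []
    for gi, gene in enumerate(spec.genes):
        chrom = f"chr{(gi % 22) + 1}"
        base = 1_000_000 + (gi // 22) * 100_000
        for si in range(gene.n_sites):
            key = (chrom, base + si * 100 + 1, "A", "G")
            layout.append((key, gene.name, gene.site_allele_freq, False))
    for ri in range(spec.n_recurrent_artifact_sites):
        gi = ri % len(spec.genes)
        gene = spec.genes[gi]
        chrom = f"chr{(gi % 22) + 1}"
        base = 1_000_000 + (gi // 22) * 100_000
        key = (chrom, base + 50_000 + ri * 100 + 1, "A", "G")
        layout.append((key, gene.name, 0.0, True))
    return layout


def _draw_annotation(rng: np.random.Generator, deleterious: bool) -> dict:
    if deleterious:
        return dict(
            sift=round(float(rng.uniform(0.0, 0.05)), 4),
            polyphen=round(float(rng.uniform(0.909, 1.0)), 4),
            mutation_taster=MutationTasterCall.DELETERIOUS,
            predictsnp2_benign_count=int(rng.integers(0, 2)),  # 0 or 1: < 2 benign
        )
    return dict(
        sift=round(float(rng.uniform(0.2, 1.0)), 4),
        polyphen=round(float(rng.uniform(0.0, 0.5)), 4),
        mutation_taster=MutationTasterCall.BENIGN,
        predictsnp2_benign_count=int(rng.integers(2, 8)),
    )


def _draw_call(
    rng: np.random.Generator,
    sample: str,
    zygosity: Zygosity,
    artifact: bool,
    low_depth: bool,
) -> GenotypeCall:
    # Depths of 20+ keep integer rounding of the allele fraction within
    # 0.025, so the drawn windows below cannot cross the QC bounds.
    depth = int(rng.integers(5, 11)) if low_depth else int(rng.integers(20, 101))
    if zygosity is Zygosity.HET:
        if artifact:
            lo, hi = (0.08, 0.30) if rng.random() < 0.5 else (0.70, 0.92)
            frac = rng.uniform(lo, hi)
        else:
            frac = rng.uniform(0.38, 0.62)
    else:
        frac = rng.uniform(0.50, 0.85) if artifact else rng.uniform(0.95, 1.0)
    alt = int(np.clip(round(frac * depth), 0, depth))
    return GenotypeCall(sample, zygosity, alt, depth)


def simulate_cohort(spec: CohortSimSpec) -> tuple[CohortTable, TruthLabels]:
    """Draw a case cohort under the given simulation parameters.

    Per site, each case sample carries the variant with probability
    ``min(1, multiplier * control carrier probability)`` (carrier probability
    from Hardy-Weinberg at the site allele frequency); carriers are
    homozygous with the conditional HW probability. Recessive-spiked genes
    additionally plant biallelic samples (two distinct het sites, or one
    hom). Artifact calls receive allele fractions outside the het QC window;
    recurrent-artifact sites are planted in more samples than the recurrence
    filter tolerates. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"case{i:03d}" for i in range(1, spec.n_cases + 1)]
    layout = _site_layout(spec)
    gene_by_name = {g.name: g for g in spec.genes}

    variants: list[AnnotatedVariant] = []
    genotypes: dict[VariantKey, dict[str, GenotypeCall]] = {}
    truth = TruthLabels(variant_pass={}, artifact_calls=set(),
                        recurrent_sites=set(), spiked_genes={})
    for g in spec.genes:
        if g.dominant_multiplier > 1:
            truth.spiked_genes[g.name] = "dom"
        elif g.recessive_spike:
            truth.spiked_genes[g.name] = "rec"

    for key, gene_name, f, is_recurrent in layout:
        gene = gene_by_name[gene_name]
        is_indel = (not is_recurrent) and rng.random() < spec.indel_fraction
        chrom, pos, ref, alt = key
        if is_indel:
            key = (chrom, pos, "A", "AT")
        deleterious = is_recurrent or rng.random() < spec.deleterious_prob
        ann = _draw_annotation(rng, deleterious)
        variant = AnnotatedVariant(
            chrom=key[0], pos=key[1], ref=key[2], alt=key[3], gene=gene_name,
            maf=f if f > 0 else None, **ann,
        )
        variants.append(variant)
        # prioritization-relevant truth: annotation + MAF rules, per variant
        if variant.is_snv:
            ann_pass = deleterious and ann["predictsnp2_benign_count"] < 2 and f < 0.001
        else:
            ann_pass = f < 0.001
        truth.variant_pass[variant.key] = bool(ann_pass)
        if is_recurrent:
            truth.recurrent_sites.add(variant.key)
            carriers = rng.choice(spec.n_cases, size=spec.recurrent_artifact_carriers,
                                  replace=False)
            calls = {}
            for ci in sorted(carriers):
                calls[samples[ci]] = _draw_call(rng, samples[ci], Zygosity.HET,
                                                artifact=False, low_depth=False)
            genotypes[variant.key] = calls
            continue

        carrier_prob_ctrl = 2 * f * (1 - f) + f * f
        p_case = min(1.0, gene.dominant_multiplier * carrier_prob_ctrl)
        p_hom_given_carrier = (f * f / carrier_prob_ctrl) if carrier_prob_ctrl > 0 else 0.0
        draws = rng.random(spec.n_cases)
        calls = {}
        for si, sample in enumerate(samples):
            if draws[si] >= p_case:
                continue
            zyg = Zygosity.HOM_ALT if rng.random() < p_hom_given_carrier else Zygosity.HET
            artifact = rng.random() < spec.artifact_fraction
            low_depth = rng.random() < spec.low_depth_fraction
            calls[sample] = _draw_call(rng, sample, zyg, artifact, low_depth)
            if artifact:
                truth.artifact_calls.add((variant.key, sample))
        if calls:
            genotypes[variant.key] = calls

    # recessive spikes: plant biallelic samples over the gene's sites
    site_keys_by_gene: dict[str, list[VariantKey]] = {}
    for v in variants:
        site_keys_by_gene.setdefault(v.gene, []).append(v.key)
    for g in spec.genes:
        if not g.recessive_spike:
            continue
        keys = [k for k in site_keys_by_gene[g.name] if k not in truth.recurrent_sites]
        for sample in samples:
            if rng.random() >= g.recessive_carrier_prob:
                continue
            if len(keys) >= 2 and rng.random() >= 0.15:
                picked = rng.choice(len(keys), size=2, replace=False)
                for ki in picked:
                    genotypes.setdefault(keys[ki], {})[sample] = _draw_call(
                        rng, sample, Zygosity.HET, artifact=False, low_depth=False)
            else:
                ki = int(rng.integers(0, len(keys)))
                genotypes.setdefault(keys[ki], {})[sample] = _draw_call(
                    rng, sample, Zygosity.HOM_ALT, artifact=False, low_depth=False)

    cohort = CohortTable(variants=variants, genotypes=genotypes, samples=samples)
    return cohort, truth


def simulate_control_summary(spec: CohortSimSpec) -> dict[VariantKey, ControlSiteSummary]:
    """Control summary matched to the cohort's site layout.

    Deterministic mode (default): AC = round(2*N*f), AN = 2*N,
    nhom = round(N*f^2). Sampled mode draws AC ~ Binomial(2N, f) and
    nhom ~ Binomial(N, f^2) (clipped to keep 2*nhom <= AC).
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of genotype draws
    summary: dict[VariantKey, ControlSiteSummary] = {}
    for key, _gene, f, _rec in _site_layout(spec):
        n = spec.control_n
        if spec.sampled_controls:
            ac = int(rng.binomial(2 * n, f))
            nhom = min(int(rng.binomial(n, f * f)), ac // 2)
        else:
            ac = round(2 * n * f)
            nhom = min(round(n * f * f), ac // 2)
        summary[key] = ControlSiteSummary(
            chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
            control_ac=ac, control_an=2 * n, control_nhom=nhom,
        )
    return summary


def simulate_gene_sets(
    catalogue_genes: list[str],
    n_terms: int = 50,
    spiked_term_genes: list[str] | None = None,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 50),
) -> tuple[GeneSetCollection, TruthLabels]:
    """Random flat gene sets over the catalogue, with one optional spiked term.

    The spiked term (id ``T_SPIKED``) contains exactly the given genes; the
    remaining terms are uniform draws from the catalogue. The background is
    the full catalogue.
    """
    if spiked_term_genes is not None:
        missing = set(spiked_term_genes) - set(catalogue_genes)
        if missing:
            raise ValueError(f"spiked genes not in catalogue: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    genes = sorted(catalogue_genes)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    truth = TruthLabels(variant_pass={}, artifact_calls=set(), recurrent_sites=set(),
                        spiked_genes={})
    if spiked_term_genes is not None:
        terms["T_SPIKED"] = ("spiked term", frozenset(spiked_term_genes))
        truth.spiked_terms.add("T_SPIKED")
    lo, hi = term_size_range
    n_random = n_terms - len(terms)
    for i in range(1, n_random + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        terms[f"T{i:04d}"] = (f"random term {i}", frozenset(genes[j] for j in members))
    collection = GeneSetCollection(terms=terms, background=frozenset(genes))
    return collection, truth


def simulate_gene_list(
    background: list[str],
    n_total: int,
    spiked_genes: list[str] | None = None,
    n_from_spiked: int = 0,
    seed: int = 0,
) -> set[str]:
    """A gene list of fixed size: some spiked members plus uniform fillers."""
    rng = np.random.default_rng(seed)
    picked: set[str] = set()
    if spiked_genes and n_from_spiked:
        idx = rng.choice(len(spiked_genes), size=min(n_from_spiked, len(spiked_genes)),
                         replace=False)
        picked |= {sorted(spiked_genes)[i] for i in sorted(idx)}
    pool = sorted(set(background) - picked)
    need = n_total - len(picked)
    if need > 0:
        idx = rng.choice(len(pool), size=min(need, len(pool)), replace=False)
        picked |= {pool[i] for i in sorted(idx)}
    return picked
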