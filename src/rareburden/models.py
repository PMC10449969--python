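"""Core domain types for the rare-variant case/control pipeline.

The pipeline compares a small, fully genotyped case cohort against a large
population control cohort known only through per-site summary statistics
(allele count AC, allele number AN, homozygote count nhom), in the style of
gnomAD exome site tables. These dataclasses are the in-memory contracts all
stages share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt), 1-based pos


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "indel"
    MNV = "MNV"


class Zygosity(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


class MutationTasterCall(str, Enum):
    DELETERIOUS = "deleterious"
    BENIGN = "benign"


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """SNV iff both alleles are single bases; equal-length multi-base
    substitutions are MNVs; anything else is an indel."""
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) == len(alt):
        return VariantClass.MNV
    return VariantClass.INDEL


@dataclass(frozen=True)
class AnnotatedVariant:
    """One normalized, biallelic variant site with functional annotations.

    Missing annotations are ``None``. A missing reference-population MAF is
    interpreted downstream as 0 (absent from the databases = maximally rare);
    missing functional scores make the variant fail any consensus filter that
    requires them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    sift: float | None = None
    polyphen: float | None = None
    mutation_taster: MutationTasterCall | None = None
    predictsnp2_benign_count: int | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError(
                f"multiallelic ALT {self.alt!r} at {self.chrom}:{self.pos}; "
                "split multiallelic records before loading"
            )
        for name, val, lo, hi in (
            ("sift", self.sift, 0.0, 1.0),
            ("polyphen", self.polyphen, 0.0, 1.0),
            ("maf", self.maf, 0.0, 0.5),
        ):
            if val is not None and not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo},{hi}] at {self.chrom}:{self.pos}")
        if self.predictsnp2_benign_count is not None and self.predictsnp2_benign_count < 0:
            raise ValueError("predictsnp2_benign_count must be non-negative")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> VariantClass:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_class is VariantClass.SNV

    @property
    def maf_or_zero(self) -> float:
        return 0.0 if self.maf is None else self.maf


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's non-reference call at one site.

    ``alt_read_count`` / ``depth`` are the AC and CD of the allele-ratio QC:
    AR = AC / CD.
    """

    sample_id: str
    zygosity: Zygosity
    alt_read_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not 0 <= self.alt_read_count <= self.depth:
            raise ValueError(
                f"alt_read_count {self.alt_read_count} outside [0, depth={self.depth}]"
            )


@dataclass(frozen=True)
class ControlSiteSummary:
    """Population-control summary at one site (gnomAD-exome style)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    control_ac: int
    control_an: int
    control_nhom: int

    def __post_init__(self) -> None:
        if self.control_an < 1:
            raise ValueError("control_an must be positive")
        if not 0 <= self.control_ac <= self.control_an:
            raise ValueError(
                f"control_ac {self.control_ac} outside [0, AN={self.control_an}] "
                f"at {self.chrom}:{self.pos}"
            )
        if 2 * self.control_nhom > self.control_ac:
            raise ValueError(
                f"2*nhom ({2 * self.control_nhom}) exceeds AC ({self.control_ac}) "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortTable:
    """A case cohort: variant sites, per-sample non-reference calls, roster.

    Genotypes are stored sparsely: hom-ref / absent calls are simply not
    present. Equality ignores variant and genotype ordering.
    """

    variants: list[AnnotatedVariant]
    genotypes: dict[VariantKey, dict[str, GenotypeCall]]
    samples: list[str]

    def __post_init__(self) -> None:
        keys = {v.key for v in self.variants}
        if len(keys) != len(self.variants):
            raise ValueError("duplicate variant keys in cohort")
        roster = set(self.samples)
        for key, calls in self.genotypes.items():
            if key not in keys:
                raise ValueError(f"genotypes reference unknown variant {key}")
            unknown = set(calls) - roster
            if unknown:
                raise ValueError(f"genotypes at {key} reference unknown samples {sorted(unknown)}")

    @property
    def n_cases(self) -> int:
        return len(self.samples)

    def variant(self, key: VariantKey) -> AnnotatedVariant:
        return self._index[key]

    @property
    def _index(self) -> dict[VariantKey, AnnotatedVariant]:
        idx = getattr(self, "_index_cache", None)
        if idx is None or len(idx) != len(self.variants):
            idx = {v.key: v for v in self.variants}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def calls(self, key: VariantKey) -> Mapping[str, GenotypeCall]:
        return self.genotypes.get(key, {})

    def carrier_samples(self, key: VariantKey) -> set[str]:
        return set(self.genotypes.get(key, {}))

    def iter_calls(self) -> Iterator[tuple[AnnotatedVariant, GenotypeCall]]:
        for v in self.variants:
            for call in self.genotypes.get(v.key, {}).values():
                yield v, call

    def subset(self, keys: Iterable[VariantKey]) -> "CohortTable":
        keep = set(keys)
        return CohortTable(
            variants=[v for v in self.variants if v.key in keep],
            genotypes={k: dict(c) for k, c in self.genotypes.items() if k in keep},
            samples=list(self.samples),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return (
            sorted(self.samples) == sorted(other.samples)
            and sorted(self.variants, key=lambda v: v.key)
            == sorted(other.variants, key=lambda v: v.key)
            and self.genotypes == other.genotypes
        )


@dataclass
class GeneSetCollection:
    """Flat gene-set terms over an explicit background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]  # term_id -> (name, genes)
    background: frozenset[str]
    dropped_genes: dict[str, int] = field(default_factory=dict)  # term_id -> n dropped

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            stray = genes - self.background
            if stray:
                raise ValueError(f"term {term_id} has genes outside background: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.terms)
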