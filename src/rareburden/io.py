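"""Readers and writers for the formats the pipeline touches.

Case cohorts travel as multi-sample VCF v4.2 (normalized, biallelic per
record), population controls as a summary table (TSV or sites-only VCF with
INFO AC/AN/nhomalt), gene sets as GMT, and the background universe as a
newline-delimited gene list.

Annotation keys are configurable through a *field map* so both plain INFO
keys and VEP-style CSQ subfields (``"CSQ:SYMBOL"``) can supply the
functional annotations.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path

import pysam

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

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """An annotation key named in the field map is absent from the input."""


class FormatError(ValueError):
    """The input violates a structural requirement (e.g. multiallelic record)."""


#: logical annotation name -> VCF key. INFO-level entries may be a plain INFO
#: key or "CSQ:SUBFIELD"; alt_reads/depth are FORMAT keys (AD is interpreted
#: as ref,alt pairs and the alt count taken).
DEFAULT_FIELD_MAP: dict[str, str] = {
    "gene": "GENE",
    "sift": "SIFT",
    "polyphen": "PPH2",
    "mutation_taster": "MTASTER",
    "predictsnp2_benign": "PSNP2B",
    "maf": "MAF",
    "alt_reads": "AD",
    "depth": "DP",
}

MANDATORY_FIELDS = ("gene", "alt_reads", "depth")

_DELETERIOUS_WORDS = {"d", "deleterious", "disease_causing", "damaging", "probably_damaging"}
_BENIGN_WORDS = {"n", "p", "t", "b", "benign", "tolerated", "polymorphism", "neutral"}


def _parse_score(raw: object) -> float | None:
    """Parse a numeric score, tolerating VEP renderings like 'deleterious(0.01)'."""
    if raw is None:
        return None
    if isinstance(raw, (int, float)):
        return float(f"{float(raw):.6g}")
    s = str(raw).strip()
    if not s or s == ".":
        return None
    try:
        val = float(s)
    except ValueError:
        m = re.search(r"\(([-+0-9.eE]+)\)", s)
        if not m:
            return None
        val = float(m.group(1))
    # cap at 6 significant digits: undoes float32 INFO noise so VCF
    # round-trips are exact; far beyond the precision of any score source
    return float(f"{val:.6g}")


def _parse_mutation_taster(raw: object) -> MutationTasterCall | None:
    if raw is None:
        return None
    s = str(raw).strip().lower()
    if s in _DELETERIOUS_WORDS:
        return MutationTasterCall.DELETERIOUS
    if s in _BENIGN_WORDS:
        return MutationTasterCall.BENIGN
    return None


def _parse_int(raw: object) -> int | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s == ".":
        return None
    try:
        return int(float(s))
    except ValueError:
        return None


class _CsqIndex:
    """Resolves 'CSQ:SUBFIELD' lookups from a VEP-style annotation header."""

    def __init__(self, header: pysam.VariantHeader, info_key: str):
        try:
            desc = header.info[info_key].description
        except KeyError:
            raise ConfigurationError(
                f"annotation key {info_key!r} not declared in VCF header"
            ) from None
        m = re.search(r"Format:\s*([\w|]+)", desc)
        if not m:
            raise ConfigurationError(
                f"INFO {info_key} header lacks a 'Format: a|b|c' subfield description"
            )
        self.fields = {name: i for i, name in enumerate(m.group(1).split("|"))}
        self.info_key = info_key

    def get(self, record: pysam.VariantRecord, subfield: str) -> str | None:
        raw = record.info.get(self.info_key)
        if raw is None:
            return None
        entry = raw[0] if isinstance(raw, tuple) else raw  # first transcript entry
        parts = str(entry).split("|")
        idx = self.fields.get(subfield)
        if idx is None:
            raise ConfigurationError(
                f"subfield {subfield!r} not in {self.info_key} Format ({sorted(self.fields)})"
            )
        if idx >= len(parts):
            return None
        return parts[idx] or None


def _info_getter(header: pysam.VariantHeader, field_map: dict[str, str]):
    """Build a lookup(record, logical_name) closure over INFO/CSQ fields."""
    csq_indexes: dict[str, _CsqIndex] = {}
    for logical, key in field_map.items():
        if logical in ("alt_reads", "depth"):
            continue
        if ":" in key:
            info_key = key.split(":", 1)[0]
            if info_key not in csq_indexes:
                csq_indexes[info_key] = _CsqIndex(header, info_key)
        elif key not in header.info and logical in MANDATORY_FIELDS:
            raise ConfigurationError(f"mandatory annotation key {key!r} missing from VCF header")

    declared = set(header.info)

    def get(record: pysam.VariantRecord, logical: str):
        key = field_map[logical]
        if ":" in key:
            info_key, subfield = key.split(":", 1)
            return csq_indexes[info_key].get(record, subfield)
        if key not in declared:  # undeclared optional key: treat as missing
            return None
        val = record.info.get(key)
        if isinstance(val, tuple):
            val = val[0]
        return val

    return get


def _zygosity_of(gt: tuple) -> Zygosity | None:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    if all(a == 1 for a in alleles):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_cohort_vcf(
    path: str | Path,
    field_map: dict[str, str] | None = None,
) -> CohortTable:
    """Load a normalized multi-sample VCF into a :class:`CohortTable`.

    One :class:`AnnotatedVariant` per record; a :class:`GenotypeCall` for
    every sample with a non-reference genotype. Records violating type
    invariants (e.g. alt reads exceeding depth) are dropped with a logged
    count. Multiallelic records abort with :class:`FormatError`.
    """
    fmap = dict(DEFAULT_FIELD_MAP, **(field_map or {}))
    for logical in MANDATORY_FIELDS:
        if logical not in fmap:
            raise ConfigurationError(f"field map lacks mandatory entry {logical!r}")

    variants: list[AnnotatedVariant] = []
    genotypes: dict[VariantKey, dict[str, GenotypeCall]] = {}
    n_rejected = 0

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        get_info = _info_getter(vcf.header, fmap)
        ad_key, dp_key = fmap["alt_reads"], fmap["depth"]
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                raise FormatError(
                    f"multiallelic or ALT-less record at {record.chrom}:{record.pos}; "
                    "pre-split multiallelics (e.g. bcftools norm -m-) before loading"
                )
            gene = get_info(record, "gene")
            try:
                variant = AnnotatedVariant(
                    chrom=record.chrom,
                    pos=record.pos,
                    ref=record.ref,
                    alt=record.alts[0],
                    gene=str(gene) if gene is not None else "",
                    sift=_parse_score(get_info(record, "sift")) if "sift" in fmap else None,
                    polyphen=_parse_score(get_info(record, "polyphen"))
                    if "polyphen" in fmap
                    else None,
                    mutation_taster=_parse_mutation_taster(get_info(record, "mutation_taster"))
                    if "mutation_taster" in fmap
                    else None,
                    predictsnp2_benign_count=_parse_int(get_info(record, "predictsnp2_benign"))
                    if "predictsnp2_benign" in fmap
                    else None,
                    maf=_parse_score(get_info(record, "maf")) if "maf" in fmap else None,
                )
            except ValueError as exc:
                logger.warning("rejecting record %s:%s: %s", record.chrom, record.pos, exc)
                n_rejected += 1
                continue

            calls: dict[str, GenotypeCall] = {}
            bad_call = False
            for sample in samples:
                sdata = record.samples[sample]
                zyg = _zygosity_of(sdata.get("GT", (None,)))
                if zyg is None:
                    continue
                ad = sdata.get(ad_key)
                alt_reads = ad[1] if isinstance(ad, tuple) and len(ad) >= 2 else _parse_int(ad)
                depth = _parse_int(sdata.get(dp_key))
                if alt_reads is None or depth is None:
                    logger.warning(
                        "rejecting call %s@%s:%s: missing %s/%s",
                        sample, record.chrom, record.pos, ad_key, dp_key,
                    )
                    bad_call = True
                    break
                try:
                    calls[sample] = GenotypeCall(sample, zyg, int(alt_reads), int(depth))
                except ValueError as exc:
                    logger.warning("rejecting record %s:%s: %s", record.chrom, record.pos, exc)
                    bad_call = True
                    break
            if bad_call:
                n_rejected += 1
                continue
            variants.append(variant)
            if calls:
                genotypes[variant.key] = calls

    if n_rejected:
        logger.warning("rejected %d record(s) failing type invariants", n_rejected)
    return CohortTable(variants=variants, genotypes=genotypes, samples=samples)


_VCF_HEADER_META = [
    ("GENE", "1", "String", "Gene symbol"),
    ("SIFT", "1", "Float", "SIFT score (0 damaging .. 1 tolerated)"),
    ("PPH2", "1", "Float", "PolyPhen2 score (1 probably damaging)"),
    ("MTASTER", "1", "String", "MutationTaster class (D deleterious / N benign)"),
    ("PSNP2B", "1", "Integer", "Count of PredictSNP2 component tools calling benign/tolerated"),
    ("MAF", "1", "Float", "Reference-population minor allele frequency"),
]


def write_cohort_vcf(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as multi-sample VCF v4.2 with GT:AD:DP genotypes.

    Inverse of :func:`read_cohort_vcf` under the default field map: the
    round trip preserves variants, zygosities, alt read counts and depths
    exactly.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
        header.contigs.add(chrom)
    for key, number, vtype, desc in _VCF_HEADER_META:
        header.info.add(key, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depth per allele (ref,alt)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for sample in cohort.samples:
        header.add_sample(sample)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(cohort.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.info["GENE"] = v.gene
            if v.sift is not None:
                rec.info["SIFT"] = v.sift
            if v.polyphen is not None:
                rec.info["PPH2"] = v.polyphen
            if v.mutation_taster is not None:
                rec.info["MTASTER"] = (
                    "D" if v.mutation_taster is MutationTasterCall.DELETERIOUS else "N"
                )
            if v.predictsnp2_benign_count is not None:
                rec.info["PSNP2B"] = v.predictsnp2_benign_count
            if v.maf is not None:
                rec.info["MAF"] = v.maf
            calls = cohort.calls(v.key)
            for sample in cohort.samples:
                call = calls.get(sample)
                sdata = rec.samples[sample]
                if call is None:
                    sdata["GT"] = (0, 0)
                else:
                    sdata["GT"] = (0, 1) if call.zygosity is Zygosity.HET else (1, 1)
                    sdata["AD"] = (call.depth - call.alt_read_count, call.alt_read_count)
                    sdata["DP"] = call.depth
            out.write(rec)


def read_control_summary(path: str | Path) -> dict[VariantKey, ControlSiteSummary]:
    """Load a control site summary from TSV (chrom,pos,ref,alt,ac,an,nhom
    header) or a sites-only VCF with INFO AC/AN/nhomalt."""
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_control_vcf(path)
    summary: dict[VariantKey, ControlSiteSummary] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return summary
        required = {"chrom", "pos", "ref", "alt", "ac", "an", "nhom"}
        missing = required - {f.lower() for f in reader.fieldnames}
        if missing:
            raise FormatError(f"control summary lacks columns: {sorted(missing)}")
        for row in reader:
            row = {k.lower(): v for k, v in row.items()}
            site = ControlSiteSummary(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                control_ac=int(row["ac"]),
                control_an=int(row["an"]),
                control_nhom=int(row["nhom"]),
            )
            summary[site.key] = site
    return summary


def _read_control_vcf(path: Path) -> dict[VariantKey, ControlSiteSummary]:
    summary: dict[VariantKey, ControlSiteSummary] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if record.alts is None or len(record.alts) != 1:
                raise FormatError(f"multiallelic control record at {record.chrom}:{record.pos}")

            def _scalar(key: str, default: int = 0) -> int:
                val = record.info.get(key, default)
                return int(val[0] if isinstance(val, tuple) else val)

            site = ControlSiteSummary(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=record.alts[0],
                control_ac=_scalar("AC"),
                control_an=_scalar("AN"),
                control_nhom=_scalar("nhomalt"),
            )
            summary[site.key] = site
    return summary


def write_control_summary(
    summary: dict[VariantKey, ControlSiteSummary], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "ac", "an", "nhom"])
        for site in sorted(summary.values(), key=lambda s: (s.chrom, s.pos, s.ref, s.alt)):
            writer.writerow(
                [site.chrom, site.pos, site.ref, site.alt,
                 site.control_ac, site.control_an, site.control_nhom]
            )


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_gene_sets(path_gmt: str | Path, background: set[str]) -> GeneSetCollection:
    """Load GMT gene sets, restricting each term to the background universe.

    Genes outside the background are dropped per term with a count recorded
    in ``dropped_genes``. A duplicate term id is an error.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    dropped: dict[str, int] = {}
    bg = frozenset(background)
    with open(path_gmt) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term_id in terms:
                raise FormatError(f"duplicate term id {term_id!r} in GMT")
            kept = frozenset(g for g in genes if g in bg)
            n_dropped = len(set(genes)) - len(kept)
            if n_dropped:
                dropped[term_id] = n_dropped
                logger.warning("term %s: dropped %d gene(s) absent from background",
                               term_id, n_dropped)
            terms[term_id] = (name, kept)
    return GeneSetCollection(terms=terms, background=bg, dropped_genes=dropped)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in collection.terms.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")
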