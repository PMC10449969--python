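"""Stage orchestration: prioritize -> enrich -> burden -> candidate report.

The driver mirrors the analysis flow the package implements end to end: the
prioritized gene list feeds the overrepresentation test; the genes of the
top enriched term(s) (or all genes, by flag) feed the burden scan; variants
in burden-significant genes feed the candidate report, optionally ranked by
a user-supplied gene-by-tissue expression table. Every run writes TSV stage
outputs plus a machine-readable JSON manifest.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .burden import (
    GeneBurdenResult,
    QualifyingCriteria,
    run_burden_scan,
)
from .enrichment import EnrichmentResult, run_enrichment
from .io import (
    read_cohort_vcf,
    read_control_summary,
    read_gene_list,
    read_gene_sets,
)
from .models import CohortTable, Zygosity
from .prioritize import (
    AlleleRatioBounds,
    PrioritizationCriteria,
    PrioritizedSet,
    prioritize,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class CandidateRow:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    zygosity: str
    sift: float | None
    polyphen: float | None
    mutation_taster: str | None
    predictsnp2_benign_count: int | None
    significant_dom: bool
    significant_rec: bool
    expression_rank: int | None = None


REQUIRED_CONFIG = ("cases_vcf", "control_summary", "gene_sets", "out_dir")


def _criteria_from_config(config: dict):
    pc = PrioritizationCriteria(
        maf_max_snv=config.get("maf_max", 0.001),
        maf_max_indel=config.get("maf_max", 0.001),
        recurrence_max_samples=config.get("recurrence_max", 5),
    )
    bounds = AlleleRatioBounds(
        het_low=config.get("ar_het_low", 0.35),
        het_high=config.get("ar_het_high", 0.65),
        hom_min=config.get("ar_hom_min", 0.9),
    )
    qc = QualifyingCriteria(
        min_depth=config.get("burden_min_depth", 10),
        sift_max=config.get("burden_sift_max", 0.05),
        polyphen_min=config.get("burden_polyphen_min", 0.8),
        maf_max=config.get("burden_maf_max", 0.01),
    )
    return pc, bounds, qc


def write_prioritized(pset: PrioritizedSet, cohort: CohortTable, out_dir: Path) -> None:
    with open(out_dir / "prioritized_variants.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "gene", "sample",
                    "zygosity", "allele_ratio", "sift", "polyphen", "maf"])
        for key, sample in pset.surviving:
            v = cohort.variant(key)
            call = cohort.calls(key)[sample]
            w.writerow([v.chrom, v.pos, v.ref, v.alt, v.gene, sample,
                        call.zygosity.value,
                        f"{call.alt_read_count / call.depth:.4f}",
                        v.sift, v.polyphen, v.maf_or_zero])
    (out_dir / "gene_list.txt").write_text("\n".join(pset.gene_list) + "\n")
    with open(out_dir / "attrition.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["filter", "removed"])
        for name, n in pset.attrition.items():
            w.writerow([name, n])
        w.writerow(["surviving", len(pset.surviving)])


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term_id": r.term_id, "term_name": r.term_name, "k": r.k, "n": r.n,
          "K": r.K, "M": r.M, "expected": r.expected, "direction": r.direction,
          "fold": r.fold, "p_value": r.p_value, "fdr": r.fdr,
          "significant": r.significant} for r in results]
    )


def burden_frame(results: list[GeneBurdenResult]) -> pd.DataFrame:
    """Tabulate per-gene burden results, mirroring the published table layout
    (case HET/HOM/CH and AC, control totals, p and FDR per model)."""
    return pd.DataFrame(
        [{"gene": r.gene,
          "case_het": r.case.het_carriers, "case_hom": r.case.hom_carriers,
          "case_ch": r.case.ch_carriers, "case_total_ac": r.case.total_ac,
          "control_total_ac": r.control.control_ac_sum,
          "control_nhom": r.control.control_nhom_sum,
          "p_dom": r.p_dom, "fdr_dom": r.fdr_dom,
          "p_rec": r.p_rec, "fdr_rec": r.fdr_rec} for r in results]
    )


def read_expression_table(path: str | Path) -> pd.Series:
    """Gene-by-tissue TSV (first column gene) -> mean expression per gene."""
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    return df.set_index(gene_col).mean(axis=1, numeric_only=True)


def candidate_report(
    burden_results: list[GeneBurdenResult],
    cohort: CohortTable,
    qualifying_by_gene: dict[str, dict] | None = None,
    expression: pd.Series | None = None,
    alpha: float = 0.05,
) -> list[CandidateRow]:
    """Variant-level rows for genes significant under either model.

    Significant genes are the union of dominant and recessive FDR < alpha.
    One row per qualifying (variant, carrier) pair in those genes; when an
    expression table is supplied, genes are ranked by mean expression
    (descending, rank 1 = highest) and rows sorted accordingly. A gene
    absent from the table gets no rank, not an error.
    """
    sig = {
        r.gene: (r.fdr_dom < alpha, r.fdr_rec < alpha)
        for r in burden_results
        if (r.fdr_dom < alpha) or (r.fdr_rec < alpha)
    }
    ranks: dict[str, int] = {}
    if expression is not None and sig:
        means = expression.reindex(sorted(sig)).dropna().sort_values(ascending=False)
        ranks = {g: i + 1 for i, g in enumerate(means.index)}

    rows: list[CandidateRow] = []
    for r in burden_results:
        if r.gene not in sig:
            continue
        keys = (
            list(qualifying_by_gene.get(r.gene, {}))
            if qualifying_by_gene is not None
            else [v.key for v in cohort.variants if v.gene == r.gene]
        )
        for key in sorted(keys):
            v = cohort.variant(key)
            for sample, call in sorted(cohort.calls(key).items()):
                rows.append(CandidateRow(
                    gene=r.gene, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    sample=sample, zygosity=call.zygosity.value,
                    sift=v.sift, polyphen=v.polyphen,
                    mutation_taster=(v.mutation_taster.value if v.mutation_taster else None),
                    predictsnp2_benign_count=v.predictsnp2_benign_count,
                    significant_dom=sig[r.gene][0], significant_rec=sig[r.gene][1],
                    expression_rank=ranks.get(r.gene),
                ))
    rows.sort(key=lambda row: (row.expression_rank if row.expression_rank is not None
                               else 10**9, row.gene, row.pos, row.sample))
    return rows


def candidate_frame(rows: list[CandidateRow]) -> pd.DataFrame:
    cols = ["gene", "chrom", "pos", "ref", "alt", "sample", "zygosity", "sift",
            "polyphen", "mutation_taster", "predictsnp2_benign_count",
            "significant_dom", "significant_rec", "expression_rank"]
    return pd.DataFrame([row.__dict__ for row in rows], columns=cols)


def run_pipeline(config: dict) -> Path:
    """Execute all stages per the config mapping; returns the artifact dir.

    Required keys: cases_vcf, control_summary, gene_sets, out_dir. The
    background universe defaults to all genes in the gene-set collection.
    Burden is restricted to the genes of the top significant enrichment
    term(s) unless ``burden_all_genes`` is set.
    """
    for key in REQUIRED_CONFIG:
        if key not in config:
            raise StageError("config", f"missing required field {key!r}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    pc, bounds, qc = _criteria_from_config(config)
    alpha = config.get("alpha", 0.05)

    stage = "load"
    try:
        cohort = read_cohort_vcf(config["cases_vcf"], config.get("field_map"))
        control = read_control_summary(config["control_summary"])
        if config.get("background"):
            background = read_gene_list(config["background"])
        else:
            background = None

        stage = "prioritize"
        pset = prioritize(cohort, pc, bounds)
        write_prioritized(pset, cohort, out_dir)

        stage = "enrich"
        if background is None:
            # default universe: every gene in the collection's terms
            import itertools
            with open(config["gene_sets"]) as fh:
                background = set(itertools.chain.from_iterable(
                    line.rstrip("\n").split("\t")[2:] for line in fh if line.strip()))
        collection = read_gene_sets(config["gene_sets"], background)
        gene_list = set(pset.gene_list) & background
        dropped = len(pset.gene_list) - len(gene_list)
        if dropped:
            logger.warning("enrich: %d prioritized gene(s) outside background dropped",
                           dropped)
        enr = run_enrichment(gene_list, collection, alpha=alpha)
        enrichment_frame(enr).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

        stage = "burden"
        if config.get("burden_all_genes"):
            subset = None
            top_terms: list[str] = []
        else:
            sig_terms = [r for r in enr if r.significant and r.direction == "over"]
            chosen = sig_terms[: config.get("n_top_terms", 1)] or enr[:1]
            top_terms = [r.term_id for r in chosen]
            subset = set()
            for r in chosen:
                subset |= set(collection.terms[r.term_id][1])
        burden_results = run_burden_scan(
            cohort, control, criteria=qc, gene_subset=subset,
            control_n=config.get("control_n", 125_748),
            recessive_strategy=config.get("recessive_strategy", "reported_hom"),
        )
        burden_frame(burden_results).to_csv(out_dir / "burden.tsv", sep="\t", index=False)

        stage = "report"
        expression = (read_expression_table(config["expression_table"])
                      if config.get("expression_table") else None)
        from .burden import select_qualifying
        qset = select_qualifying(cohort, qc)
        rows = candidate_report(burden_results, cohort, qset.by_gene,
                                expression=expression, alpha=alpha)
        candidate_frame(rows).to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "version": __version__,
        "stages": ["prioritize", "enrich", "burden", "report"],
        "inputs": {k: str(config[k]) for k in REQUIRED_CONFIG if k in config},
        "thresholds": {
            "maf_max": pc.maf_max_snv, "recurrence_max": pc.recurrence_max_samples,
            "ar": [bounds.het_low, bounds.het_high, bounds.hom_min],
            "burden": {"min_depth": qc.min_depth, "sift_max": qc.sift_max,
                       "polyphen_min": qc.polyphen_min, "maf_max": qc.maf_max},
            "alpha": alpha,
        },
        "seed": config.get("seed"),
        "n_cases": cohort.n_cases,
        "n_variants": len(cohort.variants),
        "n_prioritized_pairs": len(pset.surviving),
        "n_prioritized_genes": len(pset.gene_list),
        "top_terms": top_terms,
        "n_burden_genes": len(burden_results),
        "n_significant_dom": sum(r.fdr_dom < alpha for r in burden_results),
        "n_significant_rec": sum(r.fdr_rec < alpha for r in burden_results),
        "n_candidate_rows": len(rows),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
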