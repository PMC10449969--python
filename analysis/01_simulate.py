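"""Generate the study-condition synthetic inputs.

Draws one 50-case cohort over 200 genes (10 sites per gene at control
allele frequency 5e-4, three genes spiked at 20x the control carrier rate),
with 10% artifact calls and three recurrent-artifact sites, plus the
matched control summary (N = 125,748), a 40-term gene-set collection whose
spiked term holds the spiked genes, and the ground-truth labels.

Writes results/sim/{cases.vcf, controls.tsv, sets.gmt, background.txt,
truth.json}.
"""

import argparse
from pathlib import Path

from rareburden.io import write_cohort_vcf, write_control_summary, write_gene_sets
from rareburden.simulate import (
    CohortSimSpec,
    simulate_cohort,
    simulate_control_summary,
    simulate_gene_sets,
    spiked_gene_catalogue,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out-dir", type=Path, default=Path("results/sim"))
args = parser.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
spec = CohortSimSpec(
    seed=args.seed,
    genes=spiked_gene_catalogue(),
    artifact_fraction=0.10,
    n_recurrent_artifact_sites=3,
    deleterious_prob=0.9,
)
cohort, truth = simulate_cohort(spec)
write_cohort_vcf(cohort, args.out_dir / "cases.vcf")
write_control_summary(simulate_control_summary(spec), args.out_dir / "controls.tsv")

spiked = sorted(g for g, m in truth.spiked_genes.items() if m == "dom")
collection, set_truth = simulate_gene_sets(
    [g.name for g in spec.genes], n_terms=40, spiked_term_genes=spiked,
    seed=args.seed + 2,
)
truth.spiked_terms = set_truth.spiked_terms
write_gene_sets(collection, args.out_dir / "sets.gmt")
(args.out_dir / "background.txt").write_text(
    "\n".join(sorted(g.name for g in spec.genes)) + "\n")
truth.to_json(args.out_dir / "truth.json")

n_calls = sum(len(c) for c in cohort.genotypes.values())
print(f"cohort: {len(cohort.variants)} sites x {cohort.n_cases} cases, "
      f"{n_calls} non-reference calls")
print(f"spiked genes: {', '.join(spiked)} (dominant, 20x)")
print(f"artifact calls: {len(truth.artifact_calls)}; "
      f"recurrent sites: {len(truth.recurrent_sites)}")
print(f"wrote {args.out_dir}/")
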