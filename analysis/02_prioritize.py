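"""Run the variant-filtering cascade on the simulated cohort.

Applies the deleteriousness consensus + MAF rule, allele-ratio QC and the
recurrence filter, then collapses survivors to the deduplicated gene list.
Reports the attrition ledger and checks survivors against the generator's
truth labels.

Reads results/sim/; writes results/prioritize/.
"""

import argparse
import json
from pathlib import Path

from rareburden.io import read_cohort_vcf
from rareburden.pipeline import write_prioritized
from rareburden.prioritize import prioritize

parser = argparse.ArgumentParser()
parser.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
parser.add_argument("--out-dir", type=Path, default=Path("results/prioritize"))
args = parser.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
cohort = read_cohort_vcf(args.sim_dir / "cases.vcf")
result = prioritize(cohort)
write_prioritized(result, cohort, args.out_dir)

# sanity check against the generator's labels: no labelled artifact call
# may survive the cascade
truth = json.loads((args.sim_dir / "truth.json").read_text())
artifact_pairs = set(truth["artifact_calls"])
surviving_ids = {"|".join(map(str, key)) + "@" + sample
                 for key, sample in result.surviving}
leaked = surviving_ids & artifact_pairs
print(f"labelled artifact calls surviving QC: {len(leaked)} (expect 0)")

print("attrition ledger (calls removed, first-failing filter):")
for name, n in result.attrition.items():
    print(f"  {name:15s} {n}")
print(f"  {'surviving':15s} {len(result.surviving)}")
print(f"collapsed gene list: {len(result.gene_list)} genes "
      f"-> {args.out_dir}/gene_list.txt")
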