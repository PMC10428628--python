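#!/usr/bin/env python
"""Cross-validated prediction accuracy of all four model families.

Scenario I: random 80/20 line-level splits within environments; scenario II:
forward prediction of the last environment from designated training sets
(DT1: one earlier environment via genotype-effect transfer; DT2: the other
two environments; DT3: all three).  Writes tidy accuracy tables, a
pivot in the environment x trait layout with Tukey-Kramer letters, and the
relative-improvement summary under results/.

Chain lengths and cycle counts here are the reduced defaults; pass
--cycles/--full for longer runs.
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import maizegp as mg
from maizegp import io
from maizegp.evaluate import pivot_accuracy_table, run_scenario_two, summarize_accuracy

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=4)
parser.add_argument("--cycles", type=int, default=3)
parser.add_argument("--full", action="store_true",
                    help="full-length chains (100k iterations) and 50 cycles")
parser.add_argument("--out-dir", default="results")
args = parser.parse_args()

adjusted = io.read_phenotypes_csv(os.path.join(args.out_dir, "phenotypes_adjusted.csv"))
grm = io.read_kinship_tsv(os.path.join(args.out_dir, "kinship_vanraden.tsv"))

if args.full:
    settings = mg.MCMCSettings(seed=args.seed)
    cycles = 50
else:
    settings = mg.MCMCSettings.tiny(args.seed)
    cycles = args.cycles

# scenario I on two environments keeps the reduced run quick
cv_records = adjusted[adjusted.environment.isin(["ENV1", "ENV2"])]
table = mg.run_scenario_one(
    cv_records, grm,
    models=["mcmc_mixed", "bgge", "bmtme", "dl"],
    approaches=["UTUE", "UTME", "MTUE", "MTME"],
    scheme=mg.CVScheme(train_fraction=0.8, n_cycles=cycles, seed=args.seed),
    settings=settings,
    mlp_config=mg.MLPConfig(epochs=50, seed=args.seed),
)
table.to_csv(os.path.join(args.out_dir, "cv1_accuracy.tsv"), sep="\t", index=False)
pivot = pivot_accuracy_table(table)
pivot.to_csv(os.path.join(args.out_dir, "cv1_accuracy_pivot.csv"))
print("scenario I mean accuracy by approach:")
print(summarize_accuracy(table).groupby("approach")["mean_pearson_r"].mean().round(3).to_string())

letters = mg.compare_models(
    table[table.approach == "UTUE"], {"environment": "ENV1", "trait": "FF"}, alpha=0.01
)
print("Tukey-Kramer letters (UTUE, ENV1, FF):", letters)

gains = {
    "multi_trait_gain_pct": mg.relative_improvement(
        table[table.model.isin(["mcmc_mixed", "dl"])], {"approach": "UTUE"}, {"approach": "MTUE"}
    ),
    "multi_env_gain_pct": mg.relative_improvement(
        table, {"approach": "UTUE"}, {"approach": "UTME"}
    ),
}
print({k: round(v, 1) for k, v in gains.items()})

# scenario II: predict ENV4 forward
sets = {"DT1": ["ENV3"], "DT2": ["ENV1", "ENV2"], "DT3": ["ENV1", "ENV2", "ENV3"]}
frames = []
for dt, models in (("DT1", ["mcmc_mixed", "dl"]),
                   ("DT2", ["bgge", "bmtme", "dl"]),
                   ("DT3", ["bgge", "bmtme", "dl"])):
    t2 = run_scenario_two(adjusted, grm, models, dt, sets, "ENV4",
                          settings=settings, mlp_config=mg.MLPConfig(epochs=50, seed=args.seed))
    frames.append(t2)
    print(f"scenario II {dt}: mean accuracy {t2['pearson_r'].mean():.3f}")
import pandas as pd

pd.concat(frames, ignore_index=True).to_csv(
    os.path.join(args.out_dir, "cv2_accuracy.tsv"), sep="\t", index=False
)
with open(os.path.join(args.out_dir, "cv_gains.json"), "w") as fh:
    json.dump(gains, fh, indent=1)
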