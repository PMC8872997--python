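"""Compare the two scores' loading patterns.

Correlates the two 42-length loading vectors and attaches an empirical
p-value from a joint-shuffle permutation null (scores shuffled together
against the fixed asymmetry matrix, both CCAs re-fit per draw), then
classifies concordant/discordant regions at the |loading| > 0.2 threshold.
"""

import json
import runpy

import pandas as pd

from asymlink import compare_loading_patterns, read_cohort

cfg = runpy.run_path(__file__.replace("04_compare_patterns", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])
ai = pd.read_csv(cfg["RESULTS"] / "ai_withsex.tsv", sep="\t")

comp = compare_loading_patterns(
    cohort.table.score_ASD, cohort.table.score_SCZ, ai,
    n_perm=cfg["N_PERMUTATIONS"], seed=cfg["SEED"],
)
print(f"loading-pattern correlation r = {comp.observed_r:.3f}, "
      f"permuted p = {comp.empirical_p:.3g} ({comp.n_permutations} permutations)")
print(f"concordant regions (both |loading| > 0.2, same sign): "
      f"{comp.concordant_regions or 'none'}")
print(f"discordant regions: {comp.discordant_regions or 'none'}")

with open(cfg["RESULTS"] / "pattern_comparison.json", "w") as fh:
    json.dump({"observed_r": comp.observed_r, "empirical_p": comp.empirical_p,
               "n_permutations": comp.n_permutations,
               "concordant": comp.concordant_regions,
               "discordant": comp.discordant_regions}, fh, indent=2)
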