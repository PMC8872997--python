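"""Sex-difference map of the asymmetries and its similarity to each
score's loading pattern.

Per-region two-sample t statistics (female=1; positive t = leftward shift
in females) on AIs adjusted without sex, correlated across regions with
each score's loadings; significance from sex-label permutations.
"""

import json
import runpy

import numpy as np
import pandas as pd

from asymlink import read_cohort, scalar_cca, sex_pattern_correlation, sex_ttests

cfg = runpy.run_path(__file__.replace("05_sex_difference_map", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])
ai_nosex = pd.read_csv(cfg["RESULTS"] / "ai_nosex.tsv", sep="\t")
ai_withsex = pd.read_csv(cfg["RESULTS"] / "ai_withsex.tsv", sep="\t")

sex_map = sex_ttests(ai_nosex, cohort.table.sex)
sex_map.table().to_csv(cfg["RESULTS"] / "sex_map.tsv", sep="\t", index=False,
                       float_format="%.10g")
print(f"{int(np.sum(sex_map.p_values < 0.05))} of 42 regions sex-associated "
      f"at unadjusted p < 0.05")

out = {}
for score in ("score_ASD", "score_SCZ"):
    loadings = scalar_cca(cohort.table[score], ai_withsex).loadings
    r, p, _ = sex_pattern_correlation(sex_map, loadings, ai_nosex, cohort.table.sex,
                                      n_perm=cfg["N_PERMUTATIONS"], seed=cfg["SEED"])
    out[score] = {"r": r, "empirical_p": p}
    print(f"sex t-map vs {score} loadings: r = {r:.3f}, permuted p = {p:.3g}")

with open(cfg["RESULTS"] / "sex_similarity.json", "w") as fh:
    json.dump(out, fh, indent=2)
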