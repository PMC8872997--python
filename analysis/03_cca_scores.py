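"""Scalar canonical correlation of each polygenic score with the 42 AIs.

With a scalar score, the canonical correlation equals the multiple
correlation of the score on the asymmetry columns; loadings (the per-region
correlations with the canonical variate) are the interpretive output.
"""

import json
import runpy

import pandas as pd

from asymlink import read_cohort, scalar_cca

cfg = runpy.run_path(__file__.replace("03_cca_scores", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])
ai = pd.read_csv(cfg["RESULTS"] / "ai_withsex.tsv", sep="\t")

summary = {}
for score in ("score_ASD", "score_SCZ"):
    res = scalar_cca(cohort.table[score], ai)
    res.loading_table().to_csv(cfg["RESULTS"] / f"loadings_{score}.tsv",
                               sep="\t", index=False, float_format="%.10g")
    summary[score] = {"canonical_r": res.canonical_r, "p_value": res.p_value,
                      "n": res.n}
    print(f"{score}: canonical r = {res.canonical_r:.4f}, "
          f"p = {res.p_value:.3g} (n = {res.n})")

with open(cfg["RESULTS"] / "cca_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
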