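"""Type-driven phenome-wide scan of each score with per-score FDR control.

Continuous phenotypes are inverse-normal transformed and fit linearly;
binary, ordered, and unordered categorical phenotypes use logistic,
proportional-odds, and multinomial models; Benjamini-Hochberg adjustment
at q = 0.05 runs separately per score.
"""

import runpy

from asymlink import build_covariate_design, read_cohort, run_phewas

cfg = runpy.run_path(__file__.replace("07_phewas_scan", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])
design = build_covariate_design(cohort.table, include_sex=True)

for score in ("score_ASD", "score_SCZ"):
    res = run_phewas(cohort.table, score, list(cohort.codebook),
                     codebook=cohort.codebook, design=design, q=0.05)
    res.table.to_csv(cfg["RESULTS"] / f"phewas_{score}.tsv", sep="\t",
                     index=False, float_format="%.10g")
    hits = res.table[res.table.discovery]
    print(f"{score}: {res.n_discoveries} of {len(res.table)} phenotypes at FDR 0.05"
          + (": " + ", ".join(hits.phenotype) if len(hits) else ""))
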