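"""Six logistic regressions of handedness contrasts on the two scores.

Left vs right, mixed vs right, and non-right (left + mixed) vs right,
each on one score plus the standard covariates; coefficients are log-odds
per SD of score.
"""

import runpy

from asymlink import build_covariate_design, fit_handedness_models, read_cohort

cfg = runpy.run_path(__file__.replace("06_handedness_contrasts", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])
design = build_covariate_design(cohort.table, include_sex=True)
out = fit_handedness_models(cohort.table, design=design)
out.to_csv(cfg["RESULTS"] / "handedness.tsv", sep="\t", index=False,
           float_format="%.10g")
print(out[["contrast", "score", "beta", "se", "p", "n_cases"]].to_string(index=False))
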