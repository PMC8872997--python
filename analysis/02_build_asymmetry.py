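"""Preprocess paired measures into adjusted asymmetry matrices.

Applies the 6 SD outlier rule per unilateral measure, computes the
asymmetry index (L - R)/((L + R)/2), rank-based inverse normalization,
and covariate residualization — once with sex in the confound design (for
the polygenic-score analyses) and once without (for the sex-difference
map).
"""

import runpy

from asymlink import prepare_asymmetry_matrix, read_cohort

cfg = runpy.run_path(__file__.replace("02_build_asymmetry", "00_config"))
cohort = read_cohort(cfg["COHORT_PREFIX"])

for tag, include_sex in (("withsex", True), ("nosex", False)):
    ai = prepare_asymmetry_matrix(cohort, include_sex=include_sex)
    ai.write(str(cfg["RESULTS"] / f"ai_{tag}"))
    print(f"ai_{tag}: {ai.n} x {ai.p}, complete cases {ai.provenance['n_complete']}, "
          f"outliers removed {sum(ai.provenance['outlier_removals'].values())}")
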