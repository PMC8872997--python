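"""Sex-difference t-maps and their permutation-tested similarity to
loading patterns."""

import numpy as np
import pytest
from scipy import stats

from asymlink import (
    SimulationConfig,
    prepare_asymmetry_matrix,
    scalar_cca,
    sex_pattern_correlation,
    sex_ttests,
    simulate_cohort,
)
from asymlink.sex_analysis import _pooled_t_batch


def test_pooled_t_matches_scipy(rng):
    X = rng.standard_normal((60, 4))
    s = (rng.random(60) < 0.5).astype(float)
    T = _pooled_t_batch(X, s[:, None])[:, 0]
    for j in range(4):
        t_ref, _ = stats.ttest_ind(X[s == 1, j], X[s == 0, j], equal_var=True)
        assert T[j] == pytest.approx(t_ref, abs=1e-12)


def test_t_zero_for_identical_group_values():
    # same values in both sex groups: group means coincide exactly
    vals = np.repeat(np.arange(10.0), 2)
    sex = np.tile([0, 1], 10)
    out = sex_ttests(vals[:, None], sex)
    assert out.t_values[0] == pytest.approx(0.0, abs=1e-12)


def test_sign_convention_recovers_planted_pattern():
    """Positive planted sex effect (females more leftward) gives positive t,
    and the whole t-map correlates strongly with the planted pattern."""
    rng = np.random.default_rng(4)
    pattern = rng.normal(0, 0.3, 42)  # strong per-region effects
    cfg = SimulationConfig(n_individuals=20_000, sex_pattern=pattern,
                           outlier_rate=0.0, seed=19)
    cohort = simulate_cohort(cfg)
    ai_nosex = prepare_asymmetry_matrix(cohort, include_sex=False)
    out = sex_ttests(ai_nosex, cohort.table.sex)
    assert np.corrcoef(out.t_values, pattern)[0, 1] > 0.9
    strongest = int(np.argmax(np.abs(pattern)))
    assert np.sign(out.t_values[strongest]) == np.sign(pattern[strongest])


def test_null_pattern_gives_nominal_rejections():
    cfg = SimulationConfig(n_individuals=8000, sex_pattern=np.zeros(42),
                           score_sex_shift=0.0, outlier_rate=0.0, seed=23)
    cohort = simulate_cohort(cfg)
    ai_nosex = prepare_asymmetry_matrix(cohort, include_sex=False)
    out = sex_ttests(ai_nosex, cohort.table.sex)
    assert (out.p_values < 0.05).mean() < 0.25  # ~5% expected over 42 columns


def test_small_group_errors():
    X = np.random.default_rng(0).standard_normal((5, 2))
    with pytest.raises(ValueError, match="fewer than 2"):
        sex_ttests(X, np.array([1, 1, 1, 1, 0]))
    with pytest.raises(ValueError, match="0/1"):
        sex_ttests(X, np.array([1, 2, 1, 2, 1]))


def test_self_similarity_and_determinism(clean_cohort):
    ai_nosex = prepare_asymmetry_matrix(clean_cohort, include_sex=False)
    out = sex_ttests(ai_nosex, clean_cohort.table.sex)
    r, p, null = sex_pattern_correlation(
        out, out.t_values, ai_nosex, clean_cohort.table.sex, n_perm=50, seed=6
    )
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p == pytest.approx(1.0 / 51.0)
    r2, p2, null2 = sex_pattern_correlation(
        out, out.t_values, ai_nosex, clean_cohort.table.sex, n_perm=50, seed=6
    )
    assert (r2, p2) == (r, p)
    np.testing.assert_array_equal(null, null2)


def test_permutation_null_matches_direct_recomputation(clean_cohort):
    """The fast batched null equals per-permutation t-vectors computed
    naively; AI columns themselves are never shuffled."""
    ai_nosex = prepare_asymmetry_matrix(clean_cohort, include_sex=False)
    X = ai_nosex.values.to_numpy()
    s = clean_cohort.table.sex.to_numpy().astype(float)
    out = sex_ttests(ai_nosex, clean_cohort.table.sex)
    loadings = np.random.default_rng(1).normal(size=42)
    _, _, null = sex_pattern_correlation(out, loadings, ai_nosex,
                                         clean_cohort.table.sex, n_perm=5, seed=77)
    rng = np.random.default_rng(77)
    for k in range(5):
        sp = rng.permutation(s)
        t = np.array([
            stats.ttest_ind(X[sp == 1, j], X[sp == 0, j], equal_var=True)[0]
            for j in range(X.shape[1])
        ])
        assert null[k] == pytest.approx(np.corrcoef(t, loadings)[0, 1], abs=1e-10)


def test_refit_variant_runs(clean_cohort):
    ai_nosex = prepare_asymmetry_matrix(clean_cohort, include_sex=False)
    ai_sex = prepare_asymmetry_matrix(clean_cohort, include_sex=True)
    res = scalar_cca(clean_cohort.table.score_ASD, ai_sex)
    out = sex_ttests(ai_nosex, clean_cohort.table.sex)

    def refit(perm_sex):
        # heavier sensitivity variant: re-derive loadings under permuted sex
        from asymlink import build_covariate_design, residualize

        design = build_covariate_design(clean_cohort.table, include_sex=False)
        design = design.assign(sex=perm_sex)
        resid = residualize(ai_nosex.values.to_numpy(), design)
        return scalar_cca(clean_cohort.table.score_ASD, resid).loadings

    r, p, null = sex_pattern_correlation(
        out, res.loadings, ai_nosex, clean_cohort.table.sex,
        n_perm=3, seed=2, refit=refit,
    )
    assert len(null) == 3 and np.isfinite(null).all()
    assert 0 < p <= 1
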