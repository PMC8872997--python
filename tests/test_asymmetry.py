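"""Asymmetry-index construction, outlier rule, rank-normal transform,
and covariate residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from asymlink import (
    SimulationConfig,
    compute_asymmetry_index,
    inverse_normal_transform,
    prepare_asymmetry_matrix,
    remove_outliers,
    residualize,
    simulate_cohort,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "left,right,expected", [(3.0, 3.0, 0.0), (3.0, 1.0, 1.0), (1.0, 3.0, -1.0)]
)
def test_ai_reference_values(left, right, expected):
    assert compute_asymmetry_index(left, right) == pytest.approx(expected, abs=1e-15)


@given(left=positive, right=positive, c=st.floats(min_value=1e-3, max_value=1e3))
def test_ai_antisymmetric_and_scale_invariant(left, right, c):
    ai = compute_asymmetry_index(left, right)
    assert compute_asymmetry_index(right, left) == pytest.approx(-ai, abs=1e-12)
    assert compute_asymmetry_index(c * left, c * right) == pytest.approx(
        ai, rel=1e-9, abs=1e-12
    )


def test_ai_rejects_nonpositive_with_row_context():
    with pytest.raises(ValueError, match="right.*rows.*\\[1\\]"):
        compute_asymmetry_index([2.0, 2.0], [1.0, -1.0])


def test_outlier_removal_single_extreme():
    col = np.array([0.0] * 99 + [100.0])
    cleaned, n = remove_outliers(col)
    assert n == 1
    assert np.isnan(cleaned[-1]) and np.isfinite(cleaned[:-1]).all()


def test_outlier_removal_normal_column(rng):
    # P(|Z| > 6) ~ 2e-9: essentially nothing removed at n = 1e5
    _, n = remove_outliers(rng.standard_normal(100_000))
    assert n <= 2


def test_outlier_removal_constant_column_warns():
    with pytest.warns(RuntimeWarning, match="zero SD"):
        cleaned, n = remove_outliers(np.ones(10))
    assert n == 0 and (cleaned == 1).all()


def test_outlier_rule_not_iterated():
    # after removing 100, the column 0...0 is constant; a second pass would
    # remove nothing anyway, but the rule must use pre-removal mean/SD once
    col = np.array([0.0] * 50 + [1.0] * 49 + [100.0])
    cleaned, n = remove_outliers(col)
    assert n == 1 and np.isfinite(cleaned[:-1]).all()


def test_inverse_normal_blom_three_values():
    out = inverse_normal_transform([10.0, -5.0, 3.0])
    # ranks 3, 1, 2 with m=3: quantiles (3-3/8)/3.25, (1-3/8)/3.25, 0.5
    expected = stats.norm.ppf([(3 - 0.375) / 3.25, (1 - 0.375) / 3.25, 0.5])
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert out[2] == 0.0  # middle value maps exactly to the median


def test_inverse_normal_tie_handling():
    out = inverse_normal_transform([1.0, 2.0, 2.0, 5.0])
    assert out[1] == out[2]
    assert out[0] < out[1] < out[3]


def test_inverse_normal_monotone_and_missing(rng):
    x = rng.standard_normal(50)
    x[7] = np.nan
    out = inverse_normal_transform(x)
    assert np.isnan(out[7])
    obs = np.isfinite(x)
    order = np.argsort(x[obs])
    assert (np.diff(out[obs][order]) >= 0).all()


def test_inverse_normal_output_near_symmetric(rng):
    # normal scores of any input are close to symmetric: |skewness| small
    x = rng.exponential(size=500)  # strongly skewed input
    out = inverse_normal_transform(x)
    assert abs(stats.skew(out)) < 0.05


def test_inverse_normal_invariant_to_monotone_maps(rng):
    x = rng.standard_normal(200)
    np.testing.assert_allclose(
        inverse_normal_transform(np.exp(2 * x) + 5),
        inverse_normal_transform(x),
        atol=1e-12,
    )


def test_inverse_normal_requires_distinct_values():
    with pytest.raises(ValueError):
        inverse_normal_transform(np.ones(5))


def test_residualize_intercept_only_centers(rng):
    x = rng.standard_normal(30) + 3.0
    out = residualize(x, pd.DataFrame(index=range(30)))
    np.testing.assert_allclose(out, x - x.mean(), atol=1e-12)


def test_residualize_orthogonality_and_idempotence(rng):
    n = 500
    age = rng.uniform(45, 81, n)
    design = pd.DataFrame({"age": age})
    y = 2 * age + rng.standard_normal(n)
    r1 = residualize(y, design)
    assert abs(np.corrcoef(r1, age)[0, 1]) < 1e-6
    r2 = residualize(r1, design)
    np.testing.assert_allclose(r1, r2, atol=1e-9)


def test_residualize_handles_missing_per_column(rng):
    n = 200
    design = pd.DataFrame({"z": rng.standard_normal(n)})
    M = rng.standard_normal((n, 2))
    M[5, 0] = np.nan
    out = residualize(M, design)
    assert np.isnan(out[5, 0]) and np.isfinite(out[:, 1]).all()
    obs = np.isfinite(out[:, 0])
    assert abs(np.corrcoef(out[obs, 0], design.z[obs])[0, 1]) < 1e-6


def test_residualize_rank_deficient_names_columns(rng):
    z = rng.standard_normal(50)
    design = pd.DataFrame({"z": z, "z2": 2 * z})
    with pytest.raises(np.linalg.LinAlgError, match="z2"):
        residualize(rng.standard_normal(50), design)


def test_prepared_matrix_shape_and_classes(clean_cohort, clean_ai):
    assert clean_ai.p == 42
    assert clean_ai.measure_class.count("surface_area") == 28
    assert clean_ai.measure_class.count("thickness") == 8
    assert clean_ai.measure_class.count("volume") == 6
    assert clean_ai.provenance["n_complete"] == clean_cohort.n  # outlier-free


def test_prepared_matrix_centered_and_orthogonal(clean_ai):
    V = clean_ai.values.to_numpy()
    assert np.abs(V.mean(axis=0)).max() < 1e-8
    D = clean_ai.design.to_numpy(float)
    for j in range(D.shape[1]):
        d = D[:, j]
        if d.std() == 0:
            continue
        corr = (V.T @ (d - d.mean())) / (
            np.linalg.norm(V, axis=0) * np.linalg.norm(d - d.mean())
        )
        assert np.abs(corr).max() < 1e-6


def test_missing_ai_when_either_side_removed():
    # at low injection rates the injected points barely inflate the column
    # SD, so the 6 SD rule catches every >= 7 SD replacement
    cfg = SimulationConfig(n_individuals=4000, outlier_rate=1e-3, seed=9)
    cohort = simulate_cohort(cfg)
    ai = prepare_asymmetry_matrix(cohort)
    for col, rows in cohort.outlier_positions.items():
        region = col.replace("left_", "").replace("right_", "")
        assert ai.values[region].iloc[rows].isna().all()


def test_ai_level_outlier_option_runs(clean_cohort):
    ai = prepare_asymmetry_matrix(clean_cohort, outlier_on="ai")
    assert ai.p == 42
    with pytest.raises(ValueError):
        prepare_asymmetry_matrix(clean_cohort, outlier_on="bogus")
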