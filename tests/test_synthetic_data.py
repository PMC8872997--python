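"""Generator fidelity: planted parameters are present in the sampled cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asymlink import (
    ParameterError,
    SimulationConfig,
    compute_asymmetry_index,
    simulate_cohort,
)
from asymlink.synthetic_data import (
    generate_handedness,
    generate_phenotypes,
    generate_scores,
    write_cohort,
    read_cohort,
)


@pytest.mark.parametrize("rho", [0.0, 0.08])
def test_score_correlation_matches_planted(rho):
    cfg = SimulationConfig(n_individuals=100_000, score_correlation=rho,
                           score_sex_shift=0.0, seed=1)
    df = generate_scores(cfg, np.random.default_rng(1))
    r = np.corrcoef(df.score_ASD, df.score_SCZ)[0, 1]
    assert abs(r - rho) < 0.01
    # z-scaling within cohort
    for col in ("score_ASD", "score_SCZ"):
        assert abs(df[col].mean()) < 1e-12
        assert abs(df[col].std(ddof=0) - 1) < 1e-12


def test_female_score_shift_gives_positive_t():
    cfg = SimulationConfig(n_individuals=100_000, score_sex_shift=0.04, seed=2)
    df = generate_scores(cfg, np.random.default_rng(2))
    t, _ = stats.ttest_ind(df.score_ASD[df.sex == 1], df.score_ASD[df.sex == 0])
    assert t > 0
    assert df.score_ASD[df.sex == 1].mean() > df.score_ASD[df.sex == 0].mean()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"score_correlation": 1.2},
        {"score_sex_shift": np.inf},
        {"canonical_r_A": 1.0},
        {"canonical_r_B": -0.1},
        {"handedness_base_rates": (0.5, 0.4, 0.2)},
        {"outlier_rate": 1.5},
        {"loading_pattern_A": [1.0] * 42},  # not unit norm
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        SimulationConfig(**kwargs).validate()


def test_handedness_rates_recovered():
    rates = (0.89, 0.095, 0.015)
    cfg = SimulationConfig(
        n_individuals=100_000,
        handedness_base_rates=rates,
        handedness_betas={"score_ASD": (0.0, 0.0), "score_SCZ": (0.0, 0.0)},
        seed=3,
    )
    scores = generate_scores(cfg, np.random.default_rng(3))
    hand = generate_handedness(cfg, scores, np.random.default_rng(4))
    observed = hand.value_counts(normalize=True)
    for level, rate in zip(("right", "left", "mixed"), rates):
        assert abs(observed[level] - rate) < 0.005


def test_handedness_degenerate_simplex_all_right():
    cfg = SimulationConfig(n_individuals=500, handedness_base_rates=(1.0, 0.0, 0.0),
                           seed=5)
    scores = generate_scores(cfg, np.random.default_rng(5))
    hand = generate_handedness(cfg, scores, np.random.default_rng(5))
    assert (hand == "right").all()


def test_cohort_deterministic_and_byte_identical(tmp_path):
    cfg = SimulationConfig(n_individuals=400, seed=11)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a.table, b.table)
    write_cohort(a, str(tmp_path / "a"))
    write_cohort(b, str(tmp_path / "b"))
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    back = read_cohort(str(tmp_path / "a"))
    assert back.region_labels == a.region_labels
    assert back.config.seed == cfg.seed


def test_asymmetry_roundtrip_exact(clean_cohort):
    """The AI formula inverts the L/R construction to machine precision."""
    labels = clean_cohort.region_labels
    L = clean_cohort.table[[f"left_{l}" for l in labels]].to_numpy()
    R = clean_cohort.table[[f"right_{l}" for l in labels]].to_numpy()
    ai = compute_asymmetry_index(L, R)
    assert np.abs(ai - clean_cohort.latent_asymmetry).max() < 1e-12


def test_inverse_construction_example():
    # a = 0.5 with bilateral size 2 gives sides 2.5 / 1.5 and AI exactly 0.5
    s, a = 2.0, 0.5
    left, right = s * (1 + a / 2), s * (1 - a / 2)
    assert (left, right) == (2.5, 1.5)
    assert compute_asymmetry_index(left, right) == pytest.approx(0.5, abs=1e-15)


def test_outliers_injected_beyond_six_sd():
    cfg = SimulationConfig(n_individuals=4000, outlier_rate=1e-3, seed=13)
    cohort = simulate_cohort(cfg)
    assert cohort.outlier_positions, "expected injected outliers at this rate"
    for col, rows in cohort.outlier_positions.items():
        x = cohort.table[col].to_numpy()
        z = np.abs(x - x.mean()) / x.std()
        assert (z[rows] > 6).all()
        assert (x[rows] > 0).all()


def test_phenotype_battery_types(small_cohort):
    types = {meta["type"] for meta in small_cohort.codebook.values()}
    assert {"continuous", "binary", "ordered_categorical",
            "unordered_categorical"} <= types
    cfg = small_cohort.config
    scores = small_cohort.table[["sex", "score_ASD", "score_SCZ"]]
    df, codebook = generate_phenotypes(cfg, scores, np.random.default_rng(1))
    assert set(df.columns) == set(codebook)


def test_stage_independence_of_downstream_settings():
    """Scores are identical across cohorts that differ only in phenotype
    configuration (stages draw from independent child streams)."""
    base = SimulationConfig(n_individuals=300, seed=21)
    alt = SimulationConfig(n_individuals=300, seed=21, phenotype_specs=[])
    a, b = simulate_cohort(base), simulate_cohort(alt)
    np.testing.assert_array_equal(a.table.score_ASD, b.table.score_ASD)
    np.testing.assert_array_equal(a.table.left_area_region01, b.table.left_area_region01)
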