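"""Type-driven phenotype screening and Benjamini-Hochberg control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from asymlink import bh_fdr, classify_variable, run_phewas
from asymlink import test_phenotype as phenotype_association  # avoid test collection


def brute_force_bh(p, q=0.05):
    """Literal step-up definition, used as the oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    k = 0
    sorted_p = p[order]
    for i in range(m):
        if sorted_p[i] <= (i + 1) * q / m:
            k = i + 1
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return adj, reject


@pytest.mark.parametrize(
    "values,expected",
    [
        (pd.Series([0, 1, 0, 1, 1]), "binary"),
        (pd.Series(np.linspace(0, 1, 500)), "continuous"),
        (pd.Series(["A", "B", "C"] * 10), "unordered_categorical"),
        (pd.Series([1, 2, 3, 4] * 10), "ordered_categorical"),
        (pd.Series(list(range(50))), "continuous"),  # > k_max integer levels
    ],
)
def test_classify_variable_rules(values, expected):
    assert classify_variable(values) == expected


def test_classify_declared_type_wins_and_degenerate_raises():
    col = pd.Series([1, 2, 3, 4] * 5)
    assert classify_variable(col, declared="continuous") == "continuous"
    with pytest.raises(ValueError, match="single distinct"):
        classify_variable(pd.Series([7, 7, 7]))
    with pytest.raises(ValueError, match="unknown declared"):
        classify_variable(col, declared="fancy")


def test_bh_reference_values():
    adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
    assert rej.all()
    adj, rej = bh_fdr([1.0, 1.0, 1.0])
    assert not rej.any()
    adj, rej = bh_fdr([0.04])
    assert rej[0] and adj[0] == pytest.approx(0.04)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_matches_brute_force_oracle(p):
    adj, rej = bh_fdr(p)
    adj_ref, rej_ref = brute_force_bh(p)
    np.testing.assert_allclose(adj, adj_ref, atol=1e-12)
    np.testing.assert_array_equal(rej, rej_ref)
    assert (adj >= np.asarray(p) - 1e-12).all()  # adjusted p never smaller


def test_planted_continuous_signal_found(rng):
    n = 5000
    s = rng.standard_normal(n)
    table = pd.DataFrame({
        "score": s,
        "signal": 0.3 * s + rng.standard_normal(n),
        "noise": rng.standard_normal(n),
    })
    res = run_phewas(table, "score", ["signal", "noise"])
    row = res.table.set_index("phenotype")
    assert row.loc["signal", "discovery"]
    assert row.loc["signal", "effect"] > 0
    assert not row.loc["noise", "discovery"]


def test_typed_models_recover_planted_effects(rng):
    n = 8000
    s = rng.standard_normal(n)
    # binary via logistic model, ordered via latent-logistic thresholds
    p_bin = 1 / (1 + np.exp(-(-0.5 + 0.3 * s)))
    y_bin = (rng.random(n) < p_bin).astype(int)
    latent = 0.3 * s + rng.logistic(size=n)
    y_ord = np.searchsorted([-1.0, 0.0, 1.0], latent) + 1
    out_bin = phenotype_association(s, pd.Series(y_bin), "binary")
    assert abs(out_bin["effect"] - 0.3) < 4 * out_bin["se"]
    out_ord = phenotype_association(s, pd.Series(y_ord), "ordered_categorical",
                             levels=[1, 2, 3, 4])
    assert abs(out_ord["effect"] - 0.3) < 4 * out_ord["se"]
    assert out_ord["model"] == "ordered_logistic"


def test_unordered_uses_likelihood_ratio(rng):
    n = 6000
    s = rng.standard_normal(n)
    eta = np.column_stack([np.zeros(n), np.zeros(n), 0.4 * s])
    prob = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    y = (rng.random(n)[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)
    out = phenotype_association(s, pd.Series(np.array(list("abc"))[y]),
                         "unordered_categorical")
    assert out["model"] == "multinomial_logistic"
    assert out["p"] < 1e-6


def test_null_scan_calibrated(rng):
    n, m = 2000, 200
    table = pd.DataFrame(rng.standard_normal((n, m)),
                         columns=[f"ph{i}" for i in range(m)])
    table["score"] = rng.standard_normal(n)
    res = run_phewas(table, "score", [f"ph{i}" for i in range(m)])
    frac = (res.table.p < 0.05).mean()
    assert 0.01 < frac < 0.10          # ~5% nominal
    assert res.n_discoveries <= 2      # BH keeps the null scan nearly empty


def test_exclusions_recorded(small_cohort):
    table = small_cohort.table.copy()
    table["degenerate"] = 1.0
    res = run_phewas(
        table, "score_ASD", ["degenerate", "fluid_intelligence", "handedness"],
        codebook=small_cohort.codebook, exclude=("handedness",),
    )
    assert "degenerate" in res.excluded and "single distinct" in res.excluded["degenerate"]
    assert res.excluded["handedness"] == "on exclusion list"
    assert list(res.table.phenotype) == ["fluid_intelligence"]
    assert (res.table.p_adjusted >= res.table.p - 1e-12).all()
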