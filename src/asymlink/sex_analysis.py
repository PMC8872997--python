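"""Per-region sex differences of asymmetry and their similarity to a
polygenic-risk loading pattern.

The sex-difference map is a vector of two-sample t statistics, one per
asymmetry index, computed on AIs residualized *without* sex as a
covariate.  With females coded 1 and males 0, a positive t means an
average leftward shift of asymmetry in females relative to males.

Pattern similarity is the Pearson correlation across regions between the
t-vector and a loading vector (from a CCA in which sex *was* a
covariate).  Its null shuffles the sex labels across individuals,
recomputes the full t-vector per permutation while the loading vector is
held at its observed value, and applies the add-one empirical rule.  A
heavier variant that also re-residualizes the AIs and re-fits the CCA
under each permuted sex assignment is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cca import _as_matrix
from .pattern_comparison import empirical_pvalue, loading_correlation

__all__ = ["SexAssociationMap", "sex_ttests", "sex_pattern_correlation"]


@dataclass
class SexAssociationMap:
    t_values: np.ndarray
    p_values: np.ndarray
    n_per_test: np.ndarray
    region_labels: list[str]
    sign_convention: str = "positive t = leftward shift in females (sex: female=1)"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.region_labels, "t": self.t_values,
             "p": self.p_values, "n": self.n_per_test}
        )


def _pooled_t_batch(X: np.ndarray, S: np.ndarray):
    """Pooled-variance two-sample t per column of X for each sex assignment.

    ``X`` is n x p (complete cases), ``S`` is n x B of 0/1 labels
    (female=1).  Returns a p x B matrix of t statistics (group 1 minus
    group 0), equivalent to the OLS slope t of each column on the label.
    """
    n = X.shape[0]
    n1 = S.sum(axis=0)                      # B
    n0 = n - n1
    sum1 = X.T @ S                          # p x B
    tot = X.sum(axis=0)[:, None]
    ss1 = (X**2).T @ S
    ss_tot = (X**2).sum(axis=0)[:, None]
    mean1 = sum1 / n1[None, :]
    mean0 = (tot - sum1) / n0[None, :]
    sse = (ss1 - n1[None, :] * mean1**2) + ((ss_tot - ss1) - n0[None, :] * mean0**2)
    pooled = sse / (n - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0)[None, :])
    return (mean1 - mean0) / se


def sex_ttests(ai_nosex, sex, welch: bool = False) -> SexAssociationMap:
    """Two-sample t per AI column with sex as the predictor.

    Expects AIs residualized without sex (otherwise the sex signal has
    been regressed away).  Missing entries are dropped per column.  The
    default pooled-variance statistic equals the regression-slope t of AI
    on sex; ``welch=True`` uses unequal-variance t instead.
    """
    X, labels = _as_matrix(ai_nosex)
    s = np.asarray(sex)
    if set(np.unique(s[np.isfinite(s.astype(float))])) - {0, 1}:
        raise ValueError("sex must be coded 0/1 (female=1)")
    s = s.astype(float)
    tvals = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    ns = np.empty(X.shape[1], dtype=int)
    for j in range(X.shape[1]):
        obs = np.isfinite(X[:, j]) & np.isfinite(s)
        g1 = X[obs & (s == 1), j]
        g0 = X[obs & (s == 0), j]
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError(f"column {labels[j]}: a sex group has fewer than 2 members")
        t, p = stats.ttest_ind(g1, g0, equal_var=not welch)
        tvals[j], pvals[j], ns[j] = t, p, len(g0) + len(g1)
    return SexAssociationMap(tvals, pvals, ns, labels)


def sex_pattern_correlation(
    sex_map: SexAssociationMap,
    loadings,
    ai_nosex,
    sex,
    n_perm: int = 10000,
    seed: int = 0,
    batch: int = 256,
    sided: str = "two",
    refit=None,
):
    """Correlation of the sex t-map with a loading vector, permutation p.

    Per permutation, sex labels are shuffled across individuals and the
    t-vector recomputed on complete cases; the loading vector stays fixed
    (the stated null randomizes sex, not the polygenic score).  Passing a
    ``refit`` callable ``perm_sex -> loading_vector`` switches to the full
    variant that also re-derives the loadings under the permuted sex.

    Returns ``(observed_r, empirical_p, null_sample)``.
    """
    loadings = np.asarray(loadings, float)
    if loadings.shape != (len(sex_map.region_labels),):
        raise ValueError("loading vector does not match the region ordering of the t-map")
    observed = loading_correlation(sex_map.t_values, loadings)

    X, _ = _as_matrix(ai_nosex)
    s = np.asarray(sex, float)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(s)
    X, s = X[keep], s[keep]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if refit is not None:
        for k in range(n_perm):
            sp = rng.permutation(s)
            t = _pooled_t_batch(X, sp[:, None])[:, 0]
            null[k] = loading_correlation(t, np.asarray(refit(sp), float))
    else:
        done = 0
        lc = loadings - loadings.mean()
        lnorm = np.linalg.norm(lc)
        while done < n_perm:
            nb = min(batch, n_perm - done)
            S = np.empty((len(s), nb))
            for k in range(nb):
                S[:, k] = rng.permutation(s)
            T = _pooled_t_batch(X, S)
            Tc = T - T.mean(axis=0)
            null[done:done + nb] = (Tc.T @ lc) / (np.linalg.norm(Tc, axis=0) * lnorm)
            done += nb
    return observed, empirical_pvalue(observed, null, sided=sided), null
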