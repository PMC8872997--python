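"""Scalar-target canonical correlation analysis.

With a single variable on one side, canonical correlation analysis reduces
to multiple regression: the canonical correlation equals the multiple
correlation sqrt(R^2) of the score regressed on the asymmetry columns, and
the canonical asymmetry index is the fitted linear combination.  Loadings
are the Pearson correlations of each asymmetry column with the canonical
variate, which is oriented so that its correlation with the score is
non-negative ("positive loading" therefore means a leftward asymmetry
shift associated with higher polygenic risk).

Because exactly one canonical pair exists, the parametric p-value is the
exact overall-regression F test; Bartlett's chi-squared approximation is
available as a cross-check mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CCAResult", "scalar_cca", "cca_pvalue", "univariate_associations"]


@dataclass
class CCAResult:
    canonical_r: float
    weights: np.ndarray        # raw coefficients, scaled so the variate has unit SD
    weights_std: np.ndarray    # coefficients applied to z-scored columns
    loadings: np.ndarray       # corr(AI_j, canonical variate)
    p_value: float
    n: int
    p: int
    region_labels: list[str] = field(default_factory=list)
    sign_anchor: str = "corr(score, variate) >= 0"
    variate: np.ndarray | None = None

    def loading_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_labels,
                "loading": self.loadings,
                "weight": self.weights,
                "weight_std": self.weights_std,
            }
        )


def cca_pvalue(canonical_r: float, n: int, p: int, method: str = "f") -> float:
    """Parametric p-value for a scalar-target canonical correlation.

    ``method="f"`` (default): exact overall F test,
    ``F = (r^2 / (1 - r^2)) * ((n - p - 1) / p)`` on (p, n-p-1) degrees of
    freedom.  ``method="bartlett"``: Bartlett's large-sample chi-squared,
    ``-(n - (p + 4) / 2) * log(1 - r^2)`` on p degrees of freedom (q = 1).
    """
    if not 0.0 <= canonical_r <= 1.0:
        raise ValueError(f"canonical_r must lie in [0, 1], got {canonical_r}")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if canonical_r == 1.0:
        warnings.warn("canonical_r = 1: p-value degenerates to 0", RuntimeWarning)
        return 0.0
    r2 = canonical_r**2
    if method == "f":
        f = (r2 / (1.0 - r2)) * ((n - p - 1) / p)
        return float(stats.f.sf(f, p, n - p - 1))
    if method == "bartlett":
        chi2 = -(n - (p + 1 + 1) / 2.0 - 1.0) * np.log1p(-r2)
        return float(stats.chi2.sf(chi2, p))
    raise ValueError(f"unknown method {method!r}")


def _as_matrix(ai):
    """Accept an AsymmetryMatrix, DataFrame, or ndarray."""
    if hasattr(ai, "values") and hasattr(ai, "region_labels"):
        return ai.values.to_numpy(float), list(ai.region_labels)
    if isinstance(ai, pd.DataFrame):
        return ai.to_numpy(float), list(ai.columns)
    arr = np.asarray(ai, float)
    return arr, [f"x{j + 1}" for j in range(arr.shape[1])]


def scalar_cca(score, ai, pvalue_method: str = "f") -> CCAResult:
    """Canonical correlation of one standardized score with the AI matrix.

    Rows with any missing value (in the score or any AI column) are
    dropped; the analysis n is recorded in the result.
    """
    y = np.asarray(score, float)
    X, labels = _as_matrix(ai)
    if y.shape[0] != X.shape[0]:
        raise ValueError("score and asymmetry matrix have different lengths")
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 complete cases (n={n}, p={p})")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    col_sd = Xc.std(axis=0, ddof=0)
    if np.any(col_sd == 0):
        dead = [labels[j] for j in np.flatnonzero(col_sd == 0)]
        raise ValueError(f"constant asymmetry column(s): {', '.join(dead)}")
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("asymmetry matrix is rank deficient")

    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    variate = Xc @ beta
    v_sd = variate.std(ddof=0)
    y_sd = yc.std(ddof=0)
    if v_sd == 0:
        canonical_r = 0.0
        weights = beta
        loadings = np.zeros(p)
        variate_unit = variate
    else:
        canonical_r = float(np.dot(yc, variate) / (n * y_sd * v_sd))
        sign = 1.0 if canonical_r >= 0 else -1.0
        canonical_r = abs(canonical_r)
        weights = sign * beta / v_sd  # variate = Xc @ weights has unit SD
        variate_unit = sign * variate / v_sd
        loadings = (Xc.T @ variate_unit) / (n * col_sd)
    return CCAResult(
        canonical_r=canonical_r,
        weights=weights,
        weights_std=weights * col_sd,
        loadings=loadings,
        p_value=cca_pvalue(canonical_r, n, p, method=pvalue_method),
        n=n,
        p=p,
        region_labels=labels,
        variate=variate_unit,
    )


def univariate_associations(score, measures: pd.DataFrame) -> pd.DataFrame:
    """Post hoc Pearson correlation of the score with each (residualized)
    unilateral measure column; one (r, p, n) row per measure."""
    y = np.asarray(score, float)
    rows = []
    for name in measures.columns:
        x = measures[name].to_numpy(float)
        obs = np.isfinite(x) & np.isfinite(y)
        n = int(obs.sum())
        if n < 3 or np.std(x[obs]) == 0:
            warnings.warn(f"measure {name}: constant or too few values; skipped",
                          RuntimeWarning)
            rows.append({"measure": name, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x[obs], y[obs])
        rows.append({"measure": name, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
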