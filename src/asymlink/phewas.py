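"""Type-driven phenome-wide association scan with per-score FDR control.

Each phenotype column is classified as continuous, binary, ordered
categorical, or unordered categorical (a declared codebook type always
wins) and tested against a polygenic score with the matching model:
linear, logistic, proportional-odds (ordered logistic), or
baseline-category (multinomial) logistic regression.  Continuous outcomes
are rank-based inverse-normal transformed before the linear fit.  All
models include the standard confound covariates.  Benjamini-Hochberg
step-up adjustment at q = 0.05 is applied separately per score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .asymmetry import inverse_normal_transform

__all__ = ["PhewasResult", "classify_variable", "test_phenotype", "bh_fdr", "run_phewas"]

TYPES = ("continuous", "binary", "ordered_categorical", "unordered_categorical")


@dataclass
class PhewasResult:
    table: pd.DataFrame  # one row per phenotype
    score: str
    q: float
    excluded: dict  # phenotype -> reason

    @property
    def n_discoveries(self) -> int:
        return int(self.table["discovery"].sum())


def classify_variable(column: pd.Series, declared: str | None = None,
                      k_max: int = 10) -> str:
    """Infer a phenotype's type; an explicit declared type always wins.

    Rules: exactly two distinct values -> binary; non-numeric codes ->
    unordered categorical; integer-coded with at most ``k_max`` levels ->
    ordered categorical; otherwise continuous.  A single distinct value
    is not testable and raises.
    """
    if declared is not None:
        if declared not in TYPES:
            raise ValueError(f"unknown declared type {declared!r}")
        return declared
    v = column.dropna()
    distinct = v.unique()
    if len(distinct) < 2:
        raise ValueError(f"phenotype {column.name!r} has a single distinct value")
    if len(distinct) == 2:
        return "binary"
    if not pd.api.types.is_numeric_dtype(v):
        return "unordered_categorical"
    arr = v.to_numpy(float)
    if np.allclose(arr, np.round(arr)) and len(distinct) <= k_max:
        return "ordered_categorical"
    return "continuous"


def _design_with_score(score: np.ndarray, design: pd.DataFrame | None,
                       mask: np.ndarray, add_const: bool) -> np.ndarray:
    parts = [score[mask][:, None]]
    if design is not None:
        parts.append(design.to_numpy(float)[mask])
    X = np.column_stack(parts)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    return X


def test_phenotype(score, phenotype: pd.Series, ptype: str,
                   design: pd.DataFrame | None = None, levels=None) -> dict:
    """Association of one phenotype with the score, by type-matched model.

    Returns a dict with the model name, effect estimate (score
    coefficient; for unordered outcomes the likelihood-ratio statistic is
    reported alongside per-level coefficients), p-value, and analysis n.
    Non-convergence is reported via ``"error"`` so the caller can exclude
    the phenotype from FDR adjustment with a recorded reason.
    """
    s = np.asarray(score, float)
    y_raw = phenotype
    mask = ~pd.isna(y_raw).to_numpy() & np.isfinite(s)
    if design is not None:
        mask &= np.isfinite(design.to_numpy(float)).all(axis=1)
    n = int(mask.sum())
    out = {"model": None, "effect": np.nan, "se": np.nan, "p": np.nan,
           "n": n, "error": None}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ptype == "continuous":
                out["model"] = "linear"
                y = inverse_normal_transform(y_raw.to_numpy(float)[mask])
                X = _design_with_score(s, design, mask, add_const=True)
                fit = sm.OLS(y, X).fit()
                out.update(effect=float(fit.params[1]), se=float(fit.bse[1]),
                           p=float(fit.pvalues[1]))
            elif ptype == "binary":
                out["model"] = "logistic"
                codes = pd.Categorical(y_raw[mask]).codes.astype(float)
                X = _design_with_score(s, design, mask, add_const=True)
                fit = sm.Logit(codes, X).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True):
                    raise RuntimeError("logistic fit did not converge")
                out.update(effect=float(fit.params[1]), se=float(fit.bse[1]),
                           p=float(fit.pvalues[1]))
            elif ptype == "ordered_categorical":
                out["model"] = "ordered_logistic"
                y = pd.Categorical(y_raw[mask], categories=levels, ordered=True)
                if y.isna().any():
                    raise RuntimeError("values outside the declared level order")
                X = _design_with_score(s, design, mask, add_const=False)
                fit = OrderedModel(y.codes.astype(float), X, distr="logit").fit(
                    method="bfgs", disp=0, maxiter=200
                )
                if not fit.mle_retvals.get("converged", True):
                    raise RuntimeError("ordered logistic fit did not converge")
                out.update(effect=float(fit.params[0]), se=float(fit.bse[0]),
                           p=float(fit.pvalues[0]))
            else:  # unordered_categorical: likelihood-ratio test for the score
                out["model"] = "multinomial_logistic"
                codes = pd.Categorical(y_raw[mask]).codes.astype(float)
                k = int(codes.max()) + 1
                X_full = _design_with_score(s, design, mask, add_const=True)
                X_red = X_full[:, [0] + list(range(2, X_full.shape[1]))]
                fit_full = sm.MNLogit(codes, X_full).fit(disp=0, maxiter=200)
                fit_red = sm.MNLogit(codes, X_red).fit(disp=0, maxiter=200)
                lr = 2.0 * (fit_full.llf - fit_red.llf)
                out.update(
                    effect=float(np.max(np.abs(fit_full.params[1]))),
                    se=np.nan,
                    p=float(stats.chi2.sf(max(lr, 0.0), df=k - 1)),
                )
    except Exception as exc:  # noqa: BLE001 - surfaced as an exclusion reason
        out["error"] = f"{type(exc).__name__}: {exc}"
    return out


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    Adjusted p-values are monotone-enforced; a discovery is an adjusted
    p at or below ``q``.
    """
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def run_phewas(
    cohort_table: pd.DataFrame,
    score_col: str,
    phenotype_cols,
    codebook: dict | None = None,
    design: pd.DataFrame | None = None,
    q: float = 0.05,
    exclude=(),
) -> PhewasResult:
    """Scan one score against many phenotypes with per-score FDR control.

    ``codebook`` maps phenotype name to ``{"type": ..., "levels": [...]}``;
    missing entries fall back to :func:`classify_variable`.  ``exclude``
    lists columns to drop up front (by default the caller passes measures
    used to build the AIs, covariates, and handedness).  Phenotypes whose
    model fails to converge are excluded from the adjustment, with the
    reason recorded.
    """
    codebook = codebook or {}
    score = cohort_table[score_col].to_numpy(float)
    excluded: dict[str, str] = {}
    rows = []
    for name in phenotype_cols:
        if name in exclude:
            excluded[name] = "on exclusion list"
            continue
        entry = codebook.get(name, {})
        try:
            ptype = classify_variable(cohort_table[name], entry.get("type"))
        except ValueError as exc:
            excluded[name] = str(exc)
            continue
        res = test_phenotype(score, cohort_table[name], ptype, design,
                             levels=entry.get("levels"))
        if res["error"] is not None:
            excluded[name] = res["error"]
            continue
        rows.append({"phenotype": name, "type": ptype, **{k: res[k] for k in
                     ("model", "effect", "se", "p", "n")}})
    table = pd.DataFrame(rows, columns=["phenotype", "type", "model",
                                        "effect", "se", "p", "n"])
    if len(table):
        p_adj, disc = bh_fdr(table["p"].to_numpy(), q=q)
        table["p_adjusted"] = p_adj
        table["discovery"] = disc
    else:
        table["p_adjusted"] = []
        table["discovery"] = []
    return PhewasResult(table=table, score=score_col, q=q, excluded=excluded)
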