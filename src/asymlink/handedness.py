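"""Logistic-regression contrasts of handedness groups on polygenic scores.

Three contrasts (left vs right, mixed vs right, and non-right vs right,
where non-right pools left and mixed) are fit for each score, giving six
separate logistic regressions in the two-score configuration.  Each model
regresses group membership on the score plus the standard confound
covariates and reports the score coefficient as log-odds per SD of score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["CONTRASTS", "fit_handedness_models"]

CONTRASTS = ("left_vs_right", "mixed_vs_right", "nonright_vs_right")
_CASE_GROUPS = {
    "left_vs_right": ("left",),
    "mixed_vs_right": ("mixed",),
    "nonright_vs_right": ("left", "mixed"),
}
_MISSING_CODES = {"prefer_not_to_answer", "na", ""}


def fit_handedness_models(
    cohort_table: pd.DataFrame,
    score_cols=("score_ASD", "score_SCZ"),
    design: pd.DataFrame | None = None,
    handedness_col: str = "handedness",
    contrasts=CONTRASTS,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> pd.DataFrame:
    """Fit all contrast-by-score logistic regressions.

    ``design`` is an optional confound design aligned to the cohort rows
    (e.g. from :func:`asymlink.asymmetry.build_covariate_design`); pass
    ``None`` for score-only models.  "Prefer not to answer" is treated as
    missing.  Quasi-separated or non-converged fits are flagged rather
    than corrected.
    """
    hand = cohort_table[handedness_col].astype(str).str.lower()
    hand = hand.where(~hand.isin(_MISSING_CODES))
    rows = []
    for contrast in contrasts:
        cases = _CASE_GROUPS[contrast]
        mask = hand.isin(cases + ("right",)).to_numpy()
        if not mask.any() or not hand[mask].isin(cases).any():
            raise ValueError(f"contrast {contrast}: empty case or control group")
        y = hand[mask].isin(cases).to_numpy(float)
        for score in score_cols:
            s = cohort_table.loc[mask, score].to_numpy(float)
            if np.std(s) == 0:
                raise ValueError(f"score {score} is constant; coefficient undefined")
            parts = [pd.Series(s, name=score)]
            if design is not None:
                if len(design) != len(cohort_table):
                    raise ValueError("design must be aligned row-for-row with the cohort")
                parts.append(design.reset_index(drop=True)[mask].reset_index(drop=True))
            X = sm.add_constant(pd.concat(parts, axis=1))
            flagged = None
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X.to_numpy(float)).fit(
                        disp=0, gtol=tol, maxiter=maxiter, method="newton"
                    )
                converged = bool(fit.mle_retvals.get("converged", True))
                if not converged:
                    flagged = "non_convergence"
                # very large coefficients or vanishing Hessian indicate
                # quasi-separation; report, do not correct
                if np.any(np.abs(fit.params) > 50):
                    flagged = "quasi_separation"
                beta = float(fit.params[1])
                se = float(fit.bse[1])
                p = float(fit.pvalues[1])
            except (PerfectSeparationError, np.linalg.LinAlgError):
                flagged = "perfect_separation"
                beta = se = p = np.nan
            rows.append(
                {
                    "contrast": contrast,
                    "score": score,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "n_cases": int(y.sum()),
                    "n_controls": int((1 - y).sum()),
                    "flag": flagged,
                }
            )
    return pd.DataFrame(rows)
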