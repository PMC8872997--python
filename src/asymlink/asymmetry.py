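"""Asymmetry-index construction and preprocessing.

Turns paired left/right regional measures into the adjusted asymmetry
matrix the multivariate statistics operate on.  The pipeline order is:

1. per-measure outlier removal (values more than 6 SD from the column
   mean set missing; applied once, on the raw unilateral measures),
2. asymmetry index AI = (L - R) / ((L + R) / 2) on surviving pairs
   (missing if either side was removed),
3. rank-based inverse normal transformation per AI column,
4. ordinary-least-squares residualization against the confound design
   (age, nonlinear age, genetic principal components, scanner position,
   SNR/CNR, assessment center, genotyping array, and optionally sex and
   brain size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "AsymmetryMatrix",
    "compute_asymmetry_index",
    "remove_outliers",
    "inverse_normal_transform",
    "residualize",
    "build_covariate_design",
    "prepare_asymmetry_matrix",
    "prepare_unilateral_matrix",
]

# rank offsets c for the transform Phi^-1((rank - c) / (m - 2c + 1))
_INT_OFFSETS = {"blom": 3.0 / 8.0, "waerden": 0.0, "tukey": 1.0 / 3.0}

DEFAULT_CATEGORICAL_COVARIATES = ("center", "array")
DEFAULT_CONTINUOUS_COVARIATES = (
    ("age",)
    + tuple(f"pc{i:02d}" for i in range(1, 11))
    + ("scanner_x", "scanner_y", "scanner_z", "snr", "cnr")
)


@dataclass
class AsymmetryMatrix:
    """Preprocessed asymmetry indexes plus region labels and provenance."""

    values: pd.DataFrame  # n x p, columns are region labels
    region_labels: list[str]
    measure_class: list[str]
    provenance: dict = field(default_factory=dict)
    design: pd.DataFrame | None = None  # confound design used for residualization

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def complete_cases(self) -> np.ndarray:
        """Boolean row mask: no missing AI in any region."""
        return ~self.values.isna().any(axis=1).to_numpy()

    def write(self, prefix: str) -> None:
        self.values.to_csv(f"{prefix}.tsv", sep="\t", index=False, float_format="%.12g")
        with open(f"{prefix}.provenance.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "region_labels": self.region_labels,
                    "measure_class": self.measure_class,
                    "provenance": self.provenance,
                },
                fh,
                sort_keys=True,
            )


def compute_asymmetry_index(left, right):
    """AI = (L - R) / ((L + R) / 2) for strictly positive paired measures.

    Antisymmetric under swapping the sides and invariant to a common
    rescaling of both.  Missing values propagate; non-positive values
    raise, naming the offending rows.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    for name, side in (("left", left), ("right", right)):
        bad = np.flatnonzero(side <= 0)
        if bad.size:
            raise ValueError(
                f"{name} measure must be strictly positive; offending rows "
                f"(0-based): {bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
            )
    return (left - right) / ((left + right) / 2.0)


def remove_outliers(values, sd_threshold: float = 6.0, label: str = ""):
    """Set entries more than ``sd_threshold`` SDs from the column mean to NaN.

    Mean and SD come from the column *before* removal and the rule is
    applied once (no iteration).  Returns ``(cleaned, n_removed)``.  A
    zero-variance column is returned unchanged with a warning.
    """
    x = np.asarray(values, float).copy()
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise ValueError(f"column {label or '<unnamed>'}: need >= 2 non-missing values")
    mu = x[obs].mean()
    sd = x[obs].std()
    if sd == 0:
        warnings.warn(f"column {label or '<unnamed>'} has zero SD; no outlier removal",
                      RuntimeWarning)
        return x, 0
    out = obs & (np.abs(x - mu) > sd_threshold * sd)
    x[out] = np.nan
    return x, int(out.sum())


def inverse_normal_transform(values, offset: str = "blom"):
    """Rank-based inverse normal transform.

    Maps each non-missing value to ``Phi^-1((rank - c) / (m - 2c + 1))``
    over the m non-missing entries, with the Blom offset c = 3/8 by
    default (``"waerden"`` and ``"tukey"`` are also available).  Ties get
    average ranks and therefore identical outputs; missing stays missing.
    """
    if offset not in _INT_OFFSETS:
        raise ValueError(f"unknown rank offset {offset!r}; choose from {sorted(_INT_OFFSETS)}")
    c = _INT_OFFSETS[offset]
    x = np.asarray(values, float)
    out = np.full(x.shape, np.nan)
    obs = np.isfinite(x)
    v = x[obs]
    if np.unique(v).size < 2:
        raise ValueError("inverse normal transform needs >= 2 distinct non-missing values")
    ranks = stats.rankdata(v, method="average")
    out[obs] = stats.norm.ppf((ranks - c) / (v.size - 2.0 * c + 1.0))
    return out


def _expand_design(design: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    return X


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # sequential QR diagnostic: a near-zero diagonal of R marks the column
    # that is collinear with its predecessors
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        cols = ["intercept"] + list(names)
        raise np.linalg.LinAlgError(
            "confound design is rank deficient; collinear columns: "
            + ", ".join(cols[i] for i in bad)
        )


def residualize(matrix, design: pd.DataFrame):
    """OLS residuals of each column against the confound design (+intercept).

    Missing entries are handled per column: the fit for a column uses its
    observed rows only, and missing entries stay missing.  Residuals are
    orthogonal to every design column on the rows used.
    """
    M = np.asarray(matrix, float)
    single = M.ndim == 1
    if single:
        M = M[:, None]
    X = _expand_design(design)
    if M.shape[0] <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} design columns, got n = {M.shape[0]}")
    _check_full_rank(X, list(design.columns))

    out = np.full(M.shape, np.nan)
    complete = np.isfinite(M).all(axis=0)
    if complete.any():
        beta, *_ = np.linalg.lstsq(X, M[:, complete], rcond=None)
        out[:, complete] = M[:, complete] - X @ beta
    for j in np.flatnonzero(~complete):
        obs = np.isfinite(M[:, j])
        beta, *_ = np.linalg.lstsq(X[obs], M[obs, j], rcond=None)
        out[obs, j] = M[obs, j] - X[obs] @ beta
    return out[:, 0] if single else out


def build_covariate_design(
    cohort_table: pd.DataFrame,
    include_sex: bool = True,
    extra_covariates: list[str] | None = None,
    continuous: tuple[str, ...] | None = None,
    categorical: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assemble the numeric confound design from a cohort table.

    Includes every standard continuous covariate present in the table, the
    derived nonlinear age term ``(age - mean(age))**2``, reference-coded
    indicator columns for each categorical covariate (reference = most
    frequent level), optionally sex, and any ``extra_covariates`` (e.g.
    ``brain_size`` for the sensitivity variant).
    """
    continuous = DEFAULT_CONTINUOUS_COVARIATES if continuous is None else continuous
    categorical = DEFAULT_CATEGORICAL_COVARIATES if categorical is None else categorical
    cols: dict[str, np.ndarray] = {}
    for name in continuous:
        if name in cohort_table.columns:
            cols[name] = cohort_table[name].to_numpy(float)
    if "age" in cols:
        # nonlinear age uses the analysis-sample mean at preprocessing time
        cols["age_nl"] = (cols["age"] - cols["age"].mean()) ** 2
    for name in categorical:
        if name not in cohort_table.columns:
            continue
        v = cohort_table[name].astype(str)
        ref = v.value_counts().idxmax()
        for level in sorted(v.unique()):
            if level == ref:
                continue
            cols[f"{name}[{level}]"] = (v == level).to_numpy(float)
    if include_sex:
        cols["sex"] = cohort_table["sex"].to_numpy(float)
    for name in extra_covariates or []:
        cols[name] = cohort_table[name].to_numpy(float)
    return pd.DataFrame(cols, index=cohort_table.index)


def prepare_asymmetry_matrix(
    cohort,
    include_sex: bool = True,
    extra_covariates: list[str] | None = None,
    sd_threshold: float = 6.0,
    outlier_on: str = "unilateral",
    int_offset: str = "blom",
) -> AsymmetryMatrix:
    """Full preprocessing: cohort table -> adjusted asymmetry matrix.

    ``cohort`` is a :class:`~asymlink.synthetic_data.Cohort` (or any object
    with ``table``, ``region_labels`` and ``measure_classes`` attributes).
    ``outlier_on`` selects where the 6 SD rule operates: on the raw
    unilateral measures (default; an AI is missing if either side is
    removed) or on the computed AIs (``"ai"``, sensitivity variant).
    """
    if outlier_on not in ("unilateral", "ai"):
        raise ValueError("outlier_on must be 'unilateral' or 'ai'")
    table = cohort.table
    labels = list(cohort.region_labels)
    classes = list(cohort.measure_classes)
    removal_counts: dict[str, int] = {}

    ai_cols = {}
    for lab in labels:
        left = table[f"left_{lab}"].to_numpy(float)
        right = table[f"right_{lab}"].to_numpy(float)
        if outlier_on == "unilateral":
            left, n_l = remove_outliers(left, sd_threshold, label=f"left_{lab}")
            right, n_r = remove_outliers(right, sd_threshold, label=f"right_{lab}")
            removal_counts[lab] = n_l + n_r
            obs = np.isfinite(left) & np.isfinite(right)
            ai = np.full(len(table), np.nan)
            ai[obs] = compute_asymmetry_index(left[obs], right[obs])
        else:
            ai = compute_asymmetry_index(left, right)
            ai, n_rm = remove_outliers(ai, sd_threshold, label=lab)
            removal_counts[lab] = n_rm
        ai_cols[lab] = ai

    values = pd.DataFrame(ai_cols, index=table.index)
    transformed = values.apply(lambda col: inverse_normal_transform(col, offset=int_offset),
                               raw=True)
    design = build_covariate_design(table, include_sex=include_sex,
                                    extra_covariates=extra_covariates)
    resid = residualize(transformed.to_numpy(), design)
    out = pd.DataFrame(resid, columns=labels, index=table.index)
    provenance = {
        "steps": [
            f"outlier_removal(sd={sd_threshold}, on={outlier_on})",
            "asymmetry_index",
            f"inverse_normal({int_offset})",
            "residualize",
        ],
        "outlier_removals": removal_counts,
        "covariates": list(design.columns),
        "include_sex": include_sex,
        "extra_covariates": list(extra_covariates or []),
        "n": int(len(table)),
        "n_complete": int(np.isfinite(resid).all(axis=1).sum()),
    }
    return AsymmetryMatrix(out, labels, classes, provenance, design)


def prepare_unilateral_matrix(
    cohort,
    include_sex: bool = True,
    extra_covariates: list[str] | None = None,
    sd_threshold: float = 6.0,
) -> pd.DataFrame:
    """Outlier-cleaned, covariate-adjusted unilateral measures.

    Used for the post hoc per-measure Pearson correlations: each
    ``left_*``/``right_*`` column gets the 6 SD rule and the same
    residualization as the main analysis.
    """
    table = cohort.table
    cols = {}
    for lab in cohort.region_labels:
        for side in ("left", "right"):
            name = f"{side}_{lab}"
            cleaned, _ = remove_outliers(table[name].to_numpy(float), sd_threshold, label=name)
            cols[name] = cleaned
    design = build_covariate_design(table, include_sex=include_sex,
                                    extra_covariates=extra_covariates)
    M = pd.DataFrame(cols, index=table.index)
    resid = residualize(M.to_numpy(), design)
    return pd.DataFrame(resid, columns=M.columns, index=table.index)
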