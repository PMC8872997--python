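"""Synthetic cohort generator.

Produces per-individual tables with the statistical structure the analysis
assumes: two standardized polygenic scores, paired left/right regional
brain measures whose asymmetry indexes carry planted association patterns,
covariates, a three-category handedness variable, and typed phenotype
columns.  Every downstream stage of the pipeline is thereby testable
without access to restricted cohort data.

Construction of the regional measures inverts the asymmetry-index formula:
a latent asymmetry ``a`` is drawn on the AI scale and the two sides are set
to ``left = s * (1 + a/2)`` and ``right = s * (1 - a/2)`` for a log-normal
bilateral size ``s``, so that ``(L - R) / ((L + R) / 2)`` recovers ``a``
exactly.  The noise scale is calibrated in closed form so the planted
canonical correlations hold in expectation: with a single planted unit-norm
direction ``L`` and per-region noise SD ``sigma``, the population canonical
correlation of the score with the AI matrix equals
``c / sqrt(c**2 + sigma**2)`` where ``c`` is the signal coefficient, so
``c = r * sigma / sqrt(1 - r**2)`` plants a canonical correlation of ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .config import (
    ParameterError,
    PhenotypeSpec,
    SimulationConfig,
    _CLASS_SIZE_MEDIAN,
)

SCORE_COLUMNS = ("score_ASD", "score_SCZ")
HANDEDNESS_LEVELS = ("right", "left", "mixed")

# Latent asymmetries with |a| >= this bound would imply a non-positive side;
# they are clipped (and counted) just inside the feasible interval (-2, 2).
_AI_CLIP = 1.9


@dataclass
class Cohort:
    """A simulated cohort: the per-individual table plus its metadata."""

    table: pd.DataFrame
    region_labels: list[str]
    measure_classes: list[str]
    codebook: dict
    config: SimulationConfig
    latent_asymmetry: np.ndarray | None = None
    outlier_positions: dict = field(default_factory=dict)
    n_clipped: int = 0

    @property
    def n(self) -> int:
        return len(self.table)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_scores(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw sex and the two polygenic scores.

    Scores are bivariate normal with the configured correlation, shifted by
    ``score_sex_shift`` (standardized units, female minus male) for
    females, then z-scaled within the cohort.
    """
    config.validate()
    n = config.n_individuals
    rho = config.score_correlation
    sex = (rng.random(n) < config.female_fraction).astype(np.int64)  # female=1
    cov = np.array([[1.0, rho], [rho, 1.0]])
    scores = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    scores = scores + config.score_sex_shift * sex[:, None]
    scores = np.apply_along_axis(_zscore, 0, scores)
    return pd.DataFrame(
        {"sex": sex, SCORE_COLUMNS[0]: scores[:, 0], SCORE_COLUMNS[1]: scores[:, 1]}
    )


def generate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the confound columns declared in ``config.covariate_specs``.

    Age is uniform over the study's 45-81 year range; other continuous
    covariates are standard normal; categorical covariates are uniform over
    their levels with string codes.
    """
    n = config.n_individuals
    cols = {}
    for spec in config.covariate_specs:
        if spec.kind == "continuous":
            if spec.name == "age":
                cols[spec.name] = rng.uniform(45.0, 81.0, size=n)
            else:
                cols[spec.name] = rng.standard_normal(n)
        else:
            levels = [f"{spec.name}_{i + 1}" for i in range(spec.n_levels)]
            cols[spec.name] = np.array(levels, dtype=object)[
                rng.integers(0, spec.n_levels, size=n)
            ]
    return pd.DataFrame(cols)


def _planted_patterns(config: SimulationConfig, rng: np.random.Generator):
    """Resolve the planted loading patterns and the sex pattern.

    Unspecified patterns are drawn from the given RNG: the two loading
    directions as an orthonormal pair (so the planted multivariate
    associations of the two scores are distinct), the sex pattern as i.i.d.
    normal per-region effects.
    """
    p = config.n_regions
    la = config.loading_pattern_A
    lb = config.loading_pattern_B
    if la is None and lb is None:
        m = rng.standard_normal((p, 2))
        q, _ = np.linalg.qr(m)
        la, lb = q[:, 0], q[:, 1]
    else:
        if la is None:
            la = rng.standard_normal(p)
            la /= np.linalg.norm(la)
        if lb is None:
            lb = rng.standard_normal(p)
            lb /= np.linalg.norm(lb)
    la = np.asarray(la, float)
    lb = np.asarray(lb, float)
    if config.sex_pattern is not None:
        sp = np.asarray(config.sex_pattern, float)
        if sp.shape != (p,):
            raise ParameterError("sex_pattern must have length n_regions")
    else:
        sp = rng.standard_normal(p) * config.sex_pattern_scale
    return la, lb, sp


def _covariate_effect_matrix(config: SimulationConfig, covariates: pd.DataFrame,
                             rng: np.random.Generator) -> np.ndarray:
    """Sum of per-region covariate effects on the latent asymmetry scale.

    Each covariate enters through its standardized numeric coding
    (categorical levels use their index); effect vectors not given in the
    spec are drawn here with SD ``covariate_effect_scale``.
    """
    n, p = config.n_individuals, config.n_regions
    total = np.zeros((n, p))
    for spec in config.covariate_specs:
        if spec.effect is not None:
            eff = np.asarray(spec.effect, float)
            if eff.shape != (p,):
                raise ParameterError(f"covariate {spec.name}: effect must have length {p}")
        else:
            eff = rng.standard_normal(p) * config.covariate_effect_scale
        v = covariates[spec.name]
        if spec.kind == "categorical":
            codes = pd.Categorical(v).codes.astype(float)
        else:
            codes = np.asarray(v, float)
        sd = codes.std()
        if sd > 0:
            total += np.outer((codes - codes.mean()) / sd, eff)
    return total


def generate_regional_measures(
    config: SimulationConfig,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
):
    """Draw left/right regional measures embedding the planted structure.

    Returns ``(measures, latent_ai, outlier_positions, n_clipped)`` where
    ``measures`` holds the ``left_*``/``right_*`` columns, ``latent_ai`` is
    the n-by-p matrix of latent asymmetries on the AI scale (before outlier
    injection), ``outlier_positions`` maps column name to injected row
    indexes, and ``n_clipped`` counts latent values clipped into the
    feasible interval.
    """
    config.validate()
    n, p = config.n_individuals, config.n_regions
    labels, classes = config.region_table()
    la, lb, sp = _planted_patterns(config, rng)

    sA = scores[SCORE_COLUMNS[0]].to_numpy()
    sB = scores[SCORE_COLUMNS[1]].to_numpy()
    sex = scores["sex"].to_numpy().astype(float)

    # closed-form signal coefficients for unit per-region noise SD
    cA = config.canonical_r_A / np.sqrt(1.0 - config.canonical_r_A**2)
    cB = config.canonical_r_B / np.sqrt(1.0 - config.canonical_r_B**2)

    baseline = rng.standard_normal(p) * config.baseline_asymmetry_scale
    latent = (
        baseline[None, :]
        + cA * np.outer(sA, la)
        + cB * np.outer(sB, lb)
        + np.outer(sex - sex.mean(), sp)
        + _covariate_effect_matrix(config, covariates, rng)
        + rng.standard_normal((n, p))
    )
    ai = config.ai_scale * latent
    n_clipped = int(np.sum(np.abs(ai) > _AI_CLIP))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} latent asymmetries exceeded |a| = {_AI_CLIP} and were clipped",
            RuntimeWarning,
        )
        ai = np.clip(ai, -_AI_CLIP, _AI_CLIP)

    log_median = np.log([_CLASS_SIZE_MEDIAN[c] for c in classes])
    size = np.exp(log_median[None, :] + config.size_log_sd * rng.standard_normal((n, p)))
    left = size * (1.0 + ai / 2.0)
    right = size * (1.0 - ai / 2.0)

    measures = {}
    for j, lab in enumerate(labels):
        measures[f"left_{lab}"] = left[:, j]
        measures[f"right_{lab}"] = right[:, j]
    measures = pd.DataFrame(measures)

    outlier_positions = {}
    if config.outlier_rate > 0:
        for col in measures.columns:
            hit = np.flatnonzero(rng.random(n) < config.outlier_rate)
            if hit.size == 0:
                continue
            x = measures[col].to_numpy()
            mu, sd = x.mean(), x.std()
            mag = rng.uniform(7.0, 10.0, size=hit.size)
            sign = rng.choice([-1.0, 1.0], size=hit.size)
            val = mu + sign * mag * sd
            # raw measures are strictly positive; flip infeasible low outliers
            val = np.where(val <= 0, mu + mag * sd, val)
            x[hit] = val
            measures[col] = x
            outlier_positions[col] = hit.tolist()
    return measures, ai, outlier_positions, n_clipped


def generate_handedness(
    config: SimulationConfig, scores: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """Sample handedness from a baseline-category logit (right = reference).

    Intercepts match the configured base rates; each score contributes its
    (left-vs-right, mixed-vs-right) log-odds slopes.
    """
    config.validate()
    n = config.n_individuals
    pr, pl, pm = config.handedness_base_rates
    if pr <= 0:
        if pl == 0 and pm == 0:
            raise ParameterError("handedness base rates must include the reference")
    eta = np.zeros((n, 3))  # right, left, mixed
    with np.errstate(divide="ignore"):
        eta[:, 1] = np.log(pl / pr) if pl > 0 else -np.inf
        eta[:, 2] = np.log(pm / pr) if pm > 0 else -np.inf
    for score_col, (b_left, b_mixed) in config.handedness_betas.items():
        s = scores[score_col].to_numpy()
        eta[:, 1] = eta[:, 1] + b_left * s
        eta[:, 2] = eta[:, 2] + b_mixed * s
    emax = eta.max(axis=1, keepdims=True)
    prob = np.exp(eta - emax)
    prob /= prob.sum(axis=1, keepdims=True)
    cum = np.cumsum(prob, axis=1)
    u = rng.random(n)
    idx = (u[:, None] > cum).sum(axis=1)
    return pd.Series(np.array(HANDEDNESS_LEVELS, dtype=object)[idx], name="handedness")


def _gen_one_phenotype(spec: PhenotypeSpec, scores: pd.DataFrame,
                       rng: np.random.Generator):
    s = scores[spec.score].to_numpy()
    n = len(s)
    if spec.kind == "continuous":
        return s * spec.effect + rng.standard_normal(n), {"type": "continuous"}
    if spec.kind == "binary":
        base = np.log(spec.prevalence / (1 - spec.prevalence))
        prob = 1.0 / (1.0 + np.exp(-(base + spec.effect * s)))
        return (rng.random(n) < prob).astype(np.int64), {"type": "binary"}
    if spec.kind == "ordered":
        k = spec.n_levels
        # logistic latent variable cut at equal-probability thresholds
        latent = spec.effect * s + rng.logistic(size=n)
        cuts = np.log(np.arange(1, k) / k / (1 - np.arange(1, k) / k))
        y = np.searchsorted(cuts, latent) + 1
        return y.astype(np.int64), {"type": "ordered_categorical",
                                    "levels": list(range(1, k + 1))}
    # unordered: baseline-category logit, effect on the last category
    k = spec.n_levels
    eta = np.zeros((n, k))
    eta[:, -1] = spec.effect * s
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    idx = (rng.random(n)[:, None] > np.cumsum(prob, axis=1)).sum(axis=1)
    levels = [f"cat{i + 1}" for i in range(k)]
    return (np.array(levels, dtype=object)[idx],
            {"type": "unordered_categorical", "levels": levels})


def generate_phenotypes(config: SimulationConfig, scores: pd.DataFrame,
                        rng: np.random.Generator):
    """Emit the typed phenotype battery and its codebook."""
    config.validate()
    cols, codebook = {}, {}
    for spec in config.phenotype_specs:
        cols[spec.name], codebook[spec.name] = _gen_one_phenotype(spec, scores, rng)
    return pd.DataFrame(cols), codebook


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort table, deterministically for a given seed.

    Stages draw from independent child streams of ``config.seed``, so the
    scores of two cohorts differing only in, say, phenotype settings are
    identical.
    """
    config.validate()
    r_scores, r_cov, r_meas, r_hand, r_phen, r_size = _child_rngs(config.seed, 6)
    scores = generate_scores(config, r_scores)
    covariates = generate_covariates(config, r_cov)
    measures, latent_ai, outlier_pos, n_clipped = generate_regional_measures(
        config, scores, covariates, r_meas
    )
    handedness = generate_handedness(config, scores, r_hand)
    phenotypes, codebook = generate_phenotypes(config, scores, r_phen)
    # whole-brain size, independent of the planted asymmetry structure
    brain_size = np.exp(
        np.log(1.2e6) + config.brain_size_log_sd * r_size.standard_normal(config.n_individuals)
    )

    labels, classes = config.region_table()
    table = pd.concat(
        [
            pd.DataFrame({"iid": [f"ind{i + 1:06d}" for i in range(config.n_individuals)]}),
            scores,
            covariates,
            pd.DataFrame({"brain_size": brain_size}),
            measures,
            handedness.to_frame(),
            phenotypes,
        ],
        axis=1,
    )
    return Cohort(
        table=table,
        region_labels=labels,
        measure_classes=classes,
        codebook=codebook,
        config=config,
        latent_asymmetry=latent_ai,
        outlier_positions=outlier_pos,
        n_clipped=n_clipped,
    )


def write_cohort(cohort: Cohort, prefix: str) -> None:
    """Write the cohort as ``<prefix>.tsv`` plus a ``<prefix>.meta.yaml``
    sidecar declaring column types, region labels, and the full simulation
    configuration (including the seed)."""
    cohort.table.to_csv(f"{prefix}.tsv", sep="\t", index=False, float_format="%.12g")
    meta = {
        "region_labels": cohort.region_labels,
        "measure_classes": cohort.measure_classes,
        "codebook": cohort.codebook,
        "n_clipped": cohort.n_clipped,
        "outlier_positions": cohort.outlier_positions,
        "config": cohort.config.to_dict(),
    }
    with open(f"{prefix}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_cohort(prefix: str) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (latent matrix is not
    persisted and comes back as ``None``)."""
    table = pd.read_csv(f"{prefix}.tsv", sep="\t")
    with open(f"{prefix}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return Cohort(
        table=table,
        region_labels=meta["region_labels"],
        measure_classes=meta["measure_classes"],
        codebook=meta["codebook"],
        config=SimulationConfig.from_dict(meta["config"]),
        latent_asymmetry=None,
        outlier_positions=meta.get("outlier_positions", {}),
        n_clipped=meta.get("n_clipped", 0),
    )
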