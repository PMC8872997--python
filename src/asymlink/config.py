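"""Configuration objects for cohort simulation and pipeline runs.

The simulation configuration encodes the generative assumptions of the
synthetic cohort: two z-scaled polygenic scores with a small positive
correlation and a small female-ward mean shift, 42 paired left/right
regional brain measures whose asymmetry indexes carry planted multivariate
association patterns with each score, a per-region sex-difference pattern,
covariate effects, heavy-tailed measurement outliers, a three-category
handedness variable with score-dependent odds, and typed phenotype columns
with planted score effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml


class ParameterError(ValueError):
    """An invalid simulation or pipeline parameter."""


# Paper-scale cohort composition: 32,256 adults, 16,968 of them female, and
# handedness counts 28,703 right / 3,059 left / 490 mixed.
DEFAULT_N_INDIVIDUALS = 32256
DEFAULT_FEMALE_FRACTION = 16968 / 32256
DEFAULT_HANDEDNESS_RATES = (28703 / 32252, 3059 / 32252, 490 / 32252)

#: Region-set composition of the default 42-index configuration:
#: 28 cortical surface-area, 8 cortical-thickness, 6 subcortical-volume
#: asymmetry indexes.
DEFAULT_REGION_COMPOSITION = (("surface_area", 28), ("thickness", 8), ("volume", 6))

# Typical scale of the bilateral measures by class (used as log-normal
# medians for the simulated raw measures; mm^2, mm, and mm^3 respectively).
_CLASS_SIZE_MEDIAN = {"surface_area": 2500.0, "thickness": 2.6, "volume": 4200.0}


def default_region_table(n_regions: int = 42):
    """Region labels and measure classes for a cohort with ``n_regions`` AIs.

    For 42 regions this mirrors the 28/8/6 area/thickness/volume split;
    other sizes allocate proportionally (at least one region per class when
    n_regions >= 3).
    """
    if n_regions == 42:
        comp = DEFAULT_REGION_COMPOSITION
    else:
        weights = np.array([c for _, c in DEFAULT_REGION_COMPOSITION], float)
        alloc = np.floor(weights / weights.sum() * n_regions).astype(int)
        if n_regions >= 3:
            alloc = np.maximum(alloc, 1)
        while alloc.sum() < n_regions:
            alloc[int(np.argmax(weights))] += 1
        while alloc.sum() > n_regions:
            alloc[int(np.argmax(alloc))] -= 1
        comp = tuple(
            (name, int(k)) for (name, _), k in zip(DEFAULT_REGION_COMPOSITION, alloc) if k > 0
        )
    labels, classes = [], []
    short = {"surface_area": "area", "thickness": "thick", "volume": "vol"}
    for cls, count in comp:
        for i in range(count):
            labels.append(f"{short[cls]}_region{i + 1:02d}")
            classes.append(cls)
    return labels, classes


@dataclass
class CovariateSpec:
    """One simulated confound variable.

    Parameters
    ----------
    name:
        Column name in the cohort table.
    kind:
        ``"continuous"`` or ``"categorical"``.
    n_levels:
        Number of levels for a categorical covariate (ignored otherwise).
    effect:
        Optional per-region effect vector (length ``n_regions``) on the
        latent asymmetry scale, applied per standardized covariate unit.
        ``None`` means "draw a small random effect vector from the cohort
        seed with scale ``SimulationConfig.covariate_effect_scale``".
    """

    name: str
    kind: str = "continuous"
    n_levels: int = 0
    effect: Optional[Sequence[float]] = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ParameterError(f"covariate {self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and self.n_levels < 2:
            raise ParameterError(f"categorical covariate {self.name} needs >= 2 levels")


def default_covariate_specs() -> list[CovariateSpec]:
    """The study-style confound set: age, ten genetic principal components,
    scanner table position (X/Y/Z), T1 signal- and contrast-to-noise, and
    categorical assessment center and genotyping array."""
    specs = [CovariateSpec("age")]
    specs += [CovariateSpec(f"pc{i:02d}") for i in range(1, 11)]
    specs += [CovariateSpec(f"scanner_{ax}") for ax in "xyz"]
    specs += [CovariateSpec("snr"), CovariateSpec("cnr")]
    specs += [
        CovariateSpec("center", kind="categorical", n_levels=3),
        CovariateSpec("array", kind="categorical", n_levels=2),
    ]
    return specs


@dataclass
class PhenotypeSpec:
    """A simulated phenotype column for the phenome-wide scan.

    ``effect`` is the planted association with ``score`` on the model's
    natural scale: regression slope per score SD for continuous, log-odds
    for binary/ordered, and the last-category log-odds for unordered.
    """

    name: str
    kind: str = "continuous"  # continuous | binary | ordered | unordered
    effect: float = 0.0
    score: str = "score_ASD"
    n_levels: int = 4
    prevalence: float = 0.25

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordered", "unordered"):
            raise ParameterError(f"phenotype {self.name}: unknown kind {self.kind!r}")


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """A small typed battery with a few planted signals and several nulls."""
    specs = [
        PhenotypeSpec("hearing_difficulty", "binary", effect=0.12, score="score_ASD", prevalence=0.38),
        PhenotypeSpec("deprivation_index", "continuous", effect=0.03, score="score_ASD"),
        PhenotypeSpec("college_degree", "binary", effect=0.10, score="score_ASD", prevalence=0.33),
        PhenotypeSpec("trail_making_interval", "continuous", effect=0.10, score="score_SCZ"),
        PhenotypeSpec("fluid_intelligence", "continuous", effect=-0.14, score="score_SCZ"),
        PhenotypeSpec("total_brain_volume_z", "continuous", effect=-0.02, score="score_SCZ"),
        PhenotypeSpec("self_rated_health", "ordered", effect=0.08, score="score_SCZ", n_levels=4),
        PhenotypeSpec("employment_status", "unordered", effect=0.10, score="score_SCZ", n_levels=3),
    ]
    specs += [PhenotypeSpec(f"null_cont{i}", "continuous") for i in range(1, 4)]
    specs += [
        PhenotypeSpec("null_binary1", "binary", prevalence=0.2),
        PhenotypeSpec("null_ordered1", "ordered", n_levels=5),
        PhenotypeSpec("null_unordered1", "unordered", n_levels=3),
    ]
    return specs


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults reproduce the study conditions: n = 32,256 (52.6% female),
    score correlation 0.08, a small female-ward score shift (standardized
    mean difference 0.04), planted canonical correlations 0.03 (score A,
    "ASD-like") and 0.04 (score B, "schizophrenia-like") with independent
    unit-norm loading patterns, a per-region sex-difference pattern, and
    handedness base rates 89.0% / 9.5% / 1.5% (right/left/mixed) with a
    mixed-vs-right log-odds of 0.14 per SD of score A.
    """

    n_individuals: int = DEFAULT_N_INDIVIDUALS
    n_regions: int = 42
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    score_correlation: float = 0.08
    score_sex_shift: float = 0.04
    loading_pattern_A: Optional[Sequence[float]] = None
    loading_pattern_B: Optional[Sequence[float]] = None
    canonical_r_A: float = 0.03
    canonical_r_B: float = 0.04
    sex_pattern: Optional[Sequence[float]] = None
    sex_pattern_scale: float = 0.08
    covariate_specs: list[CovariateSpec] = field(default_factory=default_covariate_specs)
    covariate_effect_scale: float = 0.03
    handedness_base_rates: tuple[float, float, float] = DEFAULT_HANDEDNESS_RATES
    # per-score (left-vs-right, mixed-vs-right) log-odds slopes
    handedness_betas: dict = field(
        default_factory=lambda: {"score_ASD": (0.04, 0.14), "score_SCZ": (0.0, 0.0)}
    )
    phenotype_specs: list[PhenotypeSpec] = field(default_factory=default_phenotype_specs)
    outlier_rate: float = 5e-4
    # latent-to-AI scale: asymmetry indexes of regional measures are a few
    # percent in magnitude, so one latent SD maps to AI 0.05
    ai_scale: float = 0.05
    baseline_asymmetry_scale: float = 0.5
    size_log_sd: float = 0.1
    brain_size_log_sd: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_regions < 1:
            raise ParameterError("n_individuals and n_regions must be positive")
        if not -1.0 < self.score_correlation < 1.0:
            raise ParameterError(
                f"score_correlation must lie in (-1, 1), got {self.score_correlation}"
            )
        if not np.isfinite(self.score_sex_shift):
            raise ParameterError("score_sex_shift must be finite")
        for name in ("canonical_r_A", "canonical_r_B"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ParameterError(f"{name} must lie in [0, 1), got {r}")
        for name in ("loading_pattern_A", "loading_pattern_B"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != (self.n_regions,):
                    raise ParameterError(f"{name} must have length n_regions={self.n_regions}")
                if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                    raise ParameterError(f"{name} must have unit Euclidean norm")
        rates = np.asarray(self.handedness_base_rates, float)
        if rates.shape != (3,) or np.any(rates < 0) or abs(rates.sum() - 1.0) > 1e-8:
            raise ParameterError("handedness_base_rates must be a 3-simplex (right, left, mixed)")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ParameterError("outlier_rate must lie in [0, 1)")
        if not 0.0 < self.female_fraction < 1.0:
            raise ParameterError("female_fraction must lie in (0, 1)")

    def region_table(self):
        return default_region_table(self.n_regions)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("loading_pattern_A", "loading_pattern_B", "sex_pattern"):
            if d[key] is not None:
                d[key] = [float(x) for x in np.asarray(d[key]).ravel()]
        d["handedness_base_rates"] = [float(x) for x in d["handedness_base_rates"]]
        d["handedness_betas"] = {
            k: [float(x) for x in v] for k, v in d["handedness_betas"].items()
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "covariate_specs" in d:
            d["covariate_specs"] = [
                cs if isinstance(cs, CovariateSpec) else CovariateSpec(**cs)
                for cs in d["covariate_specs"]
            ]
        if "phenotype_specs" in d:
            d["phenotype_specs"] = [
                ps if isinstance(ps, PhenotypeSpec) else PhenotypeSpec(**ps)
                for ps in d["phenotype_specs"]
            ]
        if "handedness_base_rates" in d:
            d["handedness_base_rates"] = tuple(d["handedness_base_rates"])
        if "handedness_betas" in d:
            d["handedness_betas"] = {k: tuple(v) for k, v in d["handedness_betas"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
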