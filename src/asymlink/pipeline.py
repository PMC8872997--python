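"""End-to-end orchestration: simulate -> preprocess -> CCA -> pattern
comparison -> sex analysis -> handedness -> phenome scan.

A :class:`RunConfig` carries every threshold and seed; the single run seed
expands deterministically into per-stage child seeds (via
``numpy.random.SeedSequence``) so any stage can be rerun in isolation.
Outputs are TSV tables plus a machine-readable JSON summary embedding the
configuration hash and all seeds.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import asymmetry, cca, handedness, pattern_comparison, phewas, sex_analysis
from .config import SimulationConfig
from .synthetic_data import SCORE_COLUMNS, Cohort, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

_STAGES = ("simulate", "pattern", "sex", "phewas", "reserved1", "reserved2")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from one run seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    score_cols: tuple[str, str] = SCORE_COLUMNS
    n_permutations_pattern: int = 10000
    n_permutations_sex: int = 10000
    outlier_sd: float = 6.0
    loading_threshold: float = 0.2
    fdr_q: float = 0.05
    brain_size_sensitivity: bool = False
    run_phewas: bool = True
    run_univariate: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["score_cols"] = list(self.score_cols)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        d["score_cols"] = tuple(d.get("score_cols", SCORE_COLUMNS))
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _cca_summary(res: cca.CCAResult) -> dict:
    return {
        "canonical_r": float(res.canonical_r),
        "p_value": float(res.p_value),
        "n": int(res.n),
        "p": int(res.p),
    }


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None,
                 cohort: Cohort | None = None) -> dict:
    """Execute every stage and return the machine-readable summary.

    If ``output_dir`` is given, per-stage tables (cohort, loadings, sex
    map, handedness, phenome scan) and ``summary.json`` are written there.
    A pre-built ``cohort`` skips the simulation stage (its table must
    carry the standard column layout).
    """
    seeds = stage_seeds(config.seed)
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        # the run seed owns all randomness: the simulation stage uses its
        # child seed regardless of what the nested simulation config says
        sim = SimulationConfig.from_dict(config.simulation.to_dict())
        sim.seed = seeds["simulate"]
        cohort = simulate_cohort(sim)
    table = cohort.table

    summary: dict = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "n": int(len(table)),
        "stages": {},
    }
    r_scores = float(np.corrcoef(table[config.score_cols[0]],
                                 table[config.score_cols[1]])[0, 1])
    sex_t = {}
    for col in config.score_cols:
        t, p = stats.ttest_ind(table.loc[table.sex == 1, col],
                               table.loc[table.sex == 0, col])
        sex_t[col] = {"t": float(t), "p": float(p)}
    summary["stages"]["scores"] = {"correlation": r_scores, "sex_ttests": sex_t}

    # preprocessing, with and without sex in the confound design
    extra = ["brain_size"] if config.brain_size_sensitivity else None
    ai_sex = asymmetry.prepare_asymmetry_matrix(
        cohort, include_sex=True, extra_covariates=extra, sd_threshold=config.outlier_sd
    )
    ai_nosex = asymmetry.prepare_asymmetry_matrix(
        cohort, include_sex=False, extra_covariates=extra, sd_threshold=config.outlier_sd
    )
    summary["stages"]["asymmetry"] = {
        "n_complete": ai_sex.provenance["n_complete"],
        "outlier_removals": int(sum(ai_sex.provenance["outlier_removals"].values())),
        "p": ai_sex.p,
    }

    cca_results = {}
    for col in config.score_cols:
        res = cca.scalar_cca(table[col], ai_sex)
        cca_results[col] = res
        summary["stages"].setdefault("cca", {})[col] = _cca_summary(res)
        if out is not None:
            res.loading_table().to_csv(out / f"loadings_{col}.tsv", sep="\t",
                                       index=False, float_format="%.10g")

    comp = pattern_comparison.compare_loading_patterns(
        table[config.score_cols[0]],
        table[config.score_cols[1]],
        ai_sex,
        n_perm=config.n_permutations_pattern,
        seed=seeds["pattern"],
        threshold=config.loading_threshold,
    )
    summary["stages"]["pattern_comparison"] = {
        "observed_r": float(comp.observed_r),
        "empirical_p": float(comp.empirical_p),
        "n_permutations": comp.n_permutations,
        "concordant_regions": comp.concordant_regions,
        "discordant_regions": comp.discordant_regions,
    }

    sex_map = sex_analysis.sex_ttests(ai_nosex, table["sex"])
    sex_stage = {"n_significant_unadjusted": int(np.sum(sex_map.p_values < 0.05))}
    for col in config.score_cols:
        r, p_emp, _ = sex_analysis.sex_pattern_correlation(
            sex_map, cca_results[col].loadings, ai_nosex, table["sex"],
            n_perm=config.n_permutations_sex, seed=seeds["sex"],
        )
        sex_stage[col] = {"loading_t_correlation": float(r), "empirical_p": float(p_emp)}
    summary["stages"]["sex_analysis"] = sex_stage
    if out is not None:
        sex_map.table().to_csv(out / "sex_map.tsv", sep="\t", index=False,
                               float_format="%.10g")

    design = asymmetry.build_covariate_design(table, include_sex=True)
    hand = handedness.fit_handedness_models(table, score_cols=config.score_cols,
                                            design=design)
    summary["stages"]["handedness"] = hand.to_dict(orient="records")
    if out is not None:
        hand.to_csv(out / "handedness.tsv", sep="\t", index=False, float_format="%.10g")

    if config.run_phewas:
        pheno_cols = list(cohort.codebook)
        phewas_stage = {}
        for col in config.score_cols:
            res = phewas.run_phewas(table, col, pheno_cols, codebook=cohort.codebook,
                                    design=design, q=config.fdr_q)
            phewas_stage[col] = {
                "n_tested": int(len(res.table)),
                "n_discoveries": res.n_discoveries,
                "n_excluded": len(res.excluded),
            }
            if out is not None:
                res.table.to_csv(out / f"phewas_{col}.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        summary["stages"]["phewas"] = phewas_stage

    if config.run_univariate:
        unil = asymmetry.prepare_unilateral_matrix(cohort, include_sex=True,
                                                   sd_threshold=config.outlier_sd)
        for col in config.score_cols:
            uni = cca.univariate_associations(table[col], unil)
            if out is not None:
                uni.to_csv(out / f"univariate_{col}.tsv", sep="\t", index=False,
                           float_format="%.10g")
            summary["stages"].setdefault("univariate", {})[col] = {
                "n_measures": int(len(uni)),
                "n_significant_unadjusted": int((uni["p"] < 0.05).sum()),
            }

    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out / "run_config.yaml", "w") as fh:
            fh.write(config.to_yaml())
        _write_report(summary, out / "report.txt")
    return summary


def _write_report(summary: dict, path: Path) -> None:
    s = summary["stages"]
    lines = [
        "Polygenic risk and multivariate brain asymmetry: run report",
        f"config hash: {summary['config_hash']}   n = {summary['n']}",
        "",
        f"score correlation: r = {s['scores']['correlation']:.4f}",
    ]
    for col, res in s["cca"].items():
        lines.append(
            f"{col}: canonical r = {res['canonical_r']:.4f}, "
            f"p = {res['p_value']:.3g} (n = {res['n']})"
        )
    pc = s["pattern_comparison"]
    lines.append(
        f"loading-pattern correlation: r = {pc['observed_r']:.3f}, "
        f"permuted p = {pc['empirical_p']:.3g} "
        f"({pc['n_permutations']} permutations)"
    )
    lines.append(f"concordant regions: {', '.join(pc['concordant_regions']) or 'none'}")
    lines.append(f"discordant regions: {', '.join(pc['discordant_regions']) or 'none'}")
    for col in s["cca"]:
        sa = s["sex_analysis"][col]
        lines.append(
            f"sex t-map vs {col} loadings: r = {sa['loading_t_correlation']:.3f}, "
            f"permuted p = {sa['empirical_p']:.3g}"
        )
    for row in s["handedness"]:
        lines.append(
            f"handedness {row['contrast']} ~ {row['score']}: "
            f"beta = {row['beta']:.4f} (p = {row['p']:.3g})"
        )
    if "phewas" in s:
        for col, res in s["phewas"].items():
            lines.append(
                f"phenome scan {col}: {res['n_discoveries']} discoveries "
                f"of {res['n_tested']} phenotypes at FDR {0.05}"
            )
    path.write_text("\n".join(lines) + "\n")
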