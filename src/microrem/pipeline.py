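"""End-to-end orchestration: diversity -> differential abundance -> random
forests -> top-taxa score -> Cox / LPS association, from a single config.

A run writes every stage's tabular output plus ``manifest.json`` recording
the package version, resolved parameters, seeds and a SHA-256 checksum of
each output file; reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import FeatureSpec, build_features, cv_random_forest, mda_importance, top_taxa
from .lefse import cladogram_table, run_lefse
from .outcomes import (
    association_score_lps,
    baseline_table,
    cox_by_score_tertile,
    lps_fold_change,
)
from .profiles import alpha_diversity, compare_alpha, read_abundance
from .score import build_score_rules, patient_score, rules_frame, scores_frame
from .simulate import CohortTable, SimulationConfig, SyntheticCohort, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised when the run configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either ``simulate`` holds a :class:`SimulationConfig` or the four input
    paths are given. Stage parameters default to the study's stated values
    (alpha 0.05, |LDA| > 2, 10 folds, top 10 taxa) or to documented design
    defaults otherwise.
    """

    out_dir: str | Path = "microrem_run"
    simulate: SimulationConfig | None = None
    abundance_path: str | Path | None = None
    clinical_path: str | Path | None = None
    outcomes_path: str | Path | None = None
    lps_path: str | Path | None = None
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    k_folds: int = 10
    n_trees: int = 1000
    mda_repeats: int = 5
    top_m: int = 10
    rf_variants: tuple[str, ...] = ("classic", "microbiome", "combined")
    mda_variant: str = "microbiome"
    adjustment_sets: tuple[str, ...] = ("primary", "extended")
    with_lps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None:
            needed = {
                "abundance_path": self.abundance_path,
                "clinical_path": self.clinical_path,
                "outcomes_path": self.outcomes_path,
            }
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise PipelineConfigError(
                    f"either a simulate block or input paths are required; missing {missing}"
                )
            if self.with_lps and self.lps_path is None:
                raise PipelineConfigError(
                    "LPS association stage requested but no lps_path given"
                )
        if self.mda_variant not in self.rf_variants:
            raise PipelineConfigError(
                f"mda_variant {self.mda_variant!r} not among rf_variants {self.rf_variants}"
            )


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Read a YAML run configuration; keyword overrides win over the file."""
    raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    sim = raw.pop("simulate", None)
    if sim is not None:
        seed = raw.get("seed")
        if seed is not None:  # a top-level seed drives the simulate block too
            sim = {**sim, "seed": seed}
        sim = SimulationConfig(**sim)
    for key in ("rf_variants", "adjustment_sets"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(simulate=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kw)


def _load_inputs(config: RunConfig) -> tuple[SyntheticCohort | None, Any, CohortTable]:
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        return cohort, cohort.abundance, cohort.cohort
    abundance = read_abundance(config.abundance_path)
    clinical = pd.read_csv(config.clinical_path, index_col=0)
    outcomes = pd.read_csv(config.outcomes_path, index_col=0)
    lps = (
        pd.read_csv(config.lps_path, index_col=0)
        if config.lps_path is not None
        else pd.DataFrame(index=clinical.index, columns=["fasting_lps", "postprandial_lps"])
    )
    return None, abundance, CohortTable(clinical=clinical, outcomes=outcomes, lps=lps)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write outputs plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings: list[str] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s finished in %.2fs", name, timings[name])

        return _Timer()

    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("lefse", "rf", "mda"), ss.spawn(3))
    }

    with stage("inputs"):
        synthetic, abundance, cohort = _load_inputs(config)
        labels = cohort.outcomes["responder"].reindex(abundance.data.index)
        if labels.isna().any():
            raise PipelineConfigError(
                f"outcomes missing for samples: {abundance.data.index[labels.isna()].tolist()}"
            )
        if synthetic is not None:
            write_cohort(synthetic, out / "cohort")

    with stage("baseline_table"):
        baseline = baseline_table(cohort.clinical, labels)
        _write_tsv(baseline, out / "baseline.tsv")

    with stage("diversity"):
        div = alpha_diversity(abundance)
        comparison = compare_alpha(div, labels)
        _write_tsv(div.frame, out / "alpha_diversity.tsv", index_label="sample_id")
        _write_tsv(comparison, out / "alpha_comparison.tsv", index_label="index")

    with stage("lefse"):
        lefse = run_lefse(
            abundance, labels,
            alpha=config.alpha, threshold=config.lda_threshold,
            n_boot=config.n_boot, seed=seeds["lefse"],
        )
        _write_tsv(lefse, out / "lefse.tsv", index_label="lineage")
        _write_tsv(cladogram_table(lefse), out / "cladogram.tsv", index=False)

    rf_summaries: dict[str, dict[str, float]] = {}
    importance = None
    with stage("random_forest"):
        for i, variant in enumerate(config.rf_variants):
            spec = FeatureSpec(variant=variant)
            X, y = build_features(
                abundance if spec.uses_microbiome else None, cohort, spec
            )
            res = cv_random_forest(
                X, y, k=config.k_folds, n_trees=config.n_trees,
                seed=seeds["rf"] + i, variant=variant,
            )
            rf_summaries[variant] = {
                "auc_mean": res.auc_mean, "auc_sd": res.auc_sd,
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "threshold": res.threshold,
            }
            _write_tsv(res.roc_grid, out / f"roc_{variant}.tsv", index=False)
            if variant == config.mda_variant:
                importance = mda_importance(
                    X, y, k=config.k_folds, n_trees=config.n_trees,
                    n_repeats=config.mda_repeats, seed=seeds["mda"],
                )
                _write_tsv(importance, out / "importance.tsv")
        (out / "rf_models.json").write_text(json.dumps(rf_summaries, indent=2, sort_keys=True))

    with stage("score"):
        top = top_taxa(importance, m=config.top_m)
        rules = build_score_rules(abundance, labels, top, taxa=list(top.index))
        score_result = patient_score(abundance, rules)
        _write_tsv(rules_frame(rules), out / "rules.tsv")
        _write_tsv(scores_frame(score_result), out / "scores.tsv")

    cox_out: dict[str, Any] = {}
    with stage("cox"):
        surv = pd.concat(
            [cohort.outcomes[["time_years", "event"]], cohort.clinical], axis=1
        )
        for adj in config.adjustment_sets:
            res = cox_by_score_tertile(surv, score_result.tertiles, adjustment_set=adj)
            cox_out[adj] = {
                label: res.summary.loc[label].to_dict() for label in ("T2", "T3")
            }
            _write_tsv(res.curves, out / f"curves_{adj}.tsv")
        (out / "cox.json").write_text(json.dumps(cox_out, indent=2, sort_keys=True))

    if config.with_lps:
        with stage("lps_association"):
            fold, lps_terts = lps_fold_change(cohort.lps)
            assoc = association_score_lps(score_result.tertiles, lps_terts)
            payload = {
                "counts": assoc["table"].to_dict(),
                "chi2": assoc["chi2"], "p_value": assoc["p_value"], "df": assoc["df"],
                "spearman_rho": assoc["spearman_rho"], "spearman_p": assoc["spearman_p"],
            }
            (out / "association.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": _config_dict(config),
        "timings_s": timings,
        "warnings": warnings,
        "outputs": {
            p.relative_to(out).as_posix(): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    for key in ("abundance_path", "clinical_path", "outcomes_path", "lps_path"):
        if d[key] is not None:
            d[key] = str(d[key])
    if d["simulate"] is not None:
        d["simulate"]["covariate_shift"] = dict(d["simulate"]["covariate_shift"])
    d["rf_variants"] = list(d["rf_variants"])
    d["adjustment_sets"] = list(d["adjustment_sets"])
    return d
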