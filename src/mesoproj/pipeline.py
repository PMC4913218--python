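"""End-to-end orchestration of the analysis chain.

Stages run in the canonical order: obtain a raw cohort (generated or
loaded) → threshold weak regions → fit the injection-volume power law →
volume-normalize → unit-mean normalize → per-region GLM and μ_kc →
bootstrap test → correlation graph + multiscale clustering → leave-one-out
classification → combined report.  One master seed fans out to per-stage
seeds through a fixed derivation, so a config plus one integer reproduces
every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bootstrap as bt
from . import classify as cl
from . import glm, preprocess, stability
from .cohort import CohortTable, load_cohort, subset_cohort, write_cohort
from .synthetic import CohortDesign, generate_cohort

logger = logging.getLogger(__name__)

#: Stage codes for seed derivation: master seed s and stage code k give
#: stream np.random.SeedSequence([s, k]); generate_state(1) is the stage seed.
STAGE_SEEDS = {"simulate": 0, "bootstrap": 1, "cluster": 2}


def stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence([int(master), STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run description."""

    # input: either three file paths, or a generator design
    values_path: str | None = None
    metadata_path: str | None = None
    ontology_path: str | None = None
    generator: CohortDesign | None = field(default_factory=CohortDesign)
    sex: str | None = None  # optional stratification: 'M' or 'F'
    min_mean_pf: float = preprocess.DEFAULT_MIN_MEAN_PF
    volume_exponent: float | None = None  # None → fit from the data
    bootstrap_R: int = 50
    tail: str = "positive"
    cluster: bool = True
    cluster_times: tuple[float, ...] | None = None
    cluster_restarts: int = 20
    rounds: int = 100
    depth: int = 1
    scale_policy: str = "inner"
    fixed_scale: int | None = None
    residualize_once: bool = False
    seed: int = 0
    outdir: str = "mesoproj_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        if isinstance(gen, dict):
            d["generator"] = CohortDesign(**gen)
        if d.get("cluster_times") is not None:
            d["cluster_times"] = tuple(float(t) for t in d["cluster_times"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns findings (empty = valid)."""
    problems: list[str] = []
    paths = (config.values_path, config.metadata_path, config.ontology_path)
    has_paths = all(p is not None for p in paths)
    some_paths = any(p is not None for p in paths)
    if some_paths and not has_paths:
        problems.append("values_path, metadata_path and ontology_path must be given together")
    if not has_paths and config.generator is None:
        problems.append("either input file paths or a generator design is required")
    if config.sex not in (None, "M", "F"):
        problems.append(f"sex must be 'M', 'F' or null, got {config.sex!r}")
    if not (config.min_mean_pf >= 0):
        problems.append(f"min_mean_pf must be >= 0, got {config.min_mean_pf}")
    if config.bootstrap_R < 1:
        problems.append(f"bootstrap_R must be >= 1, got {config.bootstrap_R}")
    if config.tail not in bt.TAILS:
        problems.append(f"tail must be one of {bt.TAILS}, got {config.tail!r}")
    if config.cluster_times is not None:
        ts = np.asarray(config.cluster_times, dtype=float)
        if len(ts) == 0 or np.any(ts <= 0) or np.any(np.diff(ts) < 0):
            problems.append("cluster_times must be a non-empty ascending grid of positive reals")
    if config.cluster_restarts < 1:
        problems.append(f"cluster_restarts must be >= 1, got {config.cluster_restarts}")
    if config.rounds < 1:
        problems.append(f"rounds must be >= 1, got {config.rounds}")
    if config.depth < 1:
        problems.append(f"depth must be >= 1, got {config.depth}")
    if config.scale_policy not in cl.SCALE_POLICIES:
        problems.append(
            f"scale_policy must be one of {cl.SCALE_POLICIES}, got {config.scale_policy!r}"
        )
    return problems


def _obtain_cohort(config: PipelineConfig) -> tuple[CohortTable, dict | None]:
    if config.values_path is not None:
        cohort = load_cohort(config.values_path, config.metadata_path, config.ontology_path)
        truth_doc = None
    else:
        cohort, truth = generate_cohort(config.generator, stage_seed(config.seed, "simulate"))
        truth_doc = {
            "exponent": truth.exponent,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
            "clipped_fraction": truth.clipped_fraction,
            "mean_condition_effect": float(truth.condition_effect.mean()),
        }
    if config.sex is not None:
        cohort = subset_cohort(cohort, lambda a: a.sex == config.sex)
    return cohort, truth_doc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain; returns (and writes) the combined report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    timings: dict[str, float] = {}
    report: dict[str, Any] = {"config_hash": chash, "seed": config.seed}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc_type is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                else:
                    logger.info("stage %s: done in %.3fs", name, timings[name])

        return _T()

    try:
        with timed("input"):
            cohort, truth_doc = _obtain_cohort(config)
            write_cohort(cohort, outdir / "raw")
            report["n_animals"] = cohort.n_animals
            report["n_regions_raw"] = cohort.n_regions
            if truth_doc:
                report["generator_truth"] = truth_doc

        with timed("threshold"):
            thresholded, removed = preprocess.threshold_regions(cohort, config.min_mean_pf)
            report["n_regions_removed"] = len(removed)
            report["n_regions_retained"] = thresholded.n_regions

        with timed("fit_volume"):
            if config.volume_exponent is None:
                fit = preprocess.fit_volume_exponent(thresholded)
                exponent = fit.exponent
                report["power_law"] = {
                    "exponent": fit.exponent,
                    "prefactor": fit.prefactor,
                    "r_squared": fit.r_squared,
                }
            else:
                exponent = float(config.volume_exponent)
                report["power_law"] = {"exponent": exponent, "fixed": True}

        with timed("normalize"):
            volnorm = preprocess.normalize_by_volume(thresholded, exponent)
            unit = preprocess.unit_mean_normalize(volnorm)
            write_cohort(unit, outdir / "unit_mean")

        with timed("glm"):
            glm_fit = glm.fit_region_glm(unit, include_condition=True)
            glm_fit.table.to_csv(outdir / "glm_fit.csv", index_label="region")
            report["mu_kc"] = glm_fit.mean_condition_effect()

        with timed("bootstrap"):
            boot = bt.bootstrap_condition_test(
                unit,
                R=config.bootstrap_R,
                tail=config.tail,
                seed=stage_seed(config.seed, "bootstrap"),
            )
            (outdir / "bootstrap.json").write_text(
                json.dumps(boot.to_dict(), indent=2) + "\n", encoding="utf-8"
            )
            report["bootstrap"] = {
                "tail": boot.tail,
                "comparisons": boot.comparisons,
                "tail_fraction": boot.tail_fraction,
                "p_value": boot.p_value,
            }

        hierarchy = None
        if config.cluster:
            with timed("cluster"):
                features = glm.residualize_covariates(unit)
                graph = stability.region_correlation_graph(features)
                stability.graph_to_edgelist_csv(graph, outdir / "correlation_graph.csv")
                times = (
                    np.asarray(config.cluster_times, float)
                    if config.cluster_times is not None
                    else stability.default_time_grid()
                )
                hierarchy = stability.markov_stability_scan(
                    graph,
                    times=times,
                    n_restarts=config.cluster_restarts,
                    seed=stage_seed(config.seed, "cluster"),
                )
                hierarchy.to_json(outdir / "hierarchy.json")
                report["cluster"] = {
                    "n_scales": len(hierarchy),
                    "n_clusters_per_scale": [s.n_clusters for s in hierarchy],
                }

        with timed("classify"):
            loo = cl.loocv_classify(
                unit,
                hierarchy=hierarchy,
                rounds=config.rounds,
                depth=config.depth,
                scale_policy=config.scale_policy,
                fixed_scale=config.fixed_scale,
                residualize_once=config.residualize_once,
            )
            (outdir / "classification.json").write_text(
                json.dumps(loo.to_dict(), indent=2) + "\n", encoding="utf-8"
            )
            report["classification"] = {
                "error_count": loo.error_count,
                "n_animals": loo.n_animals,
                "accuracy": loo.accuracy,
                "accuracy_pct": loo.accuracy_pct,
                "binomial_p": loo.binomial_p,
                "scale_policy": loo.scale_policy,
            }
    except Exception as exc:
        stage = next(reversed(timings), "input") if timings else "input"
        raise RuntimeError(f"pipeline aborted (last stage: {stage}): {exc}") from exc

    report["timings_s"] = timings
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str) + "\n", encoding="utf-8"
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    (outdir / "report.md").write_text(_markdown_report(report), encoding="utf-8")
    return report


def _markdown_report(report: dict) -> str:
    lines = [
        "# mesoproj run report",
        "",
        f"- config hash: `{report['config_hash']}` (seed {report['seed']})",
        f"- animals: {report['n_animals']}; regions: {report['n_regions_retained']} retained "
        f"of {report['n_regions_raw']} ({report['n_regions_removed']} below threshold)",
        f"- power-law exponent n = {report['power_law']['exponent']:.4f}",
        f"- mean condition coefficient μ_kc = {report['mu_kc']:.4f}",
        f"- bootstrap ({report['bootstrap']['tail']} tail, "
        f"{report['bootstrap']['comparisons']} comparisons): p = {report['bootstrap']['p_value']:.4f}",
    ]
    if "classification" in report:
        c = report["classification"]
        lines.append(
            f"- leave-one-out classification: {c['accuracy_pct']}% "
            f"({c['error_count']} errors of {c['n_animals']}), binomial p = {c['binomial_p']:.2e}"
        )
    return "\n".join(lines) + "\n"
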