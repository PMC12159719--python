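"""End-to-end orchestration: simulate/ingest -> preprocess -> BLUEs -> CV -> GGE.

`run_pipeline` produces a deterministic run directory::

    outdir/
      data/         genotype TSV, phenotype CSV (+ ground-truth sidecars)
      blues/        per-trait BLUE and variance-component CSVs
      cv_results/   per-trait CV tables, per-approach summary, threshold stat
      gge/          environment scores, cosine matrices, biplot PNGs
      manifests/    resolved config, selected SNPs, run log

Every stochastic step derives its seed from the run seed; reruns with the
same config are byte-identical for the deterministic (linear/ridge) paths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, gge, io, preprocess
from .blues import compute_blues
from .datatypes import BLUETable
from .evaluate import NetworkSettings, loo_location_cv, variance_threshold_stat
from .simulate import SyntheticConfig, simulate_dataset


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str
    synthetic: SyntheticConfig | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    traits: list[str] | None = None
    approaches: tuple[str, ...] = evaluate.APPROACHES
    bases: tuple[str, ...] = ("linear", "ridge")
    maf_threshold: float = 0.05
    n_components: int | None = None
    validation_mode: str = "holdout"
    seed: int = 0
    network: NetworkSettings = field(default_factory=NetworkSettings)
    full_scale: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.approaches:
            raise ValueError("config requests zero approaches")
        if not self.bases:
            raise ValueError("config requests zero bases")
        if self.synthetic is None and not (self.genotypes_path
                                           and self.phenotypes_path):
            raise ValueError("need either a synthetic config or input paths")
        if self.full_scale:
            self.network.tune_draws = 300


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.pop("synthetic", None)
    net = raw.pop("network", None)
    cfg = RunConfig(
        synthetic=SyntheticConfig(**syn) if syn is not None else None,
        network=NetworkSettings(**net) if net is not None else NetworkSettings(),
        **{k: tuple(v) if k in ("approaches", "bases") else v
           for k, v in raw.items()},
    )
    return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("data")
def _stage_data(config: RunConfig, outdir: Path, log: list):
    data_dir = outdir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        markers, phen, truth = simulate_dataset(config.synthetic)
        io.write_genotypes(markers, data_dir / "genotypes.tsv")
        io.write_phenotypes(phen, data_dir / "phenotypes.csv")
        io.write_ground_truth(truth, data_dir / "truth")
        log.append({"event": "simulate", "seed": config.synthetic.seed,
                    "n_records": len(phen)})
    else:
        markers = io.read_genotypes(config.genotypes_path)
        phen = io.read_phenotypes(config.phenotypes_path, markers)
        log.append({"event": "ingest", "n_records": len(phen)})
    return markers, phen


@_stage("preprocess")
def _stage_preprocess(config: RunConfig, markers, traits, outdir: Path, log: list):
    filtered = preprocess.filter_maf(markers, config.maf_threshold)
    log.append({"event": "maf_filter", "threshold": config.maf_threshold,
                "n_snps_in": markers.n_snps, "n_snps_kept": filtered.n_snps})
    selected = {}
    for trait in traits:
        snps = preprocess.pca_feature_select(filtered, config.n_components)
        selected[trait] = snps
        io.write_selected_snps(snps, outdir / "manifests" / f"snps_{trait}.txt")
        log.append({"event": "feature_select", "trait": trait, "n_snps": len(snps)})
    return filtered, selected


@_stage("blues")
def _stage_blues(phen, traits, outdir: Path, log: list) -> BLUETable:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        blues = compute_blues(phen, traits=traits)
    for w in caught:
        log.append({"event": "blues_warning", "message": str(w.message)})
    (outdir / "blues").mkdir(exist_ok=True)
    io.write_blue_table(blues, outdir / "blues" / "blues.csv",
                        outdir / "blues" / "components.csv")
    return blues


@_stage("cv")
def _stage_cv(config: RunConfig, filtered, blues, selected, traits,
              outdir: Path, log: list) -> pd.DataFrame:
    cv_dir = outdir / "cv_results"
    cv_dir.mkdir(exist_ok=True)
    all_results = []
    for trait in traits:
        dataset = preprocess.assemble_dataset(filtered, blues, trait,
                                              selected[trait])
        results = loo_location_cv(
            dataset, approaches=config.approaches, bases=config.bases,
            seed=config.seed, validation_mode=config.validation_mode,
            network=config.network, components=blues.components, run_log=log,
        )
        results.to_csv(cv_dir / f"cv_{trait}.csv", index=False)
        all_results.append(results)
    results = pd.concat(all_results, ignore_index=True)
    summary = (results.groupby(["trait", "approach", "base"], as_index=False)
               ["accuracy"].mean())
    summary.to_csv(cv_dir / "summary.csv", index=False)
    if {"singular", "ensemble"} <= set(config.approaches):
        try:
            combos, overall = variance_threshold_stat(results)
            combos.to_csv(cv_dir / "variance_threshold.csv", index=False)
            log.append({"event": "variance_threshold",
                        "overall_mean_pct": overall})
        except ValueError as exc:
            log.append({"event": "variance_threshold_undefined",
                        "message": str(exc)})
    return results


@_stage("gge")
def _stage_gge(config: RunConfig, blues, traits, outdir: Path, log: list):
    gge_dir = outdir / "gge"
    gge_dir.mkdir(exist_ok=True)
    for trait in traits:
        try:
            result = gge.run_gge(blues, trait)
        except ValueError as exc:
            log.append({"event": "gge_skipped", "trait": trait,
                        "message": str(exc)})
            continue
        lengths, cosines = gge.env_vector_stats(result)
        scores = result.environment_scores.copy()
        scores["vector_length"] = lengths
        scores.rename_axis("environment").to_csv(gge_dir / f"env_scores_{trait}.csv")
        cosines.rename_axis("environment").to_csv(gge_dir / f"env_cosines_{trait}.csv")
        log.append({"event": "gge", "trait": trait,
                    "fill_fraction": result.fill_fraction,
                    "pc_fractions": result.pc_variance_fractions[:2].tolist()})
        if config.make_plots:
            gge.plot_biplot(result, str(gge_dir / f"biplot_{trait}.png"))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory."""
    outdir = Path(config.outdir)
    for sub in ("data", "blues", "cv_results", "gge", "manifests"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    log: list[dict] = [{"event": "run", "seed": config.seed,
                        "validation_mode": config.validation_mode}]

    markers, phen = _stage_data(config, outdir, log)
    traits = config.traits or sorted(phen["trait"].unique())
    if not traits:
        raise PipelineError("stage 'config' failed: no traits to analyze")
    filtered, selected = _stage_preprocess(config, markers, traits, outdir, log)
    blues = _stage_blues(phen, traits, outdir, log)
    _stage_cv(config, filtered, blues, selected, traits, outdir, log)
    _stage_gge(config, blues, traits, outdir, log)

    manifest = asdict(config)
    manifest["synthetic"] = (asdict(config.synthetic)
                             if config.synthetic is not None else None)
    (outdir / "manifests" / "config.yaml").write_text(
        yaml.safe_dump(_yamlable(manifest), sort_keys=True))
    (outdir / "log.txt").write_text(
        "\n".join(json.dumps(_yamlable(e), sort_keys=True) for e in log) + "\n")
    return outdir


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
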