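"""End-to-end pipeline driver.

``run_pipeline`` chains the full analysis on a synthetic or user-supplied
study: simulate/read -> QC filter + LOD imputation -> cross-sectional
screen -> longitudinal screen -> exhaustive threshold-model search and
selection -> cross-time-point transfer of the best model -> sex/age
sensitivity -> PCA. Every stage writes a CSV into the output directory;
every output carries a header comment with the package version and a hash
of the resolved configuration, and the whole bundle is deterministic given
the global seed (per-stage sub-seeds are split from it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import logistic_adjust, stratified_compare
from .io import read_study, write_study
from .longitudinal import COHORTS, interval_summary, longitudinal_screen
from .qc import filter_features, impute_below_lod, zscore
from .synth import GeneratorConfig, simulate_study
from .tables import GROUP_STRESS, FeatureTable, ValidationError
from .threshold import (
    ModelSpec,
    fit_threshold_model,
    score,
    search_models,
    select_models,
    transfer_evaluate,
)
from .unsupervised import confidence_ellipse, pca

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

ALL_STAGES = ("simulate", "qc", "screen", "longitudinal", "search", "transfer", "adjust", "pca")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run (defaults = study settings)."""

    study_dir: str | None = None  # read an existing study instead of simulating
    out_dir: str = "rinsemet_out"
    stages: tuple = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha: float = 0.05  # two-sided significance level
    magnitude: float = 0.30  # longitudinal highlight threshold
    n_boot: int = 100
    ci_level: float = 0.95
    top_k: int = 50  # candidates carried from AUC screen into bootstrap
    search_stratum: str = "Rest"
    search_families: tuple = ("single", "ratio")
    screen_strata: tuple = ("Rest", "Post-UK", "Recover", "Post-WM", "median")
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["time_points"] = list(d["generator"]["time_points"])
        d["generator"]["planted_effects"] = [
            dataclasses.asdict(e) if dataclasses.is_dataclass(e) else e
            for e in self.generator.planted_effects
        ]
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = self.resolved()
        d.pop("out_dir", None)
        d.pop("study_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON document mirroring the fields."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    gen = doc.pop("generator", {})
    if gen:
        doc["generator"] = GeneratorConfig(**gen)
    return PipelineConfig(**doc)


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rinsemet {__version__} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the configured stages; return the in-memory report bundle."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg.resolved(), "config_hash": cfg.config_hash()}
    root_seed = np.random.SeedSequence(cfg.seed)
    stage_seeds = {s: c for s, c in zip(ALL_STAGES, root_seed.spawn(len(ALL_STAGES)))}

    def stage_on(name: str) -> bool:
        return name in cfg.stages

    try:
        if cfg.study_dir is not None:
            table = read_study(cfg.study_dir)
        else:
            gen = cfg.generator.replace(seed=int(stage_seeds["simulate"].generate_state(1)[0] % 2**31))
            table = simulate_study(gen)
            if stage_on("simulate"):
                write_study(table, out / "study")
        bundle["study"] = table
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'simulate/read' failed: {e}") from e

    filtered = table
    if stage_on("qc"):
        try:
            filtered, report = filter_features(table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                filtered = impute_below_lod(filtered)
            _write(report.decisions.reset_index(), out / "qc_report.csv", cfg)
            bundle["qc_report"] = report
            bundle["filtered"] = filtered
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'qc' failed: {e}") from e
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered = impute_below_lod(table)

    if stage_on("screen"):
        try:
            from .univariate import group_screen

            frames = [group_screen(filtered, s) for s in cfg.screen_strata]
            screen = pd.concat(frames, ignore_index=True)
            _write(screen, out / "screen.csv", cfg)
            bundle["screen"] = screen
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'screen' failed: {e}") from e

    if stage_on("longitudinal"):
        try:
            frames = []
            for cohort in COHORTS:
                res = longitudinal_screen(filtered, cohort)
                summ = interval_summary(filtered, cohort, cfg.alpha, cfg.magnitude, result=res)
                frames.append(summ)
            longi = pd.concat(frames, ignore_index=True)
            _write(longi, out / "longitudinal_intervals.csv", cfg)
            bundle["longitudinal"] = longi
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'longitudinal' failed: {e}") from e

    best_model = None
    if stage_on("search"):
        try:
            seed = int(stage_seeds["search"].generate_state(1)[0] % 2**31)
            searches, selections = {}, {}
            for family in cfg.search_families:
                res = search_models(
                    filtered, cfg.search_stratum, family,
                    n_boot=cfg.n_boot, seed=seed, top_k=cfg.top_k,
                )
                searches[family] = res
                selections[family] = select_models(res, cfg.search_stratum)
                _write(res, out / f"search_{family}.csv", cfg)
                _write(selections[family], out / f"selected_{family}.csv", cfg)
            bundle["search"] = searches
            bundle["selected"] = selections
            fam = "ratio" if "ratio" in searches else cfg.search_families[0]
            top = searches[fam].iloc[0]
            best_model = fit_threshold_model(
                ModelSpec(top["numerator"], top["denominator"] if pd.notna(top["denominator"]) else None),
                filtered,
                cfg.search_stratum,
            )
            bundle["best_model"] = best_model
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'search' failed: {e}") from e

    if stage_on("transfer") and best_model is not None:
        try:
            strata = [t for t in filtered.time_points] + ["All"]
            trans = transfer_evaluate(best_model, filtered, strata)
            _write(trans, out / "transfer.csv", cfg)
            bundle["transfer"] = trans
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'transfer' failed: {e}") from e

    if stage_on("adjust") and best_model is not None:
        try:
            sub = filtered.at_time_point(cfg.search_stratum) if cfg.search_stratum != "All" else filtered
            sc = score(best_model.spec, sub)
            part = sub.samples.drop_duplicates("participant").set_index("participant")
            per_part = sc.groupby(sub.samples["participant"].to_numpy()).median()
            y = (part.loc[per_part.index, "group"] == GROUP_STRESS).to_numpy()
            fit = logistic_adjust(
                per_part.to_numpy(),
                y,
                part.loc[per_part.index, "sex"].to_numpy(),
                part.loc[per_part.index, "age_group"].to_numpy(),
            )
            strat = stratified_compare(per_part.to_numpy(), y, part.loc[per_part.index, "sex"].to_numpy())
            _write(fit.terms.reset_index(names="term"), out / "adjusted_fit.csv", cfg)
            _write(strat, out / "sex_stratified.csv", cfg)
            bundle["adjusted"] = fit
            bundle["stratified"] = strat
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'adjust' failed: {e}") from e

    if stage_on("pca"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z = zscore(filtered)
            res = pca(z, n_components=2)
            ell, inside = confidence_ellipse(res.scores, z.samples["group"].to_numpy())
            scores = res.scores.copy()
            scores["inside_own_group_ellipse"] = inside
            _write(scores.reset_index(), out / "pca_scores.csv", cfg)
            _write(ell, out / "pca_ellipses.csv", cfg)
            bundle["pca"] = res
            bundle["ellipses"] = ell
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'pca' failed: {e}") from e

    with open(out / "run_config.json", "w") as fh:
        json.dump({"hash": cfg.config_hash(), "config": cfg.resolved()}, fh, indent=2, default=str)
    return bundle
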