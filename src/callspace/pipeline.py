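"""End-to-end pipeline: simulate/load -> space -> metrics -> foxp2 -> stats.

Every stage reads and writes plain files in a run directory so stages can
be re-run in isolation; a manifest records versions, seeds, and per-stage
record counts.  A single global seed fans out into stage-keyed substreams,
so one stage's randomness never perturbs another's.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import substream
from .errors import CallspaceError, ConfigurationError
from .expression import icc_agreement, load_cell_counts, summarize_expression
from .features import load_feature_table, write_feature_table
from .glm import SamplerConfig, TTestResult, fit_glm, pooled_ttest, summarize_results
from .metrics import MetricsConfig, compute_measures
from .space import embed, make_grid
from .synthetic import SimConfig, simulate_cell_counts, simulate_flocks

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("callspace")

RESPONSES = ("vocal_diversity", "vocal_plasticity", "vocal_convergence")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Defaults reproduce the study's stated parameters: rarefaction to 180
    calls over 30 subsets, minimum 6 final-block calls, 95% HPD intervals,
    and the full-length sampler.  Either ``simulate`` is on (synthetic run)
    or ``feature_table``/``cell_counts`` point at input CSVs.
    """

    out_dir: str = "callspace_run"
    seed: int = 0
    simulate: bool = True
    feature_table: str | None = None
    cell_counts: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    embed_method: str = "tsne"
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    observer_policy: str = "average"
    stages: tuple[str, ...] = ("simulate", "space", "metrics", "foxp2", "stats", "report")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim_raw = dict(kwargs["sim"])
            from .synthetic import AgeClassParams, ExpressionParams

            if "age_params" in sim_raw:
                sim_raw["age_params"] = {
                    age: AgeClassParams(**p) for age, p in sim_raw["age_params"].items()
                }
            if "expression_params" in sim_raw:
                sim_raw["expression_params"] = {
                    age: ExpressionParams(**p) for age, p in sim_raw["expression_params"].items()
                }
            kwargs["sim"] = SimConfig(**sim_raw)
        if "metrics" in kwargs and isinstance(kwargs["metrics"], dict):
            kwargs["metrics"] = MetricsConfig(**kwargs["metrics"])
        if "sampler" in kwargs and isinstance(kwargs["sampler"], dict):
            kwargs["sampler"] = SamplerConfig(**kwargs["sampler"])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)

    def resolve_seeds(self) -> None:
        """Fan the global seed out into stage substreams (stage-name keyed)."""
        self.sim.seed = int(substream(self.seed, "simulate").integers(2**31))
        self.metrics.seed = int(substream(self.seed, "metrics").integers(2**31))
        self.sampler.seed = int(substream(self.seed, "stats").integers(2**31))
        self._embed_seed = int(substream(self.seed, "space").integers(2**31))

    def param_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        text = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _timed(manifest: dict, stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            manifest.setdefault("stages", {}).setdefault(stage, {})
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, *_):
            manifest.setdefault("stages", {}).setdefault(stage, {})["seconds"] = round(
                time.perf_counter() - self.t0, 3
            )
            log.info("stage %s: done (%.2fs)", stage, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.resolve_seeds()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
    }

    # --- inputs: simulate or load -----------------------------------------
    features_path = out / "features.csv"
    counts_path = out / "cell_counts.csv"
    if "simulate" in config.stages and config.simulate:
        with _timed(manifest, "simulate"):
            calls, truth = simulate_flocks(config.sim)
            write_feature_table(calls, features_path)
            truth.to_json(out / "ground_truth.json")
            simulate_cell_counts(config.sim).to_csv(counts_path, index=False)
            manifest["stages"]["simulate"]["n_calls"] = len(calls)
    else:
        if config.feature_table is None:
            raise CallspaceError("stage 'space' needs a feature table: none simulated or supplied")
        features_path = Path(config.feature_table)
        if not features_path.exists():
            raise CallspaceError(f"missing input file: {features_path}")
        if config.cell_counts is not None:
            counts_path = Path(config.cell_counts)

    calls = load_feature_table(features_path)

    # --- acoustic space ----------------------------------------------------
    if "space" in config.stages:
        with _timed(manifest, "space"):
            emb = embed(
                calls,
                perplexity=config.perplexity,
                seed=config._embed_seed,
                n_iter=config.tsne_iterations,
                method=config.embed_method,
            )
            emb.to_csv(out / "embedding.csv")
            manifest["stages"]["space"]["n_points"] = len(emb.coords)
            manifest["stages"]["space"]["feature_hash"] = emb.feature_hash

    # --- learning measures -------------------------------------------------
    measures = None
    if "metrics" in config.stages:
        with _timed(manifest, "metrics"):
            emb_df = pd.read_csv(out / "embedding.csv")
            from .space import EmbeddingSpace

            emb = EmbeddingSpace(
                coords=emb_df, perplexity=config.perplexity,
                seed=config._embed_seed, n_iter=config.tsne_iterations,
                method=config.embed_method, feature_hash="",
            )
            grid = make_grid(emb.points, config.metrics.pad_fraction, config.metrics.grid_cells)
            measures = compute_measures(calls, emb, config.metrics, grid)
            measures.to_csv(out / "measures.csv", index=False)
            manifest["stages"]["metrics"]["n_birds"] = len(measures)
            manifest["stages"]["metrics"]["n_included"] = int(measures["included"].sum())

    # --- FoxP2 expression ----------------------------------------------------
    expr = None
    if "foxp2" in config.stages and counts_path.exists():
        with _timed(manifest, "foxp2"):
            counts = load_cell_counts(counts_path)
            expr = summarize_expression(counts, config.observer_policy)
            expr.to_csv(out / "expression.csv", index=False)
            # inter-observer reliability on per-bird ratios, one column per observer
            obs_ratio = {
                obs: summarize_expression(
                    counts[counts["observer_id"] == obs], "average"
                ).set_index("bird_id")["foxp2_ratio"]
                for obs in sorted(counts["observer_id"].unique())
            }
            table = pd.DataFrame(obs_ratio).dropna()
            icc = icc_agreement(table)
            with open(out / "icc.json", "w") as fh:
                json.dump(vars(icc), fh, indent=1)
            manifest["stages"]["foxp2"]["n_birds"] = len(expr)
            manifest["stages"]["foxp2"]["icc"] = icc.icc

    # --- group statistics ----------------------------------------------------
    if "stats" in config.stages:
        with _timed(manifest, "stats"):
            if measures is None:
                measures = pd.read_csv(out / "measures.csv")
            if expr is None and (out / "expression.csv").exists():
                expr = pd.read_csv(out / "expression.csv")
            ttests: dict[str, TTestResult] = {}
            if expr is not None and "age_class" in expr.columns:
                groups = dict(tuple(expr.groupby("age_class", observed=True)))
                if len(groups) == 2:
                    (g1, d1), (g2, d2) = sorted(groups.items(), reverse=True)  # young first
                    for col, label in (
                        ("prop_mmst", "mmst_proportion"),
                        ("prop_vsp", "vsp_proportion"),
                        ("foxp2_ratio", "mmst_vsp_ratio"),
                    ):
                        ttests[label] = pooled_ttest(d1[col], d2[col])
            fits = {}
            if expr is not None:
                ratios = expr.set_index("bird_id")["foxp2_ratio"]
                for response in RESPONSES:
                    fits[response] = fit_glm(measures, response, ratios, config.sampler)
                    fits[response].summary().to_csv(
                        out / f"glm_{response}.csv", index=False
                    )
            report = summarize_results(ttests, fits, out / "results.json")
            manifest["stages"]["stats"]["n_models"] = len(fits)
            # Table-1-shaped CSV: one row per response x fixed effect
            rows = []
            for resp, fit in fits.items():
                for effect in ("foxp2", "age", "foxp2_x_age"):
                    c = report["glm"][resp]["coefficients"][effect]
                    rows.append(
                        {
                            "response": resp,
                            "fixed_effect": effect,
                            "estimate": c["estimate"],
                            "lower": c["hpd_lower"],
                            "upper": c["hpd_upper"],
                            "significant": c["significant"],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "coefficients.csv", index=False)

    if "report" in config.stages:
        manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
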