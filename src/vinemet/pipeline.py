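"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` names either an input abundance table (plus class
annotation) or a synthetic-cohort configuration, with the stage parameters
(alpha, correlation threshold, sign policy, p-value method, PCA depth) and an
output directory. :func:`run_pipeline` then produces, deterministically under
the configured seed:

* ``abundance.tsv`` / ``annotation.tsv`` — the analyzed table;
* ``diff_<variety>.tsv`` — per-variety temperature fold-change reports;
* ``pca_scores.tsv`` / ``pca_loadings.tsv`` / ``pca_summary.json``;
* per-variety networks in GraphML, SIF and TSV;
* ``comparison.json`` — common vs unique edge bookkeeping;
* ``graph_stats.json`` — the property table, for both the full filtered
  networks and the unique-edge networks.

Every JSON artifact is stamped with the config hash and seed, and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import diffabund, graphstats, multivariate, network, synth
from .io import (
    AbundanceTable,
    read_abundance_table,
    read_class_annotation,
    write_abundance_table,
    write_class_annotation,
    write_network,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs; exactly one data source set."""

    input_path: str | None = None
    annotation_path: str | None = None
    sim: synth.SimConfig | None = None
    alpha: float = 0.05
    threshold: float = 0.5
    sign_policy: str = "positive_only"
    p_method: str = "auto"
    pca_components: int = 2
    collapse_days: bool = True
    walktrap_t: int = 4
    outdir: str = "results/pipeline"
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("set exactly one of input_path and sim")
        if self.input_path is not None and self.annotation_path is None:
            raise ValueError("an input table needs an annotation_path")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.sign_policy not in ("positive_only", "both"):
            raise ValueError(f"unknown sign policy {self.sign_policy!r}")
        if self.p_method not in ("auto", "exact_permutation", "t_approx"):
            raise ValueError(f"unknown p-value method {self.p_method!r}")

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if self.sim is not None:
            sim = out["sim"]
            sim["effects"] = [
                {
                    "metabolite": e.metabolite,
                    "baseline_mean": e.baseline_mean,
                    "temp_fold_change": dict(e.temp_fold_change),
                    "cultivar_fold_change": dict(e.cultivar_fold_change),
                    "biochemical_class": e.biochemical_class,
                }
                for e in self.sim.effects
            ]
            sim["block_correlation"] = dict(self.sim.block_correlation)
        return out

    def content_hash(self) -> str:
        """Hash of the analysis-defining fields (the destination is excluded)."""
        payload = self.to_dict()
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def default_synthetic_config(seed: int = 1, **changes) -> PipelineConfig:
    """Paper-shaped defaults over the default synthetic cohort."""
    return PipelineConfig(sim=synth.default_config(seed=seed), seed=seed, **changes)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML/JSON pipeline config; a ``sim`` block builds a SimConfig."""
    raw = yaml.safe_load(Path(path).read_text())
    if "sim" in raw and raw["sim"] is not None:
        sim = raw["sim"]
        effects = sim.pop("effects", "fixture")
        if effects == "fixture":
            panel = synth.load_fixture_effects()
        else:
            panel = [
                synth.EffectSpec(
                    metabolite=e["metabolite"],
                    baseline_mean=e.get("baseline_mean", 100.0),
                    temp_fold_change=e.get("temp_fold_change", {"Cs": 1.0, "Sh": 1.0}),
                    cultivar_fold_change=e.get(
                        "cultivar_fold_change", {"25": 1.0, "35": 1.0}
                    ),
                    biochemical_class=e.get("biochemical_class", "carboxylic acid"),
                )
                for e in effects
            ]
        raw["sim"] = synth.SimConfig(effects=panel, **sim)
    return PipelineConfig(**raw)


def _stamp(config: PipelineConfig) -> dict[str, Any]:
    return {"config_hash": config.content_hash(), "seed": config.seed}


def _write_json(payload: dict, path: Path) -> Path:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage end to end; returns the artifact name -> path map."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- data ---------------------------------------------------------------
    if config.sim is not None:
        table = synth.generate_abundance_table(config.sim)
        annotation = config.sim.annotation()
    else:
        table = read_abundance_table(config.input_path)
        annotation = read_class_annotation(config.annotation_path)
    artifacts["abundance"] = write_abundance_table(table, outdir / "abundance.tsv")
    artifacts["annotation"] = write_class_annotation(
        annotation, outdir / "annotation.tsv"
    )

    varieties = sorted(table.samples["cultivar"].unique())

    # --- differential abundance ---------------------------------------------
    for variety in varieties:
        frame, summary = diffabund.diff_report(
            table,
            numerator={"cultivar": variety, "temperature": "35"},
            denominator={"cultivar": variety, "temperature": "25"},
            alpha=config.alpha,
            collapse_days=config.collapse_days,
        )
        frame = frame.assign(
            biochemical_class=[annotation.get(m, "unknown") for m in frame.metabolite]
        )
        path = outdir / f"diff_{variety}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts[f"diff_{variety}"] = path
        logger.info(
            "%s 35/25: %d significant, mean |change| %.1f%%",
            variety, summary.n_significant, summary.mean_abs_percent_change,
        )

    # --- PCA ----------------------------------------------------------------
    pca_res = multivariate.pca(table, k=config.pca_components)
    scores = pca_res.scores.copy()
    scores.insert(0, "cultivar", table.samples["cultivar"])
    scores.insert(1, "temperature", table.samples["temperature"])
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False,
                  float_format="%.6g")
    pca_res.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t",
                            index_label="metabolite", float_format="%.6g")
    _write_json(
        {
            **_stamp(config),
            "explained_variance_fraction": [
                round(float(f), 6) for f in pca_res.explained_variance_fraction
            ],
            "top_loadings_pc1": multivariate.top_loadings(pca_res, 1, 5),
            "top_loadings_pc2": multivariate.top_loadings(pca_res, 2, 5),
        },
        outdir / "pca_summary.json",
    )
    artifacts["pca_scores"] = outdir / "pca_scores.tsv"
    artifacts["pca_loadings"] = outdir / "pca_loadings.tsv"
    artifacts["pca_summary"] = outdir / "pca_summary.json"

    # --- networks -----------------------------------------------------------
    networks = {}
    for variety in varieties:
        ratio = network.ratio_to_control(table, variety)
        net = network.build_network(
            ratio,
            annotation,
            threshold=config.threshold,
            alpha=config.alpha,
            sign_policy=config.sign_policy,
            method=config.p_method,
        )
        networks[variety] = net
        for fmt in ("graphml", "sif", "tsv"):
            artifacts[f"network_{variety}_{fmt}"] = write_network(
                net, outdir / f"network_{variety}.{fmt}", fmt
            )

    comparison = None
    if len(varieties) == 2:
        a, b = varieties
        comparison = network.compare_networks(networks[a], networks[b])
        _write_json(
            {
                **_stamp(config),
                "varieties": list(comparison.varieties),
                "n_common": len(comparison.common),
                "common_edges": [list(p) for p in sorted(comparison.common)],
                "n_unique": {v: len(u) for v, u in comparison.unique.items()},
                "percent_common": {
                    v: round(p) for v, p in comparison.percent_common.items()
                },
            },
            outdir / "comparison.json",
        )
        artifacts["comparison"] = outdir / "comparison.json"

    # --- graph properties ---------------------------------------------------
    stats_payload: dict[str, Any] = _stamp(config)
    for variety, net in networks.items():
        entry = {"full": graphstats.graph_stats(
            net, annotation, comparison, walktrap_t=config.walktrap_t
        ).to_dict()}
        if comparison is not None:
            uniq = network.unique_edge_network(net, comparison)
            entry["unique_edges_only"] = graphstats.graph_stats(
                uniq, annotation, walktrap_t=config.walktrap_t
            ).to_dict()
        stats_payload[variety] = entry
    artifacts["graph_stats"] = _write_json(stats_payload, outdir / "graph_stats.json")
    return artifacts
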