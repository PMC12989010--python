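"""One-command execution of the full analysis.

The pipeline validates inputs before touching the output location, runs
preprocess -> GGM estimation -> centrality/communities -> (optional
case-drop bootstrap) -> linkage, and writes every artifact plus a manifest
into the output directory atomically (a temp directory renamed into place on
success, so a failed run leaves nothing behind).
"""

from __future__ import annotations

import json
import shutil
import tempfile
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .config import PipelineConfig, stage_seed
from .descriptives import CentralityProfile, CommunityPartition, expected_influence, walktrap
from .ggm import GGMNetwork, fit_ggm
from .io import read_condition_csv, read_facet_csv, write_matrix_csv
from .linkage import LinkageResult, run_linkage
from .preprocess import (
    RedundancyReport,
    estimate_correlations,
    goldbricker,
    npn_transform,
    validate_facets,
)
from .stability import StabilityResult, case_drop_bootstrap

__all__ = ["RunBundle", "run_pipeline", "simulate_dataset"]


@dataclass
class RunBundle:
    """Everything one run produced, with a consistent node-label set."""

    config: PipelineConfig
    facets: pd.DataFrame
    conditions: pd.DataFrame | None
    network: GGMNetwork
    profile: CentralityProfile
    communities: CommunityPartition
    redundancy: RedundancyReport
    stability: StabilityResult | None = None
    linkage: LinkageResult | None = None
    truth: synthetic.SyntheticSpec | None = None
    log: list[dict] = field(default_factory=list)


def simulate_dataset(cfg: PipelineConfig):
    """Generate (facets, conditions, truth spec) per the synthetic block."""
    syn = cfg.synthetic
    if syn is None:
        raise ValueError("config has no synthetic block")
    spec = synthetic.generate_true_network(
        p=syn.p,
        n_communities=syn.n_communities,
        within_prob=syn.within_prob,
        between_prob=syn.between_prob,
        weight_range=(syn.weight_lo, syn.weight_hi),
        positive_frac=syn.positive_frac,
        seed=stage_seed(cfg.seed, "network"),
        likert_items=syn.likert_items,
        item_noise_sd=syn.item_noise_sd,
    )
    facets = synthetic.sample_facet_data(spec, n=syn.n, seed=stage_seed(cfg.seed, "facets"))
    synthetic.attach_condition_model(
        spec,
        q=syn.q,
        facets_per_condition=syn.facets_per_condition,
        seed=stage_seed(cfg.seed, "loadings"),
    )
    spec.noise_sd = synthetic.noise_sd_for_r2(facets, spec.loadings, syn.condition_r2)
    conditions = synthetic.sample_condition_scores(
        facets, spec, seed=stage_seed(cfg.seed, "conditions")
    )
    return facets, conditions, spec


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        return simulate_dataset(cfg)
    facets = read_facet_csv(cfg.facets_csv)
    conditions = None
    if cfg.conditions_csv is not None:
        try:
            conditions = read_condition_csv(cfg.conditions_csv, n_expected=len(facets))
        except ValueError as exc:
            raise ValueError(f"{cfg.conditions_csv} does not match {cfg.facets_csv}: {exc}") from exc
    return facets, conditions, None


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> RunBundle:
    """Execute the full pipeline under one configuration.

    Same config + seed => identical outputs.  With ``write=True`` all
    artifacts land in ``cfg.output_dir`` (created atomically).
    """
    cfg.validate()
    log: list[dict] = []
    captured: list[str] = []

    def _stage(name):
        return _StageTimer(name, log)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        with _stage("load"):
            facets, conditions, truth = _load_inputs(cfg)
            validate_facets(facets)

        with _stage("preprocess"):
            redundancy = goldbricker(
                facets,
                cor_min=cfg.goldbricker_cor_min,
                alpha=cfg.goldbricker_alpha,
                prop_threshold=cfg.goldbricker_prop_threshold,
            )
            if cfg.reduce_nodes:
                facets = facets[redundancy.suggested_reduced_node_set]
            transformed = npn_transform(facets)
            S = estimate_correlations(transformed, method=cfg.correlation_method)

        with _stage("ggm"):
            network = fit_ggm(
                S,
                n=len(facets),
                gamma=cfg.gamma,
                n_lambda=cfg.n_lambda,
                lambda_min_ratio=cfg.lambda_min_ratio,
            )

        with _stage("descriptives"):
            profile = expected_influence(network)
            communities = walktrap(network, walk_length=cfg.walk_length)

        stability = None
        if cfg.run_stability:
            with _stage("stability"):
                stability = case_drop_bootstrap(
                    facets,
                    B=cfg.bootstrap_B,
                    drop_proportions=cfg.drop_proportions,
                    seed=stage_seed(cfg.seed, "bootstrap"),
                    correlation_method=cfg.correlation_method,
                    gamma=cfg.gamma,
                    n_lambda=cfg.stability_n_lambda or cfg.n_lambda,
                    lambda_min_ratio=cfg.lambda_min_ratio,
                )

        linkage = None
        if conditions is not None:
            with _stage("linkage"):
                linkage = run_linkage(
                    facets,
                    conditions,
                    profile,
                    method=cfg.linkage_method,
                    threshold_mode=cfg.threshold_mode,
                    threshold_value=cfg.threshold_value,
                )

        captured = [str(w.message) for w in wlist]

    bundle = RunBundle(
        config=cfg,
        facets=facets,
        conditions=conditions,
        network=network,
        profile=profile,
        communities=communities,
        redundancy=redundancy,
        stability=stability,
        linkage=linkage,
        truth=truth,
        log=log + [{"warnings": captured}],
    )
    if write:
        _write_bundle(bundle)
    return bundle


class _StageTimer:
    def __init__(self, name: str, log: list):
        self.name, self.log = name, log

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        self.log.append({"stage": self.name, "seconds": round(time.perf_counter() - self.t0, 4)})


def _write_bundle(bundle: RunBundle) -> None:
    cfg = bundle.config
    final = Path(cfg.output_dir)
    final.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".awnet_tmp_", dir=final.parent))
    try:
        write_matrix_csv(bundle.facets, tmp / "facets.csv")
        if bundle.conditions is not None:
            write_matrix_csv(bundle.conditions, tmp / "conditions.csv")
        bundle.network.write_json(tmp / "network.json")
        bundle.network.write_edge_csv(tmp / "edges.csv")
        bundle.network.write_graphml(tmp / "network.graphml")
        bundle.profile.to_frame().to_csv(tmp / "centrality.csv")
        bundle.communities.to_frame().to_csv(tmp / "communities.csv")
        with open(tmp / "redundancy.json", "w") as fh:
            json.dump(bundle.redundancy.to_dict(), fh, indent=1)
        if bundle.stability is not None:
            with open(tmp / "stability.json", "w") as fh:
                json.dump(bundle.stability.to_dict(), fh, indent=1)
            bundle.stability.correlations.to_csv(tmp / "stability_correlations.csv", index=False)
        if bundle.linkage is not None:
            with open(tmp / "linkage.json", "w") as fh:
                json.dump(bundle.linkage.to_dict(), fh, indent=1)
            bundle.linkage.step1.to_csv(tmp / "step1_correlations.csv")
            bundle.linkage.step2.to_csv(tmp / "step2_summary.csv")
            bundle.linkage.heatmap_table().to_csv(tmp / "relevance_heatmap.csv")
        if bundle.truth is not None:
            bundle.truth.to_json(tmp / "truth.json")
        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "node_labels": bundle.network.node_labels,
            "log": bundle.log,
        }
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        if final.exists():
            shutil.rmtree(final)
        tmp.rename(final)
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
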