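"""End-to-end orchestration: networks -> metrics -> dominance -> models.

Stages communicate through on-disk CSV/JSON artifacts so each is
independently inspectable, and a run manifest (configuration, seed, package
version) makes any run replayable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (observation_metadata_from_workbook,
                         read_agonistic_table, read_scan_table,
                         read_supplementary_workbook, write_adjacency)
from .dominance import analyze_group
from .mixed_models import (FULL_TERMS, aic_backward_reduction, prepare_design,
                           residual_diagnostics, tukey_contrasts, vif_check)
from .network_build import GroomingNetwork, build_networks
from .network_metrics import (MetricsOptions, compute_metrics_table,
                              metric_correlation_screen,
                              metrics_from_published, standardize_metrics)
from .reference import describe_sample

logger = logging.getLogger(__name__)

DEFAULT_RESPONSES = ["out_strength", "in_strength", "disparity", "affinity",
                     "eigenvector"]


@dataclass
class RunConfig:
    """One reproducible analysis run."""

    output_dir: str
    seed: int
    scan_table: str | None = None
    workbook: str | None = None
    agonistic_table: str | None = None
    shared_denominator: bool = False
    disparity_symmetrized: bool = False
    affinity_weighted: bool = True
    responses: list[str] = field(default_factory=lambda:
                                 list(DEFAULT_RESPONSES))
    n_rand: int = 10_000
    outlier_alpha: float = 0.05
    run_dominance: bool = True
    run_models: bool = True

    def __post_init__(self) -> None:
        if self.scan_table is None and self.workbook is None:
            raise ValueError("need a scan table or a workbook as input")


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage; returns in-memory results and writes artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- stage: load / build networks ---------------------------------
    if config.scan_table is not None:
        obs = read_scan_table(config.scan_table)
        if config.agonistic_table is not None:
            obs.agonistic_events = read_agonistic_table(
                config.agonistic_table)
            obs.validate()
        networks = build_networks(obs,
                                  shared_denominator=config.shared_denominator)
        metrics = compute_metrics_table(
            networks, obs,
            MetricsOptions(disparity_symmetrized=config.disparity_symmetrized,
                           affinity_weighted=config.affinity_weighted))
        groups_df = pd.DataFrame({
            "group_id": [n.group_id for n in networks],
            "group_size": [n.n_nodes for n in networks],
            "sex_ratio": [obs.sex_ratio(n.group_id) for n in networks]})
        individuals_df = metrics[["group_id", "individual_id", "sex", "age",
                                  "rearing"]]
    else:
        wb = read_supplementary_workbook(config.workbook)
        obs = observation_metadata_from_workbook(wb)
        networks = [GroomingNetwork(group_id=gid, nodes=list(nodes), W=W)
                    for gid, (nodes, W) in wb.matrices.items()]
        metrics = metrics_from_published(wb.individuals, wb.groups)
        groups_df = wb.groups
        individuals_df = wb.individuals

    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for net in networks:
        write_adjacency(net.nodes, net.W, net_dir / f"{net.group_id}.csv")

    results["descriptors"] = describe_sample(individuals_df, groups_df)
    with open(out / "descriptors.json", "w") as fh:
        json.dump(results["descriptors"], fh, indent=2)

    # ---- stage: metrics ------------------------------------------------
    if "degree" in metrics:
        metrics = standardize_metrics(metrics)
    metrics.to_csv(out / "metrics.csv", index=False)
    screen = metric_correlation_screen(metrics)
    screen.to_csv(out / "correlation_screen.csv", index=False)
    results["metrics"] = metrics
    results["correlation_screen"] = screen

    # ---- stage: dominance ---------------------------------------------
    if config.run_dominance and obs.agonistic_events:
        dom_rows, score_rows = [], []
        for gid in obs.group_ids:
            if len(obs.members(gid)) < 3 or not obs.events_for(gid):
                continue
            res = analyze_group(obs, gid, n_rand=config.n_rand,
                                seed=config.seed)
            dom_rows.append({
                "group_id": gid, "steepness": res.steepness,
                "p_steepness": res.p_steepness, "h": res.h,
                "h_prime": res.h_prime, "p_linearity": res.p_linearity,
                "n_unknown_dyads": res.n_unknown_dyads,
                "passes_alpha_0.10": res.passes})
            for iid, nds, cds in zip(res.nodes, res.norm_ds, res.centered_ds):
                score_rows.append({"group_id": gid, "individual_id": iid,
                                   "norm_ds": nds, "centered_ds": cds})
        dominance_df = pd.DataFrame(dom_rows)
        dominance_df.to_csv(out / "dominance.csv", index=False)
        pd.DataFrame(score_rows).to_csv(out / "davids_scores.csv",
                                        index=False)
        results["dominance"] = dominance_df

    # ---- stage: mixed models ------------------------------------------
    if config.run_models:
        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        model_results = {}
        for response in config.responses:
            try:
                design = prepare_design(metrics, response,
                                        alpha=config.outlier_alpha)
                vifs = vif_check(design)
                final, path = aic_backward_reduction(design, FULL_TERMS)
                diag = residual_diagnostics(final, model_dir)
                final.summary_frame().to_csv(
                    model_dir / f"{response}_coefficients.csv")
                with open(model_dir / f"{response}_path.json", "w") as fh:
                    json.dump([{"dropped": s.dropped,
                                "aic_before": s.aic_before,
                                "aic_after": s.aic_after} for s in path],
                              fh, indent=2)
                contrasts = None
                if "male:atypical" in final.terms:
                    contrasts = tukey_contrasts(final, design)
                    contrasts.to_csv(
                        model_dir / f"{response}_tukey.csv", index=False)
                model_results[response] = {
                    "design": design, "fit": final, "path": path,
                    "vif": vifs, "diagnostics": diag,
                    "contrasts": contrasts}
            except Exception as exc:
                logger.error("model stage failed for %s: %s", response, exc)
                raise
        results["models"] = model_results

    manifest = {"config": asdict(config), "groomnet_version": __version__,
                "numpy_version": np.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


def replay(manifest_path: str | Path) -> dict:
    """Re-run an analysis from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_full_analysis(RunConfig(**manifest["config"]))
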