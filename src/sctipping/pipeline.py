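"""End-to-end orchestration: simulate/read -> log -> surprisal -> graph ->
cluster -> criticality -> network, with deterministic seeding and a
machine-readable summary.

A single global seed fans out to per-stage seeds through a CRC32 hash of
the stage name, so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import criticality as crit
from . import graph as graphmod
from . import network as netmod
from .cluster import cluster_by_day
from .data import (
    SingleCellTable,
    ValidationError,
    log_transform,
    read_table,
    write_table,
    zscore_normalize,
)
from .surprisal import decompose, orient_scores_by_marker
from .synthetic import GeneratorConfig, generate, write_truth


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_path: str | None = None
    simulate: GeneratorConfig | None = None
    floor: float | None = None
    zscore: bool = False
    n_modules: int = 2
    k_intra: int = 5
    k_inter: int = 3
    cluster_markers: tuple[str, ...] | None = None
    k_mode: str | int | dict = "auto"
    k_max: int = 8
    criticality_index: str = "snai"
    criticality_analytes: tuple[str, ...] | None = None
    network_alpha: float = 0.05
    path_marker: str = "MITF"
    out_dir: str = "run"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValidationError(
                "exactly one of input_path / simulate must be configured"
            )
        if self.criticality_index not in ("snai", "ic"):
            raise ValidationError("criticality_index must be 'snai' or 'ic'")
        if not 0 < self.network_alpha < 1:
            raise ValidationError("network_alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("n_cells_per_day", "days", "lambda1_schedule"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg = dataclasses.replace(cfg, simulate=GeneratorConfig(**sim))
        return cfg

    def config_hash(self) -> str:
        """Stable hash of everything that affects the analysis (not out_dir)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        canon = json.dumps(payload, sort_keys=True, default=_jsonify)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: CRC32 of the stage name folded into the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: SingleCellTable
    decomposition: object
    cell_graph: object
    assignment: object
    report: object
    networks: dict
    summary: dict
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Identical config and seed give a byte-identical ``summary.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    def run_stage(name: str, fn):
        log(f"stage {name} start")
        try:
            result = fn()
        except Exception as exc:
            log(f"stage {name} FAILED: {exc}")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError(name, exc) from exc
        log(f"stage {name} done")
        return result

    # -- input -----------------------------------------------------------
    def _input():
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(
                config.simulate, seed=stage_seed(config.seed, "simulate")
            )
            table, truth = generate(sim_cfg)
            write_table(table, out / "table.csv")
            write_truth(truth, out / "ground_truth.csv")
            return table
        return read_table(config.input_path, floor=config.floor)

    table = run_stage("input", _input)

    # -- preprocessing ---------------------------------------------------
    def _preprocess():
        logged = log_transform(table, floor=config.floor)
        return zscore_normalize(logged) if config.zscore else logged

    log_table = run_stage("preprocess", _preprocess)

    # -- surprisal -------------------------------------------------------
    def _surprisal():
        res = decompose(log_table, n_modules=config.n_modules)
        res.scores_frame().to_csv(out / "scores.csv", index=False)
        res.loadings_frame().to_csv(out / "loadings.csv", index=False)
        (out / "scree.txt").write_text(res.scree().to_string(index=False) + "\n")
        return res

    decomp = run_stage("surprisal", _surprisal)

    # -- trajectory graph ------------------------------------------------
    def _graph():
        cg = graphmod.build_graph(
            log_table, k_intra=config.k_intra, k_inter=config.k_inter
        )
        graphmod.layout(cg, seed=stage_seed(config.seed, "layout"))
        for j in range(1, config.n_modules + 1):
            cg.set_overlay(
                f"lambda{j}",
                dict(zip(log_table.cell_ids, decomp.module_scores[:, j - 1])),
            )
        cg.write_graphml(out / "graph.graphml")
        cg.edges_frame().to_csv(out / "graph_edges.csv", index=False)
        return cg

    cell_graph = run_stage("graph", _graph)

    # -- clustering ------------------------------------------------------
    def _cluster():
        assignment = cluster_by_day(
            log_table,
            markers=config.cluster_markers,
            k_per_day=config.k_mode,
            k_max=config.k_max,
        )
        frame = log_table.to_frame()[["cell_id", "day"]].copy()
        frame["cluster"] = assignment.labels
        frame.to_csv(out / "clusters.csv", index=False)
        rows = [
            {"day": d, "k": k, "wss": w}
            for d, curve in assignment.wss_curves.items()
            for k, w in curve
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "wss_curves.csv", index=False)
        return assignment

    assignment = run_stage("cluster", _cluster)

    # -- criticality -----------------------------------------------------
    def _criticality():
        lam2 = decomp.module_scores[:, min(1, config.n_modules - 1)]
        if config.path_marker in log_table.panel.names:
            lam2 = orient_scores_by_marker(
                lam2, log_table.column(config.path_marker)
            )
        report = crit.criticality_report(
            log_table,
            assignment,
            module2_scores=lam2,
            analytes=config.criticality_analytes,
            index=config.criticality_index,
        )
        report.frame.to_csv(out / "criticality.csv", index=False)
        return report

    report = run_stage("criticality", _criticality)

    # -- tipping + networks ---------------------------------------------
    def _network():
        networks: dict[str, object] = {}
        paths_summary: dict[str, dict] = {}
        analytes = list(log_table.panel.names)
        for path in ("upper", "lower"):
            tip = crit.tipping_cluster(
                report, path, index=config.criticality_index
            )
            members = assignment.members(tip)
            net = netmod.correlation_network(
                log_table.values[members],
                analytes,
                alpha=config.network_alpha,
                cluster_id=tip,
            )
            metrics = net.metrics_frame()
            metrics.to_csv(out / f"network_metrics_{path}.csv", index=False)
            net.edges_frame().to_csv(out / f"network_edges_{path}.csv", index=False)
            net.write_graphml(out / f"network_{path}.graphml")
            top3 = (
                metrics.sort_values(
                    ["hub_scaled", "analyte"], ascending=[False, True]
                )["analyte"]
                .head(3)
                .tolist()
            )
            row = report.row(tip)
            paths_summary[path] = {
                "tipping_cluster": int(tip),
                "day": int(row["day"]),
                "n_cells": int(row["n_cells"]),
                "snai": float(row["snai"]),
                "ic": float(row["ic"]),
                "top_hub_analytes": top3,
            }
            networks[path] = net
        return networks, paths_summary

    networks, paths_summary = run_stage("network", _network)

    summary = {
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "n_cells": int(log_table.n_cells),
        "n_analytes": int(log_table.n_analytes),
        "k_per_day": {str(d): int(k) for d, k in assignment.k_per_day.items()},
        "criticality_index": config.criticality_index,
        "paths": paths_summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, default=_jsonify) + "\n"
    )
    log("pipeline complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        config=config,
        table=table,
        decomposition=decomp,
        cell_graph=cell_graph,
        assignment=assignment,
        report=report,
        networks=networks,
        summary=summary,
        out_dir=out,
    )
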