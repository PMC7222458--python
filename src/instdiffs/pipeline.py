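"""End-to-end orchestration: config in, report bundle out.

``run_pipeline`` composes the stages -- load, impute, reliability,
screen, group comparison, partial correlations, path model, reduced
models -- and writes each product as a plain-text table plus a run
manifest, so a full analysis is reproducible from a single JSON config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd

from . import __version__
from .impute import knn_impute
from .pathmodel import build_path_model, export_graph, reduced_model
from .registry import load_matrix, load_registry, save_matrix, subset_units
from .reliability import cronbach_alpha, summarize_reliabilities
from .registry import OccasionPanel
from .screen import correlation_screen, group_compare, partial_correlation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    matrix_path: str
    registry_path: str
    output_dir: str
    panel_paths: dict[str, str] = field(default_factory=dict)  # measure -> CSV
    imputation_k: int = 5
    g: float | str = "uip"
    edge_bf: float = 3.0
    null_bf: float = 1.0 / 3.0
    p_alpha: float = 0.05
    group_flag_measure: str | None = None  # binary measure defining the partition
    group_unit_ids: list[str] | None = None  # or an explicit first-group id list
    exclude_units: list[str] = field(default_factory=list)
    partials: list[dict] = field(default_factory=list)  # {x, y, controls}
    focal_measures: list[str] = field(default_factory=list)
    path_model_measures: list[str] | None = None
    seed: int | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        cfg = json.loads(Path(path).read_text())
        return cls(**cfg)

    def validate(self) -> None:
        if not self.matrix_path:
            raise ValueError("matrix_path is required")
        if not self.registry_path:
            raise ValueError("registry_path is required")
        if not self.output_dir:
            raise ValueError("output_dir is required")
        if self.imputation_k < 1:
            raise ValueError("imputation_k must be >= 1")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str, manifest: dict, func, *args, **kwargs):
    start = time.perf_counter()
    try:
        result = func(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["stages"][name] = round(time.perf_counter() - start, 3)
    logger.info("stage %s done in %.3fs", name, manifest["stages"][name])
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the manifest (also written as ``manifest.json``), which
    records package version, config hash, seed and per-stage wall time.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    registry = _stage("registry", manifest, load_registry, config.registry_path)
    matrix = _stage("load", manifest, load_matrix, config.matrix_path, registry)
    if config.exclude_units:
        matrix = _stage(
            "exclude", manifest, subset_units, matrix, config.exclude_units
        )

    # reliability over any configured occasion panels
    if config.panel_paths:
        def _reliability():
            results = []
            for measure, path in config.panel_paths.items():
                wide = pd.read_csv(path, index_col=0)
                results.append(cronbach_alpha(OccasionPanel(measure, wide)))
            table = pd.DataFrame(
                [
                    {
                        "measure": r.measure_name,
                        "alpha": r.alpha,
                        "n_occasions": r.n_occasions,
                        "n_units": r.n_units,
                    }
                    for r in results
                ]
            )
            summary = summarize_reliabilities(results)
            return table, summary

        rel_table, rel_summary = _stage("reliability", manifest, _reliability)
        rel_table.to_csv(out / "reliability.csv", index=False)
        rel_summary.to_csv(out / "reliability_summary.csv", header=["value"])
        manifest["outputs"] += ["reliability.csv", "reliability_summary.csv"]

    if matrix.n_missing:
        completed, report = _stage(
            "impute", manifest, knn_impute, matrix, config.imputation_k
        )
        (out / "imputation_report.json").write_text(
            json.dumps(asdict(report), indent=2)
        )
        save_matrix(completed, out / "imputed_matrix.csv")
        manifest["outputs"] += ["imputation_report.json", "imputed_matrix.csv"]
    else:
        completed = matrix

    screen = _stage("screen", manifest, correlation_screen, completed)
    screen.to_long().to_csv(out / "screen.csv", index=False)
    counts = screen.tier_counts()
    (out / "screen_counts.json").write_text(
        json.dumps(
            {
                "n_pairs": screen.n_pairs,
                "effective_tests": screen.effective_tests,
                "tukey_alpha": screen.tukey_alpha,
                "n_p05_or_better": screen.n_significant("p05"),
                "n_tukey": screen.n_significant("tukey"),
                **counts,
            },
            indent=2,
        )
    )
    manifest["outputs"] += ["screen.csv", "screen_counts.json"]

    flag = None
    if config.group_flag_measure:
        col = completed.values[config.group_flag_measure]
        flag = (col > col.median()) if col.nunique() > 2 else (col == col.max())
    elif config.group_unit_ids:
        flag = completed.values.index.isin(config.group_unit_ids)
    if flag is not None:
        comparison = _stage(
            "group_compare", manifest, group_compare, completed, flag
        )
        comparison.table.to_csv(out / "group_comparison.csv")
        manifest["outputs"].append("group_comparison.csv")

    if config.partials:
        rows = []
        for spec in config.partials:
            pc = _stage(
                f"partial[{spec['x']}~{spec['y']}]",
                manifest,
                partial_correlation,
                completed,
                spec["x"],
                spec["y"],
                spec.get("controls", []),
            )
            rows.append(
                {
                    "x": pc.x,
                    "y": pc.y,
                    "controls": ";".join(pc.controls),
                    "r_p": pc.r_p,
                    "df": pc.df,
                    "p": pc.p,
                }
            )
        pd.DataFrame(rows).to_csv(out / "partial_correlations.csv", index=False)
        manifest["outputs"].append("partial_correlations.csv")

    path_matrix = completed
    if config.path_model_measures:
        path_matrix = completed.select_measures(config.path_model_measures)
    model = _stage(
        "path_model",
        manifest,
        build_path_model,
        path_matrix,
        registry,
        config.g,
        config.edge_bf,
        config.null_bf,
    )
    (out / "path_edges.csv").write_text(export_graph(model, "edge_csv"))
    (out / "path_model.dot").write_text(export_graph(model, "dot"))
    (out / "path_model.graphml").write_text(export_graph(model, "graphml"))
    (out / "path_counts.json").write_text(
        json.dumps(
            {
                "evaluated_pairs": model.evaluated_pairs,
                "n_edges": model.n_edges,
                "tier_counts": model.tier_counts,
            },
            indent=2,
        )
    )
    manifest["outputs"] += [
        "path_edges.csv",
        "path_model.dot",
        "path_model.graphml",
        "path_counts.json",
    ]

    for focal in config.focal_measures:
        sub = _stage(f"reduced[{focal}]", manifest, reduced_model, model, focal)
        name = f"reduced_{focal}.csv".replace("/", "_")
        (out / name).write_text(export_graph(sub, "edge_csv"))
        manifest["outputs"].append(name)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
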