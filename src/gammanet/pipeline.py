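"""End-to-end pipeline: read or build a network, cluster it level by level,
transform to a tree, lay it out and render it, writing all artifacts plus a
JSON manifest. One global seed deterministically derives the per-stage
seeds, so a config reproduces its outputs byte for byte (the manifest holds
no timestamps for exactly that reason)."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import graph_core as gcore
from .gamma_cluster import ClusterSearchParams, write_clusters_tsv
from .hierarchy import (GammaSchedule, create_multilevel_clusters,
                        level_subgraph, mean_level_density,
                        write_hierarchy_graphml)
from .layout import LayoutParams, force_layout, write_positions_json
from .netbuild import correlation_network, read_expression_tsv
from .render import StyleMap, render_svg
from .tree_transform import (tree_transformation, write_parent_map,
                             write_tree_graphml)

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str
    input_format: str = "edgelist"  # edgelist | graphml | expression
    delimiter: str | None = None
    correlation_threshold: float = 0.72
    gamma_schedule: tuple[float, ...] = (0.5, 0.7)
    min_size: int = 3
    restarts: int = 20
    rcl_alpha: float = 0.2
    layout: LayoutParams = field(default_factory=LayoutParams)
    style: StyleMap = field(default_factory=StyleMap)
    seed: int = 0
    out_dir: str = "gammanet_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        layout_kwargs = raw.pop("layout", {})
        if "area" in layout_kwargs:
            layout_kwargs["area"] = tuple(layout_kwargs["area"])
        style_kwargs = raw.pop("style", {})
        if "palette" in style_kwargs:
            style_kwargs["palette"] = tuple(style_kwargs["palette"])
        if "gamma_schedule" in raw:
            raw["gamma_schedule"] = tuple(raw["gamma_schedule"])
        return cls(layout=LayoutParams(**layout_kwargs),
                   style=StyleMap(**style_kwargs), **raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["layout"]["area"] = list(self.layout.area)
        d["style"]["palette"] = list(self.style.palette)
        d["gamma_schedule"] = list(self.gamma_schedule)
        return d


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # propagate with the stage name
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: %.3fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("input")
def _load_input(config: PipelineConfig):
    if config.input_format == "edgelist":
        return gcore.read_edge_list(config.input_path, config.delimiter)
    if config.input_format == "graphml":
        return gcore.read_graphml(config.input_path)
    if config.input_format == "expression":
        matrix = read_expression_tsv(config.input_path)
        return correlation_network(matrix, config.correlation_threshold)
    raise ValueError(f"unknown input format {config.input_format!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages and return the manifest (also written to
    ``<out_dir>/manifest.json``). Identical configs give byte-identical
    outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    graph = _load_input(config)

    params = ClusterSearchParams(
        gamma=config.gamma_schedule[0], min_size=config.min_size,
        restarts=config.restarts, rcl_alpha=config.rcl_alpha,
        seed=derive_seed(config.seed, "cluster"))
    schedule = GammaSchedule(tuple(config.gamma_schedule))

    hierarchy = _stage("hierarchy")(create_multilevel_clusters)(
        graph, schedule, params)
    tree = _stage("tree")(tree_transformation)(
        hierarchy, seed=derive_seed(config.seed, "tree"))
    layout_params = dataclasses.replace(
        config.layout, seed=derive_seed(config.seed, "layout"))
    result = _stage("layout")(force_layout)(tree, layout_params)

    files = {
        "clusters": str(out_dir / "clusters.tsv"),
        "hierarchy": str(out_dir / "hierarchy.graphml"),
        "tree": str(out_dir / "tree.graphml"),
        "parents": str(out_dir / "parents.tsv"),
        "positions": str(out_dir / "positions.json"),
        "svg": str(out_dir / "network.svg"),
        "manifest": str(out_dir / "manifest.json"),
    }
    write_clusters_tsv(hierarchy.clusters, files["clusters"])
    write_hierarchy_graphml(hierarchy, files["hierarchy"])
    write_tree_graphml(tree, files["tree"])
    write_parent_map(tree, files["parents"])
    write_positions_json(result, files["positions"])
    _stage("render")(render_svg)(tree, result, files["svg"], config.style)

    levels = []
    for lvl in range(hierarchy.n_levels + 1):
        sub = level_subgraph(hierarchy, lvl)
        levels.append({
            "level": lvl,
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "density": round(mean_level_density(hierarchy, lvl), 6),
            "n_clusters": sum(1 for c in hierarchy.clusters if c.level == lvl),
        })
    manifest = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "n_levels": hierarchy.n_levels,
        "n_clusters": len(hierarchy.clusters),
        "n_orphan_components": len(tree.orphan_attachments),
        "layout_iterations": result.iterations_run,
        "layout_converged": result.converged,
        "levels": levels,
        "files": files,
    }
    Path(files["manifest"]).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
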