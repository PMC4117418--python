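"""Gating-strategy serialization, cross-condition signaling induction, and
the end-to-end pipeline runner.

A gating strategy is the final purified tree expressed as, per target
population, the ordered gate list (marker, threshold, side) along its
unique root-to-leaf path.  Export writes a self-contained JSON document
(markers by name, thresholds at full precision, provenance with config
hash and seeds) whose re-import reproduces tree routing exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gating_tree import GatingNode, GatingTree, apply_tree
from .io_cyto import ExpressionTable, arcsinh_transform, read_events, select_markers
from .mixture_clustering import hclust_labels, npem_fit
from .purification import PurificationResult, ccast_purify
from .silhouette_refinement import refine_labels
from .stability import bootstrap_tree_stability
from .synthetic_data import default_spec, simulate

__all__ = [
    "export_strategy",
    "import_strategy",
    "signaling_induction",
    "PipelineConfig",
    "run_pipeline",
]


def _tree_to_json(tree: GatingTree) -> dict:
    nodes = []
    for node in tree.nodes.values():
        entry = {"id": node.id, "kind": node.kind, "size": node.size}
        if node.kind == "internal":
            entry.update(
                marker=node.marker,
                split_point=node.split_point,
                p_value=node.p_value,
                children=list(node.children),
            )
        else:
            entry.update(
                composition={str(k): v for k, v in node.composition.items()},
                dominant=node.dominant,
                purity=node.purity,
            )
        nodes.append(entry)
    return {"root": tree.root, "nodes": nodes}


def _tree_from_json(doc: dict) -> GatingTree:
    tree = GatingTree(root=doc["root"])
    for entry in doc["nodes"]:
        node = GatingNode(id=entry["id"], kind=entry["kind"], size=entry.get("size", 0))
        if entry["kind"] == "internal":
            node.marker = entry["marker"]
            node.split_point = float(entry["split_point"])
            node.p_value = entry.get("p_value")
            node.children = tuple(entry["children"])
        else:
            node.composition = {int(k): v for k, v in entry["composition"].items()}
            node.dominant = entry["dominant"]
            node.purity = entry["purity"]
        tree.nodes[node.id] = node
    return tree


def export_strategy(
    result: PurificationResult, path: str | Path, provenance: dict | None = None
) -> Path:
    """Write the gating strategy as a self-contained JSON document.

    Per population: leaf id, mapped cluster, and the ordered gate sequence
    along the root-to-leaf path; thresholds are the tree's split points at
    full precision.
    """
    tree = result.final_tree
    populations = []
    for leaf in tree.leaves():
        gates = [
            {"marker": m, "threshold": c, "side": side}
            for m, c, side in tree.path_to(leaf.id)
        ]
        populations.append(
            {
                "leaf": leaf.id,
                "cluster": result.leaf_to_cluster[leaf.id],
                "size": leaf.size,
                "purity": leaf.purity,
                "gates": gates,
            }
        )
    doc = {
        "format": "ccast-gating-strategy",
        "version": __version__,
        "provenance": provenance or {},
        "pruning_level": result.L,
        "n_rounds": result.n_rounds,
        "n_retained": int(len(result.retained)),
        "n_extra_bin": int(len(result.extra_bin)),
        "populations": populations,
        "tree": _tree_to_json(tree),
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def import_strategy(path: str | Path) -> tuple[GatingTree, dict]:
    """Read back an exported strategy; returns the tree and the document."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ccast-gating-strategy":
        raise ValueError(f"{path} is not a gating-strategy document")
    return _tree_from_json(doc["tree"]), doc


def signaling_induction(
    unstim: ExpressionTable,
    stim: ExpressionTable,
    tree: GatingTree,
    surface_markers: list[str],
    signaling_markers: list[str],
    mode: str = "mean-difference",
) -> pd.DataFrame:
    """Per-population signaling change between stimulated and unstimulated cells.

    Cells of both conditions are routed through the tree using the surface
    markers only; per population and signaling marker the default is
    ``mean(stim) - mean(unstim)`` of arcsinh intensities, while
    ``mode="abs"`` reports ``|mean(stim)| - |mean(unstim)|``.  Populations
    empty in either condition get ``NaN`` (missing), never zero.
    """
    if mode not in ("mean-difference", "abs"):
        raise ValueError(f"unknown induction mode {mode!r}")
    leaf_u = apply_tree(tree, select_markers(unstim, surface_markers))
    leaf_s = apply_tree(tree, select_markers(stim, surface_markers))
    leaf_ids = sorted(leaf.id for leaf in tree.leaves())
    rows = []
    for lid in leaf_ids:
        in_u, in_s = leaf_u == lid, leaf_s == lid
        row = {}
        for marker in signaling_markers:
            if not in_u.any() or not in_s.any():
                row[marker] = np.nan
                continue
            mu_u = float(unstim.marker(marker)[in_u].mean())
            mu_s = float(stim.marker(marker)[in_s].mean())
            if mode == "mean-difference":
                row[marker] = mu_s - mu_u
            else:
                row[marker] = abs(mu_s) - abs(mu_u)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(leaf_ids, name="population"))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration for a full transform -> cluster -> refine -> purify ->
    bootstrap -> export run.

    ``input_path=None`` simulates the default synthetic design instead of
    reading a file.  ``components`` is the (over-specified) component count
    handed to the clusterer; silhouette refinement decides the effective
    number.
    """

    input_path: str | None = None
    input_format: str | None = None
    markers: tuple[str, ...] | None = None
    transform: bool = False
    cofactor: float = 5.0
    clusterer: str = "npem"  # "npem" | "hclust"
    components: int = 10
    linkage: str = "ward"
    alpha: float = 0.05
    minbucket: int | None = None
    purity: float = 1.0
    bootstrap_n: int = 0
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write a reproducible run directory.

    Outputs: ``strategy.json`` (gating strategy + provenance),
    ``labels.csv`` (event id, cluster, leaf, retained flag),
    ``bootstrap.json`` (if requested), ``report.json`` and ``run.log``.
    Fully determined by the config (including its seed); reruns differ only
    in timestamps, which live solely in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "software": f"ccast {__version__}",
    }
    stage = "load"
    try:
        if config.input_path is None:
            table, _ = simulate(default_spec(seed=config.seed))
            log("simulated default 850-cell design")
        else:
            table = read_events(config.input_path, format=config.input_format)
            log(f"read {table.n_cells} events x {table.n_markers} markers")

        stage = "transform"
        if config.transform and not table.transformed:
            table = arcsinh_transform(table, cofactor=config.cofactor)
            log(f"arcsinh transform, cofactor {config.cofactor}")
        if config.markers:
            table = select_markers(table, list(config.markers))

        stage = "cluster"
        if config.clusterer == "npem":
            fit = npem_fit(table, m=config.components, seed=config.seed)
            initial = fit.hard_labels
        elif config.clusterer == "hclust":
            initial = hclust_labels(table, m=config.components, linkage=config.linkage)
        else:
            raise ValueError(f"unknown clusterer {config.clusterer!r}")
        log(f"{config.clusterer} clustering with m={config.components}")

        stage = "refine"
        refined = refine_labels(table, initial)
        log(f"silhouette refinement: {refined.n_clusters} clusters "
            f"after {refined.n_iter} iterations")

        stage = "purify"
        result = ccast_purify(
            table,
            refined.labels,
            alpha=config.alpha,
            minbucket=config.minbucket,
            purity=config.purity,
        )
        log(f"purification: L={result.L}, {result.n_rounds} rounds, "
            f"{len(result.extra_bin)} cells to extra bin")

        stage = "bootstrap"
        bootstrap_doc = None
        if config.bootstrap_n > 0:
            summary = bootstrap_tree_stability(
                table,
                refined.labels,
                B=config.bootstrap_n,
                seed=config.seed,
                alpha=config.alpha,
                minbucket=config.minbucket,
                purity=config.purity,
            )
            bootstrap_doc = {
                "B": summary.B,
                "hierarchy_identical_fraction": summary.hierarchy_identical_fraction,
                "n_failed": summary.n_failed,
                "ranges": [
                    {"path": [list(p) if isinstance(p, tuple) else p for p in path],
                     "min": lo, "max": hi}
                    for path, (lo, hi) in sorted(
                        summary.per_node_ranges.items(), key=lambda kv: str(kv[0])
                    )
                ],
            }
            log(f"bootstrap B={summary.B}: hierarchy identical fraction "
                f"{summary.hierarchy_identical_fraction:.3f}")

        stage = "export"
        export_strategy(result, out / "strategy.json", provenance=provenance)
        leaf_of = apply_tree(result.final_tree, table)
        retained = np.isin(table.event_ids, result.retained)
        pd.DataFrame(
            {
                "event_id": table.event_ids,
                "cluster": refined.labels,
                "leaf": leaf_of,
                "retained": retained.astype(int),
            }
        ).to_csv(out / "labels.csv", index=False)
        if bootstrap_doc is not None:
            (out / "bootstrap.json").write_text(
                json.dumps({"provenance": provenance, **bootstrap_doc},
                           indent=2, sort_keys=True)
            )
        report = {
            "provenance": provenance,
            "n_cells": table.n_cells,
            "n_clusters": refined.n_clusters,
            "n_populations": len(result.final_tree.leaves()),
            "n_cluster_populations": len(set(result.leaf_to_cluster.values())),
            "markers_used": list(result.final_tree.markers_used),
            "pruning_level": result.L,
            "n_rounds": result.n_rounds,
            "n_retained": int(retained.sum()),
            "n_extra_bin": len(result.extra_bin),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        (out / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
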