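"""Readers and writers for the pipeline's tab-separated and JSON artifacts.

All TSV dialects are tab-separated, UTF-8, header row, ``.`` decimal
separator.  Floats are written with a fixed repr-faithful format so that a
rerun with the same configuration reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bn_learning import EdgeStat, FeatureTable
from .datatypes import DAGModel, NodeDefinition, TimeSeriesMatrix
from .discrimination import ClassificationReport

__all__ = [
    "read_node_definitions",
    "packaged_node_definitions",
    "write_edge_list",
    "read_edge_list",
    "write_feature_table",
    "read_feature_table",
    "write_node_series",
    "read_node_series",
    "write_classification_report",
    "write_pattern",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def read_node_definitions(path, default_radius_mm: float = 6.0) -> list[NodeDefinition]:
    """Parse a node-definition TSV (``name  x  y  z  [radius_mm]``).

    A missing ``radius_mm`` column falls back to the conventional 6 mm
    sphere with a logged notice.  Raises distinct errors for a missing
    required column, a duplicate node name, and a non-numeric coordinate.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"node table {path}: missing required column(s) {sorted(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"node table {path}: duplicate node name(s) {dupes}")
    if "radius_mm" not in df.columns:
        logger.info("node table %s has no radius_mm column; defaulting to %g mm",
                    path, default_radius_mm)
        df = df.assign(radius_mm=default_radius_mm)
    nodes = []
    for _, row in df.iterrows():
        try:
            center = (float(row["x"]), float(row["y"]), float(row["z"]))
            radius = float(row["radius_mm"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"node table {path}: non-numeric coordinate or radius in row "
                f"{row['name']!r}"
            ) from exc
        nodes.append(NodeDefinition(name=str(row["name"]), center_mm=center,
                                    radius_mm=radius))
    return nodes


def packaged_node_definitions(radius_mm: float | None = None) -> list[NodeDefinition]:
    """The nine packaged resting-state network nodes (6 mm spheres at the
    published MNI peaks); ``radius_mm`` overrides the sphere size for
    radius-sensitivity runs."""
    path = importlib.resources.files("rsbn.data").joinpath("rsn_nodes.tsv")
    nodes = read_node_definitions(path)
    if radius_mm is not None:
        nodes = [dataclasses.replace(n, radius_mm=radius_mm) for n in nodes]
    return nodes


def write_edge_list(
    model: DAGModel,
    path,
    stats: list[EdgeStat] | None = None,
    sidecar: dict | None = None,
) -> None:
    """Write a learned network as a TSV edge list, optionally with per-edge
    significance columns, plus a JSON sidecar (``<path>.json``) carrying the
    score and provenance."""
    path = Path(path)
    rows = [
        {"source": s, "target": t, "weight": w} for s, t, w in model.edges()
    ]
    if stats is not None:
        by_edge = {(e.source, e.target): e for e in stats}
        for row in rows:
            e = by_edge.get((row["source"], row["target"]))
            if e is not None:
                row["p_value"] = e.p_value
                row["significant"] = e.significant
    pd.DataFrame(rows, columns=["source", "target", "weight", "p_value", "significant"]
                 if stats is not None else ["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    meta = {"node_names": model.node_names, "bic": model.bic}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def read_edge_list(path, node_names: list[str] | None = None) -> DAGModel:
    """Read a ``source  target  weight`` TSV back into a :class:`DAGModel`."""
    from .synthetic_data import dag_from_edge_list

    return dag_from_edge_list(pd.read_csv(path, sep="\t"), node_names=node_names)


def write_feature_table(features: FeatureTable, path) -> None:
    features.to_dataframe().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    feat_cols = [c for c in df.columns if "->" in c]
    node_names: list[str] = []
    for c in feat_cols:
        s = c.split("->")[0]
        if s not in node_names:
            node_names.append(s)
    return FeatureTable(
        matrix=df[feat_cols].to_numpy(dtype=float),
        node_names=node_names,
        labels=df["condition"].tolist(),
        subject_ids=df["subject_id"].tolist(),
    )


def write_node_series(ts: TimeSeriesMatrix, path) -> None:
    """One row per timepoint, one named column per node."""
    pd.DataFrame(ts.data, columns=ts.node_names).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_node_series(
    path, subject_id: str = "unknown", condition: str = "unknown", tr: float = 2.0
) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesMatrix(
        subject_id=subject_id, condition=condition,
        data=df.to_numpy(dtype=float), node_names=list(df.columns), tr=tr,
    )


def write_classification_report(report: ClassificationReport, path) -> None:
    payload = {
        "accuracy_by_k": report.accuracy_by_k,
        "ranking": list(report.ranking.order),
        "best_k": report.best_k,
        "best_accuracy": report.best_accuracy,
        "config": report.config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_pattern(pattern: pd.DataFrame, path) -> None:
    pattern.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
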