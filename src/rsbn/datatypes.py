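"""Core containers shared across the pipeline.

The pipeline passes around four kinds of objects: sphere-node definitions
in MNI space, directed acyclic network models with edge weights, per-recording
node time-series matrices, and multi-subject cohorts of those recordings.
All containers validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "NodeDefinition",
    "DAGModel",
    "TimeSeriesMatrix",
    "CohortDataset",
    "CONDITIONS",
]

#: Recognized resting-state condition labels: eyes closed / eyes open.
CONDITIONS = ("EC", "EO")


@dataclass(frozen=True)
class NodeDefinition:
    """A named network node: a sphere centred at an MNI peak coordinate.

    Parameters
    ----------
    name
        Unique node label (e.g. ``"SN"`` for the salience network).
    center_mm
        ``(x, y, z)`` peak coordinate in MNI millimetres.
    radius_mm
        Sphere radius in millimetres; must be positive.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"node {self.name!r}: radius_mm must be > 0")
        if len(self.center_mm) != 3:
            raise ValueError(f"node {self.name!r}: center_mm must have 3 coordinates")
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))


@dataclass
class DAGModel:
    """A weighted directed acyclic network over a fixed node set.

    ``weights[i, j]`` is the linear coefficient of the directed edge
    ``node i -> node j``; zero means no edge.  ``noise_sd`` holds the
    standard deviation of each node's additive Gaussian error term in the
    linear structural equation model ``x_j = sum_i w_ij x_i + eps_j``.

    Raises
    ------
    ValueError
        If the diagonal is nonzero, the graph has a directed cycle, or any
        noise standard deviation is not strictly positive.
    """

    node_names: list[str]
    weights: np.ndarray
    noise_sd: np.ndarray = None  # type: ignore[assignment]
    bic: float | None = None

    def __post_init__(self) -> None:
        self.node_names = list(self.node_names)
        k = len(self.node_names)
        if len(set(self.node_names)) != k:
            raise ValueError("node names must be unique")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (k, k):
            raise ValueError(f"weights must be {k}x{k}, got {self.weights.shape}")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal of weights must be all zero (no self-loops)")
        if self.noise_sd is None:
            self.noise_sd = np.ones(k)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.noise_sd.shape != (k,):
            raise ValueError(f"noise_sd must have length {k}")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be strictly positive")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("weight matrix encodes a directed cycle")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def graph(self) -> nx.DiGraph:
        """The directed graph of nonzero weights, node labels attached."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        src, tgt = np.nonzero(self.weights)
        g.add_edges_from(
            (self.node_names[i], self.node_names[j], {"weight": self.weights[i, j]})
            for i, j in zip(src, tgt)
        )
        return g

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as ``(source, target, weight)``, lexicographic order."""
        out = [
            (self.node_names[i], self.node_names[j], float(self.weights[i, j]))
            for i, j in zip(*np.nonzero(self.weights))
        ]
        return sorted(out)

    def parent_sets(self) -> dict[int, frozenset[int]]:
        """Parent indices per node index (the structure, weights dropped)."""
        return {
            j: frozenset(int(i) for i in np.nonzero(self.weights[:, j])[0])
            for j in range(self.n_nodes)
        }

    def topological_order(self) -> list[int]:
        """Node indices in a topological order of the DAG."""
        name_to_idx = {n: i for i, n in enumerate(self.node_names)}
        return [name_to_idx[n] for n in nx.topological_sort(self.graph())]

    def implied_covariance(self) -> np.ndarray:
        """Population covariance of the linear-Gaussian model.

        For weight matrix ``W`` (``W[i, j]`` on edge i->j) and error variances
        ``D``, the stationary solution of the structural equations gives
        ``Sigma = (I - W^T)^{-1} D (I - W^T)^{-T}``.
        """
        k = self.n_nodes
        a = np.linalg.inv(np.eye(k) - self.weights.T)
        return a @ np.diag(self.noise_sd**2) @ a.T

    def weight(self, source: str, target: str) -> float:
        i = self.node_names.index(source)
        j = self.node_names.index(target)
        return float(self.weights[i, j])

    def with_weights(self, weights: np.ndarray) -> "DAGModel":
        return replace(self, weights=np.asarray(weights, dtype=float), bic=None)


@dataclass
class TimeSeriesMatrix:
    """One subject-condition recording: ``data`` is timepoints x nodes.

    ``tr`` is the repetition time in seconds (sampling interval of the
    volume series); it sets the Nyquist frequency for temporal filtering.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    node_names: list[str]
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.node_names = list(self.node_names)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D timepoints x nodes matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 timepoints")
        if self.data.shape[1] != len(self.node_names):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.node_names)} node names were given"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series values must all be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "TimeSeriesMatrix":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class CohortDataset:
    """A cohort of recordings sharing one node set, two conditions per subject."""

    recordings: list[TimeSeriesMatrix]
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("cohort must contain at least one recording")
        if not self.node_names:
            self.node_names = list(self.recordings[0].node_names)
        trs = {r.tr for r in self.recordings}
        if len(trs) != 1:
            raise ValueError(f"recordings disagree on tr: {sorted(trs)}")
        for r in self.recordings:
            if r.node_names != self.node_names:
                raise ValueError(
                    f"recording {r.subject_id}/{r.condition} has a different node list"
                )
        seen: set[tuple[str, str]] = set()
        for r in self.recordings:
            key = (r.subject_id, r.condition)
            if key in seen:
                raise ValueError(f"duplicate recording for subject/condition {key}")
            seen.add(key)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for r in self.recordings:
            if r.subject_id not in out:
                out.append(r.subject_id)
        return out

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for r in self.recordings:
            if r.condition not in out:
                out.append(r.condition)
        return out

    def by_condition(self, condition: str) -> list[TimeSeriesMatrix]:
        recs = [r for r in self.recordings if r.condition == condition]
        if not recs:
            raise ValueError(f"no recordings with condition {condition!r}")
        return recs
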