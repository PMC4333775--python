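"""Synthetic cohorts of node time series from ground-truth directed networks.

Real resting-state recordings for the eyes-open (EO) / eyes-closed (EC)
paradigm are not redistributable, so the pipeline is exercised on data
simulated from the published condition-specific network structures that ship
with the package.  The generative family is the linear-Gaussian structural
equation model (SEM) that the Bayesian-network learner itself assumes:

    x_j = sum_i w_ij * x_i + eps_j,      eps_j ~ N(0, noise_sd_j^2)

sampled independently at each timepoint in topological order of the DAG.
Per-subject heterogeneity is emulated by jittering the nonzero edge weights
with independent Gaussian perturbations.  An optional AR(1) innovation mode
introduces temporal autocorrelation to stress-test robustness; it is off by
default because the learner's model is i.i.d.

The module can also render a node time series into a toy 4-D NIfTI volume
with sphere-shaped regions, so the image-extraction stage is testable
without any external download.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS, CohortDataset, DAGModel, NodeDefinition, TimeSeriesMatrix

__all__ = [
    "load_ground_truth",
    "ground_truth_node_names",
    "simulate_subject",
    "simulate_cohort",
    "render_volumes",
    "default_grid",
]

#: Canonical node order of the packaged fixtures (Table-style index order).
GROUND_TRUTH_NODES = ["PVN", "HVN", "PSMN", "VMN", "DAN", "CEN", "aDMN", "pDMN", "SN"]


def _fixture_path(name: str):
    return importlib.resources.files("rsbn.data").joinpath(name)


def ground_truth_node_names() -> list[str]:
    """Node labels of the packaged ground-truth networks, in canonical order."""
    return list(GROUND_TRUTH_NODES)


def load_ground_truth(condition: str) -> DAGModel:
    """Load the packaged ground-truth DAG for one resting condition.

    Parameters
    ----------
    condition
        ``"EC"`` (eyes closed) or ``"EO"`` (eyes open).

    Returns
    -------
    DAGModel
        The published directed network for that condition, with unit noise
        standard deviation on every node.

    Raises
    ------
    ValueError
        If ``condition`` is not a recognized label.
    FileNotFoundError
        If the packaged fixture file is missing.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    path = _fixture_path(f"ground_truth_{condition.lower()}.tsv")
    if not path.is_file():
        raise FileNotFoundError(f"packaged ground-truth fixture missing: {path}")
    edges = pd.read_csv(path, sep="\t")
    return dag_from_edge_list(edges, node_names=GROUND_TRUTH_NODES)


def dag_from_edge_list(
    edges: pd.DataFrame, node_names: list[str] | None = None
) -> DAGModel:
    """Build a :class:`DAGModel` from a ``source/target/weight`` edge table."""
    required = {"source", "target", "weight"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    if node_names is None:
        node_names = sorted(set(edges["source"]) | set(edges["target"]))
    idx = {n: i for i, n in enumerate(node_names)}
    k = len(node_names)
    w = np.zeros((k, k))
    for _, row in edges.iterrows():
        s, t = row["source"], row["target"]
        if s not in idx or t not in idx:
            raise ValueError(f"edge {s}->{t} uses a node outside the node list")
        w[idx[s], idx[t]] = float(row["weight"])
    return DAGModel(node_names=node_names, weights=w)


def _jitter_weights(dag: DAGModel, jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb nonzero weights with N(0, jitter_sd^2); structure unchanged."""
    w = dag.weights.copy()
    if jitter_sd > 0:
        nz = w != 0
        w[nz] += rng.normal(0.0, jitter_sd, size=int(nz.sum()))
        # A jittered coefficient that lands exactly on 0 would silently drop
        # the edge; nudge it to keep the support fixed (measure-zero event).
        w[nz & (w == 0)] = np.finfo(float).tiny
    return w


def simulate_subject(
    dag: DAGModel,
    n_timepoints: int,
    jitter_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-01",
    condition: str = "EC",
    tr: float = 2.0,
    ar_coefficient: float = 0.0,
) -> TimeSeriesMatrix:
    """Simulate one recording from a linear-Gaussian SEM.

    Subject-specific weights are drawn once (``dag.weights`` plus Gaussian
    jitter on nonzero entries only, so the structure — and hence acyclicity —
    is preserved), then each time sample is generated in topological order.
    Deterministic given ``seed``.

    Parameters
    ----------
    ar_coefficient
        AR(1) coefficient of the innovation processes.  0 (default) gives the
        i.i.d. sampling the network learner assumes; positive values add the
        kind of temporal autocorrelation real recordings have.  Innovations
        are scaled by ``sqrt(1 - rho^2)`` so marginal variances are unchanged.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if not -1 < ar_coefficient < 1:
        raise ValueError("ar_coefficient must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    w = _jitter_weights(dag, jitter_sd, rng)
    k = dag.n_nodes
    eps = rng.normal(size=(n_timepoints, k)) * dag.noise_sd
    if ar_coefficient != 0.0:
        rho = ar_coefficient
        eps = eps * np.sqrt(1.0 - rho**2)
        for t in range(1, n_timepoints):
            eps[t] += rho * eps[t - 1]
        eps[0] /= np.sqrt(1.0 - rho**2)  # stationary start
    data = np.empty_like(eps)
    for j in dag.topological_order():
        parents = np.nonzero(w[:, j])[0]
        data[:, j] = eps[:, j]
        if parents.size:
            data[:, j] += data[:, parents] @ w[parents, j]
    return TimeSeriesMatrix(
        subject_id=subject_id,
        condition=condition,
        data=data,
        node_names=dag.node_names,
        tr=tr,
    )


def simulate_cohort(
    dag_ec: DAGModel,
    dag_eo: DAGModel,
    n_subjects: int = 20,
    n_timepoints: int = 230,
    jitter_sd: float = 0.1,
    master_seed: int = 0,
    tr: float = 2.0,
    ar_coefficient: float = 0.0,
) -> CohortDataset:
    """Simulate a two-condition cohort (one EC and one EO recording per subject).

    Each subject gets an independently jittered weight draw per condition.
    Per-recording randomness is derived from ``master_seed`` through
    ``numpy.random.SeedSequence(master_seed).spawn_key = (subject, condition)``,
    so any single recording is reproducible in isolation.
    """
    if dag_ec.node_names != dag_eo.node_names:
        raise ValueError("the two condition DAGs must share node names and order")
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    width = max(2, len(str(n_subjects)))
    recordings = []
    for s in range(n_subjects):
        sid = f"sub-{s + 1:0{width}d}"
        for c, dag in enumerate((dag_ec, dag_eo)):
            ss = np.random.SeedSequence(master_seed, spawn_key=(s, c))
            recordings.append(
                simulate_subject(
                    dag,
                    n_timepoints=n_timepoints,
                    jitter_sd=jitter_sd,
                    seed=ss,
                    subject_id=sid,
                    condition=CONDITIONS[c],
                    tr=tr,
                    ar_coefficient=ar_coefficient,
                )
            )
    return CohortDataset(recordings=recordings, node_names=dag_ec.node_names)


def default_grid(voxel_mm: float = 3.0) -> tuple[tuple[int, int, int], np.ndarray]:
    """Standard isotropic grid covering MNI -90..90 / -126..90 / -72..108.

    Returns ``(shape, affine)`` with the affine mapping voxel indices to MNI
    millimetres.  At 3 mm this is the usual 61 x 73 x 61 resampled grid.
    """
    lows = np.array([-90.0, -126.0, -72.0])
    highs = np.array([90.0, 90.0, 108.0])
    shape = tuple(int(round((h - l) / voxel_mm)) + 1 for l, h in zip(lows, highs))
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_mm
    affine[:3, 3] = lows
    return shape, affine


#: Column names of the synthetic confound table: three tissue signals plus
#: six rigid-body motion traces (translations in mm, rotations in degrees).
CONFOUND_COLUMNS = [
    "global_mean",
    "white_matter",
    "csf",
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
]


def render_volumes(
    ts: TimeSeriesMatrix,
    nodes: list[NodeDefinition],
    shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
    background_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
):
    """Render a node time series into a toy 4-D image plus a confound table.

    Every volume is i.i.d. Gaussian background noise; voxels inside node k's
    sphere additionally carry ``ts.data[t, k]``.  The confound table holds
    nine synthetic nuisance traces (smooth AR(1) processes standing in for
    tissue signals and head motion) aligned with the volumes.

    Returns
    -------
    (nibabel.Nifti1Image, pandas.DataFrame)

    Raises
    ------
    ValueError
        If a node's sphere extends outside the grid, or the node count does
        not match the time-series columns.
    """
    import nibabel as nib

    from .roi_extraction import sphere_mask

    if shape is None or affine is None:
        shape, affine = default_grid()
    if len(nodes) != ts.n_nodes:
        raise ValueError(
            f"time series has {ts.n_nodes} columns but {len(nodes)} nodes given"
        )
    inv = np.linalg.inv(affine)
    for node in nodes:
        center_vox = (inv @ np.append(node.center_mm, 1.0))[:3]
        vox_sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        lo = center_vox - node.radius_mm / vox_sizes
        hi = center_vox + node.radius_mm / vox_sizes
        if np.any(lo < -0.5) or np.any(hi > np.array(shape) - 0.5):
            raise ValueError(f"sphere for node {node.name!r} extends outside the grid")
    rng = np.random.default_rng(seed)
    t = ts.n_timepoints
    vol = rng.normal(0.0, background_sd, size=shape + (t,)) if background_sd > 0 else np.zeros(shape + (t,))
    for k, node in enumerate(nodes):
        ii, jj, kk = sphere_mask(node, affine, shape).T
        vol[ii, jj, kk, :] += ts.data[:, k]
    # Smooth synthetic nuisance traces; amplitude is arbitrary, only their
    # regression behaviour matters downstream.
    conf = rng.normal(size=(t, len(CONFOUND_COLUMNS)))
    for row in range(1, t):
        conf[row] = 0.8 * conf[row - 1] + 0.6 * conf[row]
    confounds = pd.DataFrame(conf, columns=CONFOUND_COLUMNS)
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms((*np.sqrt((affine[:3, :3] ** 2).sum(axis=0)), ts.tr))
    return img, confounds
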