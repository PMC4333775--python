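"""From 4-D images (or raw node matrices) to clean node time series.

The stages mirror standard resting-state preprocessing at the node level:
discard initial volumes (signal equilibration), average voxel intensities
inside a sphere at each node's MNI peak, band-pass filter (0.01-0.08 Hz by
default, removing slow drift and high-frequency physiological noise), and
regress out nine nuisance covariates (global mean, white matter, CSF, six
motion parameters).

Nuisance regression is applied after sphere averaging rather than per voxel;
both operations are linear in the data, so the two orders agree exactly
(see the commutation test).  Confounds are band-pass filtered together with
the data before regression so that the regression cannot reintroduce
stop-band energy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import NodeDefinition, TimeSeriesMatrix

__all__ = [
    "BandpassSpec",
    "discard_initial",
    "sphere_mask",
    "extract_node_series",
    "bandpass_filter",
    "regress_out",
    "preprocess_pipeline",
    "motion_exceeds_limits",
    "PreprocessParams",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandpassSpec:
    """A temporal pass band in Hz for a series sampled every ``tr`` seconds."""

    f_lo: float = 0.01
    f_hi: float = 0.08
    tr: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 <= self.f_lo < self.f_hi <= nyquist):
            raise ValueError(
                f"band [{self.f_lo}, {self.f_hi}] Hz invalid for tr={self.tr}s "
                f"(Nyquist {nyquist:.4g} Hz)"
            )


def discard_initial(data, n_discard: int):
    """Drop the first ``n_discard`` frames of a time-indexed object.

    Accepts a :class:`TimeSeriesMatrix`, a 2-D array (time x anything), a
    DataFrame, or a 4-D nibabel image (time last); returns the same kind.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if isinstance(data, TimeSeriesMatrix):
        if n_discard >= data.n_timepoints:
            raise ValueError(
                f"cannot discard {n_discard} of {data.n_timepoints} timepoints"
            )
        return data.with_data(data.data[n_discard:])
    if isinstance(data, pd.DataFrame):
        if n_discard >= len(data):
            raise ValueError(f"cannot discard {n_discard} of {len(data)} rows")
        return data.iloc[n_discard:].reset_index(drop=True)
    if hasattr(data, "get_fdata"):  # nibabel spatial image, time on the last axis
        import nibabel as nib

        t = data.shape[-1]
        if n_discard >= t:
            raise ValueError(f"cannot discard {n_discard} of {t} volumes")
        if n_discard == 0:
            return data
        return data.__class__(
            np.asanyarray(data.dataobj)[..., n_discard:], data.affine, data.header
        )
    arr = np.asarray(data)
    if n_discard >= arr.shape[0]:
        raise ValueError(f"cannot discard {n_discard} of {arr.shape[0]} frames")
    return arr[n_discard:]


def sphere_mask(
    node: NodeDefinition, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Voxel indices whose centres lie within the node's sphere.

    A voxel belongs to the mask when its centre, mapped through ``affine``
    to millimetres, is at Euclidean distance <= ``radius_mm`` from the node
    centre.  The mask is clipped at the grid boundary.

    Returns
    -------
    ndarray of shape (n_voxels, 3)
        Integer (i, j, k) indices, lexicographically sorted.

    Raises
    ------
    ValueError
        If no voxel centre falls inside the sphere (names the node).
    """
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(node.center_mm, 1.0))[:3]
    # Bounding box in voxel space; generous for oblique affines.
    vox_extent = np.abs(inv[:3, :3]).sum(axis=1) * node.radius_mm
    lo = np.maximum(np.floor(center_vox - vox_extent).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + vox_extent).astype(int), np.array(shape) - 1)
    if np.any(lo > hi):
        raise ValueError(f"sphere mask for node {node.name!r} is empty (outside grid)")
    ii, jj, kk = np.meshgrid(
        *(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij"
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    dist2 = ((mm - np.asarray(node.center_mm)) ** 2).sum(axis=1)
    inside = vox[dist2 <= node.radius_mm**2 + 1e-9]
    if inside.size == 0:
        raise ValueError(f"sphere mask for node {node.name!r} is empty (outside grid)")
    order = np.lexsort((inside[:, 2], inside[:, 1], inside[:, 0]))
    return inside[order]


def extract_node_series(
    image, nodes: list[NodeDefinition], tr: float | None = None,
    subject_id: str = "unknown", condition: str = "unknown",
) -> TimeSeriesMatrix:
    """Average voxel intensities inside each node's sphere at every volume.

    ``image`` is a 4-D nibabel image (time last).  Column k at time t is the
    arithmetic mean over node k's mask voxels in volume t.
    """
    names = [n.name for n in nodes]
    if len(set(names)) != len(names):
        raise ValueError("node names must be unique")
    affine = image.affine
    shape = image.shape[:3]
    data = np.asanyarray(image.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    out = np.empty((data.shape[-1], len(nodes)))
    for k, node in enumerate(nodes):
        ii, jj, kk = sphere_mask(node, affine, shape).T
        out[:, k] = data[ii, jj, kk, :].mean(axis=0)
    if tr is None:
        zooms = image.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return TimeSeriesMatrix(
        subject_id=subject_id, condition=condition, data=out,
        node_names=names, tr=tr,
    )


def _bandpass_columns(data: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Ideal rectangular FFT filter with linear-trend removal, per column.

    Implemented as one orthogonal projection — onto the span of the retained
    Fourier modes minus the directions spanned by the (band-filtered)
    constant and linear-ramp vectors — so applying it twice equals applying
    it once exactly.
    """
    t = data.shape[0]

    def band(x: np.ndarray) -> np.ndarray:
        freqs = np.fft.rfftfreq(t, d=spec.tr)
        spectrum = np.fft.rfft(x, axis=0)
        keep = (freqs >= spec.f_lo) & (freqs <= spec.f_hi)
        spectrum[~keep] = 0.0
        return np.fft.irfft(spectrum, n=t, axis=0)

    out = band(data)
    # remove what survives of the detrending directions inside the band
    # (SVD, not QR: a numerically zero column must not leak an arbitrary
    # direction into the basis)
    trend = band(np.column_stack([np.ones(t), np.arange(t, dtype=float)]))
    u, s, _ = np.linalg.svd(trend, full_matrices=False)
    q = u[:, s > 1e-10 * max(1.0, s.max(initial=0.0))]
    if q.size:
        out -= q @ (q.T @ out)
    return out


def bandpass_filter(ts: TimeSeriesMatrix, spec: BandpassSpec | None = None) -> TimeSeriesMatrix:
    """Band-pass filter each node series.

    Each column is linearly detrended, transformed with a real FFT, discrete
    frequencies outside ``[f_lo, f_hi]`` (inclusive) are zeroed, and the
    series is transformed back.  The rectangular frequency-domain filter is
    an orthogonal projection, hence idempotent.
    """
    if spec is None:
        spec = BandpassSpec(tr=ts.tr)
    elif abs(spec.tr - ts.tr) > 1e-12:
        raise ValueError(f"spec.tr={spec.tr} does not match recording tr={ts.tr}")
    if ts.n_timepoints < 8:
        raise ValueError("need at least 8 timepoints to band-pass filter")
    return ts.with_data(_bandpass_columns(ts.data, spec))


def regress_out(ts: TimeSeriesMatrix, confounds: pd.DataFrame | np.ndarray) -> TimeSeriesMatrix:
    """Replace each node series by its least-squares residual against the
    confounds (plus an intercept).

    Collinear confound columns are dropped with a logged warning so the
    design stays full rank; residuals are therefore always well defined.
    """
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {conf.shape[0]} rows but recording has "
            f"{ts.n_timepoints} timepoints"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), conf])
    # Greedily drop columns that do not increase rank (keeps the intercept).
    keep: list[int] = []
    rank = 0
    for c in range(design.shape[1]):
        cand = design[:, keep + [c]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(c)
            rank = r
    if len(keep) < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        logger.warning(
            "dropping %d collinear confound column(s): design indices %s",
            len(dropped), dropped,
        )
    x = design[:, keep]
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    return ts.with_data(ts.data - x @ beta)


def motion_exceeds_limits(
    confounds: pd.DataFrame,
    max_translation_mm: float = 1.0,
    max_rotation_deg: float = 1.0,
) -> bool:
    """Flag recordings whose motion traces exceed the usual exclusion limits
    (>1 mm displacement or >1 degree rotation in any direction).

    This only reports; whether to exclude the recording is the caller's
    decision.
    """
    trans = confounds[["trans_x", "trans_y", "trans_z"]].to_numpy()
    rot = confounds[["rot_x", "rot_y", "rot_z"]].to_numpy()
    return bool(
        np.any(np.abs(trans) > max_translation_mm)
        or np.any(np.abs(rot) > max_rotation_deg)
    )


@dataclass
class PreprocessParams:
    """Knobs of :func:`preprocess_pipeline`.

    ``n_discard`` initial frames are dropped first; filtering and nuisance
    regression can be switched off independently (e.g. for data that is
    already clean, such as simulated node matrices).
    """

    n_discard: int = 10
    bandpass: BandpassSpec | None = None
    do_filter: bool = True
    do_regress: bool = True


def preprocess_pipeline(
    image_or_ts,
    confounds: pd.DataFrame | None = None,
    nodes: list[NodeDefinition] | None = None,
    params: PreprocessParams | None = None,
    subject_id: str = "unknown",
    condition: str = "unknown",
) -> TimeSeriesMatrix:
    """Full node-level preprocessing: discard -> extract -> filter -> regress.

    ``image_or_ts`` may be a 4-D nibabel image (``nodes`` required) or an
    already-extracted :class:`TimeSeriesMatrix` (extraction skipped).  The
    confound table must cover the full pre-discard length; it is trimmed,
    filtered and regressed alongside the data.
    """
    if params is None:
        params = PreprocessParams()
    if isinstance(image_or_ts, TimeSeriesMatrix):
        ts = discard_initial(image_or_ts, params.n_discard)
        logger.info("discard: %d -> %d timepoints", image_or_ts.n_timepoints, ts.n_timepoints)
    else:
        if nodes is None:
            raise ValueError("nodes are required to extract from an image")
        image = discard_initial(image_or_ts, params.n_discard)
        ts = extract_node_series(image, nodes, subject_id=subject_id, condition=condition)
        logger.info(
            "extract: image %s -> %d x %d node matrix",
            tuple(image.shape), ts.n_timepoints, ts.n_nodes,
        )
    if confounds is not None:
        confounds = discard_initial(confounds, params.n_discard)
        if len(confounds) != ts.n_timepoints:
            raise ValueError("confound rows do not match timepoints after discard")
    if params.do_filter:
        spec = params.bandpass or BandpassSpec(tr=ts.tr)
        ts = bandpass_filter(ts, spec)
        if confounds is not None:
            filtered = _bandpass_columns(confounds.to_numpy(dtype=float), spec)
            confounds = pd.DataFrame(filtered, columns=confounds.columns)
        logger.info("bandpass: kept %.3g-%.3g Hz", spec.f_lo, spec.f_hi)
    if params.do_regress:
        if confounds is None:
            warnings.warn("no confounds supplied; skipping nuisance regression")
        else:
            ts = regress_out(ts, confounds)
            logger.info("regressed out %d confound column(s)", confounds.shape[1])
    return ts
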