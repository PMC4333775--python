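"""Run configuration for the end-to-end experiment."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a full pipeline run, loadable from a flat YAML file.

    Paths left as ``None`` fall back to the packaged fixtures (the nine
    published nodes and the two condition ground-truth networks).
    """

    # paths
    nodes_path: str | None = None
    dag_ec_path: str | None = None
    dag_eo_path: str | None = None
    out_dir: str = "rsbn_out"
    # cohort
    n_subjects: int = 20
    n_timepoints: int = 230
    jitter_sd: float = 0.1
    ar_coefficient: float = 0.0
    tr: float = 2.0
    # extraction (used when rendering toy volumes)
    render: bool = False
    radius_mm: float | None = None
    background_sd: float = 1.0
    n_discard: int = 10
    f_lo: float = 0.01
    f_hi: float = 0.08
    # learner
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    n_restarts: int = 10
    alpha: float = 0.05
    # classifier
    svc_cost: float = 1.0
    cv_mode: str = "by_subject"
    nested: bool = False
    # seeding
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_timepoints < 2:
            raise ValueError("n_subjects >= 1 and n_timepoints >= 2 required")
        if self.jitter_sd < 0 or self.background_sd < 0:
            raise ValueError("jitter_sd and background_sd must be non-negative")
        if not 0 <= self.f_lo < self.f_hi <= 1 / (2 * self.tr):
            raise ValueError("band must satisfy 0 <= f_lo < f_hi <= Nyquist")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.cv_mode not in ("by_subject", "by_sample"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        if self.svc_cost <= 0 or self.n_restarts < 0 or self.n_lambdas < 1:
            raise ValueError("svc_cost > 0, n_restarts >= 0, n_lambdas >= 1 required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the configuration (used in the run manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
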