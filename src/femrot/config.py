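"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import FemrotError
from .synthetic import CohortParams


@dataclass
class RunConfig:
    """Configuration for a generate -> measure -> analyse run.

    Flat keys; YAML config files use the same names, and CLI flags override
    file values. A fixed ``seed`` makes the whole run reproducible.
    """

    n: int = 120
    seed: int = 0
    observers: int = 2
    sessions: int = 2
    sigma: float = 0.3
    outlier_threshold: float = 2.0
    icc_form: str = "agreement"
    out_dir: str = "femrot_run"
    log_level: str = "INFO"
    # Cohort distribution overrides (degrees).
    ws_mean: float = 2.54
    ws_sd: float = 2.30
    atea_mean: float = 4.21
    atea_sd: float = 1.01
    pcl_mean: float = 0.50
    pcl_sd: float = 1.06
    valgus_mean: float = 7.9
    valgus_sd: float = 1.5
    side_fraction_right: float = 0.5

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0:
            raise FemrotError("outlier threshold must be positive")
        if self.icc_form not in ("agreement", "consistency"):
            raise FemrotError("icc_form must be 'agreement' or 'consistency'")

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n=self.n,
            ws_mean=self.ws_mean,
            ws_sd=self.ws_sd,
            atea_mean=self.atea_mean,
            atea_sd=self.atea_sd,
            pcl_mean=self.pcl_mean,
            pcl_sd=self.pcl_sd,
            valgus_mean=self.valgus_mean,
            valgus_sd=self.valgus_sd,
            side_fraction_right=self.side_fraction_right,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FemrotError("config file must contain a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FemrotError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
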