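"""Pipeline configuration: thresholds, paths, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end workflow, with published defaults."""

    expression: str | None = None
    gtf: str | None = None
    clinical: str | None = None
    immune_genes: str | None = None
    infiltration: str | None = None
    ic50: str | None = None
    outdir: str = "lncpair_run"

    r_threshold: float = 0.4
    corr_p_threshold: float = 0.001
    corr_mode: str = "signed"
    lfc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    min_minority_frac: float = 0.2
    cox_p_threshold: float = 0.05
    n_reps: int = 1000
    n_folds: int = 10
    freq_threshold: int = 100
    horizons_years: tuple = (1.0, 3.0, 5.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.r_threshold <= 1):
            raise ValueError("r_threshold must be in [0, 1]")
        for name in ("corr_p_threshold", "fdr_threshold", "cox_p_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 <= self.min_minority_frac < 0.5):
            raise ValueError("min_minority_frac must be in [0, 0.5)")
        if self.corr_mode not in ("signed", "absolute"):
            raise ValueError("corr_mode must be 'signed' or 'absolute'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_reps < self.n_folds:
            raise ValueError("n_reps must be >= n_folds")
        if self.freq_threshold >= self.n_reps:
            raise ValueError("freq_threshold must be < n_reps")
        if any(h <= 0 for h in self.horizons_years):
            raise ValueError("horizons must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.horizons_years, list):
            cfg.horizons_years = tuple(cfg.horizons_years)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["horizons_years"] = list(self.horizons_years)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
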