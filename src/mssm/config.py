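"""Run configuration: a flat key-value document (YAML) with validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


# the model families of the classification zoo, in canonical order
DEFAULT_MODELS = [
    "svm_linear",
    "svm_sigmoid",
    "svm_polynomial",
    "svm_rbf",
    "neural_network",
    "random_forest",
    "logistic_regression",
    "k_nearest_neighbors",
    "gaussian_process",
]


@dataclass
class RunConfig:
    """Parameters shared across pipeline stages.

    depth_fractions
        Cortical depths sampled for gray-matter intensity, as fractions of
        the white->pial segment (0 = gray/white border, 1 = gray/CSF border).
    wm_offsets_mm
        Distances below the gray/white border at which white matter is
        sampled (mm).
    smoothing_fwhm_mm
        Target FWHM of the surface smoothing kernel (mm).
    fdr_q
        Benjamini-Hochberg false discovery rate for vertex statistics.
    split_fractions
        Train / validation / test fractions (sum to 1).
    """

    depth_fractions: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8])
    wm_offsets_mm: list[float] = field(default_factory=lambda: [0.5, 1.0])
    smoothing_fwhm_mm: float = 5.0
    fdr_q: float = 0.05
    split_fractions: list[float] = field(default_factory=lambda: [0.6, 0.2, 0.2])
    seed: int = 0
    models: list[str] = field(default_factory=lambda: list(DEFAULT_MODELS))
    n_initializations: int = 5
    n_cv_folds: int = 4
    ensemble_size: int = 3
    final_refit_on: str = "train"          # train | train+val
    interpolation: str = "trilinear"       # trilinear | nearest
    smooth_thickness: bool = True
    ratio_direction: str = "gm_over_wm"    # gm_over_wm | wm_over_gm

    def validate(self) -> "RunConfig":
        if not all(0.0 < f < 1.0 for f in self.depth_fractions):
            raise ConfigError("depth_fractions must lie strictly inside (0, 1)")
        if not all(o > 0 for o in self.wm_offsets_mm):
            raise ConfigError("wm_offsets_mm must be positive")
        if self.smoothing_fwhm_mm < 0:
            raise ConfigError("smoothing_fwhm_mm must be >= 0")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must be in (0, 1)")
        if len(self.split_fractions) != 3 or abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must be three numbers summing to 1")
        if self.final_refit_on not in ("train", "train+val"):
            raise ConfigError("final_refit_on must be 'train' or 'train+val'")
        if self.interpolation not in ("trilinear", "nearest"):
            raise ConfigError("interpolation must be 'trilinear' or 'nearest'")
        if self.ratio_direction not in ("gm_over_wm", "wm_over_gm"):
            raise ConfigError("ratio_direction must be 'gm_over_wm' or 'wm_over_gm'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict, **overrides) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {**d, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged).validate()


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a flat YAML config; CLI flag overrides win over file values."""
    d: dict = {}
    if path is not None:
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
    return RunConfig.from_dict(d, **overrides)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
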