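"""Flat key-value pipeline configuration with strict key validation."""
from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

__all__ = ["ConfigError", "MissingInputError", "PipelineConfig", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Unknown or invalid configuration content."""


class MissingInputError(FileNotFoundError):
    """A stage's required input file is absent."""

    def __init__(self, stage: str, what: str, hint: str | None = None):
        msg = f"stage {stage}: missing input {what}"
        if hint:
            msg += f" (run {hint} first)"
        super().__init__(msg)
        self.stage = stage


_FACTORS = ("sin3b", "hdac1", "h3k27ac")
_CONDS = ("control", "ko")

PATH_KEYS = (
    ["chrom_sizes", "genes", "counts"]
    + [f"peaks_{f}_{c}" for f in _FACTORS for c in _CONDS]
    + [f"track_{f}_{c}" for f in _FACTORS for c in _CONDS]
)

DEFAULTS: dict[str, object] = {
    "window_size": 6000,
    "step": 6000,
    "promoter_flank": 3000,
    "stitch_gap": 12500,
    "se_assignment_radius": 50000,
    "fc_threshold": 1.3,
    "fc_pseudocount": 0.1,
    "log_pseudocount": 0.01,
    "fc_cutoff": 1.3,
    "alpha": 0.05,
    "tpm_pseudocount": 1.0,
    "se_condition": "KO",
    "pair_gain_class": "Pro",
    "seed": 0,
    "expressed_only": False,
    "adjust_p": False,
    "control_samples": "",
    "ko_samples": "",
}

ALLOWED_KEYS = set(DEFAULTS) | set(PATH_KEYS) | {
    f"total_mapped_track_{f}_{c}" for f in _FACTORS for c in _CONDS
}

_POSITIVE = (
    "window_size",
    "step",
    "promoter_flank",
    "stitch_gap",
    "se_assignment_radius",
    "fc_threshold",
    "fc_pseudocount",
    "log_pseudocount",
    "fc_cutoff",
    "alpha",
    "tpm_pseudocount",
)


class PipelineConfig:
    """Validated flat configuration; relative paths resolve against its dir."""

    def __init__(self, values: dict[str, object], base_dir: Path | None = None):
        unknown = sorted(set(values) - ALLOWED_KEYS)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        self.values = {**DEFAULTS, **values}
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        for key in _POSITIVE:
            try:
                v = float(self.values[key])
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key} must be numeric") from None
            if v <= 0:
                raise ConfigError(f"config key {key} must be > 0")

    def get(self, key: str):
        return self.values.get(key)

    def path(self, key: str) -> Path | None:
        v = self.values.get(key)
        if v is None:
            return None
        p = Path(str(v))
        return p if p.is_absolute() else self.base_dir / p

    def require_path(self, key: str, stage: str, hint: str | None = None) -> Path:
        p = self.path(key)
        if p is None or not p.exists():
            raise MissingInputError(stage, f"{key} ({p})" if p else key, hint)
        return p

    def total_mapped(self, track_key: str) -> float | None:
        v = self.values.get(f"total_mapped_{track_key}")
        return float(v) if v is not None else None

    def sha256(self) -> str:
        payload = yaml.safe_dump(
            {k: self.values[k] for k in sorted(self.values)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    return PipelineConfig(raw, base_dir=path.parent)
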