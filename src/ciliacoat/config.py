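"""Run configuration: one YAML file per pipeline invocation.

A config is a flat mapping of stage parameters plus a mandatory ``seed`` for
every stochastic stage and input/output paths.  Unknown keys are rejected so
typos cannot silently fall back to defaults; CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "log_run"]

logger = logging.getLogger("ciliacoat")

_KNOWN_KEYS = {
    "seed",
    "inputs",
    "outputs",
    "params",
}


@dataclass
class RunConfig:
    seed: int
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("config must set an explicit seed")
        self.seed = int(self.seed)
        for name in ("params", "inputs", "outputs"):
            value = getattr(self, name)
            if not isinstance(value, dict):
                raise ValidationError(f"config section {name!r} must be a mapping")

    def override(self, **params) -> "RunConfig":
        """New config with the given parameters overriding the file values."""
        merged = dict(self.params)
        merged.update({k: v for k, v in params.items() if v is not None})
        return RunConfig(self.seed, merged, dict(self.inputs), dict(self.outputs))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must hold a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "seed" not in raw:
        raise ValidationError("config must set an explicit seed")
    return RunConfig(
        seed=raw["seed"],
        params=raw.get("params", {}) or {},
        inputs=raw.get("inputs", {}) or {},
        outputs=raw.get("outputs", {}) or {},
    )


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while chunk := fh.read(1 << 20):
            h.update(chunk)
    return h.hexdigest()[:16]


def log_run(stage: str, config: RunConfig) -> None:
    """Log tool version, stage parameters, seed and input hashes."""
    try:
        ver = version("ciliacoat")
    except PackageNotFoundError:
        ver = "unknown"
    logger.info("ciliacoat %s | stage=%s | seed=%d", ver, stage, config.seed)
    for key, value in sorted(config.params.items()):
        logger.info("  param %s = %r", key, value)
    for key, path in sorted(config.inputs.items()):
        p = Path(path)
        digest = _file_sha256(p) if p.is_file() else "missing"
        logger.info("  input %s = %s (sha256:%s)", key, path, digest)
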