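"""Pipeline configuration: schema, validation, and reproducibility hashing.

A run is fully described by one config object; every stochastic stage has
an explicit seed and the config's canonical-JSON SHA-256 hash is embedded in
all outputs so deterministic stages can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decision_models import MODELS
from .gamble_engine import GambleSetConfig
from .inference import FitOptions
from .synthetic_cohort import DEFAULT_MISSED_RATE, DEFAULT_RT_SPEC, RtGeneratorSpec

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the pipeline end to end."""

    seed: int = 0
    # gamble generator
    gamble: GambleSetConfig = field(default_factory=GambleSetConfig)
    # cohort simulation
    n_agents: int = 22
    generating_model: int = 7
    generating_params: dict | None = None
    missed_rate: float = DEFAULT_MISSED_RATE
    rt: RtGeneratorSpec = DEFAULT_RT_SPEC
    # fitting
    models: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    optimizer: FitOptions = field(default_factory=FitOptions)
    # comparison
    ic: str = "bic"
    bms_prior_alpha: float = 1.0
    bms_samples: int = 1_000_000
    # rt analysis
    rt_re_structure: str = "full"

    def __post_init__(self) -> None:
        if self.ic not in ("bic", "aic"):
            raise ValueError("ic must be 'bic' or 'aic'")
        unknown = [m for m in self.models if m not in MODELS]
        if unknown:
            raise ValueError(f"unknown model ids {unknown}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (0.0 <= self.missed_rate < 1.0):
            raise ValueError("missed_rate must lie in [0, 1)")
        if self.bms_prior_alpha <= 0 or self.bms_samples < 1:
            raise ValueError("BMS prior and sample count must be positive")
        if self.rt_re_structure not in ("full", "intercept"):
            raise ValueError("rt_re_structure must be 'full' or 'intercept'")

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON encoding of the config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Build a validated config from a YAML (or JSON) file.

    Nested sections ``gamble``, ``optimizer`` and ``rt`` accept the fields
    of :class:`GambleSetConfig`, :class:`FitOptions` and
    :class:`RtGeneratorSpec` respectively; lists are coerced to tuples.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")

    def tup(x):
        return tuple(tuple(v) if isinstance(v, list) else v for v in x)

    kwargs: dict = {}
    if "gamble" in raw:
        g = dict(raw.pop("gamble"))
        for key in ("combos", "gains"):
            if key in g:
                g[key] = tup(g[key])
        kwargs["gamble"] = GambleSetConfig(**g)
    if "optimizer" in raw:
        kwargs["optimizer"] = FitOptions(**raw.pop("optimizer"))
    if "rt" in raw:
        r = dict(raw.pop("rt"))
        for key in ("gamma", "re_sd"):
            if key in r:
                r[key] = tuple(r[key])
        kwargs["rt"] = RtGeneratorSpec(**r)
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    known = PipelineConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
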