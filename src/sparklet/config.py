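"""Run configuration and result bundles.

A ``RunConfig`` is schema-validated on construction, serialized verbatim
into every output bundle, and drives all randomness through a single seed
split with ``numpy.random.SeedSequence(seed).spawn`` (one child stream per
site, in site order; rendering uses the gating stream's child).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._errors import ConfigError
from .gating_sim import GatingParams, RenderParams
from .quantal import SiteConfig
from .trace_ops import KalmanParams


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic-data stage: how many sites and with what gating/rendering."""

    n_sites: int = 1
    n_cells: int = 15
    gating: GatingParams = field(default_factory=GatingParams)
    render: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ConfigError("n_sites must be >= 0")
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be > 0")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    frame_rate: float = 30.0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    kalman: KalmanParams = field(default_factory=KalmanParams)
    use_kalman: bool = False  # apply Kalman to traces before quantal analysis
    site: SiteConfig = field(default_factory=SiteConfig)
    trace_paths: tuple[str, ...] = ()
    vessel_csv: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not (self.frame_rate > 0):
            raise ConfigError("frame_rate must be > 0")
        if self.simulate is None and not self.trace_paths:
            raise ConfigError("nothing to do: no simulation and no input traces")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if d.get("simulate") is not None:
                sim = dict(d["simulate"])
                sim["gating"] = GatingParams(**sim.get("gating", {}))
                sim["render"] = RenderParams(**sim.get("render", {}))
                d["simulate"] = SimulateConfig(**sim)
            if "kalman" in d:
                d["kalman"] = KalmanParams(**d["kalman"])
            if "site" in d:
                d["site"] = SiteConfig(**d["site"])
            if "trace_paths" in d:
                d["trace_paths"] = tuple(d["trace_paths"])
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ResultBundle:
    """Everything a run produced, with full config provenance."""

    config: dict
    sites: list[dict]
    vessel: list[dict]
    version: str
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "sites": self.sites,
            "vessel": self.vessel,
            "version": self.version,
            "log": self.log,
        }

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON of the deterministic payload (no log)."""
        payload = {"config": self.config, "sites": self.sites, "vessel": self.vessel}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()
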