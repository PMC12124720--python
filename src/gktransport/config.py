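"""Run configuration: every external knob of the analysis in one
serializable record.

A run is reproducible end-to-end from a :class:`RunConfig` plus a seed:
interval length, lag cap, plateau policy and thresholds, stride,
volume, temperature.  Serializes to plain-text YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    """Analysis knobs (times in ps; volume in nm^3; temperature in K)."""

    interval_length: float = 1000.0
    max_lag: float | None = None  # default: half the interval
    plateau: str = "auto"  # "auto" or "t0:t1" in ps
    agreement_sigma: float = 1.0
    min_fraction: float = 0.5
    stride: int = 1
    volume: float | None = None
    temperature: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.interval_length <= 0:
            raise ValueError("interval_length must be positive")
        if self.max_lag is not None and self.max_lag <= 0:
            raise ValueError("max_lag must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        for name in ("volume", "temperature"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def plateau_window(self):
        """Parsed plateau policy: "auto" or a (t0, t1) tuple in ps."""
        if self.plateau == "auto":
            return "auto"
        t0, t1 = (float(x) for x in self.plateau.split(":"))
        return (t0, t1)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
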