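"""Run configuration shared across CLI subcommands.

A run is parameterized by instrument constants, detection thresholds and
statistical settings.  Values resolve in order: built-in defaults, then a
YAML config file, then explicit CLI flags (flags win).  Every analysis
output embeds the resolved configuration and the top-level seed, from
which all per-stage random streams derive.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, fields

import numpy as np
import yaml

from .core import InstrumentParams


@dataclass
class RunConfig:
    # instrument constants
    autofluor_donor: float = 0.0
    autofluor_acceptor: float = 0.0
    crosstalk: float = 0.0
    gamma: float = 1.0
    monomer_brightness: float | None = None  # override; else estimated from data
    # thresholds
    event_threshold: int = 10  # photon counts per bin, each channel
    mask_k: float = 3.0  # blank-sd multiples for the direct-channel mask
    step_penalty: float = 2.0  # BIC multiplier per change point
    coincidence_radius: float = 2.0  # pixels
    # statistics
    histogram_bin_width: float = 0.05
    n_resamples: int = 9999
    seed: int = 0

    @property
    def instrument(self) -> InstrumentParams:
        return InstrumentParams(
            autofluor_donor=self.autofluor_donor,
            autofluor_acceptor=self.autofluor_acceptor,
            crosstalk=self.crosstalk,
            gamma=self.gamma,
            monomer_brightness=self.monomer_brightness,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def resolve(cls, config_path=None, **overrides) -> "RunConfig":
        """Defaults <- YAML file <- keyword overrides (non-None only)."""
        values: dict = {}
        if config_path is not None:
            with open(config_path) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from one top seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])
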