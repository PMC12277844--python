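"""Run configuration: every analysis constant in one serialisable record.

Defaults are the analysis constants the pipeline is built around: 20-ms PSTH bins, order-4 binomial
smoothing, a mean+4SD detection threshold from 10 s of darkness, a 500-ms
onset / 50-300-ms offset response window, a 10-Hz low-signal cutoff,
dilation magnifications {1, 5, 10, 15} for the graft areas, 500-um sampling
circles, and 1.5-um / 10-um proximity rules for synapse detection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


@dataclass(frozen=True)
class RunConfig:
    # MEA analysis
    bin_width: float = 0.020              # s
    filter_order: int = 4
    onset_window: float = 0.5             # s after light onset
    offset_window: tuple[float, float] = (0.05, 0.3)  # s after light offset
    low_signal_cutoff: float = 10.0       # spikes/s, on the corrected peak
    sd_multiplier: float = 4.0
    dark_duration: float = 10.0           # s of spontaneous activity
    ir_n_bounds: tuple[float, float] = (0.1, 10.0)
    ir_i50_bounds: tuple[float, float] | None = None  # default: data-derived
    dilation_magnifications: tuple[float, ...] = (1, 5, 10, 15)
    dilation_base_radius: float = 200.0   # um, one electrode pitch
    reference_intensity: float = 95.23    # R*/rod/s flash used for labels
    # HC mosaics
    circle_diameter: float = 500.0        # um
    nnd_bin_width: float = 5.0            # um
    nnd_range: tuple[float, float] = (0.0, 100.0)
    # synapse detection
    synapse_radius: float = 1.5           # um
    rbc_reach: float = 10.0               # um
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        def _tup(name):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, tuple(v))

        for name in ("offset_window", "ir_n_bounds", "ir_i50_bounds",
                     "dilation_magnifications", "nnd_range"):
            _tup(name)
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if self.onset_window <= 0:
            raise ConfigError("onset_window must be positive")
        lo, hi = self.offset_window
        if not (0 <= lo < hi):
            raise ConfigError("offset_window must be an increasing pair")
        for name in ("low_signal_cutoff", "sd_multiplier", "dark_duration",
                     "dilation_base_radius", "circle_diameter", "nnd_bin_width",
                     "synapse_radius", "rbc_reach", "reference_intensity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        mags = self.dilation_magnifications
        if len(mags) != 4 or any(m <= 0 for m in mags) or list(mags) != sorted(mags):
            raise ConfigError("dilation_magnifications must be 4 increasing positives")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected, missing defaulted."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:  # wrong value shape
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
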