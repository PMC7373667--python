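"""YAML run configuration shared by the command-line subcommands.

A config file is a small YAML mapping with up to three sections::

    detection:            # waveform.DetectionConfig fields
      baseline_window_n: 10
      onset_threshold_au: 0.01
      onset_min_consecutive: 3
      plateau_slope_fraction: 0.05
      smoothing_window_n: 5
    simulate:             # generator overrides
      noise_sd_au: 0.003
      lysis_rate_per_min: 0.06
    io:
      precision: 10       # significant digits in written tables
      layout: long        # kinetic table layout

Every key is optional; omitted keys keep package defaults.  Unknown keys
raise, so typos fail loudly rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional

import yaml

from .waveform import DetectionConfig

__all__ = ["RunConfig", "load_config", "config_digest"]

_SECTIONS = {"detection", "simulate", "io"}
_SIM_KEYS = {"noise_sd_au", "lysis_rate_per_min"}
_IO_KEYS = {"precision", "layout"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    detection: DetectionConfig = DetectionConfig()
    noise_sd_au: Optional[float] = None
    lysis_rate_per_min: Optional[float] = None
    precision: int = 10
    layout: str = "long"

    def digest(self) -> str:
        return config_digest(self)


def load_config(path: Optional[str]) -> RunConfig:
    """Parse a YAML config file into a RunConfig (defaults when path is None)."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path!r}: top level must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"config {path!r}: unknown section(s) {sorted(unknown)}")
    det_kwargs = raw.get("detection") or {}
    known_det = {f.name for f in dataclasses.fields(DetectionConfig)}
    bad = set(det_kwargs) - known_det
    if bad:
        raise ValueError(f"config {path!r}: unknown detection key(s) {sorted(bad)}")
    sim = raw.get("simulate") or {}
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ValueError(f"config {path!r}: unknown simulate key(s) {sorted(bad)}")
    io = raw.get("io") or {}
    bad = set(io) - _IO_KEYS
    if bad:
        raise ValueError(f"config {path!r}: unknown io key(s) {sorted(bad)}")
    return RunConfig(
        detection=DetectionConfig(**det_kwargs),
        noise_sd_au=sim.get("noise_sd_au"),
        lysis_rate_per_min=sim.get("lysis_rate_per_min"),
        precision=int(io.get("precision", 10)),
        layout=str(io.get("layout", "long")),
    )


def config_digest(cfg: RunConfig) -> str:
    """Short stable hash of the effective configuration, for output headers."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
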