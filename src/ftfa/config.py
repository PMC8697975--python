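"""Declarative analysis configuration (flat YAML, validated at load time).

Every run's config is serialized verbatim into the provenance attribute of
each output container, together with a content hash, so any artifact can be
traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    # inputs: either a recording+events pair, or a synthetic session
    recording: str | None = None        # .edf or .h5 recording container
    events: str | None = None           # CSV with sample,condition
    montage: str | None = None          # CSV with label,x,y (else built-in 10-20)
    simulate: bool = False              # generate the demo session instead
    channels: list[str] = field(default_factory=lambda: ["C3", "Cz", "C4", "Pz"])
    n_runs: int = 6
    trials_per_condition_per_run: int = 12

    # epoching / baseline
    tmin_s: float = -2.0
    tmax_s: float = 4.0
    baseline_s: tuple[float, float] = (-2.0, 0.0)
    baseline_mode: str = "ratio"

    # wavelet decomposition
    f_lo: float = 1.0
    f_hi: float = 100.0
    f_step: float = 1.0
    n_cycles: float = 7.0

    # statistics
    alpha: float = 0.01
    correction: str = "none"

    # topography requests: band (Hz) and time windows (s)
    topo_bands: list[tuple[float, float]] = field(default_factory=lambda: [(17.0, 27.0), (9.0, 15.0)])
    topo_windows: list[tuple[float, float]] = field(default_factory=lambda: [(0.5, 1.5), (1.5, 2.5), (2.5, 3.5)])

    seed: int = 0
    out_dir: str = "ftfa_out"
    figures: bool = True

    def __post_init__(self) -> None:
        if not self.tmax_s > self.tmin_s:
            raise ValueError("config field tmax_s must exceed tmin_s")
        b0, b1 = self.baseline_s
        if not (self.tmin_s <= b0 < b1 <= self.tmax_s):
            raise ValueError("config field baseline_s must lie inside the epoch window")
        if not (0 < self.f_lo <= self.f_hi and self.f_step > 0):
            raise ValueError("config fields f_lo/f_hi/f_step invalid")
        if not 0 < self.alpha < 1:
            raise ValueError("config field alpha must lie in (0, 1)")
        if self.correction not in ("none", "bonferroni", "bh-fdr"):
            raise ValueError("config field correction must be none|bonferroni|bh-fdr")
        if self.baseline_mode not in ("ratio", "percent", "dB", "none"):
            raise ValueError("config field baseline_mode invalid")
        if not self.simulate and (self.recording is None or self.events is None):
            raise ValueError("config requires recording+events paths unless simulate is true")

    def freqs(self):
        import numpy as np

        n = int(round((self.f_hi - self.f_lo) / self.f_step)) + 1
        return self.f_lo + self.f_step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_s"] = list(d["baseline_s"])
        d["topo_bands"] = [list(b) for b in d["topo_bands"]]
        d["topo_windows"] = [list(w) for w in d["topo_windows"]]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Read a YAML config; keyword overrides (e.g. CLI flags) win over the file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a mapping of keys to values")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("baseline_s",):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("topo_bands", "topo_windows"):
        if key in raw:
            raw[key] = [tuple(x) for x in raw[key]]
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return AnalysisConfig(**raw)
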