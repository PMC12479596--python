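"""Pipeline configuration: dataclasses, validation, hashing, YAML round-trip.

Defaults follow the analysis parameters the pipeline is built around:
1-40 Hz band-pass with 50 Hz notch and 250 Hz target rate; cluster range
1-12 with 300 restarts and a 0.80 merge threshold; back-fit threshold 0.5
with smoothing half-window 3 / strength 10; alpha 0.05 with 5000
permutations and 5000 bootstrap resamples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PreprocConfig",
    "ClusterConfig",
    "BackfitConfig",
    "StatsConfig",
    "SimulationConfig",
    "PipelineConfig",
    "validate_config",
    "config_hash",
]


@dataclass
class PreprocConfig:
    low_hz: float = 1.0
    high_hz: float = 40.0
    notch_hz: float = 50.0
    target_hz: float = 250.0


@dataclass
class ClusterConfig:
    k_min: int = 1
    k_max: int = 12
    restarts: int = 300
    merge_threshold: float = 0.80
    subject_k: int | None = None
    subject_restarts: int | None = None


@dataclass
class BackfitConfig:
    threshold: float = 0.5
    half_window: int = 3
    strength: float = 10.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 5000
    n_boot: int = 5000


@dataclass
class SimulationConfig:
    n_per_group: int = 18
    n_channels: int = 64
    duration_s: float = 240.0
    sfreq: float = 250.0
    snr: float = 4.0
    n_maps: int = 4
    dwell_effect: float = 1.3
    dwell_effect_map: int = 2
    transition_effect: float = 1.0
    transition_effect_pair: tuple[int, int] = (1, 2)


@dataclass
class PipelineConfig:
    """Either ``simulation`` or ``input_dir`` must be set."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_dir: str | None = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    backfit: BackfitConfig = field(default_factory=BackfitConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            if "transition_effect_pair" in sim:
                sim["transition_effect_pair"] = tuple(sim["transition_effect_pair"])
            d["simulation"] = SimulationConfig(**sim)
        for key, klass in (
            ("preproc", PreprocConfig),
            ("cluster", ClusterConfig),
            ("backfit", BackfitConfig),
            ("stats", StatsConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# documented (field, check, range description) triples
def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations (empty means the config is valid)."""
    v: list[str] = []
    if config.simulation is None and config.input_dir is None:
        v.append("either simulation or input_dir is required")
    p = config.preproc
    if not 0 < p.low_hz < p.high_hz:
        v.append(f"preproc.low_hz/high_hz: need 0 < low ({p.low_hz}) < high ({p.high_hz})")
    if not p.high_hz < p.target_hz / 2:
        v.append(f"preproc.high_hz={p.high_hz}: must be below target Nyquist {p.target_hz / 2}")
    if not p.notch_hz > 0:
        v.append(f"preproc.notch_hz={p.notch_hz}: range (0, inf)")
    c = config.cluster
    if not 1 <= c.k_min < c.k_max:
        v.append(f"cluster.k_min/k_max: need 1 <= k_min ({c.k_min}) < k_max ({c.k_max})")
    if c.restarts < 1:
        v.append(f"cluster.restarts={c.restarts}: range [1, inf)")
    if not 0 < c.merge_threshold <= 1:
        v.append(f"cluster.merge_threshold={c.merge_threshold}: range (0, 1]")
    b = config.backfit
    if not 0 <= b.threshold <= 1:
        v.append(f"backfit.threshold={b.threshold}: range [0, 1]")
    if b.half_window < 0:
        v.append(f"backfit.half_window={b.half_window}: range [0, inf)")
    if b.strength < 0:
        v.append(f"backfit.strength={b.strength}: range [0, inf)")
    s = config.stats
    if not 0 < s.alpha < 1:
        v.append(f"stats.alpha={s.alpha}: range (0, 1)")
    if s.n_perm < 1:
        v.append(f"stats.n_perm={s.n_perm}: range [1, inf)")
    if s.n_boot < 1:
        v.append(f"stats.n_boot={s.n_boot}: range [1, inf)")
    sim = config.simulation
    if sim is not None:
        if sim.n_per_group < 2:
            v.append(f"simulation.n_per_group={sim.n_per_group}: range [2, inf)")
        if sim.n_channels < 8:
            v.append(f"simulation.n_channels={sim.n_channels}: range [8, inf)")
        if sim.duration_s <= 0:
            v.append(f"simulation.duration_s={sim.duration_s}: range (0, inf)")
        if not 2 <= sim.n_maps <= 7:
            v.append(f"simulation.n_maps={sim.n_maps}: range [2, 7]")
        if sim.snr <= 0:
            v.append(f"simulation.snr={sim.snr}: range (0, inf)")
    return v


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full parameter set (provenance tag)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
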