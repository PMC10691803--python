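"""Pipeline configuration: one YAML file drives a full run.

All analysis constants live here with defaults matching the emulated study
protocol: order-4 band-pass of +-2 Hz around the individual alpha peak,
order-8 low-pass at 3 Hz, epochs of -0.4..1.3 s with a -0.2..-0.05 s
baseline, 0.3-0.7 s spatial-filter training window, 0.2-1.0 s peak search,
20 envelope bins for the baseline-shift index, 5 subject bins for the
group contrasts, and a cluster-forming threshold of p = 1e-4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # filtering
    alpha_band_halfwidth_hz: float = 2.0
    alpha_filter_order: int = 4
    lowpass_hz: float = 3.0
    lowpass_order: int = 8
    # windows (seconds, relative to stimulus onset)
    epoch_window_s: tuple = (-0.4, 1.3)
    baseline_window_s: tuple = (-0.2, -0.05)
    train_window_s: tuple = (0.3, 0.7)
    peak_window_s: tuple = (0.2, 1.0)
    post_window_s: tuple = (0.2, 1.0)
    # statistics
    n_permutations: int = 10000
    cluster_p_threshold: float = 1e-4
    bonferroni_base_p: float = 1e-4
    n_bsi_bins: int = 20
    n_subject_bins: int = 5
    n_boot: int = 2000
    # orchestration
    seed: int = 0
    peak_sensor: str = "Pz"

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        lo, hi = self.epoch_window_s
        for name in ("baseline_window_s", "train_window_s",
                     "peak_window_s", "post_window_s"):
            a, b = getattr(self, name)
            if not (lo <= a < b <= hi):
                raise ValueError(f"{name}={a, b} not inside epoch {lo, hi}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in list(d.items()):
            if isinstance(val, tuple):
                d[key] = list(val)
        for key, val in list(d["cohort"].items()):
            if isinstance(val, tuple):
                d["cohort"][key] = list(val)
        return d


def _tupleise(d: dict, keys) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v
            for k, v in d.items()}


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    window_keys = {"epoch_window_s", "baseline_window_s", "train_window_s",
                   "peak_window_s", "post_window_s"}
    raw = _tupleise(raw, window_keys)
    if "cohort" in raw:
        dist_keys = {"mean_offset", "depth", "peak_latency_s", "alpha_freq_hz",
                     "noise_exponent", "noise_level_uv", "age_range"}
        raw["cohort"] = _tupleise(raw["cohort"], dist_keys)
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
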