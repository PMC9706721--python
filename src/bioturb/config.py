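"""Pipeline configuration: every stage threshold in one place.

Defaults are the canonical screening thresholds of the analysis: the
parameter screen |rho| > 0.60 at p < 0.05, the network gate rho > 0.65 at
p < 0.001, differential FDR < 0.05, MIC cutoffs 0.35 / 0.55, top-10
modules with a 10% bsASV share. The config round-trips losslessly through
YAML, and its hash is recorded in every output header.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    pasv_rho_min: float = 0.60
    pasv_alpha: float = 0.05
    mantel_alpha: float = 0.05
    indicator_alpha: float = 0.05
    max_combo_size: int = 2
    fdr_alpha: float = 0.05
    network_rho_min: float = 0.65
    network_p_max: float = 0.001
    mic_threshold: float = 0.35
    mic_strong_threshold: float = 0.55
    mic_alpha: float = 0.6
    mic_c: float = 15.0
    top_k_modules: int = 10
    bsmodule_min_share: float = 0.10
    n_perm: int = 999
    seed: int = 0
    pasv_per_type: bool = True

    def __post_init__(self) -> None:
        checks = {
            "pasv_rho_min": (self.pasv_rho_min, 0.0, 1.0),
            "network_rho_min": (self.network_rho_min, 0.0, 1.0),
            "mic_threshold": (self.mic_threshold, 0.0, 1.0),
            "mic_strong_threshold": (self.mic_strong_threshold, 0.0, 1.0),
            "pasv_alpha": (self.pasv_alpha, 0.0, 1.0),
            "mantel_alpha": (self.mantel_alpha, 0.0, 1.0),
            "indicator_alpha": (self.indicator_alpha, 0.0, 1.0),
            "fdr_alpha": (self.fdr_alpha, 0.0, 1.0),
            "network_p_max": (self.network_p_max, 0.0, 1.0),
            "bsmodule_min_share": (self.bsmodule_min_share, 0.0, 1.0),
        }
        for name, (val, lo, hi) in checks.items():
            if not lo < val <= hi:
                raise ValueError(f"config: {name}={val} outside ({lo}, {hi}]")
        if self.mic_threshold > self.mic_strong_threshold:
            raise ValueError("config: mic_threshold > mic_strong_threshold")
        if self.n_perm < 99:
            raise ValueError("config: n_perm must be >= 99")
        if self.top_k_modules < 1 or self.max_combo_size < 1:
            raise ValueError("config: top_k_modules and max_combo_size must be >= 1")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Named substream: stage-level seeds derived from the root seed,
        independent of execution order."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)
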