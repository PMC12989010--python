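"""Declarative run configuration.

One flat YAML file (or keyword overrides) drives the whole pipeline; every
output bundle embeds the exact configuration it was produced with.  A single
master seed feeds all randomness; per-stage seeds are derived from it
deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["PipelineConfig", "SyntheticConfig", "stage_seed"]


@dataclass
class SyntheticConfig:
    """Generator settings for synthetic-mode runs (no input files)."""

    n: int = 280
    p: int = 27
    q: int = 10
    n_communities: int = 4
    within_prob: float = 0.4
    between_prob: float = 0.02
    weight_lo: float = 0.28
    weight_hi: float = 0.45
    positive_frac: float = 0.9
    likert_items: int = 4
    item_noise_sd: float = 0.3
    facets_per_condition: int = 3
    condition_r2: float = 0.5

    @classmethod
    def well_separated(cls, **overrides) -> "SyntheticConfig":
        """Community-recovery scenario: dense within-community support and
        almost no between-community edges, so the planted partition is
        unambiguous."""
        base = dict(within_prob=0.6, between_prob=0.01, weight_lo=0.30, weight_hi=0.45)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.n < 2 or self.p < 3 or self.q < 1:
            raise ValueError("need n >= 2, p >= 3, q >= 1")
        if not (0.0 <= self.between_prob <= self.within_prob <= 1.0):
            raise ValueError("require 0 <= between_prob <= within_prob <= 1")
        if not (0.0 <= self.weight_lo <= self.weight_hi < 1.0):
            raise ValueError("weight range must satisfy 0 <= lo <= hi < 1")
        if not (0.0 < self.condition_r2 <= 1.0):
            raise ValueError("condition_r2 must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Everything a run needs; validated before any computation starts."""

    facets_csv: str | None = None
    conditions_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    # estimation
    correlation_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    # redundancy screen
    goldbricker_cor_min: float = 0.50
    goldbricker_alpha: float = 0.05
    goldbricker_prop_threshold: float = 0.25
    reduce_nodes: bool = False
    # descriptives
    walk_length: int = 4
    # stability
    run_stability: bool = False
    bootstrap_B: int = 1000
    drop_proportions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75)
    stability_n_lambda: int | None = None
    # linkage
    threshold_mode: str = "mean"
    threshold_value: float | None = None
    linkage_method: str = "spearman"
    # run control
    seed: int = 0
    output_dir: str = "awnet_run"

    def validate(self) -> None:
        if self.synthetic is None and self.facets_csv is None:
            raise ValueError("either facets_csv or a synthetic block is required")
        if self.synthetic is not None and self.facets_csv is not None:
            raise ValueError("facets_csv and synthetic mode are mutually exclusive")
        if self.synthetic is not None:
            self.synthetic.validate()
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")
        if not (0.0 <= self.gamma):
            raise ValueError("gamma must be non-negative")
        if self.n_lambda < 1 or not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("need n_lambda >= 1 and 0 < lambda_min_ratio < 1")
        if self.threshold_mode not in ("mean", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("threshold_mode 'fixed' requires threshold_value")
        if any(not (0.0 <= d < 1.0) for d in self.drop_proportions):
            raise ValueError("drop proportions must lie in [0, 1)")
        if self.bootstrap_B < 1 or self.walk_length < 1:
            raise ValueError("bootstrap_B and walk_length must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_proportions"] = list(self.drop_proportions)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "drop_proportions" in d and d["drop_proportions"] is not None:
            d["drop_proportions"] = tuple(float(x) for x in d["drop_proportions"])
        cfg = cls(**d)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn) if isinstance(syn, dict) else syn
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


#: fixed offsets so each stage draws from an independent, reproducible stream
_STAGE_OFFSETS = {"network": 1, "facets": 2, "conditions": 3, "bootstrap": 4, "loadings": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
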