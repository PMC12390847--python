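"""Run configuration: every analysis constant lives here, none hard-coded.

The defaults consolidate the study's printed constants: globally fixed model
parameters (gamma = 4.8/day, K_A = K~_C = 0.01 mM), regime thresholds (0.05
and 1.5 mM/day), the enrichment significance level (alpha = 0.05) and
pseudocounts (0.5 counts for z-scores, 1e-3 on the abundance scale for folds,
0.01 for display transforms).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # fixed model parameters
    gamma: float = 4.8  # 1/day
    k_a: float = 0.01  # mM
    k_c_tilde: float = 0.01  # mM
    # regime thresholds (mM/day)
    x_thr: float = 0.05
    c_thr: float = 1.5
    # enrichment
    alpha: float = 0.05
    pseudo_counts: float = 0.5
    nn_n_asv: int = 2500  # n_ASV convention for the no-nitrate contrast
    noise_high_thresh: float = 50.0
    noise_coverage: float = 0.67
    # folds
    pseudo_abundance: float = 1e-3
    display_pseudo: float = 0.01
    # fitting
    n_starts: int = 8
    # nmf
    nmf_rank: int = 2
    nmf_restarts: int = 10
    # regression
    lasso_folds: int = 10
    rel_thresh: float = 0.001
    tax_level: str = "family"
    n_perm: int = 1000
    # seeds
    seed: int = 0
    # paths (optional; pipeline falls back to synthetic data when absent)
    timeseries_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    meta_path: str | None = None
    out_dir: str = "soilregimes_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]
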