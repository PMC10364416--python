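"""Structured run configuration with validation and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict

import yaml

from .reconstruct import AbcParams, PipelineConfig


@dataclass
class RunConfig:
    """All pipeline tunables with their method defaults.

    usage_threshold: TPM above which an element is in usage (strict).
    max_distance: candidate enhancer window around the TSS, bp.
    n_null / fdr: size of the trans-chromosomal null and the empirical FDR.
    abc_gamma / abc_d0 / abc_background: ABC contact decay exponent,
    pseudo-distance (bp) and promoter background term.
    linkage: hierarchical clustering linkage for state networks.
    flank: gene-body flank for proximal SNP assignment, bp.
    alpha: BH significance level for gene prioritization.
    """

    usage_threshold: float = 1.0
    max_distance: int = 1_000_000
    n_null: int = 10_000
    fdr: float = 0.05
    fdr_mode: str = "quantile"
    abc_gamma: float = 1.0
    abc_d0: float = 5000.0
    abc_background: float = 0.0
    cv_folds: int = 5
    linkage: str = "average"
    flank: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.usage_threshold < 0:
            raise ValueError("usage_threshold must be >= 0")
        if self.max_distance <= 0 or self.n_null <= 0 or self.flank < 0:
            raise ValueError("max_distance and n_null must be positive; flank >= 0")
        if self.abc_gamma < 0 or self.abc_d0 < 0 or self.abc_background < 0:
            raise ValueError("require abc_gamma >= 0, abc_d0 >= 0, abc_background >= 0")
        if self.fdr_mode not in {"quantile", "ratio"}:
            raise ValueError("fdr_mode must be 'quantile' or 'ratio'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run provenance."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            usage_threshold=self.usage_threshold,
            max_distance=self.max_distance,
            n_null=self.n_null,
            fdr=self.fdr,
            abc=AbcParams(self.abc_gamma, self.abc_d0, self.abc_background),
            cv_folds=self.cv_folds,
            fdr_mode=self.fdr_mode,
        )
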