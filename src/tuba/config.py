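"""Run configuration: the two tunable knobs plus bookkeeping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated parameters of one biclustering run.

    percentile
        Fraction in (0, 0.5] of samples in each gene's extremal set.
    direction
        'high' (top of the expression profile) or 'low' (bottom).
    cutoff
        Overlap-significance cut-off in (0, 1) applied per gene pair.
    cutoff_mode
        'fdr' thresholds the BH-adjusted p-value, 'raw' the raw p-value.
    seed
        Seed for any randomized step (permutation null, simulation).
    min_nonzero
        Optional: genes with fewer non-zero values are dropped before a
        'low'-direction run, where all-tied zeros would dominate the sets.
    """

    percentile: float = 0.05
    direction: str = "high"
    cutoff: float = 1e-8
    cutoff_mode: str = "fdr"
    seed: int = 0
    min_nonzero: int | None = None
    fdr_threshold: float = 0.05  # used only by the quality summary Q

    def validate(self) -> "RunConfig":
        if not 0.0 < self.percentile <= 0.5:
            raise ValueError(f"percentile must lie in (0, 0.5], got {self.percentile}")
        if self.direction not in ("high", "low"):
            raise ValueError(f"direction must be 'high' or 'low', got {self.direction!r}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must lie in (0, 1), got {self.cutoff}")
        if self.cutoff_mode not in ("fdr", "raw"):
            raise ValueError(f"cutoff_mode must be 'fdr' or 'raw', got {self.cutoff_mode!r}")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if self.min_nonzero is not None and self.min_nonzero < 0:
            raise ValueError("min_nonzero must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
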