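"""Run configuration shared by every analysis stage.

All the thresholds that the pipeline treats as decisions — duplicate-pair
identity/coverage, the tandem distance, the synonymous clock rate, DEG and
coexpression cutoffs — live in one flat record so a run can be reproduced
from its config file alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import InputError


@dataclass
class AnalysisConfig:
    """Thresholds and rates used across the pipeline.

    lambda_rate is the synonymous substitution clock in substitutions per
    site per year used to convert Ks into an age (T = Ks / 2λ).
    """

    lambda_rate: float = 6.1e-9
    promoter_len: int = 2000
    tandem_dist: int = 100_000
    pair_identity_min: float = 0.75
    pair_coverage_min: float = 0.75
    deg_p_max: float = 0.05
    deg_abs_log2fc_min: float = 1.0
    pcc_min: float = 0.95
    pcc_p_max: float = 0.05
    pcc_method: str = "pearson"
    enrich_p_max: float = 0.01
    enrich_fdr_max: float = 0.05
    min_chain: int = 3
    tandem_requires_adjacency: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise InputError("lambda_rate must be positive")
        for name in ("pair_identity_min", "pair_coverage_min", "pcc_min",
                     "deg_p_max", "pcc_p_max", "enrich_p_max", "enrich_fdr_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.promoter_len <= 0 or self.tandem_dist <= 0:
            raise InputError("promoter_len and tandem_dist must be positive")
        if self.pcc_method not in ("pearson", "spearman"):
            raise InputError("pcc_method must be 'pearson' or 'spearman'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a flat key=value config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise InputError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(key: str, val: str):
    if key == "pcc_method":
        return val
    if key == "tandem_requires_adjacency":
        return val.lower() in ("1", "true", "yes")
    if key in ("promoter_len", "tandem_dist", "rng_seed", "min_chain"):
        return int(val)
    return float(val)
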