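"""Run configuration for the pipeline presets.

A :class:`RunConfig` is a flat, validated bag of stage parameters; unknown
keys are rejected so typos fail loudly.  Every pipeline run writes the
resolved configuration as YAML next to its outputs, which together with the
seed makes runs byte-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    # simulation scale
    n_genes: int = 60
    reads_per_gene: float = 30.0
    read_length: int = 100
    n_replicates: int = 3
    error_rate: float = 1e-3
    # edit calling
    min_base_quality: int = 20
    min_coverage: int = 5
    call_error_rate: float = 1e-3
    min_confidence: float = 0.9
    # cluster calling
    bin_size: int = 30
    merge_gap: int = 15
    fdr: float = 0.1
    # translation
    epr_scale: float = 1.0
    cds_bias: float = 1.5
    min_reads: int = 10
    epr_fdr: float = 0.05
    # overlap testing
    n_perm: int = 200
    # classifier
    window_width: int = 200
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.resolved(), sort_keys=True, default_flow_style=False)
        )
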