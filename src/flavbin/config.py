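"""Pipeline configuration: every printed threshold of the protocol in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds of the binning/quality/variant/biogeography protocol.

    Defaults are the protocol's standard operating points: a 0.90 Pearson
    cutoff for cluster extraction, >3 kb scaffolds in the first binning
    pass and >5 kb in the second, >1.9 Mbp cumulative bin size, >10,000
    reads per bin, subdivision until duplication <10%, a <60% taxonomy
    vote for scaffold removal, >=85% shared genes for scaffold dedup,
    SNPs at >=4x coverage with >=2 mutated reads, CDS analysis above 7x,
    Q30 base-quality screening, dS saturation at 2.0, and 10,000
    permutations for abundance tests.
    """

    r_min: float = 0.90
    min_scaffold_bp_pass1: int = 3_000
    min_scaffold_bp_pass2: int = 5_000
    min_bin_bp: int = 1_900_000
    min_bin_reads: int = 10_000
    dup_max_pct: float = 10.0
    taxon_vote_min: float = 0.60
    target_phylum: str = "Bacteroidetes"
    dedup_min_shared: float = 0.85
    snp_min_cov: int = 4
    snp_min_alt: int = 2
    cds_min_cov: float = 7.0
    q_min: int = 30
    ds_saturation: float = 2.0
    permutations: int = 10_000
    rng_seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("rng_seed", "target_phylum"):
                continue
            if not isinstance(v, (int, float)) or v <= 0:
                raise ValueError(f"threshold {f.name} must be positive, got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
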