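"""Pipeline configuration shared by all stages.

Default thresholds follow the discovery pipeline for haploid megagametophyte
sequencing: minimum per-sample depth 5x, genotype quality 15, site mapping
quality 30, alternative-allele frequency 0.25 (the floor forced by four
haploid samples), 50 bp minimum inter-SNP spacing, base-quality trim
threshold 10, and a k-mer coverage band of [10, 40] with a 90% in-band
fraction for the low-copy read filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass
class PipelineConfig:
    """Thresholds and sizes used across the pipeline stages.

    Attributes
    ----------
    k : int
        k-mer length used by the low-copy read filter (odd).
    cov_band : tuple[int, int]
        Inclusive fold-coverage band ``[low, high]``; a k-mer whose pooled
        count falls inside the band is considered single/low copy.
    min_kmer_frac : float
        Minimum fraction of a read's k-mers that must fall inside
        ``cov_band`` for the read to be kept.
    min_depth : int
        Minimum per-sample depth for a variant call.
    min_gq : int
        Minimum per-sample genotype quality (phred).
    min_mq : int
        Minimum site mapping quality (phred, RMS over contributing reads).
    min_af : float
        Minimum alternative-allele frequency among called haploids.
    min_spacing : int
        Minimum spacing (bp) between retained SNPs on a contig.
    trim_q : int
        3' base-quality trimming threshold (phred).
    genome_size : int
        Haploid genome size in bp (used for coverage arithmetic).
    seed : int
        Seed for every stochastic stage.
    """

    k: int = 25
    cov_band: tuple[int, int] = (10, 40)
    min_kmer_frac: float = 0.9
    min_depth: int = 5
    min_gq: int = 15
    min_mq: int = 30
    min_af: float = 0.25
    min_spacing: int = 50
    trim_q: int = 10
    genome_size: int = 17_300_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.cov_band
        if not low < high:
            raise ConfigError(f"cov_band low must be < high, got {self.cov_band}")
        if not 0.0 < self.min_af <= 1.0:
            raise ConfigError(f"min_af must lie in (0, 1], got {self.min_af}")
        if not 0.0 <= self.min_kmer_frac <= 1.0:
            raise ConfigError(f"min_kmer_frac must lie in [0, 1], got {self.min_kmer_frac}")
        for name in ("k", "min_depth", "min_gq", "min_mq", "min_spacing", "trim_q", "genome_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "cov_band" in raw:
            raw["cov_band"] = tuple(raw["cov_band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cov_band"] = list(self.cov_band)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
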