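"""Pipeline configuration: every published filter constant in one place.

The defaults reproduce the thresholds of the original mining protocol:
alignment scoring (+1/-1, gap open 7, extend 1, score >= 30), region
merging (< 20 kb), contig-end exclusion (1 kb), soft-clip support (>= 3
reads of >= 7 clipped nt), clip-to-mtDNA identity (> 0.75) and E-value
(< 1e-4), breakpoint grouping (100 bp), the R1/R2 genotype ratios, the
30-bp minimum insertion length, the two-dataset replication rule and the
0.97 polymorphism threshold.  Overriding any of them is allowed but logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

log = logging.getLogger("numt_atlas")


@dataclass
class ScoringScheme:
    """Local-alignment scoring: match bonus and positive penalties."""

    match: int = 1
    mismatch: int = 1
    gap_open: int = 7
    gap_extend: int = 1
    min_score_threshold: int = 30

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class Thresholds:
    score: int = 30
    merge_gap: int = 20_000
    end_exclusion: int = 1_000
    clip_support: int = 3
    clip_length: int = 7
    clip_identity: float = 0.75
    clip_evalue: float = 1e-4
    group_window: int = 100
    r1_min: float = 0.75
    r2_absent: float = 0.30
    r2_hom: float = 0.80
    min_length: int = 30
    min_datasets: int = 2
    polymorphic: float = 0.97
    depth_min: float = 6.0
    depth_window: int = 200
    mismap: float = 1e-5
    synteny_fraction: float = 0.50
    mt_overlap_fraction: float = 0.40


@dataclass
class RateConfig:
    """Nuclear substitution rates (per site per year) used for Kimura dating."""

    mammalian: float = 2.2e-9
    ruminant: float = 2.48e-9
    pig_pedigree: float = 1.2e-9
    default: str = "mammalian"

    def __post_init__(self) -> None:
        for name in ("mammalian", "ruminant", "pig_pedigree"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be positive")

    @property
    def default_rate(self) -> float:
        return getattr(self, self.default)


@dataclass
class DivergenceTimes:
    """Divergence scaffold in Mya: within-genus, subfamily, family-level."""

    sus: float = 3.5
    suinae: float = 10.0
    bovid: float = 55.0
    pairs: dict = field(default_factory=dict)  # optional per-pair overrides


@dataclass
class PipelineConfig:
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: Thresholds = field(default_factory=Thresholds)
    rates: RateConfig = field(default_factory=RateConfig)
    divergence: DivergenceTimes = field(default_factory=DivergenceTimes)
    karlin_k: float = 0.1
    seed_k: int = 11
    xdrop: int = 20
    seed: int = 0
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "scoring",
                "thresholds",
                "rates",
                "divergence",
            ):
                sub_cls = {
                    "scoring": ScoringScheme,
                    "thresholds": Thresholds,
                    "rates": RateConfig,
                    "divergence": DivergenceTimes,
                }[f.name]
                kwargs[f.name] = sub_cls(**value)
            else:
                kwargs[f.name] = value
        cfg = cls(**kwargs)
        cfg._warn_overrides()
        return cfg

    def _warn_overrides(self) -> None:
        ref = type(self)()
        for group in ("scoring", "thresholds", "rates"):
            cur, base = getattr(self, group), getattr(ref, group)
            for f in dataclasses.fields(cur):
                if getattr(cur, f.name) != getattr(base, f.name):
                    log.warning(
                        "threshold override: %s.%s = %r (default %r)",
                        group, f.name, getattr(cur, f.name), getattr(base, f.name),
                    )

    def validate(self) -> list[str]:
        """Return a list of problems; empty means the config is usable."""
        problems = []
        t = self.thresholds
        if not (0 <= t.r2_absent <= t.r2_hom <= 1):
            problems.append("R2 bounds must satisfy 0 <= absent <= hom <= 1")
        if not (0 <= t.r1_min <= 1):
            problems.append("R1 threshold must be in [0, 1]")
        if not (0 < t.clip_identity < 1):
            problems.append("clip identity must be in (0, 1)")
        if t.min_length < 1 or t.min_datasets < 1:
            problems.append("min_length and min_datasets must be >= 1")
        if t.merge_gap < 0 or t.end_exclusion < 0:
            problems.append("merge_gap and end_exclusion must be >= 0")
        try:
            RateConfig(
                self.rates.mammalian, self.rates.ruminant, self.rates.pig_pedigree
            )
        except ValueError as exc:
            problems.append(str(exc))
        if self.divergence.sus <= 0 or self.divergence.suinae <= self.divergence.sus:
            problems.append("divergence times must be positive and ordered")
        return problems

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
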