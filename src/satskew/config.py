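"""Study-level configuration: consensus thresholds, likelihood-simulation
parameters and skew-analysis settings, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class ConsensusThresholds:
    """Multi-tube acceptance rules for fecal-DNA genotyping.

    A heterozygote needs the same allele pair in at least
    ``het_min_amplifications`` amplifications spread over at least
    ``het_min_samples`` independent samples; a homozygote needs
    ``hom_min_amplifications`` consistent amplifications.  When a third
    allele shows up, both counts are multiplied by
    ``third_allele_multiplier``.
    """

    het_min_amplifications: int = 4
    het_min_samples: int = 2
    hom_min_amplifications: int = 6
    third_allele_multiplier: int = 2

    def __post_init__(self) -> None:
        for name in (
            "het_min_amplifications",
            "het_min_samples",
            "hom_min_amplifications",
            "third_allele_multiplier",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class LikelihoodParams:
    """Simulation parameters for calibrating the LOD-gap (delta) criterion."""

    n_simulated_offspring: int = 100
    n_candidates: int = 56
    prop_candidates_sampled: float = 0.96
    prop_loci_typed: float = 0.99
    error_rate: float = 0.01
    min_typed_loci: int = 10
    confidence_level: float = 0.95
    relaxed_confidence_level: float = 0.80

    def __post_init__(self) -> None:
        for name in ("prop_candidates_sampled", "prop_loci_typed", "confidence_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.n_simulated_offspring < 1 or self.n_candidates < 1:
            raise ValueError("simulation counts must be positive")


@dataclass
class SkewParams:
    mc_replicates: int = 10_000
    ci_method: str = "bootstrap_multinomial"  # or "null_quantiles"
    sampling_coverage_min: float = 0.45

    def __post_init__(self) -> None:
        if self.mc_replicates < 1:
            raise ValueError("mc_replicates must be positive")
        if not 0.0 <= self.sampling_coverage_min <= 1.0:
            raise ValueError("sampling_coverage_min must lie in [0, 1]")
        if self.ci_method not in ("bootstrap_multinomial", "null_quantiles"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


@dataclass
class StudyConfig:
    consensus: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    likelihood: LikelihoodParams = field(default_factory=LikelihoodParams)
    skew: SkewParams = field(default_factory=SkewParams)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            consensus=ConsensusThresholds(**raw.get("consensus", {})),
            likelihood=LikelihoodParams(**raw.get("likelihood", {})),
            skew=SkewParams(**raw.get("skew", {})),
            rng_seed=int(raw.get("rng_seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
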