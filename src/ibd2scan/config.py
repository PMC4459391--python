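"""Parameter objects for simulation, IBD2 calling and variant prioritization.

All tunables used anywhere in the pipeline live in one of the dataclasses
below, so a run is fully described by (config, seed) and can be reproduced
from the config echo written next to every output bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .genome import HG19_AUTOSOME_LENGTHS


# Consequence terms counted as "predicted deleterious" by default: loss of
# function, in-frame indels, missense, and splice-site terms.  Intronic
# variants are additionally admitted when they lie within two bases of an
# exon boundary (see PrioritizationParams.max_splice_distance).
DEFAULT_DELETERIOUS_CONSEQUENCES: frozenset[str] = frozenset(
    {
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "stop_gained",
        "stop_lost",
        "missense_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

# Intronic / splice-region terms for which the distance-to-exon rule applies.
SPLICE_DISTANCE_CONSEQUENCES: frozenset[str] = frozenset(
    {"intron_variant", "splice_region_variant"}
)


@dataclass(frozen=True)
class AlleleFrequencyModel:
    """Population ALT-allele-frequency law for simulated sites.

    Frequencies are drawn from Beta(``alpha``, ``beta``); when ``fixed`` is
    set the law is degenerate and every site gets that frequency.
    """

    alpha: float = 0.8
    beta: float = 0.8
    fixed: float | None = None

    def __post_init__(self) -> None:
        if self.fixed is None:
            if self.alpha <= 0 or self.beta <= 0:
                raise ValueError("Beta parameters must be positive")
        elif not 0.0 <= self.fixed <= 1.0:
            raise ValueError("fixed allele frequency must lie in [0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.fixed is not None:
            return np.full(n, self.fixed)
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic family-exome generator.

    Defaults emulate a sibling-exome study design: biallelic SNVs at ~5.4 kb
    mean spacing, ~60x mean depth with capture overdispersion, Mendelian
    transmission at ~1 cM/Mb, and binomial allelic-count noise.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(HG19_AUTOSOME_LENGTHS)
    )
    variant_spacing_bp: float = 5400.0
    mean_depth: float = 60.0
    depth_dispersion: float = 8.0  # NB size; var = m + m^2/size
    base_error_rate: float = 0.005
    crossover_rate_per_bp: float = 1e-8
    n_children: int = 3
    allele_freq_distribution: AlleleFrequencyModel = field(
        default_factory=AlleleFrequencyModel
    )
    pass_rate: float = 0.97
    seed: int = 0
    plant_causal: bool = True
    causal_gene: str = "GENE_CAUSAL"
    max_plant_retries: int = 20
    artifact_fraction: float = 0.0  # fraction of sites tagged ARTIFACT in INFO

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if length < self.variant_spacing_bp:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one "
                    f"variant spacing unit ({self.variant_spacing_bp} bp)"
                )
        if self.variant_spacing_bp <= 0:
            raise ValueError("variant_spacing_bp must be positive")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if not 0.0 < self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must lie in (0, 0.5)")
        if self.crossover_rate_per_bp < 0:
            raise ValueError("crossover_rate_per_bp must be non-negative")
        if self.n_children < 1:
            raise ValueError("need at least one child")
        if not 0.0 < self.pass_rate <= 1.0:
            raise ValueError("pass_rate must lie in (0, 1]")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class IBDCallParams:
    """Windowed IBD2-calling rule.

    A run of ``window`` consecutive non-missing sites is an IBD2 candidate
    when its mean absolute allelic-ratio difference is below
    ``mean_threshold`` and fewer than ``max_spike_fraction`` of its sites
    exceed ``spike_cutoff``.  Candidate windows within ``merge_gap_bp`` are
    merged; merged regions failing the minimum size or supporting-site count
    are dropped.
    """

    window: int = 25
    mean_threshold: float = 0.06
    spike_cutoff: float = 0.35
    max_spike_fraction: float = 0.10
    merge_gap_bp: int = 1_000_000
    min_region_bp: int = 1_000_000
    min_sites: int = 50

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2 variants")
        for name in ("mean_threshold", "spike_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.max_spike_fraction <= 1.0:
            raise ValueError("max_spike_fraction must lie in (0, 1]")
        for name in ("merge_gap_bp", "min_region_bp", "min_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class PrioritizationParams:
    """Rare predicted-deleterious filter and segregation-model settings."""

    max_allele_freq: float = 0.01  # strict "<"
    deleterious_consequences: frozenset[str] = DEFAULT_DELETERIOUS_CONSEQUENCES
    max_splice_distance: int = 2  # intronic bases still counted as splice-site
    honor_database_flag: bool = True
    missing_af_is_rare: bool = True
    restrict_to_regions: bool = True
    min_parent_depth: int = 15  # depth needed to trust a parental hom-REF call

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_allele_freq <= 1.0:
            raise ValueError("max_allele_freq must lie in [0, 1]")
        if not self.deleterious_consequences:
            raise ValueError("deleterious consequence set must be non-empty")
        if self.max_splice_distance < 0:
            raise ValueError("max_splice_distance must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["deleterious_consequences"] = sorted(self.deleterious_consequences)
        return d
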