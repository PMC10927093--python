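"""Configuration models for the simulator and the pipeline.

All randomness in a run flows from one integer seed; every threshold the
analysis uses (internal-priming window, clustering window, TSI threshold,
FDR levels, DE fold cut-off) is a named key with its default documented.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["SimConfig", "CallPasConfig", "ApaConfig", "DeConfig",
           "PipelineConfig", "load_pipeline_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class SimConfig(BaseModel):
    """Study conditions for the synthetic 3'-end tag generator.

    The generator emulates tandem-3'UTR genes carrying 2-4 poly(A) sites,
    canonical AATAAA/ATTAAA hexamers 10-30 nt upstream of each cleavage
    site, negative-binomial tag totals allocated multinomially to sites,
    cleavage-site microheterogeneity (rounded-Normal jitter), library-size
    differences, condition-dependent proximal-usage shifts, and optional
    internal-priming artifact sites over genomic A-tracts.
    """

    n_genes: int = Field(200, ge=1)
    pas_per_gene: tuple[int, int] = (2, 4)
    utr_length_range: tuple[int, int] = (800, 2400)
    cds_length: int = Field(300, ge=60)
    hexamer_offset_range: tuple[int, int] = (10, 30)
    #: fraction of true sites given AATAAA; the rest get ATTAAA
    aataaa_fraction: float = Field(0.8, ge=0.0, le=1.0)
    #: fraction of true sites given a random non-canonical hexamer (default 0:
    #: all-canonical, for unambiguous recall testing)
    noncanonical_fraction: float = Field(0.0, ge=0.0, le=1.0)
    #: per-gene baseline usage over its k sites; None = uniform 1/k
    usage_baseline: Optional[list[float]] = None
    shift_delta: float = Field(0.3, ge=0.0, lt=1.0)
    #: per-sample multiplier on shift_delta; None = linear ramp 0 -> 1
    shift_profile: Optional[list[float]] = None
    n_shortened: int = Field(0, ge=0)
    n_lengthened: int = Field(0, ge=0)
    n_samples: int = Field(2, ge=1)
    depth_per_gene: float = Field(500.0, gt=0)
    dispersion: float = Field(0.1, ge=0.0)
    libsize_factors: Optional[list[float]] = None
    n_de_up: int = Field(0, ge=0)
    de_fold: float = Field(4.0, gt=0)
    ip_artifact_rate: float = Field(0.0, ge=0.0, le=1.0)
    ip_tract_length: int = Field(18, ge=15)
    ip_tag_fraction: float = Field(0.3, ge=0.0, le=1.0)
    cleavage_jitter_sd: float = Field(3.0, ge=0.0)
    min_pas_gap: int = Field(100, ge=50)
    intergenic_gap: int = Field(6000, ge=1000)
    genes_per_chrom: int = Field(50, ge=1)
    seed: int = 0

    @field_validator("pas_per_gene", "utr_length_range", "hexamer_offset_range")
    @classmethod
    def _ordered_range(cls, v):
        lo, hi = v
        if lo > hi or lo < 0:
            raise ValueError(f"range must be ordered and non-negative, got {v}")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "SimConfig":
        if self.hexamer_offset_range[0] < 6:
            raise ValueError("hexamer offset must be >= 6 so the motif fits upstream")
        if self.usage_baseline is not None:
            s = sum(self.usage_baseline)
            if abs(s - 1.0) > 1e-9 or any(p < 0 for p in self.usage_baseline):
                raise ValueError("usage_baseline must be a probability vector")
            k_lo, k_hi = self.pas_per_gene
            if not (k_lo == k_hi == len(self.usage_baseline)):
                raise ValueError("explicit usage_baseline requires fixed pas_per_gene "
                                 "of matching length")
        if self.shift_profile is not None and len(self.shift_profile) != self.n_samples:
            raise ValueError("shift_profile length must equal n_samples")
        if self.libsize_factors is not None and len(self.libsize_factors) != self.n_samples:
            raise ValueError("libsize_factors length must equal n_samples")
        if self.n_shortened + self.n_lengthened + self.n_de_up > 3 * self.n_genes:
            raise ValueError("more perturbed genes than genes")
        if self.n_shortened + self.n_lengthened > self.n_genes:
            raise ValueError("more shifted genes than genes")
        # the shifted proximal probability must remain a valid probability
        base_prox = (self.usage_baseline[0] if self.usage_baseline
                     else 1.0 / self.pas_per_gene[0])
        if self.n_shortened and base_prox + self.shift_delta > 1.0 + 1e-12:
            raise ValueError("shift_delta pushes proximal usage above 1")
        if self.n_lengthened and base_prox - self.shift_delta < -1e-12:
            raise ValueError("shift_delta pushes proximal usage below 0")
        if self.utr_length_range[0] < self.min_pas_gap * self.pas_per_gene[1]:
            raise ValueError("UTRs too short for the requested number of spaced PASs")
        return self

    @property
    def sample_names(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]

    def resolved_shift_profile(self) -> list[float]:
        if self.shift_profile is not None:
            return list(self.shift_profile)
        if self.n_samples == 1:
            return [0.0]
        return [i / (self.n_samples - 1) for i in range(self.n_samples)]

    def resolved_libsize(self) -> list[float]:
        return list(self.libsize_factors) if self.libsize_factors else [1.0] * self.n_samples


class CallPasConfig(BaseModel):
    """Poly(A)-site calling parameters."""

    #: single-linkage clustering window (nt): adjacent cleavage coordinates
    #: with a gap <= window share a cluster
    window: int = Field(24, ge=1)
    #: minimum pooled (all-sample) tag count for a cluster to be retained
    min_count: int = Field(5, ge=1)
    #: internal-priming filter: flag if >= max_run consecutive A in the 20-nt
    #: downstream window, or >= max_in_10 As within any 10-nt sub-window
    ip_max_run: int = Field(6, ge=1)
    ip_max_in_10: int = Field(7, ge=1)
    ip_window: int = Field(20, ge=10)
    #: hexamer scan window (nt upstream of the representative site)
    hexamer_scan: tuple[int, int] = (10, 40)
    #: how far past the annotated distal end a cluster still belongs to the
    #: gene ("extended/downstream" class)
    extension_bp: int = Field(4000, ge=0)


class ApaConfig(BaseModel):
    """APA-switching test parameters."""

    tsi_threshold: float = Field(0.1, gt=0.0, le=1.0)
    fdr: float = Field(0.01, gt=0.0, lt=1.0)


class DeConfig(BaseModel):
    """3'-end differential-expression test parameters."""

    fold: float = Field(3.0, gt=0.0)
    fdr: float = Field(0.01, gt=0.0, lt=1.0)
    pseudocount_cpm: float = Field(0.5, ge=0.0)
    control: Optional[str] = None
    treatment: Optional[str] = None


class PipelineConfig(BaseModel):
    """Schema for the single YAML config behind the `apakit` CLI."""

    schema_version: int = 1
    seed: int = 0
    outdir: str = "results/run"
    simulate: Optional[SimConfig] = None
    #: required when `simulate` is absent: paths to existing inputs
    genome_fasta: Optional[str] = None
    annotation: Optional[str] = None
    annotation_dialect: str = "bed12"
    tags: Optional[dict[str, str]] = None  # sample id -> BED6 path
    mirna_tsv: Optional[str] = None
    callpas: CallPasConfig = CallPasConfig()
    apa: ApaConfig = ApaConfig()
    de: DeConfig = DeConfig()
    #: contrasts for target-set logic: [[A, B], [B, C]] sample-name pairs
    contrasts: Optional[list[list[str]]] = None

    @model_validator(mode="after")
    def _inputs_present(self) -> "PipelineConfig":
        if self.simulate is None:
            missing = [k for k in ("genome_fasta", "annotation", "tags")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    "without a `simulate` section these fields are required: "
                    + ", ".join(missing))
        return self


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline config, reporting field-level errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
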