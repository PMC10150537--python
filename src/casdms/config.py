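"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScreenConfig(_Strict):
    """Survival-screen simulation parameters."""

    n_codons: int = Field(300, ge=1)
    frac_beneficial: float = Field(0.10, ge=0, le=1)
    frac_deleterious: float = Field(0.15, ge=0, le=1)
    frac_null: float = Field(0.05, ge=0, le=1)
    effect_scale: float = Field(2.0, gt=0)
    n_rounds: int = Field(4, ge=1)
    sequenced_rounds: tuple[int, ...] = (3, 4)
    n_replicates: int = Field(3, ge=1)
    depth: int = Field(1_000_000, ge=0)
    bottleneck: int | None = None


class EnrichConfig(_Strict):
    pseudocount: float = Field(0.5, ge=0)
    min_count: int = Field(50, ge=0)
    level: str = "aa"
    pre_round: int = 3
    post_round: int = 4
    min_syn_anchors: int = Field(10, ge=1)


class SpecseqConfig(_Strict):
    target_seq: str = "TTTACCCAGTAGCTGACGTCAATG"  # TTTA PAM + 20-nt protospacer
    k_max: int = Field(2, ge=0)
    mode: str = "exhaustive"
    quota_per_k: int | None = None
    depth: int = Field(1_000_000, ge=0)
    mu: float = 0.0
    cleavage_rate_scale: float = Field(1.0, gt=0)


class PlantsConfig(_Strict):
    n_plants: int = Field(120, ge=1)
    profile: dict[str, float] | None = None
    chimeric_noise: float = Field(0.0, ge=0, le=1)
    depth: int = Field(2000, ge=0)


class GenotypeConfig(_Strict):
    min_depth: int = 100
    major_allele: float = 0.35
    wt_call: float = 0.95
    homozygous_allele: float = 0.90
    wt_absent: float = 0.05
    mono_wt_low: float = 0.35
    mono_wt_high: float = 0.65


class RunConfig(_Strict):
    """Top-level pipeline configuration; one seed, forked per stage."""

    schema_version: int = 1
    seed: int = 0
    screen: ScreenConfig = ScreenConfig()
    enrich: EnrichConfig = EnrichConfig()
    specseq: SpecseqConfig = SpecseqConfig()
    plants: PlantsConfig = PlantsConfig()
    genotype: GenotypeConfig = GenotypeConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
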