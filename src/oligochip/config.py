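"""Pipeline configuration: one plain-text YAML artifact, per-module
sections, strict key validation, stable hashing for manifests."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PreclusterConfig:
    min_identity: float = 90.0
    min_length: int = 30
    mask_window: int = 16
    mask_entropy_threshold: float = 1.2
    mask_dinucleotide: bool = False


@dataclass(frozen=True)
class DesignConfig:
    tm_target: float = 67.0
    tm_tol: float = 3.0
    length_target: int = 65
    length_tol: int = 5
    gc_target: float = 43.0
    gc_tol: float = 5.0
    max_dist_3prime: int = 1000
    max_stem: int = 8
    max_selfdimer: int = 12
    min_loop: int = 3
    na_mM: float = 25.0
    oligo_nM: float = 50.0


@dataclass(frozen=True)
class ScreenConfig:
    id_threshold: float = 70.0
    lcs_threshold: int = 20


@dataclass(frozen=True)
class QCConfig:
    sd_multiplier: float = 2.0
    filter_percentile: float = 90.0
    present_k: int = 5
    present_n: int = 6
    expression_combine: str = "per_channel"


@dataclass(frozen=True)
class NormalizeConfig:
    span: float = 0.4
    iterations: int = 2


@dataclass(frozen=True)
class DEConfig:
    n_permutations: int = 200
    alpha: float = 0.01
    s0_percentile: float = 5.0


@dataclass(frozen=True)
class PowerConfig:
    n_per_group: int = 6
    alpha: float = 0.10
    target_power: float = 0.90
    noise_model: str = "lognormal"


@dataclass(frozen=True)
class QPCRConfig:
    convention: str = "standard_negative_exponent"
    base: float = 2.0


@dataclass(frozen=True)
class FixtureConfig:
    n_unigenes: int = 30
    n_spots: int = 200
    n_negative_controls: int = 30
    n_de_genes: int = 20
    de_log2_fold: float = 1.0
    dye_bias_amplitude: float = 0.0
    m_noise_sd: float = 0.3


@dataclass(frozen=True)
class PipelineConfig:
    """Toplevel configuration; a fully-defaulted config is valid."""

    seed: int = 0
    input_fasta: str | None = None
    slide_dir: str | None = None
    output_dir: str = "oligochip_out"
    precluster: PreclusterConfig = field(default_factory=PreclusterConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    de: DEConfig = field(default_factory=DEConfig)
    power: PowerConfig = field(default_factory=PowerConfig)
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


_SECTIONS = {
    "precluster": PreclusterConfig,
    "design": DesignConfig,
    "screen": ScreenConfig,
    "qc": QCConfig,
    "normalize": NormalizeConfig,
    "de": DEConfig,
    "power": PowerConfig,
    "qpcr": QPCRConfig,
    "fixtures": FixtureConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown toplevel key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value or {}, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]
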