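"""Pipeline configuration with a stable identifying hash.

Every numeric output of the pipeline embeds the hash of the configuration
that produced it, so features computed under different settings (band
edges, complexity flags, channel format) can never be silently mixed —
the classifier refuses feature tables whose hash differs from its
training hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class PreprocessingConfig:
    band: tuple = (1.0, 30.0)
    epoch_length_s: float | None = 20.0
    target_fs: float | None = None


@dataclasses.dataclass
class ClusteringConfig:
    k: int = 4                 # fixed class count; used when select_k is False
    select_k: bool = False     # choose k per subject by the KL criterion
    k_range: tuple = (2, 8)
    n_init: int = 20
    gfp_peaks_only: bool = True
    min_duration_ms: float = 0.0
    seed: int = 11


@dataclasses.dataclass
class ComplexityConfig:
    collapse_runs: bool = True
    normalize: bool = False


@dataclasses.dataclass
class SpectralConfig:
    theta: tuple = (4.0, 8.0)
    total: tuple = (1.0, 30.0)


@dataclasses.dataclass
class ClassifierConfig:
    kernel: str = "rbf"
    C: float = 1.0
    folds: int = 10
    positive: str = "AD"
    seed: int = 17


@dataclasses.dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = dataclasses.field(default_factory=PreprocessingConfig)
    clustering: ClusteringConfig = dataclasses.field(default_factory=ClusteringConfig)
    complexity: ComplexityConfig = dataclasses.field(default_factory=ComplexityConfig)
    spectral: SpectralConfig = dataclasses.field(default_factory=SpectralConfig)
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            return obj

        return {f.name: convert(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "preprocessing": PreprocessingConfig,
            "clustering": ClusteringConfig,
            "complexity": ComplexityConfig,
            "spectral": SpectralConfig,
            "classifier": ClassifierConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            section = dict(data.get(name, {}))
            fields = {f.name: f for f in dataclasses.fields(klass)}
            clean = {}
            for key, value in section.items():
                if key not in fields:
                    raise KeyError(f"unknown config key {name}.{key}")
                if isinstance(value, list):
                    value = tuple(value)
                clean[key] = value
            kwargs[name] = klass(**clean)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
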