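"""Run configuration: analysis thresholds and reproducibility settings.

The defaults encode the filtering rules of the study design this package
implements: differential expression requires BH-adjusted p < 0.05 and
|log2 fold change| >= 1; the 10% most variable genes enter the PCA; genes are
ranked by their contribution to the selected component (component 2 by
default) and the top 20% are retained; a core gene counts as replicated when
it appears in at least 3 external studies.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and settings shared across pipeline stages.

    Parameters
    ----------
    fdr_max
        BH-adjusted p-value ceiling for calling a gene (or exon) significant.
    lfc_min
        Minimum absolute log2 fold change for the DE flag.
    variance_fraction
        Fraction of genes, ranked by log-expression variance, kept as PCA input.
    loading_fraction
        Fraction of PCA-input genes, ranked by squared loading on the
        selection component, kept in the PCA selection.
    selection_component
        1-based principal component used for loading-based selection.
    replication_threshold
        Minimum number of external studies containing a gene for the
        "replicated" class.
    min_mean_count
        Genes with mean normalized count below this are not tested for DE.
    seed
        Seed for every stochastic step of a run.
    """

    fdr_max: float = 0.05
    lfc_min: float = 1.0
    variance_fraction: float = 0.10
    loading_fraction: float = 0.20
    selection_component: int = 2
    replication_threshold: int = 3
    min_mean_count: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_fraction <= 1.0):
            raise ConfigError(f"variance_fraction must be in (0, 1], got {self.variance_fraction}")
        if not (0.0 < self.loading_fraction <= 1.0):
            raise ConfigError(f"loading_fraction must be in (0, 1], got {self.loading_fraction}")
        if self.fdr_max <= 0 or self.lfc_min <= 0:
            raise ConfigError("fdr_max and lfc_min must be positive")
        if self.selection_component < 1:
            raise ConfigError("selection_component must be >= 1")
        if self.replication_threshold < 1:
            raise ConfigError("replication_threshold must be >= 1")
        if self.min_mean_count < 0:
            raise ConfigError("min_mean_count must be non-negative")

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields replaced (CLI flags win)."""
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key–value (YAML) config file into a :class:`RunConfig`.

    Unknown keys are rejected so that typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # wrong value type
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a config, recorded in output provenance lines."""
    text = ";".join(f"{k}={v}" for k, v in sorted(cfg.to_dict().items()))
    return hashlib.sha1(text.encode()).hexdigest()[:12]
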