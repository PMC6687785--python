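"""Pipeline configuration with YAML loading and strict validation."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds and seeds for the full analysis.

    Defaults are the pipeline's standard operating point: one-sided
    purity filter at R <= -0.4 with FDR < 0.01, tumor-vs-cell-line DE at
    |LFC| > 2 with FDR < 0.01, template genes at LFC > 1 with FDR < 0.01,
    5000 variable genes, nearest-template assignment at FDR <= 0.05, an
    80% test-accuracy gate, and 5 cell lines per tumor type in panels.
    """

    purity_r_cutoff: float = -0.4
    purity_fdr_cutoff: float = 0.01
    purity_filter_mode: str = "negative"
    de_lfc_cutoff: float = 2.0
    de_fdr_cutoff: float = 0.01
    template_lfc_cutoff: float = 1.0
    template_fdr_cutoff: float = 0.01
    n_variable_genes: int = 5000
    ntp_fdr_cutoff: float = 0.05
    accuracy_gate: float = 0.80
    panel_size: int = 5
    train_frac: float = 0.8
    n_resample: int = 1000
    n_perm: int = 1000
    pseudocount: float = 1.0
    voom_span: float = 0.5
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.purity_r_cutoff <= 1.0:
            raise ValueError("purity_r_cutoff must lie in [-1, 1]")
        for name in ("purity_fdr_cutoff", "de_fdr_cutoff", "template_fdr_cutoff",
                     "ntp_fdr_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.purity_filter_mode not in ("negative", "two_sided"):
            raise ValueError("purity_filter_mode must be 'negative' or 'two_sided'")
        if self.de_lfc_cutoff < 0 or self.template_lfc_cutoff < 0:
            raise ValueError("LFC cutoffs must be non-negative")
        if self.n_variable_genes < 1:
            raise ValueError("n_variable_genes must be >= 1")
        if not 0.0 <= self.accuracy_gate <= 1.0:
            raise ValueError("accuracy_gate must lie in [0, 1]")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.n_resample < 1 or self.n_perm < 1:
            raise ValueError("resampling counts must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a YAML config; unknown keys are errors (typo protection)."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys {unknown}; known keys: {sorted(known)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
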