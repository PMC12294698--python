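"""Pipeline configuration: every stage threshold with its literature
default, YAML round-tripping, and schema validation before any compute."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .synth import SynthConfig


@dataclass
class PipelineConfig:
    """Stage thresholds. Defaults are the published operating points:
    250 kb candidate window with r > 0.4 for CRE links, FDR <= 0.05 and
    log2FC >= 0.57 for marker peaks, 500 kb SE windows at p_cutoff 0.05,
    SE specificity tau > 0.7 with normalized accessibility > 0.5, target
    correlation > 0.3, TF expression correlation > 0.5, LS > 10, Cox
    p < 0.05, 100 pseudotime bins."""

    seed: int = 0
    window_bp: int = 250_000
    cor_cutoff: float = 0.4
    fdr: float = 0.05
    log2fc: float = 0.57
    super_range: int = 500_000
    p_cutoff: float = 0.05
    tau_cut: float = 0.7
    acc_cut: float = 0.5
    target_r_cut: float = 0.3
    tf_r_cut: float = 0.5
    ls_cut: float = 10.0
    cox_p: float = 0.05
    n_bins: int = 100
    # synthetic-scale structural settings
    k_agg: int = 20
    n_agg: int = 50
    n_accessons: int = 10
    n_background: int = 50
    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    focal_type: str | None = None  # default: last cell type (trajectory end)
    # per-cell QC rules (published defaults)
    qc_min_genes: int = 200
    qc_max_mito: float = 0.20
    qc_min_fragments: int = 1000
    qc_min_tss: float = 4.0

    def validate(self) -> None:
        if not (-1.0 <= self.cor_cutoff <= 1.0):
            raise ValueError(f"cor_cutoff must lie in [-1, 1], got {self.cor_cutoff}")
        for name in ("fdr", "p_cutoff", "cox_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("tau_cut", "acc_cut"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (-1.0 <= self.target_r_cut <= 1.0):
            raise ValueError("target_r_cut must lie in [-1, 1]")
        if not (-1.0 <= self.tf_r_cut <= 1.0):
            raise ValueError("tf_r_cut must lie in [-1, 1]")
        for name in ("window_bp", "super_range", "n_bins", "k_agg", "n_agg",
                     "n_accessons", "n_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _from_dict(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    obj = cls(**d)
    obj.validate()
    return obj


def load_config(path: Path) -> tuple[PipelineConfig, SynthConfig]:
    """Read a YAML config with optional ``pipeline:`` and ``synth:``
    sections; validation errors are raised before any compute."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pcfg = _from_dict(PipelineConfig, raw.get("pipeline", {}))
    sdict = dict(raw.get("synth", {}))
    if "genome" in sdict:
        sdict["genome"] = tuple((str(c), int(n)) for c, n in sdict["genome"])
    scfg = SynthConfig(**sdict)
    scfg.validate()
    return pcfg, scfg


def save_config(pcfg: PipelineConfig, scfg: SynthConfig, path: Path) -> None:
    sdict = asdict(scfg)
    sdict["genome"] = [list(g) for g in sdict["genome"]]
    Path(path).write_text(yaml.safe_dump(
        {"pipeline": pcfg.to_dict(), "synth": sdict}, sort_keys=True))
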