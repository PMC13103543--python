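"""Pipeline configuration.

Defaults reproduce the reference analysis: 22-TR windows (44 s at TR = 2 s)
advanced by 1 TR, k = 3 connectivity states fitted with 500 random
initializations of up to 500 Lloyd iterations, BH-FDR at alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    window_length_tr: int = 22
    step_tr: int = 1
    k: int | str = 3  # integer, or "auto" to pick via the elbow criterion
    k_range: tuple[int, int] = (1, 8)
    replicates: int = 500
    max_iter: int = 500
    seed: int = 0
    fisher_epsilon: float = 1e-7
    fdr_alpha: float = 0.05
    tr_seconds: float = 2.0
    harmonize: bool = True
    # "window": each windowed edge-vector is one ComBat observation carrying
    # its subject's site; "subject": subjects' window-mean vectors are the
    # observations and the fitted adjustment is broadcast to their windows.
    harmonize_level: str = "window"
    # "across_edges": exemplar signal is the variance over the E edge values
    # within each window; "per_edge_time": per-edge temporal variance summed
    # over edges, maxima over the resulting series.
    exemplar_variance: str = "across_edges"
    node_subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_length_tr < 2:
            raise ValueError("window_length_tr must be >= 2")
        if self.step_tr < 1:
            raise ValueError("step_tr must be >= 1")
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError("k must be a positive integer or 'auto'")
        elif self.k < 1:
            raise ValueError("k must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.fisher_epsilon <= 1e-3):
            raise ValueError("fisher_epsilon must lie in (0, 1e-3]")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.harmonize_level not in ("window", "subject"):
            raise ValueError("harmonize_level must be 'window' or 'subject'")
        if self.exemplar_variance not in ("across_edges", "per_edge_time"):
            raise ValueError(
                "exemplar_variance must be 'across_edges' or 'per_edge_time'"
            )
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]
        if len(self.k_range) != 2 or self.k_range[0] < 1 or self.k_range[0] > self.k_range[1]:
            raise ValueError("k_range must be (lo, hi) with 1 <= lo <= hi")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value file whose keys mirror the config fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return path
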