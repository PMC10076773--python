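"""Pipeline configuration with the published operating constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Tunable constants of the incident-lacune pipeline.

    Defaults encode the standard operating point: a two-class K-means
    threshold on the difference map, the STRIVE lacune diameter bounds of
    3–15 mm, 3x3x3-box dilations for every neighborhood notion, and
    26-connectivity for clusters.
    """

    k_classes: int = 2
    diameter_min_mm: float = 3.0
    diameter_max_mm: float = 15.0
    dilation_kernel_shape: tuple[int, int, int] = (3, 3, 3)
    kmeans_seed: int = 0
    connectivity: int = 26
    include_ventricle_margin: bool = True
    tissue_classes: int = 3  # K-means tiers for the CSF segmentation

    def __post_init__(self) -> None:
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if not (0 < self.diameter_min_mm < self.diameter_max_mm):
            raise ValueError("need 0 < diameter_min_mm < diameter_max_mm")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        self.dilation_kernel_shape = tuple(int(k) for k in self.dilation_kernel_shape)

    @property
    def dilation_kernel(self):
        import numpy as np

        return np.ones(self.dilation_kernel_shape, dtype=bool)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "dilation_kernel_shape" in raw:
        raw["dilation_kernel_shape"] = tuple(raw["dilation_kernel_shape"])
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["dilation_kernel_shape"] = list(data["dilation_kernel_shape"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
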