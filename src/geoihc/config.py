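"""Analysis configuration, loadable from YAML.

Defaults follow the standardized study design: 0.502 µm/pixel ROIs of
3426 x 1379 pixels, search radii 25 and 125 µm with downstream analysis at
25 µm, a 10-cell eligibility threshold, any-stain positivity for densities
with strong-only positivity for spatial analysis, and a 10% minimum group
share for admissible survival cut-points.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .types import DEFAULT_PIXEL_SIZE, DEFAULT_WINDOW_PX


@dataclass
class AnalysisConfig:
    pixel_size: float = DEFAULT_PIXEL_SIZE
    window_px: tuple[float, float] = DEFAULT_WINDOW_PX
    radii: tuple[float, ...] = (25.0, 125.0)
    analysis_radius: float = 25.0
    min_cells: int = 10
    positivity_rule: str = "any_stain"       # density / percent positivity
    spatial_rule: str = "strong_only"        # positivity for point patterns
    min_prop: float = 0.1
    cutpoint_policy: str = "per_endpoint"    # or "os"
    fdr_scope: str = "within_endpoint"       # or "global"
    responder_pfs_gt: float = 9.0
    resistant_pfs_lt: float = 6.0

    def __post_init__(self) -> None:
        if self.analysis_radius not in self.radii:
            raise ValueError("analysis_radius must be one of the configured radii")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_px"] = list(self.window_px)
        d["radii"] = list(self.radii)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_px", "radii"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
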