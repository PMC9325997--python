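"""Pipeline configuration: defaults reproduce the canonical parameters.

Defaults — CLAHE clip limit 12.0 on a 10x10 tile grid, median filter of
size 4, three retained components — are the published operating point of
the workflow; change them only deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Literal

import yaml

from .exceptions import ParameterError
from .preprocess import DEFAULT_CLIP_LIMIT, DEFAULT_MEDIAN_SIZE, DEFAULT_TILE_GRID, ClaheParams


@dataclass
class PipelineConfig:
    branch: Literal["std", "clahe", "both"] = "both"
    clip_limit: float = DEFAULT_CLIP_LIMIT
    tile_grid: tuple[int, int] = DEFAULT_TILE_GRID
    median_size: int = DEFAULT_MEDIAN_SIZE
    n_components: int = 3
    save_intermediates: bool = False
    seed: int = 0  # used by the phantom subcommand only
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.branch not in ("std", "clahe", "both"):
            raise ParameterError(f"branch must be std|clahe|both, got {self.branch!r}")
        if self.median_size < 1:
            raise ParameterError(f"median_size must be >= 1, got {self.median_size}")
        if self.n_components < 1:
            raise ParameterError(f"n_components must be >= 1, got {self.n_components}")
        self.tile_grid = (int(self.tile_grid[0]), int(self.tile_grid[1]))
        self.output_dir = Path(self.output_dir)

    @property
    def branches(self) -> list[str]:
        return ["std", "clahe"] if self.branch == "both" else [self.branch]

    @property
    def clahe_params(self) -> ClaheParams:
        return ClaheParams(clip_limit=self.clip_limit, tile_grid=self.tile_grid)

    def echo(self) -> dict:
        """JSON-serializable parameter record for provenance reports."""
        return {
            "branch": self.branch,
            "clip_limit": self.clip_limit,
            "tile_grid": list(self.tile_grid),
            "median_size": self.median_size,
            "n_components": self.n_components,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file, with keyword (CLI-flag) values taking precedence."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "tile_grid" in raw:
            raw["tile_grid"] = tuple(raw["tile_grid"])
        return cls(**raw)
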