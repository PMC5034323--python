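"""Run configuration: one serializable record of every tunable parameter.

A run's effective configuration is written next to its outputs so that
config + inputs fully determine the result.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import DEFAULT_EXCLUSION_MIN_FRACTION, DEFAULT_ROLLING_BALL_RADIUS
from .segment import DEFAULT_CLOSE_RADIUS_UM, DEFAULT_MIN_AREA_UM2
from .celltype import DEFAULT_NUCLEUS_DIAMETER_UM
from .stereology import DEFAULT_GRID_SPACING_UM
from .analytics import DEFAULT_BIN_WIDTH, SINGLE_CELL_AREA_UM2

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # inputs
    image_path: str = ""
    contours_path: str = ""
    channel_map: dict = field(default_factory=dict)   # role -> page index or path
    pixel_size: float = 1.0
    output_dir: str = "isletquant_out"
    # preprocessing
    background_subtraction: bool = True
    rolling_ball_radius_px: int = DEFAULT_ROLLING_BALL_RADIUS
    thresholds: dict = field(default_factory=dict)    # channel -> value; empty = auto
    exclusion_min_fraction: float = DEFAULT_EXCLUSION_MIN_FRACTION
    # islet segmentation
    close_radius_um: float = DEFAULT_CLOSE_RADIUS_UM
    min_islet_area_um2: float = DEFAULT_MIN_AREA_UM2
    # cell typing
    ring_width_px: int = 1
    expected_nucleus_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM
    hormone_priority: list = field(default_factory=list)  # tie-break order
    # analytics
    bin_width_log10: float = DEFAULT_BIN_WIDTH
    single_cell_area_um2: float = SINGLE_CELL_AREA_UM2
    pp_channel: str = "pp"
    min_pp_cells: int = 1
    # stereology
    grid_spacing_um: float = DEFAULT_GRID_SPACING_UM
    panel_size_um: list = field(default_factory=lambda: [868.0, 662.0])
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.channel_map:
            roles = list(self.channel_map)
            if roles.count("nuclei") != 1:
                raise ValueError("channel_map must name exactly one 'nuclei' channel")
            if not 1 <= len(roles) - 1 <= 3:
                raise ValueError("channel_map must name 1-3 hormone channels")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
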