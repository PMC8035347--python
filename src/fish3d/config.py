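"""Run configuration shared by every pipeline stage.

All physical defaults are the acquisition and scoring constants of the
break-apart FISH assay this package targets: 0.16 μm/pixel in XY, 0.6 μm
z interval, 0.6 μm gene-signal spot diameter, a 1.2 μm 3D break-apart
cutoff (twice or more the spot diameter) and a 10% abnormal-fraction
rule for the negative diagnosis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

MATCH_METHODS = ("SD", "NSD", "C", "NC", "CC", "NcC")

#: canonical channel order: nuclear counterstain, green probe, red probe
DEFAULT_CHANNELS = ("DAPI", "FITC", "TRITC")

PAGE_ORDERS = ("layer_major", "channel_major")


@dataclass
class RunConfig:
    """Parameters of one scoring run.

    Lengths are in μm unless the name says pixels. ``abnormal_fraction_cutoff``
    is a percentage of counted nuclei: a case is negative when the break-apart
    ratio is at or below it.
    """

    # calibration (used when TIFF metadata is absent; wins on conflict)
    pixel_size_xy: float = 0.16
    z_interval: float = 0.6
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    page_order: str = "layer_major"

    # scoring constants
    spot_diameter_um: float = 0.6
    breakapart_cutoff_um: float = 1.2
    abnormal_fraction_cutoff: float = 10.0
    abnormal_includes_other: bool = False

    # preprocessing
    gaussian_sigma: float = 1.0
    morphology_shape: str = "disk"
    morphology_radius: int = 2

    # segmentation
    match_method: str = "NcC"
    match_threshold: float = 0.6
    nms_overlap: float = 0.3
    link_overlap: float = 0.5
    min_component_size: int | None = None  # None -> disk of radius 2 μm
    nucleus_volume_bounds: tuple[float, float] | None = None  # voxels, (lo, hi)
    template_radii_um: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    template_aspects: tuple[float, ...] = (1.0, 1.3)
    template_orientation_step_deg: float = 30.0
    template_dir: str | None = None

    # spot detection
    intensity_floor_k: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_diameter_um <= 0 or self.breakapart_cutoff_um <= 0:
            raise ValueError("spot diameter and break-apart cutoff must be > 0")
        if self.pixel_size_xy <= 0 or self.z_interval <= 0:
            raise ValueError("pixel_size_xy and z_interval must be > 0")
        if not 0.0 <= self.abnormal_fraction_cutoff <= 100.0:
            raise ValueError("abnormal_fraction_cutoff must lie in [0, 100]")
        if self.match_method not in MATCH_METHODS:
            raise ValueError(
                f"match_method must be one of {MATCH_METHODS}, got {self.match_method!r}"
            )
        if self.page_order not in PAGE_ORDERS:
            raise ValueError(f"page_order must be one of {PAGE_ORDERS}")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        self.channel_names = tuple(self.channel_names)
        self.template_radii_um = tuple(self.template_radii_um)
        self.template_aspects = tuple(self.template_aspects)
        if self.nucleus_volume_bounds is not None:
            self.nucleus_volume_bounds = tuple(self.nucleus_volume_bounds)

    def min_size_px(self) -> int:
        """Minimum in-plane component area in pixels.

        Defaults to the area of a 2 μm-radius disk at the configured pixel
        size; components smaller than this are treated as isolated vertices
        and erased.
        """
        if self.min_component_size is not None:
            return int(self.min_component_size)
        return int(round(np.pi * (2.0 / self.pixel_size_xy) ** 2))

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_names"] = list(self.channel_names)
        d["template_radii_um"] = list(self.template_radii_um)
        d["template_aspects"] = list(self.template_aspects)
        if self.nucleus_volume_bounds is not None:
            d["nucleus_volume_bounds"] = list(self.nucleus_volume_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a RunConfig from a YAML or JSON file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path
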