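"""Image containers and TIFF I/O.

A nucleus is acquired as one 3D stack per fluorescence channel (DAPI
counterstain, Cy3 telomere probe, optional FITC/CD34 immunostain).  Stacks are
stored as plain multi-page TIFF with a JSON sidecar carrying the physical
voxel spacing, which the quantification steps need to work in nanometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("DAPI", "Cy3", "FITC")


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical sampling distance of the stack, in nanometres.

    Defaults follow a typical widefield 3D acquisition: 102 nm laterally and
    200 nm between optical sections.
    """

    dx: float = 102.0
    dy: float = 102.0
    dz: float = 200.0

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def zyx(self) -> np.ndarray:
        """Spacing as a (dz, dy, dx) array, matching stack axis order."""
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz * 1e-9


@dataclass
class ImageStack3D:
    """A single-channel 3D voxel grid with physical spacing.

    Axis order is (z, y, x); intensities are non-negative arbitrary units.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    channel: str = "Cy3"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.voxels.shape}")
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("stack intensities must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a ``.json`` spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels)
    sidecar = {
        "channel": stack.channel,
        "dx_nm": stack.spacing.dx,
        "dy_nm": stack.spacing.dy,
        "dz_nm": stack.spacing.dz,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path: str | Path) -> ImageStack3D:
    """Read a TIFF written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing spacing sidecar for {path}")
    meta = json.loads(sidecar_path.read_text())
    spacing = VoxelSpacing(dx=meta["dx_nm"], dy=meta["dy_nm"], dz=meta["dz_nm"])
    return ImageStack3D(tifffile.imread(path), spacing=spacing, channel=meta["channel"])
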