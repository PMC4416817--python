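"""Multichannel 3-D image stacks with physical voxel dimensions.

The in-memory container used throughout the package. Axis order is
``(z, y, x)`` everywhere; voxel dimensions are given in nanometres as
``(dz, dy, dx)`` to match. Super-resolution reconstructions are strongly
anisotropic (default 125 nm axially vs 39.5 nm laterally), so every
physical distance in the package is computed with per-axis scaling rather
than in voxel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import tifffile

from .errors import InputError

#: Default voxel dimensions (dz, dy, dx) in nm of the reconstructed stacks.
DEFAULT_VOXEL_DIMS: Tuple[float, float, float] = (125.0, 39.5, 39.5)

#: Conventional channel names.
DAPI, LAMIN, NUP = "DAPI", "laminB", "NUP153"


@dataclass
class ImageStack:
    """Named 3-D intensity grids sharing a shape and voxel geometry.

    Parameters
    ----------
    channels
        Mapping channel name -> float array of shape ``(z, y, x)``.
    voxel_dims
        Physical voxel size ``(dz, dy, dx)`` in nanometres.
    """

    channels: Dict[str, np.ndarray]
    voxel_dims: Tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise InputError("stack must contain at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise InputError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 3:
            raise InputError("channels must be 3-D (z, y, x)")
        if any(d <= 0 for d in self.voxel_dims):
            raise InputError("voxel dimensions must be positive")
        for name, arr in self.channels.items():
            if np.any(arr < 0):
                raise InputError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_dims
        return dz * dy * dx * 1e-9  # nm^3 -> um^3

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise InputError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path: str | Path) -> None:
        """Write as a multipage TIFF, channels stacked on the first axis.

        Channel names and voxel dimensions are stored in the image
        description as JSON so a round trip is lossless.
        """
        names = sorted(self.channels)
        data = np.stack([self.channels[n].astype(np.float32) for n in names])
        desc = json.dumps(
            {"channels": names, "voxel_dims_nm": list(self.voxel_dims)}
        )
        tifffile.imwrite(path, data, description=desc, metadata=None)

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        try:
            info = json.loads(desc)
            names = info["channels"]
            dims = tuple(info["voxel_dims_nm"])
        except (json.JSONDecodeError, KeyError, TypeError):
            # plain TIFF without our metadata: single unnamed channel set
            if data.ndim == 3:
                data = data[None]
            names = [f"ch{i}" for i in range(data.shape[0])]
            dims = DEFAULT_VOXEL_DIMS
        if data.ndim == 3:
            data = data[None]
        channels = {n: np.asarray(data[i], dtype=np.float32) for i, n in enumerate(names)}
        return cls(channels=channels, voxel_dims=dims)
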