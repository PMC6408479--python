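"""Image grids and coordinate conventions.

Arrays are indexed ``[row, col]`` = ``[y, x]``. Pixel coordinates are
0-based with ``x`` rightward and ``y`` downward; angles are measured in
degrees counterclockwise from +x (with y downward this is the screen-
clockwise direction, but the convention is applied consistently
everywhere, so rotations compose correctly). Lengths are stored in µm
and converted to pixels only at the array boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A rectangular pixel grid with a physical pixel size.

    Parameters
    ----------
    height, width:
        Grid size in pixels; each must be >= 32.
    pixel_size:
        Physical edge length of one pixel in µm (> 0).
    """

    height: int
    width: int
    pixel_size: float = 0.2

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("grid must be at least 32x32 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size**2

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical (height, width) of the field of view in µm."""
        return (self.height * self.pixel_size, self.width * self.pixel_size)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) pixel-index meshes, shape (height, width)."""
        y, x = np.mgrid[0 : self.height, 0 : self.width]
        return x.astype(float), y.astype(float)

    def um_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) meshes in µm."""
        x, y = self.pixel_coords()
        return x * self.pixel_size, y * self.pixel_size

    def to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size

    def to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size
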