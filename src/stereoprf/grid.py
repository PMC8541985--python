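"""Discretised visual field shared by stimuli, pRFs and Gabor filters.

The visual field is a square pixel raster in degrees of visual angle with
fixation at the exact centre pixel.  Convention: x increases rightward,
y increases upward; images are stored row-major with row 0 at the top, so
pixel (0, 0) maps to the upper-left corner (-half_extent, +half_extent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VisualFieldGrid", "make_grid"]


@dataclass(frozen=True)
class VisualFieldGrid:
    """Square sampling grid over the visual field.

    Parameters
    ----------
    half_extent : float
        Radius of the modelled field in degrees of visual angle.
    pixels_per_degree : float
        Sampling density.  Pixel dimensions are always odd so that one
        pixel centre sits exactly at fixation.
    """

    half_extent: float
    pixels_per_degree: float
    width: int = field(init=False)
    height: int = field(init=False)

    def __post_init__(self) -> None:
        if self.half_extent <= 0:
            raise ValueError("half_extent must be positive")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        n = 2 * int(round(self.half_extent * self.pixels_per_degree)) + 1
        object.__setattr__(self, "width", n)
        object.__setattr__(self, "height", n)

    @property
    def pixel_size(self) -> float:
        """Edge length of one pixel in degrees."""
        return 1.0 / self.pixels_per_degree

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def x_coords(self) -> np.ndarray:
        """Pixel-centre x coordinates (degrees), left to right."""
        half = (self.width - 1) // 2
        return (np.arange(self.width) - half) * self.pixel_size

    @property
    def y_coords(self) -> np.ndarray:
        """Pixel-centre y coordinates (degrees), row 0 first (top = +y)."""
        half = (self.height - 1) // 2
        return (half - np.arange(self.height)) * self.pixel_size

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate images of shape ``(height, width)``."""
        return np.meshgrid(self.x_coords, self.y_coords)

    def eccentricity(self) -> np.ndarray:
        x, y = self.mesh()
        return np.hypot(x, y)

    def polar_angle(self) -> np.ndarray:
        """Angle image in radians, measured counter-clockwise from +x."""
        x, y = self.mesh()
        return np.arctan2(y, x)

    def pixel_to_degrees(self, row: np.ndarray, col: np.ndarray):
        """Map pixel indices to degree coordinates of the pixel centres."""
        half = (self.width - 1) // 2
        x = (np.asarray(col) - half) * self.pixel_size
        y = (half - np.asarray(row)) * self.pixel_size
        return x, y

    def degrees_to_pixel(self, x: np.ndarray, y: np.ndarray):
        """Map degree coordinates to (row, col) of the nearest pixel."""
        half = (self.width - 1) // 2
        col = np.rint(np.asarray(x) * self.pixels_per_degree).astype(int) + half
        row = half - np.rint(np.asarray(y) * self.pixels_per_degree).astype(int)
        return row, col


def make_grid(half_extent: float, pixels_per_degree: float) -> VisualFieldGrid:
    """Construct a :class:`VisualFieldGrid`.

    ``pixels_per_degree`` below 10 is rejected so that the smallest
    disparity used in the experiments (0.2 deg) spans at least 2 pixels.
    """
    if pixels_per_degree < 10:
        raise ValueError("pixels_per_degree must be >= 10")
    return VisualFieldGrid(half_extent, pixels_per_degree)
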