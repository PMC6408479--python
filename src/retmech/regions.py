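"""Central/edge partition of a cell along its best-fit-ellipse major axis.

The mask's projected extent along the major axis is cut into five
equal-length slabs (four cuts perpendicular to the axis). The two
outermost slabs form the edge region; the middle three form the central
region. Boundaries are half-open [lo, hi) with the last slab closed, so
every mask pixel gets exactly one label and the slabs tile the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CellMask, Ellipse, RetardationImage

__all__ = ["RegionLabels", "partition_cell", "regional_retardation"]

N_SLABS = 5
EDGE_SLABS = (1, N_SLABS)  # outermost slabs on either end
OUTSIDE = 0


@dataclass
class RegionLabels:
    """Per-pixel labels: 0 outside, 1..5 slabs along the major axis."""

    labels: np.ndarray
    grid_pixel_size: float

    @property
    def central_mask(self) -> np.ndarray:
        return (self.labels > 1) & (self.labels < N_SLABS)

    @property
    def edge_mask(self) -> np.ndarray:
        return np.isin(self.labels, EDGE_SLABS)

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE


def partition_cell(mask: CellMask, ellipse: Ellipse) -> RegionLabels:
    """Label mask pixels by five equal intervals of major-axis projection."""
    ys, xs = np.nonzero(mask.mask)
    px = mask.grid.pixel_size
    ex, ey = ellipse.major_axis_vector
    proj = xs * px * ex + ys * px * ey
    lo, hi = proj.min(), proj.max()
    if hi - lo < N_SLABS * px:
        raise ValueError("mask too thin along the major axis to partition")
    # half-open intervals [lo, hi); the top edge joins the last slab
    idx = np.floor((proj - lo) / (hi - lo) * N_SLABS).astype(int)
    idx = np.clip(idx, 0, N_SLABS - 1)
    labels = np.zeros(mask.grid.shape, dtype=np.int8)
    labels[ys, xs] = idx + 1
    return RegionLabels(labels=labels, grid_pixel_size=px)


def regional_retardation(
    image: RetardationImage, labels: RegionLabels
) -> tuple[float, float]:
    """(central_mean, edge_mean) retardation in nm over the two regions."""
    if image.retardation.shape != labels.labels.shape:
        raise ValueError("image and label grids differ")
    central = labels.central_mask
    edge = labels.edge_mask
    if not central.any() or not edge.any():
        raise ValueError("empty central or edge region")
    return (
        float(image.retardation[central].mean()),
        float(image.retardation[edge].mean()),
    )
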