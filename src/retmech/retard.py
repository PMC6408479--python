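"""Retardation measurement: background subtraction, segmentation and
single-cell metrics (Ret_Cell, A_Cell, Ret_CellTotal, I_Cell).

Ret_Cell is the arithmetic mean retardation over the cell mask (nm),
A_Cell the projected cell area (µm²), and Ret_CellTotal their exact
product (nm µm²) — the area-corrected contractility readout. Time
courses are normalized metric-wise by their 0-min values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats
from skimage.filters import gaussian, threshold_otsu

from .model import CellMask, CellMetrics, RetardationImage, TimeCourse

__all__ = [
    "subtract_background",
    "segment_cell",
    "mean_cell_retardation",
    "cell_area",
    "total_cell_retardation",
    "mean_cell_intensity",
    "normalize_timecourse",
    "pixel_colocalization",
    "measure_cell",
]


class SegmentationError(RuntimeError):
    """No acceptable cell component was found."""


def subtract_background(
    observed: RetardationImage, background: RetardationImage
) -> RetardationImage:
    """Pixelwise observed - background, clipped at zero.

    Retardation is a magnitude, so negative differences (background
    overestimates) are clipped to 0 rather than kept signed.
    """
    if observed.grid != background.grid:
        raise ValueError("observed and background grids differ")
    diff = np.clip(observed.retardation - background.retardation, 0.0, None)
    return RetardationImage(retardation=diff, grid=observed.grid, slow_axis=observed.slow_axis)


def segment_cell(
    image: np.ndarray | RetardationImage,
    grid=None,
    method: str = "otsu_threshold",
    min_area: float = 20.0,
    provided_mask: np.ndarray | None = None,
    smooth_sigma: float = 1.0,
) -> CellMask:
    """Segment the cell region from an intensity or retardation map.

    Otsu threshold on a Gaussian-smoothed image, keep the largest
    connected component, fill holes; components below ``min_area``
    (µm²) are rejected. Alternatively a provided mask (the manual-
    outline path) is passed through unchanged.
    """
    if isinstance(image, RetardationImage):
        grid = image.grid
        data = image.retardation
    else:
        if grid is None:
            raise ValueError("grid is required for a bare array")
        data = np.asarray(image, dtype=float)
    if method == "provided_mask":
        if provided_mask is None:
            raise ValueError("provided_mask method needs a mask")
        return CellMask(mask=provided_mask, grid=grid, provenance="manual")
    if method != "otsu_threshold":
        raise ValueError(f"unknown segmentation method {method!r}")
    if data.size == 0 or np.ptp(data) == 0:
        raise SegmentationError("image has no contrast to segment")
    # log compression keeps Otsu from splitting cytoplasm off bright
    # fibers instead of cell off background
    compressed = np.log1p(np.clip(data, 0, None))
    smoothed = gaussian(compressed, sigma=smooth_sigma, preserve_range=True)
    binary = smoothed > threshold_otsu(smoothed)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] * grid.pixel_area < min_area:
        raise SegmentationError(
            f"largest component ({sizes[best - 1] * grid.pixel_area:.1f} µm²) "
            f"below min_area ({min_area} µm²)"
        )
    mask = ndimage.binary_fill_holes(labels == best)
    return CellMask(mask=mask, grid=grid, provenance="threshold")


def mean_cell_retardation(image: RetardationImage, mask: CellMask) -> float:
    """Ret_Cell: mean retardation (nm) over the cell mask, unweighted."""
    if image.grid != mask.grid:
        raise ValueError("image and mask grids differ")
    if mask.n_pixels == 0:
        raise ValueError("empty cell mask")
    return float(image.retardation[mask.mask].mean())


def cell_area(mask: CellMask) -> float:
    """A_Cell: projected cell area in µm² (pixel count x pixel area)."""
    return float(mask.n_pixels * mask.grid.pixel_area)


def total_cell_retardation(ret_cell: float, a_cell: float) -> float:
    """Ret_CellTotal = Ret_Cell * A_Cell (nm µm²), the exact product."""
    if not (np.isfinite(ret_cell) and np.isfinite(a_cell)):
        raise ValueError("inputs must be finite")
    if ret_cell < 0 or a_cell < 0:
        raise ValueError("inputs must be nonnegative")
    return float(ret_cell * a_cell)


def mean_cell_intensity(fluor: np.ndarray, mask: CellMask) -> float:
    """I_Cell: mean fluorescence grey value over the cell mask."""
    fluor = np.asarray(fluor, dtype=float)
    if fluor.shape != mask.grid.shape:
        raise ValueError("fluorescence image shape does not match mask grid")
    if mask.n_pixels == 0:
        raise ValueError("empty cell mask")
    return float(fluor[mask.mask].mean())


def measure_cell(
    image: RetardationImage,
    mask: CellMask,
    fluor: np.ndarray | None = None,
    timepoint: float | None = None,
) -> CellMetrics:
    """Convenience bundle: Ret_Cell, A_Cell (and I_Cell) for one cell."""
    ret = mean_cell_retardation(image, mask)
    area = cell_area(mask)
    i_cell = mean_cell_intensity(fluor, mask) if fluor is not None else None
    return CellMetrics(ret_cell=ret, a_cell=area, i_cell=i_cell, timepoint=timepoint)


def normalize_timecourse(tc: TimeCourse) -> TimeCourse:
    """Divide each metric by its own 0-min value (idempotent)."""
    if tc.normalized:
        return TimeCourse(metrics=[m for m in tc.metrics], normalized=True)
    base = tc.metrics[0]
    if base.ret_cell <= 0 or base.a_cell <= 0:
        raise ValueError("0-min metrics must be positive to normalize")
    out = []
    for m in tc.metrics:
        i_cell = None
        if m.i_cell is not None:
            if base.i_cell is None or base.i_cell <= 0:
                raise ValueError("0-min intensity must be positive to normalize")
            i_cell = m.i_cell / base.i_cell
        out.append(
            CellMetrics(
                ret_cell=m.ret_cell / base.ret_cell,
                a_cell=m.a_cell / base.a_cell,
                i_cell=i_cell,
                timepoint=m.timepoint,
            )
        )
    return TimeCourse(metrics=out, normalized=True)


def pixel_colocalization(
    fluor: np.ndarray, ret: RetardationImage, mask: CellMask
) -> float:
    """Pearson correlation between a fluorescence channel and retardation
    over the cell mask — the quantitative colocalization readout."""
    fluor = np.asarray(fluor, dtype=float)
    if fluor.shape != ret.grid.shape or ret.grid != mask.grid:
        raise ValueError("fluorescence, retardation and mask grids must agree")
    if mask.n_pixels < 10:
        raise ValueError("mask too small for a meaningful correlation")
    a = fluor[mask.mask]
    b = ret.retardation[mask.mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a channel; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r)
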