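"""File I/O: 32-bit float single-channel TIFFs for images, CSV for
tables (unit-annotated headers), YAML for configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import ImageGrid
from .model import CellMask, DisplacementField, RetardationImage, TractionField

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_mask",
    "read_mask",
    "write_retardation",
    "read_retardation",
    "write_vector_field",
    "write_csv",
    "write_yaml",
    "read_yaml",
]


def write_tiff(path: str | Path, image: np.ndarray, pixel_size: float | None = None) -> None:
    meta = {"pixel_size_um": pixel_size} if pixel_size else None
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32), metadata=meta)


def read_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_mask(path: str | Path, mask: CellMask) -> None:
    tifffile.imwrite(str(path), mask.mask.astype(np.uint8))


def read_mask(path: str | Path, grid: ImageGrid, provenance: str = "manual") -> CellMask:
    arr = tifffile.imread(str(path)) > 0
    return CellMask(mask=arr, grid=grid, provenance=provenance)


def write_retardation(path: str | Path, image: RetardationImage) -> None:
    write_tiff(path, image.retardation, image.grid.pixel_size)


def read_retardation(path: str | Path, grid: ImageGrid) -> RetardationImage:
    return RetardationImage(retardation=np.clip(read_tiff(path), 0, None), grid=grid)


def write_vector_field(
    path_x: str | Path, path_y: str | Path, field: TractionField | DisplacementField
) -> None:
    if isinstance(field, TractionField):
        cx, cy = field.t_x, field.t_y
    else:
        cx, cy = field.u_x, field.u_y
    write_tiff(path_x, cx, field.grid.pixel_size)
    write_tiff(path_y, cy, field.grid.pixel_size)


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_yaml(path: str | Path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
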