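"""Reading and writing of imaging artifacts and feature tables.

Stacks are multi-page grayscale TIFF (one page per focal plane, page order =
z order); exclusion masks and label images are single-page TIFF. Droplet
tables are plain CSV with a fixed column set. Pixel coordinates are 0-based
(row, column), row-major, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "ExclusionMask",
    "FormatError",
    "DROPLET_TABLE_COLUMNS",
    "read_zstack",
    "write_zstack",
    "read_mask",
    "write_mask",
    "read_label_image",
    "write_label_image",
    "read_droplet_table",
    "write_droplet_table",
]


class FormatError(ValueError):
    """An input file exists but does not have the expected layout."""


#: Fixed column set of the on-disk droplet table.
DROPLET_TABLE_COLUMNS = [
    "droplet_id",
    "source_image",
    "slice_first_seen",
    "area_px",
    "centroid_row",
    "centroid_col",
    "perimeter_px",
    "circularity",
    "integrated_intensity",
    "max_intensity",
    "excluded_reason",
]


@dataclass
class ZStack:
    """An ordered set of 2D intensity planes acquired at successive depths.

    Parameters
    ----------
    planes : ndarray, shape (n_slices, height, width)
        Non-negative integer intensities, one plane per focal depth.
    pixel_depth : int
        Nominal detector bit depth (16 for the acquisitions emulated here).
    z_step : float
        Physical slice spacing in micrometres. Metadata only; no volumetric
        calculation uses it, but it is carried through for provenance.
    channel : str
        Free-text channel label.
    """

    planes: np.ndarray
    pixel_depth: int = 16
    z_step: float = 0.3
    channel: str = ""

    def __post_init__(self) -> None:
        planes = np.asarray(self.planes)
        if planes.ndim != 3 or planes.shape[0] < 1:
            raise ValueError("planes must be a (n_slices, height, width) array")
        if not np.issubdtype(planes.dtype, np.integer):
            raise ValueError("plane intensities must be integer")
        if planes.min() < 0:
            raise ValueError("plane intensities must be non-negative")
        if planes.max() > 2**self.pixel_depth - 1:
            raise ValueError(
                f"intensities exceed {self.pixel_depth}-bit range"
            )
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        self.planes = planes

    @property
    def n_slices(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1:]


@dataclass
class ExclusionMask:
    """Binary mask marking dead or incompletely imaged cells.

    True pixels are excluded regions; any detected object overlapping them
    is discarded from the droplet list.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        self.grid = grid.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "ExclusionMask":
        return cls(np.zeros(shape, dtype=bool))


def _load_pages(path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # tifffile raises assorted types on bad files
        raise FormatError(f"cannot read TIFF {path!s}: {exc}") from exc
    return arr


def read_zstack(path, z_step: float = 0.3, channel: str = "") -> ZStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`ZStack`.

    Page order is preserved as z order and raw integer intensities are kept
    untouched (no rescaling). RGB pages are rejected rather than silently
    converted to avoid channel ambiguity.
    """
    arr = _load_pages(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(
            f"{path!s}: expected grayscale pages, got array of shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        # (h, w, 3/4) single RGB(A) page masquerading as a stack
        raise FormatError(f"{path!s}: RGB images are not supported")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path!s}: expected integer pixel type, got {arr.dtype}")
    return ZStack(planes=arr, pixel_depth=8 * arr.dtype.itemsize,
                  z_step=z_step, channel=channel)


def write_zstack(stack: ZStack, path) -> None:
    """Write a stack as a multi-page TIFF, one page per plane."""
    tifffile.imwrite(path, np.asarray(stack.planes))


def read_mask(path, shape: tuple[int, int] | None = None) -> ExclusionMask:
    """Read a single-plane image as a boolean exclusion mask.

    Any nonzero pixel means excluded. If ``shape`` is given, a mismatch with
    the image dimensions raises :class:`FormatError`.
    """
    arr = _load_pages(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path!s}: mask must be a single 2D plane")
    if shape is not None and tuple(arr.shape) != tuple(shape):
        raise FormatError(
            f"{path!s}: mask shape {arr.shape} does not match expected {tuple(shape)}"
        )
    return ExclusionMask(arr != 0)


def write_mask(mask: ExclusionMask, path) -> None:
    """Write an exclusion mask as an 8-bit TIFF (255 = excluded)."""
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255))


def read_label_image(path) -> np.ndarray:
    """Read a single-plane label image (0 = background, k > 0 = object k)."""
    arr = _load_pages(path)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path!s}: label image must be a single 2D plane")
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0:
        raise FormatError(f"{path!s}: labels must be non-negative integers")
    return arr.astype(np.int32)


def write_label_image(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    dtype = np.uint16 if labels.max() < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def write_droplet_table(table: pd.DataFrame, path) -> None:
    """Write a droplet table as CSV with the fixed column set.

    Extra in-memory columns (recursion depth, forced flag, ...) are dropped;
    missing ones are filled with defaults so round trips are stable.
    """
    out = table.copy()
    for col in DROPLET_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col in ("source_image", "excluded_reason") else 0
    out = out[DROPLET_TABLE_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6g")


def read_droplet_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in DROPLET_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path!s}: droplet table missing columns {missing}")
    return table


def write_phenotype_table(table: pd.DataFrame, path) -> None:
    """Write per-cell records as CSV (cut_status encoded 0/1)."""
    out = table.copy()
    if "cut_status" in out.columns:
        out["cut_status"] = out["cut_status"].astype(int)
    cols = ["cell_id", "strain", "medium", "cut_status", "droplet_count", "total_intensity"]
    out = out[[c for c in cols if c in out.columns]]
    out.to_csv(path, index=False, float_format="%.6g")


def read_phenotype_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[])
    if "cut_status" in table.columns:
        table["cut_status"] = table["cut_status"].astype(bool)
    return table
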