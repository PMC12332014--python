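"""Image reading, channel handling and pixel-level preprocessing.

Two-photon merges display collagen second-harmonic generation (SHG) in the
green plane and two-photon fluorescence (TPF) in the red plane; inputs may
also arrive as per-channel grayscale TIFF/PNG or as two-page TIFFs
(page 0 = SHG, page 1 = TPF). All downstream texture code works on 2-D
integer fields quantized to a declared number of gray levels, with an
optional boolean exclusion mask (True = pixel excluded, e.g. saturated
dye-accumulation artifacts at section edges).

Coordinate convention: row-major arrays, origin at the top-left, 0-based
indices. This convention fixes the meaning of the co-occurrence angles
downstream (0 deg = along a row, 90 deg = up a column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

CHANNELS = ("SHG", "TPF")
GROUPS = ("group1", "group2")
DIAGNOSES = ("primary_SCC", "primary_HGD", "metachronous_HGD")

#: manifest columns required to identify and label every image file
MANIFEST_COLUMNS = ("file", "channel", "group", "diagnosis", "patient_id", "field_id")


class FormatError(ValueError):
    """Raised when an input image or manifest violates the expected format."""


@dataclass
class LabeledImage:
    """One channel's pixel field plus its study labels.

    Parameters
    ----------
    pixels : ndarray of int, shape (H, W)
        Nonnegative gray values in ``[0, levels - 1]``.
    channel : {"SHG", "TPF"}
    group : {"group1", "group2"}
    diagnosis : {"primary_SCC", "primary_HGD", "metachronous_HGD"}
    patient_id, field_id : str
        Free-form labels tying fields to patients.
    mask : ndarray of bool, optional
        True marks excluded pixels (artifacts); same shape as ``pixels``.
    levels : int
        Number of gray levels the pixel field is quantized to (256 for raw
        8-bit input).
    """

    pixels: np.ndarray
    channel: str
    group: str
    diagnosis: str
    patient_id: str
    field_id: str
    mask: np.ndarray | None = None
    levels: int = 256

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError("pixels must be an integer array")
        if self.channel not in CHANNELS:
            raise FormatError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.diagnosis not in DIAGNOSES:
            raise FormatError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}"
            )
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.levels - 1
        ):
            raise FormatError(
                f"pixel values outside [0, {self.levels - 1}] for declared levels"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise FormatError("mask shape must match pixels shape")

    def quantized(self, levels: int) -> "LabeledImage":
        """Return a copy quantized to ``levels`` gray levels (mask preserved)."""
        if self.levels != 256:
            raise ValueError("quantized() expects raw 8-bit input (levels == 256)")
        return LabeledImage(
            pixels=to_gray_quantized(self.pixels, levels),
            channel=self.channel,
            group=self.group,
            diagnosis=self.diagnosis,
            patient_id=self.patient_id,
            field_id=self.field_id,
            mask=self.mask,
            levels=levels,
        )


@dataclass
class TileGrid:
    """A row-major plan of abutting stitching tiles (positions in micrometres)."""

    rows: int
    cols: int
    tile_size_um: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    positions: list[tuple[float, float]] = field(default_factory=list)

    @property
    def tile_count(self) -> int:
        return self.rows * self.cols


def split_channels(rgb_image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a merged RGB image into its (SHG, TPF) pixel fields.

    SHG is taken from the green plane and TPF from the red plane, matching
    the display convention of two-photon merges (collagen SHG rendered
    green-yellow, TPF rendered red); the blue plane is discarded.
    """
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise FormatError(
            f"expected an H x W x 3 RGB image, got shape {rgb_image.shape}"
        )
    shg = rgb_image[:, :, 1].copy()
    tpf = rgb_image[:, :, 0].copy()
    return shg, tpf


def to_gray_quantized(image: np.ndarray, levels: int) -> np.ndarray:
    """Quantize an 8-bit gray field to ``levels`` uniform bins.

    Uses the monotone mapping ``floor(v * levels / 256)``, so ``levels=256``
    is the identity on 8-bit input and each output level collects an equal
    number of input values.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    image = np.asarray(image)
    if image.size and (image.min() < 0 or image.max() > 255):
        raise ValueError("input values must lie in [0, 255]")
    return (image.astype(np.int64) * levels) // 256


def build_artifact_mask(
    image: np.ndarray, saturation_threshold: int, min_blob_px: int
) -> np.ndarray:
    """Mask connected saturated blobs of at least ``min_blob_px`` pixels.

    A reproducible stand-in for the manual exclusion of bright
    dye-accumulation artifacts: pixels at or above ``saturation_threshold``
    are grouped into 8-connected components and components smaller than
    ``min_blob_px`` are dropped. Returns a boolean mask (True = excluded);
    an all-false mask is a valid result.
    """
    image = np.asarray(image)
    hot = image >= saturation_threshold
    if not hot.any():
        return np.zeros(image.shape, dtype=bool)
    labels, n = ndimage.label(hot, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros(image.shape, dtype=bool)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_blob_px)
    keep = keep[keep > 0]  # label 0 is background
    return np.isin(labels, keep)


def plan_tile_grid(
    rows: int,
    cols: int,
    tile_size_um: tuple[float, float] = (400.0, 400.0),
    origin: tuple[float, float] = (0.0, 0.0),
) -> TileGrid:
    """Plan a rows x cols grid of abutting stitching tiles.

    Positions are emitted in row-major order as (y_um, x_um) offsets from
    ``origin``; adjacent tiles abut exactly (no overlap modeling). A
    15 x 15 plan of 400 x 400 um tiles covers a 6 x 6 mm field with 225
    single acquisitions.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows} x {cols}")
    dy, dx = float(tile_size_um[0]), float(tile_size_um[1])
    if dy <= 0 or dx <= 0:
        raise ValueError("tile size must be positive")
    oy, ox = origin
    positions = [
        (oy + r * dy, ox + c * dx) for r in range(rows) for c in range(cols)
    ]
    return TileGrid(
        rows=rows,
        cols=cols,
        tile_size_um=(dy, dx),
        origin=(float(oy), float(ox)),
        positions=positions,
    )


# ---------------------------------------------------------------------------
# manifest + file I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit image (TIFF or PNG) as a 2-D uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise FormatError(
            f"{path} is multi-channel; use split_channels on RGB merges"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr.astype(np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask as a boolean array (nonzero = excluded)."""
    return np.asarray(iio.imread(Path(path))) > 0


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and structurally validate a dataset manifest CSV."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    return df


def load_labeled_images(
    manifest: pd.DataFrame, root: str | Path, levels: int = 256
) -> list[LabeledImage]:
    """Load every manifest row into a LabeledImage, quantizing to ``levels``.

    ``root`` is the directory the manifest's relative file paths resolve
    against. Rows with a ``mask_file`` entry get their exclusion mask loaded
    alongside.
    """
    root = Path(root)
    images = []
    for _, row in manifest.iterrows():
        pixels = read_image(root / row["file"])
        mask = None
        mask_file = row.get("mask_file")
        if isinstance(mask_file, str) and mask_file:
            mask = read_mask(root / mask_file)
        img = LabeledImage(
            pixels=pixels.astype(np.int64),
            channel=row["channel"],
            group=row["group"],
            diagnosis=row["diagnosis"],
            patient_id=str(row["patient_id"]),
            field_id=str(row["field_id"]),
            mask=mask,
            levels=256,
        )
        if levels != 256:
            img = img.quantized(levels)
        images.append(img)
    return images


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2-D uint8 field as grayscale TIFF or PNG by extension."""
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=np.uint8) * 255))
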