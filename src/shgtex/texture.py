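"""Gray-level co-occurrence matrices and Haralick texture features.

The GLCM tallies how often pairs of quantized gray levels co-occur at a
fixed pixel offset. Four offsets are used, one per angle, in image
coordinates (row index grows downward, angles measured counter-clockwise
from the row axis):

    0 deg   -> (row  0, col +d)        90 deg  -> (row -d, col  0)
    45 deg  -> (row -d, col +d)        135 deg -> (row -d, col -d)

Matrices are symmetrized (each ordered pair counted in both directions) and
normalized to sum to one, so the two marginal distributions coincide, which
simplifies the correlation feature. Pairs that touch a masked (excluded)
pixel or leave the image are skipped.

Pair counting is implemented here directly because exclusion masks must be
honored pixel-by-pixel; the implementation is cross-checked in the test
suite against brute-force enumeration and against skimage's
``graycomatrix`` on unmasked images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import LabeledImage

ANGLES = (0, 45, 90, 135)

#: (row, col) unit offsets per angle, scaled by the pair distance
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

FEATURE_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "asm",
    "correlation",
)


class DegenerateGLCMError(ValueError):
    """Raised when features are requested from a GLCM with no valid pairs."""


@dataclass
class CooccurrenceMatrix:
    """A normalized symmetric gray-level pair-frequency matrix.

    ``p`` sums to 1 whenever ``n_pairs > 0``; ``n_pairs`` counts the valid
    directed pixel pairs found before symmetrization. ``n_pairs == 0``
    only occurs for degenerate geometry (offset larger than the image, or
    everything masked).
    """

    p: np.ndarray
    levels: int
    distance_px: int
    angle_deg: int
    n_pairs: int


@dataclass
class TextureFeatures:
    """The six scalar texture statistics derived from one GLCM."""

    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    asm: float
    correlation: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def compute_glcm(
    image: np.ndarray,
    levels: int,
    distance_px: int = 1,
    angle_deg: int = 0,
    mask: np.ndarray | None = None,
) -> CooccurrenceMatrix:
    """Count co-occurring gray-level pairs at one (distance, angle).

    Parameters
    ----------
    image : 2-D int array
        Pixel field already quantized to ``[0, levels - 1]``.
    levels : int
        Declared number of gray levels (matrix is levels x levels).
    distance_px : int
        Pair offset length in pixels (>= 1).
    angle_deg : {0, 45, 90, 135}
    mask : 2-D bool array, optional
        True marks excluded pixels; any pair touching one is skipped.

    Returns
    -------
    CooccurrenceMatrix
        Symmetric, normalized. If the offset does not fit in the image (or
        all pairs are masked) the matrix is all-zero with ``n_pairs = 0``
        and a warning is emitted.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if distance_px < 1:
        raise ValueError(f"distance_px must be >= 1, got {distance_px}")
    if angle_deg not in OFFSETS:
        raise ValueError(f"angle_deg must be one of {ANGLES}, got {angle_deg}")
    if image.size and (image.min() < 0 or image.max() >= levels):
        raise ValueError(f"image values must lie in [0, {levels - 1}]")

    dr, dc = OFFSETS[angle_deg]
    dr, dc = dr * distance_px, dc * distance_px
    h, w = image.shape

    rows = slice(max(0, -dr), h - max(0, dr))
    cols = slice(max(0, -dc), w - max(0, dc))
    rows_t = slice(rows.start + dr, rows.stop + dr)
    cols_t = slice(cols.start + dc, cols.stop + dc)

    p = np.zeros((levels, levels), dtype=float)
    if rows.start >= rows.stop or cols.start >= cols.stop:
        warnings.warn(
            f"image {h}x{w} smaller than offset for d={distance_px}, "
            f"angle={angle_deg}; degenerate GLCM",
            stacklevel=2,
        )
        return CooccurrenceMatrix(p, levels, distance_px, angle_deg, 0)

    a = image[rows, cols]
    b = image[rows_t, cols_t]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        valid = ~mask[rows, cols] & ~mask[rows_t, cols_t]
        a, b = a[valid], b[valid]
    else:
        a, b = a.ravel(), b.ravel()

    n_pairs = int(a.size)
    if n_pairs == 0:
        warnings.warn(
            f"no valid pixel pairs for d={distance_px}, angle={angle_deg} "
            "(all pairs masked); degenerate GLCM",
            stacklevel=2,
        )
        return CooccurrenceMatrix(p, levels, distance_px, angle_deg, 0)

    counts = np.bincount(
        a.astype(np.int64) * levels + b.astype(np.int64), minlength=levels * levels
    ).reshape(levels, levels)
    sym = counts + counts.T
    p = sym / sym.sum()
    return CooccurrenceMatrix(p, levels, distance_px, angle_deg, n_pairs)


def haralick_features(m: CooccurrenceMatrix) -> TextureFeatures:
    """Derive the six texture statistics from a normalized GLCM.

    With ``p(i, j)`` the normalized matrix and ``i, j`` the gray levels:

    * contrast      = sum p(i,j) (i-j)^2
    * dissimilarity = sum p(i,j) |i-j|
    * homogeneity   = sum p(i,j) / (1 + (i-j)^2)
    * ASM           = sum p(i,j)^2, energy = sqrt(ASM)
    * correlation   = sum p(i,j) (i-mu)(j-mu) / sigma^2, with mu and
      sigma^2 the marginal mean and variance (equal on both axes by
      symmetry). A constant texture has sigma^2 = 0 and is defined to be
      perfectly self-correlated (correlation = 1).
    """
    if m.n_pairs == 0:
        raise DegenerateGLCMError(
            "texture features are undefined for a degenerate GLCM (no valid pairs)"
        )
    p = m.p
    idx = np.arange(m.levels, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j
    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    asm = float((p**2).sum())
    energy = float(np.sqrt(asm))
    marginal = p.sum(axis=1)
    mu = float((idx * marginal).sum())
    var = float(((idx - mu) ** 2 * marginal).sum())
    if var <= 0:
        correlation = 1.0
    else:
        correlation = float((p * (i - mu) * (j - mu)).sum() / var)
    return TextureFeatures(contrast, dissimilarity, homogeneity, energy, asm, correlation)


def features_per_angle(
    image: LabeledImage,
    distance_px: int = 1,
    angles: tuple[int, ...] = ANGLES,
) -> list[dict]:
    """Extract one feature record per co-occurrence angle.

    Each record is a flat dict carrying the image's labels, the angle, and
    the six features; records are never averaged across angles — every
    angle is a separate datapoint downstream.
    """
    records = []
    for angle in angles:
        m = compute_glcm(
            image.pixels,
            levels=image.levels,
            distance_px=distance_px,
            angle_deg=angle,
            mask=image.mask,
        )
        feats = haralick_features(m)
        rec = {
            "channel": image.channel,
            "group": image.group,
            "diagnosis": image.diagnosis,
            "patient_id": image.patient_id,
            "field_id": image.field_id,
            "angle_deg": angle,
        }
        rec.update(feats.as_dict())
        records.append(rec)
    return records


class GLCMFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer turning images into GLCM texture features.

    Parameters
    ----------
    levels : int, default 64
        Gray levels to quantize 8-bit input to before pair counting.
    distance_px : int, default 1
        Co-occurrence offset length.
    angles : tuple of int, default (0, 45, 90, 135)
    per_angle : bool, default False
        If False, ``transform`` returns one row per image with the angles'
        features concatenated (shape ``(n_images, 6 * len(angles))``),
        which keeps the sample count stable as sklearn pipelines expect.
        If True, every (image, angle) pair becomes its own row — the
        datapoint convention used by the study pipeline.

    ``transform`` accepts a list of 2-D uint8 arrays, ``(array, mask)``
    pairs, or :class:`LabeledImage` instances (whose masks are honored).
    The transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        levels: int = 64,
        distance_px: int = 1,
        angles: tuple[int, ...] = ANGLES,
        per_angle: bool = False,
    ):
        self.levels = levels
        self.distance_px = distance_px
        self.angles = angles
        self.per_angle = per_angle

    def _validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance_px < 1:
            raise ValueError("distance_px must be >= 1")
        bad = [a for a in self.angles if a not in OFFSETS]
        if bad:
            raise ValueError(f"unsupported angles {bad}; choose from {ANGLES}")

    def fit(self, X, y=None):  # noqa: D102 — sklearn contract, stateless
        self._validate()
        self.n_features_out_ = 6 * (1 if self.per_angle else len(self.angles))
        return self

    def _image_features(self, item) -> list[list[float]]:
        from .image_io import to_gray_quantized

        if isinstance(item, LabeledImage):
            if item.levels == 256 and self.levels != 256:
                item = item.quantized(self.levels)
            pixels, mask = item.pixels, item.mask
        elif isinstance(item, tuple):
            pixels, mask = item
            pixels = to_gray_quantized(np.asarray(pixels), self.levels)
        else:
            pixels = to_gray_quantized(np.asarray(item), self.levels)
            mask = None
        rows = []
        for angle in self.angles:
            m = compute_glcm(pixels, self.levels, self.distance_px, angle, mask)
            f = haralick_features(m)
            rows.append([getattr(f, name) for name in FEATURE_NAMES])
        return rows

    def transform(self, X) -> np.ndarray:
        self._validate()
        out = []
        for item in X:
            rows = self._image_features(item)
            if self.per_angle:
                out.extend(rows)
            else:
                out.append([v for row in rows for v in row])
        return np.asarray(out, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self._validate()
        if self.per_angle:
            return np.asarray(FEATURE_NAMES, dtype=object)
        return np.asarray(
            [f"{name}_{a}deg" for a in self.angles for name in FEATURE_NAMES],
            dtype=object,
        )
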