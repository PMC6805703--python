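"""Slice-scan image operations for TTC / Evans-blue double-stained brains.

A scanned coronal slice carries three colour populations: TTC-stained
viable tissue (deep red), unstained infarct (pale, near white) and
Evans-blue extravasation (dark blue).  Because Evans blue is dark under
ordinary luminance conversion, dyed infarct is miscounted as viable tissue
when thresholding a plain grayscale scan.  The remedy implemented here is a
linear channel mix that keeps only the blue channel: Evans blue and pale
infarct both map bright, viable red maps dark, and a single threshold then
recovers the full infarct regardless of dye coverage.

The module is deliberately pixel-based and unit-free: all areas are pixel
counts, as produced by thresholding a flatbed scan.  Physical calibration
(mm per pixel) is carried on :class:`SliceImage` but never required.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .errors import DegenerateSplitError, ImageFormatError, NoTissueError

__all__ = [
    "SliceImage",
    "GrayImage",
    "TissueMask",
    "SliceMeasurement",
    "InfarctClassification",
    "ImagingConfig",
    "LUMINANCE_WEIGHTS",
    "DEFAULT_BLUE_COEFFICIENTS",
    "load_slice_image",
    "apply_blue_filter",
    "to_grayscale",
    "segment_tissue",
    "find_midline",
    "split_hemispheres",
    "classify_infarct",
    "detect_blue_area",
    "measure_slice",
]

#: ITU-R 601 luma weights used for the unfiltered ("ablated") conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

#: Channel-mixer coefficients of the blue filter: monochrome = 100% blue.
DEFAULT_BLUE_COEFFICIENTS = (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SliceImage:
    """One scanned coronal slice as an 8-bit RGB raster.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    slice_index
        1-based position of the slice in the rostro-caudal series
        (a standard brain is cut into six 2 mm slices).
    scale_mm_per_px
        Optional physical calibration; informational only.
    """

    pixels: np.ndarray
    slice_index: int
    scale_mm_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("slice image must be at least 16x16 pixels")
        if self.slice_index < 1:
            raise ValueError("slice_index is 1-based and must be >= 1")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel image with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("GrayImage expects a 2-D array")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValueError("gray intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TissueMask:
    """Boolean foreground mask; must contain at least one pixel."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != bool:
            raise ValueError("TissueMask expects a 2-D boolean array")
        if not px.any():
            raise ValueError("TissueMask must contain at least one pixel")
        object.__setattr__(self, "pixels", px)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SliceMeasurement:
    """Per-slice pixel areas feeding the brain-level formulas."""

    slice_index: int
    left_area_px: int
    right_area_px: int
    infarct_area_px: int
    blue_area_px: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = (
            self.left_area_px,
            self.right_area_px,
            self.infarct_area_px,
            self.blue_area_px,
        )
        if any(c < 0 for c in counts):
            raise ValueError("pixel counts must be non-negative")
        total = self.left_area_px + self.right_area_px
        if self.infarct_area_px > total or self.blue_area_px > total:
            raise ValueError("classified area exceeds tissue area")


@dataclass(frozen=True)
class InfarctClassification:
    """Infarct mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold: Optional[float]
    flags: tuple[str, ...] = ()

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ImagingConfig:
    """All knobs of the per-slice measurement pipeline.

    ``use_blue_filter=False`` switches the infarct channel to plain
    luminance — the ablation that demonstrates why the blue filter is
    needed in the first place.
    """

    orientation: str = "left_is_left"
    background: str = "white"
    threshold_method: str = "otsu"
    threshold_level: Optional[float] = None
    blue_margin: float = 30 / 255
    filter_coefficients: tuple[float, float, float] = DEFAULT_BLUE_COEFFICIENTS
    use_blue_filter: bool = True
    min_object_px: int = 64
    background_tolerance: float = 30 / 255
    min_contrast: float = 0.15
    midline: Optional[int] = None
    ipsilateral: str = "right"
    blue_scope: str = "ipsilateral"  # or "slice"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _coerce_rgb8(arr: np.ndarray, path: str) -> np.ndarray:
    """Promote gray to RGB, rescale 16-bit, composite alpha onto white."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        pass
    elif arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer) and arr.size and 0 <= arr.min() and arr.max() <= 65535:
        # PIL mode "I" delivers int32; treat as 16-bit payload
        arr = (arr.astype(np.uint32) // 257).astype(np.uint8)
    else:
        raise ImageFormatError(f"{path}: unsupported bit depth / dtype {arr.dtype}")

    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        gray, alpha = arr[..., 0], arr[..., 1]
        arr = np.stack([gray] * 3 + [alpha], axis=-1)

    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageFormatError(f"{path}: expected gray/RGB/RGBA raster, got shape {arr.shape}")

    if arr.shape[2] == 4:
        a = arr[..., 3:4].astype(float) / 255.0
        rgb = arr[..., :3].astype(float)
        arr = np.rint(rgb * a + 255.0 * (1.0 - a)).astype(np.uint8)
    return arr


def load_slice_image(path: os.PathLike | str, slice_index: int) -> SliceImage:
    """Read a PNG/TIFF scan as an 8-bit RGB :class:`SliceImage`.

    16-bit inputs are rescaled to 8 bits by integer division; an alpha
    channel is composited onto a white background (scanner lid) and then
    dropped.
    """
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode == "P":
                    im = im.convert("RGBA")
                arr = np.asarray(im)
    except ImageFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise decoder chatter
        raise IOError(f"cannot read slice image {path!r}: {exc}") from exc
    return SliceImage(_coerce_rgb8(arr, path), slice_index)


# ---------------------------------------------------------------------------
# colour transforms
# ---------------------------------------------------------------------------


def apply_blue_filter(
    img: SliceImage,
    coefficients: Sequence[float] = DEFAULT_BLUE_COEFFICIENTS,
) -> GrayImage:
    """Linear channel mix, by default monochrome = 100% blue channel.

    ``out = clamp(cR*R + cG*G + cB*B, 0, 255) / 255``.  With the default
    ``(0, 0, 1)`` Evans-blue pixels map bright (infarct-like) and TTC-red
    viable tissue maps dark, which is what makes infarct thresholding
    immune to the dye.  Coefficients follow the channel-mixer convention
    and must each lie in [-2, 2].
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if coeffs.shape != (3,):
        raise ValueError("coefficients must be three numbers (cR, cG, cB)")
    if not np.all(np.isfinite(coeffs)) or np.any(np.abs(coeffs) > 2):
        raise ValueError("each coefficient must be finite and within [-2, 2]")
    mixed = img.pixels.astype(float) @ coeffs
    return GrayImage(np.clip(mixed, 0.0, 255.0) / 255.0)


def to_grayscale(img: SliceImage) -> GrayImage:
    """Standard luminance conversion (0.299, 0.587, 0.114), scaled to [0, 1]."""
    return GrayImage(img.pixels.astype(float) @ np.asarray(LUMINANCE_WEIGHTS) / 255.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_tissue(
    img: SliceImage,
    background: str = "white",
    min_object_px: int = 64,
    tolerance: float = 30 / 255,
) -> TissueMask:
    """Separate tissue from the scanner background.

    Foreground is every pixel whose Euclidean RGB distance from the declared
    background colour exceeds ``tolerance`` (on the [0, 1] per-channel
    scale).  Connected components smaller than ``min_object_px`` (debris,
    dust) are dropped and interior holes are filled.
    """
    if background not in ("white", "black"):
        raise ValueError("background must be 'white' or 'black'")
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    bg = 255.0 if background == "white" else 0.0
    diff = img.pixels.astype(float) - bg
    dist = np.sqrt(np.sum(diff * diff, axis=-1)) / 255.0
    fg = dist > tolerance
    if min_object_px > 0 and fg.any():
        labels, _ = ndimage.label(fg)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = (sizes >= min_object_px)[labels]
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        raise NoTissueError("no tissue detected against the declared background")
    return TissueMask(fg)


def find_midline(mask: TissueMask, method: str = "waist") -> int:
    """Locate the interhemispheric midline column.

    ``"waist"`` scans the central mass window (between the 25% and 75%
    column-mass quantiles) for the column with the least tissue — the
    interhemispheric fissure is the narrowest point of a well-oriented
    slice.  If no clear notch exists (minimum not below half the window
    median) the method falls back to the centroid column, which is exact
    for bilaterally symmetric slices but biased toward a swollen
    hemisphere.
    """
    cols = mask.pixels.sum(axis=0).astype(float)
    centroid = int(round(float(np.average(np.arange(cols.size), weights=cols))))
    if method == "centroid":
        return centroid
    if method != "waist":
        raise ValueError("midline method must be 'waist' or 'centroid'")
    cum = np.cumsum(cols)
    total = cum[-1]
    lo = int(np.searchsorted(cum, 0.25 * total))
    hi = int(np.searchsorted(cum, 0.75 * total))
    if hi <= lo + 1:
        return centroid
    window = cols[lo : hi + 1]
    wmin = window.min()
    if wmin < 0.5 * np.median(window):
        ties = np.flatnonzero(window == wmin) + lo
        return int(ties[len(ties) // 2])
    return centroid


def split_hemispheres(
    mask: TissueMask,
    orientation: str = "left_is_left",
    midline: Optional[int] = None,
) -> tuple[TissueMask, TissueMask]:
    """Split tissue into anatomical left / right hemispheres.

    Pixels in columns strictly left of ``midline`` form one hemisphere, the
    remainder the other; by default the midline is detected with
    :func:`find_midline`.  ``orientation="flipped"`` swaps the anatomical
    labels (prone vs supine scans).  The two areas always sum to the tissue
    area.
    """
    if orientation not in ("left_is_left", "flipped"):
        raise ValueError("orientation must be 'left_is_left' or 'flipped'")
    ncols = mask.shape[1]
    if midline is None:
        midline = find_midline(mask)
    if not 0 < midline < ncols:
        raise ValueError(f"midline {midline} outside image columns (0, {ncols})")
    colgrid = np.arange(ncols)[None, :]
    left_px = mask.pixels & (colgrid < midline)
    right_px = mask.pixels & (colgrid >= midline)
    if not left_px.any() or not right_px.any():
        raise DegenerateSplitError("hemisphere split left one side empty")
    if orientation == "flipped":
        left_px, right_px = right_px, left_px
    return TissueMask(left_px), TissueMask(right_px)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _otsu_threshold(values: np.ndarray) -> tuple[float, float]:
    """Exact Otsu on the empirical gray levels.

    Returns ``(threshold, class_separation)`` where the threshold is the
    smallest gray level maximising the between-class variance of the split
    ``{v < t} | {v >= t}`` and the separation is ``mu1 - mu0`` at that
    split.  Works on the actual unique values rather than histogram bins,
    so it is exactly reproducible by exhaustive search.
    """
    uniq, counts = np.unique(values, return_counts=True)
    n0 = np.cumsum(counts)[:-1].astype(float)
    s0 = np.cumsum(counts * uniq)[:-1]
    n = float(values.size)
    s = float((counts * uniq).sum())
    w0 = n0 / n
    w1 = 1.0 - w0
    mu0 = s0 / n0
    mu1 = (s - s0) / (n - n0)
    var = w0 * w1 * (mu1 - mu0) ** 2
    k = int(np.argmax(var))  # first maximum -> smallest threshold on ties
    return float(uniq[k + 1]), float(mu1[k] - mu0[k])


def classify_infarct(
    gray: GrayImage,
    tissue: TissueMask,
    method: str = "otsu",
    level: Optional[float] = None,
    min_contrast: float = 0.15,
) -> InfarctClassification:
    """Threshold bright (pale / unstained) pixels within tissue as infarct.

    Under the blue-filter convention infarct and Evans-blue pixels are
    bright and viable TTC-red tissue is dark, so ``intensity >= threshold``
    marks infarct.  ``"otsu"`` picks the threshold from the within-tissue
    histogram; ``"fixed"`` uses ``level``.

    Two degenerate situations declare the slice infarct-free and flag it
    instead of guessing: a single-valued histogram, and an Otsu split whose
    class means differ by less than ``min_contrast`` (thresholding pure
    noise on a slice without a pale population).
    """
    if gray.shape != tissue.shape:
        raise ValueError("gray image and tissue mask shapes differ")
    empty = np.zeros(tissue.shape, dtype=bool)
    if method == "fixed":
        if level is None or not 0.0 < level < 1.0:
            raise ValueError("method 'fixed' requires level in (0, 1)")
        mask = tissue.pixels & (gray.pixels >= level)
        return InfarctClassification(mask, float(level))
    if method != "otsu":
        raise ValueError("method must be 'otsu' or 'fixed'")
    vals = gray.pixels[tissue.pixels]
    if np.unique(vals).size < 2:
        return InfarctClassification(empty, None, ("degenerate-histogram",))
    thr, separation = _otsu_threshold(vals)
    if separation < min_contrast:
        return InfarctClassification(empty, None, ("low-contrast",))
    mask = tissue.pixels & (gray.pixels >= thr)
    return InfarctClassification(mask, thr)


def detect_blue_area(
    img: SliceImage,
    tissue: TissueMask,
    blue_margin: float = 30 / 255,
) -> np.ndarray:
    """Mask of Evans-blue pixels: blue dominance over red and green.

    A tissue pixel is blue iff ``(B - max(R, G)) / 255 > blue_margin``.
    The rule is hue-free and monotone in the margin.  Runs on the original
    RGB scan, never on the filtered image.
    """
    if not 0.0 < blue_margin < 1.0:
        raise ValueError("blue_margin must lie in (0, 1)")
    if img.shape != tissue.shape:
        raise ValueError("image and tissue mask shapes differ")
    px = img.pixels.astype(np.int16)
    dominance = (px[..., 2] - np.maximum(px[..., 0], px[..., 1])) / 255.0
    return tissue.pixels & (dominance > blue_margin)


# ---------------------------------------------------------------------------
# per-slice pipeline
# ---------------------------------------------------------------------------


def measure_slice(img: SliceImage, config: ImagingConfig = ImagingConfig()) -> SliceMeasurement:
    """Run the full per-slice protocol and return pixel areas.

    Order of operations mirrors the bench protocol: segment tissue, split
    hemispheres, detect Evans blue on the raw colours, then apply the blue
    filter and threshold the infarct.  Infarct pixels are counted over the
    whole tissue; blue pixels over the ipsilateral hemisphere (the occluded
    side) unless ``blue_scope="slice"``.
    """
    try:
        tissue = segment_tissue(
            img,
            background=config.background,
            min_object_px=config.min_object_px,
            tolerance=config.background_tolerance,
        )
        left, right = split_hemispheres(tissue, config.orientation, config.midline)
        blue = detect_blue_area(img, tissue, config.blue_margin)
        if config.use_blue_filter:
            gray = apply_blue_filter(img, config.filter_coefficients)
        else:
            gray = to_grayscale(img)
        inf = classify_infarct(
            gray,
            tissue,
            method=config.threshold_method,
            level=config.threshold_level,
            min_contrast=config.min_contrast,
        )
    except (ValueError, NoTissueError, DegenerateSplitError) as exc:
        raise type(exc)(f"slice {img.slice_index}: {exc}") from exc

    if config.blue_scope == "slice":
        blue_count = int(blue.sum())
    elif config.blue_scope == "ipsilateral":
        ipsi = right if config.ipsilateral == "right" else left
        blue_count = int((blue & ipsi.pixels).sum())
    else:
        raise ValueError("blue_scope must be 'ipsilateral' or 'slice'")

    return SliceMeasurement(
        slice_index=img.slice_index,
        left_area_px=left.area_px,
        right_area_px=right.area_px,
        infarct_area_px=inf.area_px,
        blue_area_px=blue_count,
        flags=inf.flags,
    )
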