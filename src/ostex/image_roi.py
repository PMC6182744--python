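"""Image/ROI containers, loading and grey-level quantization.

A knee/timepoint is represented as a :class:`SliceSeries`: the five most
central coronal slices, each paired with boolean masks for the medial tibial
and medial femoral subchondral bone.  Texture computation operates on
:class:`QuantizedROI` objects obtained by min-max binning of the in-mask
intensities into ``2**bits`` grey levels (4 bits for gradient features,
6 bits for co-occurrence and run-length features).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

REGION_LABELS = ("medial_tibia", "medial_femur")

#: Shorthand accepted in manifests / CLI for the two regions.
REGION_ALIASES = {
    "tibia": "medial_tibia",
    "tibial": "medial_tibia",
    "medial_tibia": "medial_tibia",
    "femur": "medial_femur",
    "femoral": "medial_femur",
    "medial_femur": "medial_femur",
}


class GeometryError(ValueError):
    """Image/mask shapes are incompatible."""


class InputError(ValueError):
    """Malformed or missing study input."""


@dataclass(frozen=True)
class GrayImage:
    """One 2-D grayscale slice in arbitrary scanner units."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise GeometryError(f"image must be 2-D, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise GeometryError(f"image too small: {px.shape} (need >= 8x8)")
        if not np.all(np.isfinite(px)):
            raise InputError("image contains non-finite intensities")
        if px.min() < 0:
            raise InputError("image contains negative intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROIMask:
    """Boolean region over one slice; nonzero = inside the ROI."""

    mask: np.ndarray
    region_label: str

    MIN_PIXELS = 64

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2:
            raise GeometryError(f"mask must be 2-D, got shape {m.shape}")
        label = REGION_ALIASES.get(str(self.region_label))
        if label is None:
            raise InputError(
                f"unknown region label {self.region_label!r}; "
                f"expected one of {sorted(REGION_ALIASES)}"
            )
        if int(m.sum()) < self.MIN_PIXELS:
            raise InputError(
                f"ROI {label!r} has {int(m.sum())} pixels; need >= {self.MIN_PIXELS}"
            )
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "region_label", label)

    def check_congruent(self, image: GrayImage) -> None:
        if self.mask.shape != image.pixels.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{image.pixels.shape}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Slice:
    """One coronal image with its per-region masks."""

    image: GrayImage
    masks: dict[str, ROIMask]

    def __post_init__(self) -> None:
        for mask in self.masks.values():
            mask.check_congruent(self.image)


@dataclass
class SliceSeries:
    """Ordered central slices for one knee at one timepoint."""

    slices: list[Slice]
    subject_id: str | None = None
    timepoint: str | None = None

    DEFAULT_N_SLICES = 5

    def __post_init__(self) -> None:
        if not self.slices:
            raise InputError("SliceSeries requires at least one slice")
        shape0 = self.slices[0].image.pixels.shape
        for s in self.slices[1:]:
            if s.image.pixels.shape != shape0:
                raise GeometryError("all slices in a series must share dimensions")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.slices[0].masks)


@dataclass(frozen=True)
class QuantizedROI:
    """In-mask pixels binned to integer grey levels in ``[1, 2**bits]``.

    ``grid`` keeps the levels in place on the full image grid (0 outside
    the mask) so spatial features can address neighbours; ``levels`` is the
    flat in-mask view.
    """

    grid: np.ndarray
    mask: np.ndarray
    bits: int
    degenerate: bool = False

    @property
    def levels(self) -> np.ndarray:
        return self.grid[self.mask]

    @property
    def n_levels(self) -> int:
        return 1 << self.bits

    @property
    def positions(self) -> np.ndarray:
        return np.argwhere(self.mask)


def quantize(
    image: GrayImage | np.ndarray,
    mask: ROIMask | np.ndarray,
    bits: int,
    *,
    normalization: str = "minmax",
    sigma_width: float = 3.0,
) -> QuantizedROI:
    """Bin in-mask intensities into ``2**bits`` equal-width grey levels.

    The default window is the ROI min-max: bin edges are half-open
    ``[lo, hi)`` with the top edge closed, so the in-mask minimum maps to
    level 1 and the maximum to level ``2**bits``.  ``normalization="sigma"``
    instead windows at mean +/- ``sigma_width``*SD with values clipped into
    the window.  A constant ROI quantizes to all level 1 and is flagged
    degenerate.
    """
    if bits not in (4, 6):
        raise ValueError(f"bits must be 4 or 6, got {bits}")
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask).astype(bool)
    if m.shape != px.shape:
        raise GeometryError(f"mask shape {m.shape} != image shape {px.shape}")

    values = px[m]
    n_levels = 1 << bits
    if normalization == "minmax":
        lo, hi = float(values.min()), float(values.max())
    elif normalization == "sigma":
        mu, sd = float(values.mean()), float(values.std())
        lo, hi = mu - sigma_width * sd, mu + sigma_width * sd
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    grid = np.zeros(px.shape, dtype=np.int16)
    if hi <= lo:  # constant ROI
        grid[m] = 1
        return QuantizedROI(grid=grid, mask=m, bits=bits, degenerate=True)

    scaled = (px[m] - lo) / (hi - lo)  # [0, 1] for minmax; may exceed for sigma
    levels = np.floor(np.clip(scaled, 0.0, None) * n_levels).astype(np.int16) + 1
    np.clip(levels, 1, n_levels, out=levels)  # closes the top edge
    grid[m] = levels
    return QuantizedROI(grid=grid, mask=m, bits=bits, degenerate=False)


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale slice from PNG/TIFF or NIfTI as a float array."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    suffixes = "".join(path.suffixes[-2:])
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        return np.squeeze(data)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an RGB(A) export
        arr = arr[..., 0]
    return arr.astype(float)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an ROI mask; any nonzero pixel is in-ROI."""
    return read_image(path) > 0


def write_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 16-bit grayscale PNG (intensities clipped to uint16 range)."""
    import imageio.v3 as iio

    arr = np.round(np.clip(np.asarray(pixels), 0, 65535)).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask).astype(np.uint8) * 255))


def load_slice_series(
    image_paths: Sequence[str | Path],
    mask_paths: dict[str, Sequence[str | Path]],
    *,
    subject_id: str | None = None,
    timepoint: str | None = None,
    allow_short: bool = False,
) -> SliceSeries:
    """Load an ordered slice series with per-region masks.

    ``mask_paths`` maps region label -> one mask path per slice, in the
    same order as ``image_paths``.  Fewer than five slices raises unless
    ``allow_short`` (then a warning is logged and analysis proceeds).
    """
    missing = set(REGION_LABELS) - {REGION_ALIASES.get(k) for k in mask_paths}
    if missing:
        raise InputError(f"mask_paths missing region(s): {sorted(missing)}")
    for region, paths in mask_paths.items():
        if len(paths) != len(image_paths):
            raise InputError(
                f"region {region!r}: {len(paths)} masks for {len(image_paths)} images"
            )
    if len(image_paths) < SliceSeries.DEFAULT_N_SLICES:
        msg = (
            f"series has {len(image_paths)} slices "
            f"(expected {SliceSeries.DEFAULT_N_SLICES})"
        )
        if not allow_short:
            raise InputError(msg + "; pass allow_short=True to proceed")
        logger.warning("%s; proceeding (allow_short)", msg)
        warnings.warn(msg, stacklevel=2)

    slices = []
    for i, img_path in enumerate(image_paths):
        image = GrayImage(read_image(img_path))
        masks = {}
        for region, paths in mask_paths.items():
            label = REGION_ALIASES[region]
            roi = ROIMask(read_mask(paths[i]), label)
            roi.check_congruent(image)
            masks[label] = roi
        slices.append(Slice(image=image, masks=masks))
    return SliceSeries(slices=slices, subject_id=subject_id, timepoint=timepoint)
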