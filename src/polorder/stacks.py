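"""Four-polarization image stacks: I/O, flat-field correction, normalization.

Excitation-resolved fluorescence polarization microscopy acquires, per field of
view, four co-registered images at excitation polarizations of 0°, 45°, 90° and
135° relative to the positive x-axis. This module houses the stack containers
and the pre-processing chain that feeds the order-factor computation:

1. flat-field correction — element-wise division by a normalized reference
   stack acquired on a uniformly autofluorescent slide;
2. pixel-wise normalization — each pixel's four intensities divided by their
   maximum across polarizations;
3. average-intensity image — per-pixel mean of the corrected stack, used for
   segmentation and signal/background estimation.

Coordinate convention: row-major rasters, origin top-left, x increases with
column index, y increases with row index; polarization and azimuth angles are
measured from the positive x-axis, positive counterclockwise in the (x, -y
screen) frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger("polorder")

POL_ANGLES = (0, 45, 90, 135)

#: Flat-field elements below this fraction of the stack maximum are rejected.
FLAT_FIELD_EPS = 1e-6


def _validate_images(images: np.ndarray, what: str) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3 or images.shape[0] != 4:
        raise ValueError(f"{what}: expected 4 images of identical shape, got array of shape {images.shape}")
    if not np.all(np.isfinite(images)):
        raise ValueError(f"{what}: intensities must be finite")
    return images


@dataclass
class PolarizationStack:
    """Four co-registered intensity images, one per excitation polarization.

    ``images`` has shape ``(4, rows, cols)`` ordered I0, I45, I90, I135.
    """

    images: np.ndarray
    pol_angles: tuple = POL_ANGLES
    pixel_size: float | None = None
    field_id: str = ""
    #: acquisition metadata only, never used in computation
    exposure_ms: float | None = None
    laser_mw: float | None = None

    def __post_init__(self):
        self.images = _validate_images(self.images, "PolarizationStack")
        if tuple(self.pol_angles) != POL_ANGLES:
            raise ValueError(f"pol_angles must be {POL_ANGLES} in storage order")
        if np.any(self.images < 0):
            raise ValueError("PolarizationStack: intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class FlatFieldStack:
    """Normalized flat-field reference; global maximum equals 1, all elements > 0."""

    images: np.ndarray
    source_count: int = 1
    flat_id: str = ""

    def __post_init__(self):
        self.images = _validate_images(self.images, "FlatFieldStack")
        mx = float(self.images.max())
        if not np.isclose(mx, 1.0):
            raise ValueError(f"FlatFieldStack: global maximum must be 1, got {mx}")
        if np.any(self.images <= FLAT_FIELD_EPS):
            raise ValueError(
                "FlatFieldStack: contains elements <= "
                f"{FLAT_FIELD_EPS} of the maximum; division semantics undefined"
            )


@dataclass
class CorrectedStack:
    """Flat-field corrected stack; same dimensions as the raw input."""

    images: np.ndarray
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.images = _validate_images(self.images, "CorrectedStack")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class NormalizedStack:
    """Pixel-wise max-normalized stack.

    At every valid pixel the maximum across the four polarizations equals 1;
    pixels whose four-channel maximum was 0 are flagged invalid and carry 0.
    """

    images: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.images = _validate_images(self.images, "NormalizedStack")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.images.shape[1:], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.images.shape[1:]:
            raise ValueError("valid_mask shape must match image shape")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, field_id: str | None = None) -> PolarizationStack:
    """Read one four-page TIFF as a PolarizationStack (page order I0, I45, I90, I135)."""
    stacks = read_stacks(path, layout="sequential")
    if len(stacks) != 1:
        raise ValueError(f"{path}: expected 4 pages per field, found {4 * len(stacks)} pages; use read_stacks for multi-field files")
    st = stacks[0]
    if field_id is not None:
        st.field_id = field_id
    return st


def read_stacks(path: str | Path, layout: str = "sequential") -> list[PolarizationStack]:
    """Read a multi-page TIFF holding one or more four-polarization stacks.

    Parameters
    ----------
    layout : {"sequential", "interleaved"}
        "sequential": pages grouped per field (f0:I0,I45,I90,I135, f1:...).
        "interleaved": pages grouped per polarization angle
        (I0 of every field, then I45 of every field, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D grayscale pages, got shape {pages.shape}")
    n = pages.shape[0]
    if n < 4 or n % 4:
        raise ValueError(f"{path}: expected 4 pages per field, got {n} pages")
    n_fields = n // 4
    if layout == "sequential":
        per_field = [pages[4 * i: 4 * (i + 1)] for i in range(n_fields)]
    elif layout == "interleaved":
        per_field = [pages[i::n_fields] for i in range(n_fields)]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return [
        PolarizationStack(imgs.astype(np.float64), field_id=f"{path.stem}:{i}")
        for i, imgs in enumerate(per_field)
    ]


def write_stack(images: np.ndarray | PolarizationStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write four rasters as a multi-page TIFF (page order I0, I45, I90, I135).

    Simulated raw data is written as 16-bit unsigned integers; corrected and
    derived rasters as 32-bit float (``dtype="float32"``).
    """
    if isinstance(images, PolarizationStack):
        images = images.images
    images = np.asarray(images)
    path = Path(path)
    if dtype == "uint16":
        out = np.clip(np.rint(images), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype == "float32":
        out = images.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Correction chain
# ---------------------------------------------------------------------------

def build_flat_field(raw_flat_stacks: Sequence[PolarizationStack]) -> FlatFieldStack:
    """Average reference stacks per polarization, then divide by the global maximum.

    The reference stacks are acquired at different locations on a uniformly
    autofluorescent slide; averaging suppresses their shot noise, and the
    single global maximum of the averaged four-image stack sets the scale.
    """
    if len(raw_flat_stacks) == 0:
        raise ValueError("need at least one raw flat-field stack")
    shape = raw_flat_stacks[0].shape
    for st in raw_flat_stacks:
        if st.shape != shape:
            raise ValueError("flat-field stacks have inconsistent dimensions")
    mean = np.mean([st.images for st in raw_flat_stacks], axis=0)
    mx = float(mean.max())
    if mx <= 0:
        raise ValueError("flat-field stacks are all zero; cannot normalize")
    norm = mean / mx
    if np.any(norm <= FLAT_FIELD_EPS):
        raise ValueError(
            "flat field contains elements <= "
            f"{FLAT_FIELD_EPS} of the maximum; acquire brighter references"
        )
    return FlatFieldStack(norm, source_count=len(raw_flat_stacks))


def flat_field_correct(raw: PolarizationStack, flat: FlatFieldStack) -> CorrectedStack:
    """Divide each element of the raw stack by the matching flat-field element."""
    if raw.images.shape != flat.images.shape:
        raise ValueError(
            f"dimension mismatch: raw {raw.images.shape} vs flat {flat.images.shape}"
        )
    corrected = raw.images / flat.images
    if not np.all(np.isfinite(corrected)):
        raise ValueError("flat-field correction produced non-finite values")
    logger.info("flat-field corrected field=%s flat=%s", raw.field_id, flat.flat_id)
    return CorrectedStack(corrected, provenance=(raw.field_id, flat.flat_id))


def normalize_stack(corrected: CorrectedStack) -> NormalizedStack:
    """Divide each pixel's four intensities by their maximum across polarizations.

    Pixels whose four-channel maximum is 0 carry value 0 and are flagged
    invalid; 0/0 has no physical meaning and the flag propagates downstream.
    """
    imgs = corrected.images
    mx = imgs.max(axis=0)
    valid = mx > 0
    out = np.zeros_like(imgs)
    np.divide(imgs, mx[None], out=out, where=valid[None])
    return NormalizedStack(out, valid_mask=valid)


def average_intensity(corrected: CorrectedStack) -> np.ndarray:
    """Per-pixel arithmetic mean of the four corrected images."""
    return corrected.images.mean(axis=0)
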