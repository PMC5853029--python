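"""Image I/O and the preprocessing utilities used around the classifier."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = ["ImageRecord", "read_image", "write_image", "remove_artifact",
           "select_best_focus"]

log = logging.getLogger("focusqc")


@dataclass
class ImageRecord:
    """A single-channel 16-bit image plus provenance metadata."""

    pixels: np.ndarray
    path: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("ImageRecord holds single-channel 2-D data")
        if px.dtype != np.uint16:
            if np.any(px < 0) or np.any(px > 65535):
                raise ValueError("pixel values outside the 16-bit range")
            px = px.astype(np.uint16)
        self.pixels = px


def read_image(path: str | Path) -> ImageRecord:
    """Read a 16-bit grayscale TIFF or PNG.

    8-bit input is promoted to 16-bit by multiplying by 257 (so 255 maps to
    65535), logged at INFO.  Color input raises: convert to grayscale
    explicitly before calling.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported format {path.suffix!r} (TIFF or PNG)")
    if arr.ndim == 3:
        raise ValueError(
            f"{path} is multi-channel; convert to single-channel grayscale "
            "first (e.g. select one channel)")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(
            f"{path} holds float data; convert to 16-bit counts first")
    if arr.dtype == np.uint8:
        log.info("promoting 8-bit image %s to 16-bit (values x 257)", path)
        arr = arr.astype(np.uint16) * 257
    return ImageRecord(pixels=arr.astype(np.uint16), path=str(path))


def write_image(record: ImageRecord | np.ndarray, path: str | Path) -> None:
    """Write 16-bit data losslessly as TIFF or PNG."""
    path = Path(path)
    px = record.pixels if isinstance(record, ImageRecord) else \
        ImageRecord(np.asarray(record)).pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, px)
    else:
        raise ValueError(f"unsupported format {path.suffix!r} (TIFF or PNG)")


def remove_artifact(image: np.ndarray, constant: int = 1000) -> np.ndarray:
    """Subtract a constant sensor artifact and clip at zero.

    Removes an additive bright-pixel camera artifact by subtracting
    ``constant`` from every pixel and clipping the result at zero.
    """
    img = np.asarray(image)
    return np.maximum(img.astype(np.int64) - constant, 0).astype(img.dtype)


def select_best_focus(stack: list[ImageRecord]) -> ImageRecord:
    """The stack member with the largest pixel standard deviation.

    For sparse bright scenes, defocus spreads intensity and lowers the
    variance, so the sharpest plane maximizes the standard deviation.
    Ties go to the lowest index.
    """
    if not stack:
        raise ValueError("empty stack")
    stds = [float(np.std(rec.pixels.astype(np.float64))) for rec in stack]
    return stack[int(np.argmax(stds))]
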