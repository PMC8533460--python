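"""Raster image container shared by both imaging modalities.

Coordinates are physical nanometres throughout the public interfaces:
the origin sits at the *center* of the top-left pixel, ``x`` runs along
columns and ``y`` along rows, so pixel ``(row, col)`` has center
``(x, y) = (col * pixel_size_nm[0], row * pixel_size_nm[1])``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)


class UnsupportedFormatError(ValueError):
    """Raised for image files the pipeline cannot interpret."""


@dataclass
class RasterImage:
    """A 2-D intensity grid with physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Non-negative intensities.
    pixel_size_nm : (float, float)
        Physical pixel pitch ``(x, y)`` in nanometres.
    modality : str
        Free-form tag, conventionally ``"tirf"`` or ``"esem"``.
    """

    data: np.ndarray
    pixel_size_nm: tuple[float, float]
    modality: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("image data must be a non-empty 2-D array")
        if np.isscalar(self.pixel_size_nm):
            self.pixel_size_nm = (float(self.pixel_size_nm),) * 2
        else:
            self.pixel_size_nm = tuple(float(p) for p in self.pixel_size_nm)
        if len(self.pixel_size_nm) != 2 or min(self.pixel_size_nm) <= 0:
            raise ValueError("pixel_size_nm must be two positive lengths")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def field_nm(self) -> tuple[float, float]:
        """Physical extent (width, height) spanned by pixel centers plus one pitch."""
        rows, cols = self.data.shape
        return cols * self.pixel_size_nm[0], rows * self.pixel_size_nm[1]

    def px_to_nm(self, rowcol: np.ndarray) -> np.ndarray:
        """Convert ``(row, col)`` (possibly fractional) to ``(x, y)`` nm."""
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        out = np.column_stack(
            [rc[:, 1] * self.pixel_size_nm[0], rc[:, 0] * self.pixel_size_nm[1]]
        )
        return out if np.asarray(rowcol).ndim > 1 else out[0]

    def nm_to_px(self, xy: np.ndarray) -> np.ndarray:
        """Convert ``(x, y)`` nm to fractional ``(row, col)``."""
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.column_stack(
            [p[:, 1] / self.pixel_size_nm[1], p[:, 0] / self.pixel_size_nm[0]]
        )
        return out if np.asarray(xy).ndim > 1 else out[0]


def read_image(path, pixel_size_nm=None, modality: str = "unknown") -> RasterImage:
    """Read a single-page grayscale TIFF into a :class:`RasterImage`.

    ``pixel_size_nm`` from the argument wins over TIFF resolution metadata;
    a mismatch between the two is logged as a warning, never an error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise UnsupportedFormatError(
                f"{path}: expected a single-page TIFF, found {len(tf.pages)} pages; "
                "split channels/planes before loading"
            )
        page = tf.pages[0]
        data = page.asarray()
        meta_px = _pixel_size_from_tags(page)
    if data.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: expected single-channel grayscale data, got shape {data.shape}"
        )
    if pixel_size_nm is None:
        if meta_px is None:
            raise UnsupportedFormatError(
                f"{path}: no resolution metadata; pass pixel_size_nm explicitly"
            )
        pixel_size_nm = meta_px
    elif meta_px is not None:
        arg = (pixel_size_nm,) * 2 if np.isscalar(pixel_size_nm) else tuple(pixel_size_nm)
        if not np.allclose(arg, meta_px, rtol=1e-3):
            msg = (
                f"{path}: metadata pixel size {meta_px} nm disagrees with "
                f"argument {arg} nm; using the argument"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
    return RasterImage(data, pixel_size_nm, modality)


def write_image(path, image: RasterImage) -> None:
    """Write as single-page TIFF with pixel size stored in resolution tags."""
    px, py = image.pixel_size_nm
    # TIFF resolution = pixels per unit; use centimetres (1 cm = 1e7 nm).
    tifffile.imwrite(
        str(path),
        image.data,
        resolution=(1e7 / px, 1e7 / py),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def _pixel_size_from_tags(page) -> tuple[float, float] | None:
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit))  # inch, cm
    if unit_nm is None:
        return None

    def to_nm(res):
        num, den = (res if isinstance(res, tuple) else (res, 1))
        if num == 0:
            return None
        return unit_nm * den / num

    px, py = to_nm(xres), to_nm(yres)
    if px is None or py is None:
        return None
    return px, py
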