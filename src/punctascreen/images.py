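"""Single-channel fluorescence image container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class FluorImage:
    """One single-channel 2D intensity raster — the unit of acquisition.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities. Stored as float64 so that noise-free
        expectation images keep sub-integer values; values must lie in
        ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        Camera bit depth (8 or 16 typical); defines the saturation value.
    well_id, field_id : str, optional
        Provenance identifiers for plate-based workflows.
    pixel_size : float, optional
        Pixel edge length in µm, when known; enables areas in µm².
    """

    pixels: np.ndarray
    bit_depth: int = 16
    well_id: str | None = None
    field_id: str | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={self.pixels.ndim}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth: {self.bit_depth}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > self.max_value):
            raise ValueError(
                f"pixel values outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> float:
        """Largest representable intensity (saturation level)."""
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def saturated_mask(self) -> np.ndarray:
        """Boolean mask of pixels at the saturation value."""
        return self.pixels >= self.max_value


def save_tiff(image: FluorImage, path: str | Path) -> Path:
    """Write the image as an unsigned-integer single-channel TIFF."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = np.clip(np.rint(image.pixels), 0, image.max_value).astype(dtype)
    tifffile.imwrite(path, data)
    return path


def load_tiff(
    path: str | Path,
    *,
    bit_depth: int | None = None,
    well_id: str | None = None,
    field_id: str | None = None,
    pixel_size: float | None = None,
) -> FluorImage:
    """Read a single-channel TIFF into a :class:`FluorImage`.

    Bit depth is inferred from the stored dtype unless given explicitly.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D TIFF, got shape {data.shape}")
    if bit_depth is None:
        bit_depth = 8 if data.dtype == np.uint8 else 16
    return FluorImage(
        pixels=data.astype(np.float64),
        bit_depth=bit_depth,
        well_id=well_id,
        field_id=field_id,
        pixel_size=pixel_size,
    )
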