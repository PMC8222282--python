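"""Multi-channel cell image container and OME-TIFF I/O.

Coordinate convention used throughout the package: images are 0-based
row-major rasters; the physical coordinate of pixel ``(row, col)`` is the
pixel *center* at ``(x, y) = (col * pixel_size_nm, row * pixel_size_nm)``.
All physical quantities are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class CellImage:
    """A set of equally shaped 2D intensity channels with a physical pixel size.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Named 2D non-negative intensity rasters, all of identical shape.
    pixel_size_nm : float
        Physical pixel pitch in nanometres (sample scale, i.e. already
        corrected for any expansion factor).
    z_index : int, optional
        Index of the z-plane this image was taken from, if part of a stack.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    z_index: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("CellImage needs at least one channel")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share one shape, got {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def stack(self) -> np.ndarray:
        """Channels stacked into a (C, Y, X) array in insertion order."""
        return np.stack([self.channels[n] for n in self.channels], axis=0)

    def pixel_centers_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every pixel center, each shaped like the raster."""
        ny, nx = self.shape
        y, x = np.mgrid[0:ny, 0:nx].astype(float)
        return x * self.pixel_size_nm, y * self.pixel_size_nm


def write_ome_tiff(path, image: CellImage) -> None:
    """Write channels as separate planes of an OME-TIFF with physical pixel size."""
    um = image.pixel_size_nm / 1000.0
    data = image.stack().astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": image.channel_names},
        },
        ome=True,
    )


def read_ome_tiff(path, pixel_size_nm: float | None = None) -> CellImage:
    """Read a (C, Y, X) OME-TIFF written by :func:`write_ome_tiff`.

    ``pixel_size_nm`` overrides the file metadata when given (plain TIFFs
    without OME metadata require it).
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        names = None
        px = pixel_size_nm
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pix = root.find(".//ome:Pixels", ns)
            if pix is not None:
                if px is None and pix.get("PhysicalSizeX"):
                    px = float(pix.get("PhysicalSizeX")) * 1000.0
                ch_names = [c.get("Name") for c in pix.findall("ome:Channel", ns)]
                if ch_names and all(n is not None for n in ch_names):
                    names = ch_names
    if px is None:
        raise ValueError("pixel size not found in metadata; pass pixel_size_nm")
    if data.ndim == 2:
        data = data[None]
    if names is None or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    channels = {n: np.asarray(data[i], dtype=float) for i, n in enumerate(names)}
    return CellImage(channels=channels, pixel_size_nm=px)
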