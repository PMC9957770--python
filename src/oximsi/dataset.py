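"""In-memory container for centroided mass spectrometry imaging data.

Spectra are stored as flat, pixel-sorted peak arrays so that ion-image
construction is a single vectorized pass.  imzML round-tripping uses
pyimzml (processed mode, centroided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MSIDataset"]


@dataclass
class MSIDataset:
    """A pixel grid of centroided spectra.

    Parameters
    ----------
    shape
        (n_rows, n_cols) of the pixel grid.
    pixel_px, peak_mz, peak_intensity
        Flat peak table: for peak *i*, ``pixel_px[i]`` is the flattened
        (row-major) pixel index, with m/z and intensity alongside.  Sorted
        by pixel index on construction.
    pixel_size_um
        Physical size of one pixel (raster step), micrometres.
    """

    shape: tuple[int, int]
    pixel_px: np.ndarray
    peak_mz: np.ndarray
    peak_intensity: np.ndarray
    pixel_size_um: float = 75.0
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.pixel_px = np.asarray(self.pixel_px, dtype=np.int64)
        self.peak_mz = np.asarray(self.peak_mz, dtype=np.float64)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=np.float64)
        if not (len(self.pixel_px) == len(self.peak_mz) == len(self.peak_intensity)):
            raise ValueError("peak arrays must have equal length")
        if np.any(self.peak_intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(self.pixel_px, kind="stable")
        self.pixel_px = self.pixel_px[order]
        self.peak_mz = self.peak_mz[order]
        self.peak_intensity = self.peak_intensity[order]
        n = self.n_pixels
        if len(self.pixel_px) and (self.pixel_px[0] < 0 or self.pixel_px[-1] >= n):
            raise ValueError("pixel index out of range")
        self._offsets = np.searchsorted(self.pixel_px, np.arange(n + 1))

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def spectrum(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        """Centroided spectrum (m/z, intensity) at one pixel."""
        idx = row * self.shape[1] + col
        lo, hi = self._offsets[idx], self._offsets[idx + 1]
        return self.peak_mz[lo:hi], self.peak_intensity[lo:hi]

    def physical_coords_um(self, row: int, col: int) -> tuple[float, float]:
        return row * self.pixel_size_um, col * self.pixel_size_um

    # -- imzML I/O ---------------------------------------------------------

    def write_imzml(self, path) -> None:
        """Write as processed-mode centroided imzML (+ .ibd sidecar)."""
        from pyimzml.ImzMLWriter import ImzMLWriter

        with ImzMLWriter(str(path), mode="processed") as writer:
            for row in range(self.shape[0]):
                for col in range(self.shape[1]):
                    mzs, ints = self.spectrum(row, col)
                    # imzML coordinates are 1-based (x, y)
                    writer.addSpectrum(mzs, ints, (col + 1, row + 1))

    @classmethod
    def read_imzml(cls, path, pixel_size_um: float = 75.0) -> "MSIDataset":
        from pyimzml.ImzMLParser import ImzMLParser

        parser = ImzMLParser(str(path))
        coords = np.asarray([(y - 1, x - 1) for (x, y, *_rest) in parser.coordinates])
        nrows = int(coords[:, 0].max()) + 1
        ncols = int(coords[:, 1].max()) + 1
        px_list, mz_list, int_list = [], [], []
        for i, (r, c) in enumerate(coords):
            mzs, ints = parser.getspectrum(i)
            mzs = np.asarray(mzs, dtype=np.float64)
            ints = np.asarray(ints, dtype=np.float64)
            px_list.append(np.full(len(mzs), r * ncols + c, dtype=np.int64))
            mz_list.append(mzs)
            int_list.append(ints)
        return cls(
            shape=(nrows, ncols),
            pixel_px=np.concatenate(px_list) if px_list else np.empty(0, np.int64),
            peak_mz=np.concatenate(mz_list) if mz_list else np.empty(0),
            peak_intensity=np.concatenate(int_list) if int_list else np.empty(0),
            pixel_size_um=pixel_size_um,
        )
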