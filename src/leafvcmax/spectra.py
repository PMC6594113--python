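"""The :class:`Spectrum` carrier used throughout the package.

A spectrum is a pair of equally long arrays: a strictly increasing
wavelength grid in nanometres and the values sampled on it.  The same
container carries radiances (flux per nm), reflectance/transmittance
(dimensionless), specific absorption coefficients and fluorescence
emission, so no unit is enforced here; role-specific contracts (e.g.
rho/tau in [0, 1]) are checked by the operations that need them.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError, GridError

__all__ = ["Spectrum", "GRID_FULL", "GRID_EXCITATION", "GRID_EMISSION"]

#: 1 nm grids used by the leaf models (inclusive of both endpoints).
GRID_FULL = np.arange(400.0, 2501.0)
GRID_EXCITATION = np.arange(400.0, 751.0)
GRID_EMISSION = np.arange(640.0, 851.0)


class Spectrum:
    """Wavelength grid plus values; the universal spectral carrier."""

    __slots__ = ("wavelengths", "values")

    def __init__(self, wavelengths, values):
        wl = np.asarray(wavelengths, dtype=float)
        v = np.asarray(values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise GridError(
                f"wavelengths ({wl.shape}) and values ({v.shape}) must be "
                "1-d arrays of equal length"
            )
        if wl.size == 0:
            raise GridError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(v)):
            raise DataError("spectrum contains NaN or infinite values")
        self.wavelengths = wl
        self.values = v

    def __len__(self):
        return self.wavelengths.size

    def __repr__(self):
        return (
            f"Spectrum({self.wavelengths[0]:.0f}-{self.wavelengths[-1]:.0f} nm,"
            f" n={len(self)})"
        )

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at a single wavelength."""
        wl = float(wavelength)
        if wl < self.wavelengths[0] or wl > self.wavelengths[-1]:
            raise GridError(
                f"{wl} nm outside spectral range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return float(np.interp(wl, self.wavelengths, self.values))

    def band(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum on the closed window [lo, hi] nm."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise GridError(f"no samples inside [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[mask], self.values[mask])

    def band_values(self, lo: float, hi: float) -> np.ndarray:
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise GridError(f"no samples inside [{lo}, {hi}] nm")
        return self.values[mask]

    def band_mean(self, lo: float, hi: float) -> float:
        return float(np.mean(self.band_values(lo, hi)))

    def integral(self, lo: float | None = None, hi: float | None = None) -> float:
        """Trapezoidal integral of the values over wavelength [per-nm units]."""
        wl, v = self.wavelengths, self.values
        if lo is not None or hi is not None:
            lo = wl[0] if lo is None else lo
            hi = wl[-1] if hi is None else hi
            mask = (wl >= lo) & (wl <= hi)
            wl, v = wl[mask], v[mask]
        return float(np.trapezoid(v, wl))

    def interp_to(self, wavelengths) -> "Spectrum":
        """Interpolate onto a new grid (must lie inside the current range)."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl[0] < self.wavelengths[0] or wl[-1] > self.wavelengths[-1]:
            raise GridError(
                "target grid extends beyond the spectrum's coverage "
                f"([{self.wavelengths[0]}, {self.wavelengths[-1]}] nm)"
            )
        return Spectrum(wl, np.interp(wl, self.wavelengths, self.values))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * float(factor))

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.wavelengths, other.wavelengths))
        )


def require_same_grid(*spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridError("spectra are not on a common wavelength grid")


def require_unit_interval(s: Spectrum, what: str = "spectrum") -> None:
    if np.any(s.values < 0.0) or np.any(s.values > 1.0):
        raise DataError(f"{what} has values outside [0, 1]")
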