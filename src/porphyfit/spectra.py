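"""Absorbance/emission spectra containers and Soret-band utilities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Spectrum", "differential_spectrum", "find_soret_peak"]


@dataclass
class Spectrum:
    """One wavelength-resolved trace (absorbance in AU or emission in counts)."""

    wavelengths: np.ndarray  # nm, strictly ascending
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


def differential_spectrum(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Pointwise sample − reference on an identical wavelength grid.

    This reproduces the reference-read protocol in which ligand-in-buffer is
    measured alongside ligand-plus-protein: the difference isolates the
    spectral change caused by complex formation (e.g. the Soret red shift).
    Grids must match exactly; no silent interpolation.
    """
    if sample.wavelengths.shape != reference.wavelengths.shape or not np.array_equal(
        sample.wavelengths, reference.wavelengths
    ):
        raise ValueError("sample and reference wavelength grids differ")
    return Spectrum(sample.wavelengths.copy(), sample.values - reference.values)


def find_soret_peak(spectrum: Spectrum, search_window: tuple[float, float]) -> float | None:
    """Peak wavelength within a window, refined by quadratic interpolation.

    Returns None when the trace is monotone in the window (no interior
    maximum), which distinguishes a genuine band from a rising shoulder.
    """
    lo, hi = search_window
    if lo >= hi:
        raise ValueError("search window must satisfy lo < hi")
    wl, val = spectrum.wavelengths, spectrum.values
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError("search window extends beyond spectrum range")
    mask = (wl >= lo) & (wl <= hi)
    w = wl[mask]
    v = val[mask]
    if w.size < 3:
        raise ValueError("fewer than 3 samples inside search window")
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1:
        return None  # monotone within window
    # Quadratic through the three samples around the discrete argmax
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(w[i])
    # Offset of vertex in grid units, assuming locally uniform spacing
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (w[i + 1] - w[i - 1])
    return float(w[i] + delta * step)
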