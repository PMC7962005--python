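"""Steady-state emission spectrum processing.

Implements the standard corrections applied to protein emission scans
before interpretation: blank (buffer) subtraction, inner-filter-effect
correction, peak normalisation, normalised difference spectra and band
(maximum / shoulder) location.

The inner-filter factor is the usual half-absorbance antilog form

    G = 10 ** ((dA_exc + dA_em) / 2)

where ``dA_exc`` and ``dA_em`` are the absorbance changes at the
excitation and emission wavelengths caused by adding the chromophore.
Normalisation divides a corrected spectrum by its maximum so that
spectra of samples at different concentrations can be compared and
subtracted point-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import argrelmin, find_peaks, savgol_filter


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan at a fixed excitation wavelength.

    Parameters
    ----------
    exc_wavelength : float
        Excitation wavelength in nm.
    wavelengths : ndarray
        Strictly increasing emission wavelength grid in nm.
    intensities : ndarray
        Nonnegative intensities (counts, or dimensionless once
        normalised).
    corrections_applied : frozenset of str
        Subset of ``{"blank", "inner_filter", "normalized"}``.
    """

    exc_wavelength: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    corrections_applied: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or w.shape != i.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if w.size < 2 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)
        object.__setattr__(self, "corrections_applied", frozenset(self.corrections_applied))

    @property
    def is_normalized(self) -> bool:
        return "normalized" in self.corrections_applied

    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.intensities))])


def inner_filter_factor(delta_A_exc: float, delta_A_em: float) -> float:
    """Inner-filter correction factor G = 10**((dA_exc + dA_em)/2).

    Both arguments are absorbance changes (dimensionless, >= 0); the
    returned factor is >= 1 and multiplies the blank-subtracted
    intensities.
    """
    if delta_A_exc < 0 or delta_A_em < 0:
        raise ValueError("absorbance changes must be nonnegative")
    return float(10.0 ** ((delta_A_exc + delta_A_em) / 2.0))


def _align_grids(a: EmissionSpectrum, b: EmissionSpectrum) -> EmissionSpectrum:
    """Return *b* resampled onto *a*'s grid, or raise on gross mismatch.

    Linear interpolation is allowed only when the two grid steps differ
    by at most 1 nm; anything coarser is treated as a user error.
    """
    if a.wavelengths.shape == b.wavelengths.shape and np.allclose(
        a.wavelengths, b.wavelengths
    ):
        return b
    step_a = float(np.median(np.diff(a.wavelengths)))
    step_b = float(np.median(np.diff(b.wavelengths)))
    if abs(step_a - step_b) > 1.0:
        raise ValueError(
            f"wavelength grids differ by more than 1 nm in step ({step_a} vs {step_b})"
        )
    if a.wavelengths[0] < b.wavelengths[0] - 1e-9 or a.wavelengths[-1] > b.wavelengths[-1] + 1e-9:
        raise ValueError("grids do not overlap over the full target range")
    new_i = np.interp(a.wavelengths, b.wavelengths, b.intensities)
    return replace(b, wavelengths=a.wavelengths.copy(), intensities=new_i)


def correct_spectrum(
    raw: EmissionSpectrum, blank: EmissionSpectrum, G: float = 1.0
) -> EmissionSpectrum:
    """Blank-subtract and inner-filter-correct a raw spectrum.

    ``intensities = clip((raw - blank) * G, 0, inf)``.  Negative
    residuals after blank subtraction carry no physical meaning and are
    clipped at zero.
    """
    if G < 1.0 - 1e-12:
        raise ValueError("inner-filter factor must be >= 1")
    blank = _align_grids(raw, blank)
    corrected = np.clip((raw.intensities - blank.intensities) * G, 0.0, None)
    flags = set(raw.corrections_applied) | {"blank"}
    if G > 1.0:
        flags.add("inner_filter")
    return replace(raw, intensities=corrected, corrections_applied=frozenset(flags))


def normalize_spectrum(s: EmissionSpectrum) -> EmissionSpectrum:
    """Divide by the maximum intensity so that the peak equals 1."""
    m = float(np.max(s.intensities))
    if m <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(
        s,
        intensities=s.intensities / m,
        corrections_applied=frozenset(set(s.corrections_applied) | {"normalized"}),
    )


@dataclass(frozen=True)
class DifferenceSpectrum:
    """Signed point-wise difference of two normalised spectra."""

    wavelengths: np.ndarray
    values: np.ndarray
    min_wavelength: float | None
    max_wavelength: float | None


def difference_spectrum(a: EmissionSpectrum, b: EmissionSpectrum) -> DifferenceSpectrum:
    """Point-wise a - b of two *normalised* spectra, with extrema.

    The wavelengths of the most negative and most positive points are
    reported; for an identically zero difference both are ``None``.
    """
    if not (a.is_normalized and b.is_normalized):
        raise ValueError("difference spectra require normalised inputs")
    b = _align_grids(a, b)
    d = a.intensities - b.intensities
    if np.allclose(d, 0.0):
        return DifferenceSpectrum(a.wavelengths.copy(), d, None, None)
    return DifferenceSpectrum(
        a.wavelengths.copy(),
        d,
        float(a.wavelengths[int(np.argmin(d))]),
        float(a.wavelengths[int(np.argmax(d))]),
    )


def locate_bands(
    s: EmissionSpectrum,
    shoulder_sensitivity: float = 0.01,
    smooth_window: int = 7,
    smooth_order: int = 2,
) -> list[dict]:
    """Locate emission maxima and shoulders.

    Candidate band centres are local minima of the smoothed second
    derivative (band curvature); a candidate coinciding with a local
    maximum of the smoothed intensity is a ``maximum``, otherwise (a
    concave bulge on a flank) it is a ``shoulder``.  Curvature dips
    shallower than ``shoulder_sensitivity`` times the strongest dip are
    ignored.

    Returns a list of ``{"wavelength", "kind"}`` dicts sorted by
    wavelength, ``kind`` in ``{"maximum", "shoulder"}``.
    """
    y = s.intensities
    if np.ptp(y) == 0:
        return []
    n = y.size
    win = min(smooth_window, n if n % 2 == 1 else n - 1)
    if win <= smooth_order:
        raise ValueError("spectrum too short for the requested smoothing window")
    smooth = savgol_filter(y, win, smooth_order)
    step = float(np.median(np.diff(s.wavelengths)))
    d2 = savgol_filter(y, win, max(smooth_order, 2), deriv=2, delta=step)

    maxima_idx, _ = find_peaks(smooth, prominence=shoulder_sensitivity * np.ptp(smooth))
    (cand_idx,) = argrelmin(d2)
    if d2.size and cand_idx.size:
        floor = shoulder_sensitivity * abs(d2.min())
        cand_idx = cand_idx[d2[cand_idx] < -floor]

    bands: list[dict] = []
    used = np.zeros(n, bool)
    for i in maxima_idx:
        bands.append({"wavelength": float(s.wavelengths[i]), "kind": "maximum"})
        lo, hi = max(0, i - 2), min(n, i + 3)
        used[lo:hi] = True
    for i in cand_idx:
        if used[max(0, i - 2) : min(n, i + 3)].any():
            continue
        bands.append({"wavelength": float(s.wavelengths[i]), "kind": "shoulder"})
    bands.sort(key=lambda b: b["wavelength"])
    return bands


def read_spectrum(path, exc_wavelength: float = float("nan")) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) delimited text file."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, intensity)")
    return EmissionSpectrum(exc_wavelength, data[:, 0], data[:, 1])


def write_spectrum(s: EmissionSpectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([s.wavelengths, s.intensities]),
        header="wavelength_nm intensity",
        fmt="%.6g",
    )
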