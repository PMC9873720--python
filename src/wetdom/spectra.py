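"""Absorbance and fluorescence (EEM) processing and CDOM optical indices.

This module holds the measurement-side corrections applied to raw
excitation-emission matrices (blank subtraction, Raman normalization,
inner-filter-effect correction, scatter removal) and the standard optical
indices used to characterise chromophoric dissolved organic matter:
``a254``, SUVA254, spectral slopes and their ratio, the fluorescence
index, and the classical fluorophore peaks B, T, A, M and C.

Conventions
-----------
* Absorbance is stored as *decadic* absorbance for the measured path
  length; the Napierian absorption coefficient ``a(lambda)`` (in 1/m)
  is derived as ``ln(10) * A / path_length``.
* EEM intensity matrices are oriented emission x excitation (rows are
  emission wavelengths), matching the wide on-disk layout.
* Raman normalization uses the integrated water Raman peak of a blank at
  excitation 350 nm over emission 371-428 nm (Lawaetz-Stedmon bounds).
* IFE correction uses the absorbance (ABA) method:
  ``F_corr = F_obs * 10**((A_ex + A_em) / 2)`` with absorbance rescaled
  to a 1 cm path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AbsorbanceSpectrum",
    "EEM",
    "OpticalIndices",
    "ScatterWidths",
    "RAMAN_SHIFT_CM1",
    "raman_emission_wavelength",
    "blank_subtract",
    "raman_area",
    "raman_normalize",
    "ife_correct",
    "remove_scatter",
    "absorption_coefficient",
    "suva254",
    "spectral_slope",
    "slope_ratio",
    "fluorescence_index",
    "pick_peaks",
    "peak_ratio",
    "compute_indices",
]

#: Stokes shift of the water Raman band, in 1/cm.
RAMAN_SHIFT_CM1 = 3400.0

#: Default Raman integration window (emission nm) at excitation 350 nm.
RAMAN_EX_NM = 350.0
RAMAN_EM_WINDOW_NM = (371.0, 428.0)

LN10 = float(np.log(10.0))


def raman_emission_wavelength(ex_nm: np.ndarray | float,
                              shift_cm1: float = RAMAN_SHIFT_CM1):
    """Emission wavelength (nm) of the water Raman band for excitation ``ex_nm``.

    The Raman scatter of water appears red-shifted from the excitation line
    by a fixed energy (~3400 1/cm): ``1/em = 1/ex - shift`` in wavenumbers.
    """
    ex = np.asarray(ex_nm, dtype=float)
    # 1 cm^-1 == 1e-7 nm^-1
    return 1.0 / (1.0 / ex - shift_cm1 * 1e-7)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A decadic absorbance spectrum with its measurement path length.

    Parameters
    ----------
    wavelength
        Strictly increasing wavelength grid in nm.
    absorbance
        Decadic absorbance (dimensionless) at each wavelength, for the
        measured ``path_length``.
    path_length
        Cuvette path length in metres (default 0.01 m = 1 cm).
    """

    wavelength: np.ndarray
    absorbance: np.ndarray
    path_length: float = 0.01

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelength and absorbance must be equal-length 1-D arrays")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.path_length > 0:
            raise ValueError("path_length must be positive")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)

    def value_at(self, wavelength_nm: np.ndarray | float) -> np.ndarray | float:
        """Decadic absorbance at ``wavelength_nm``, linearly interpolated."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside measured range [{lo}, {hi}] nm"
            )
        out = np.interp(lam, self.wavelength, self.absorbance)
        return float(out) if np.isscalar(wavelength_nm) else out

    def absorbance_1cm(self, wavelength_nm) -> np.ndarray | float:
        """Decadic absorbance rescaled to a 1 cm path."""
        scale = 0.01 / self.path_length
        val = self.value_at(wavelength_nm)
        return val * scale


@dataclass
class EEM:
    """An excitation-emission matrix with its correction state.

    ``intensity`` has shape (n_em, n_ex); rows follow ``em``, columns
    follow ``ex``. NaN cells mark removed (missing) data, e.g. scatter
    regions. Correction flags are monotone: an applied correction cannot
    be undone, and operations refuse inputs in the wrong state.
    """

    ex: np.ndarray
    em: np.ndarray
    intensity: np.ndarray
    blank_corrected: bool = False
    raman_normalized: bool = False
    ife_corrected: bool = False
    scatter_removed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ex = np.asarray(self.ex, dtype=float)
        self.em = np.asarray(self.em, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.em.size, self.ex.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"(n_em, n_ex) = ({self.em.size}, {self.ex.size})"
            )
        for grid, name in ((self.ex, "ex"), (self.em, "em")):
            if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing 1-D")

    def same_grids(self, other: "EEM") -> bool:
        return (self.ex.shape == other.ex.shape
                and self.em.shape == other.em.shape
                and np.allclose(self.ex, other.ex)
                and np.allclose(self.em, other.em))

    def copy_with(self, **changes) -> "EEM":
        base = dict(
            ex=self.ex, em=self.em, intensity=self.intensity,
            blank_corrected=self.blank_corrected,
            raman_normalized=self.raman_normalized,
            ife_corrected=self.ife_corrected,
            scatter_removed=self.scatter_removed,
            metadata=dict(self.metadata),
        )
        base.update(changes)
        return EEM(**base)


@dataclass(frozen=True)
class OpticalIndices:
    """Per-sample optical summary of a DOM sample.

    Units: ``a254`` 1/m (Napierian); ``suva254`` L/(mg C·m) (decadic per
    metre over DOC); slopes 1/nm; ``s_r``, ``fi`` and ``a_t_ratio``
    dimensionless; peaks in the EEM's intensity units (Raman units after
    normalization).
    """

    a254: float
    suva254: float
    s275_295: float
    s350_400: float
    s_r: float
    fi: float
    peaks: Mapping[str, float]
    a_t_ratio: float


# ---------------------------------------------------------------------------
# Grid helpers
# ---------------------------------------------------------------------------

def _snap_index(grid: np.ndarray, target: float) -> int:
    """Nearest-grid-point index; half-step ties round toward longer wavelength."""
    d = np.abs(grid - target)
    # last minimiser -> longer wavelength on exact ties
    idx = int(grid.size - 1 - np.argmin(d[::-1]))
    step = np.min(np.diff(grid))
    if d[idx] > step / 2 + 1e-9:
        raise ValueError(
            f"requested wavelength {target} nm is more than half a grid step "
            f"from the nearest grid point ({grid[idx]} nm)"
        )
    return idx


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------

def blank_subtract(sample: EEM, blank: EEM) -> EEM:
    """Subtract an ultrapure-water blank EEM from a sample EEM."""
    if not sample.same_grids(blank):
        raise ValueError("sample and blank EEMs are on different wavelength grids")
    if sample.blank_corrected:
        raise ValueError("sample is already blank corrected")
    return sample.copy_with(
        intensity=sample.intensity - blank.intensity,
        blank_corrected=True,
    )


def raman_area(blank: EEM,
               ex: float = RAMAN_EX_NM,
               em_window: tuple[float, float] = RAMAN_EM_WINDOW_NM) -> float:
    """Integrated water Raman peak of a blank at excitation ``ex``.

    Trapezoidal integral of the blank's emission scan over ``em_window``
    (default 371-428 nm at ex 350 nm), in intensity*nm. This area defines
    one Raman unit (R.U.).
    """
    j = _snap_index(blank.ex, ex)
    lo, hi = em_window
    if lo < blank.em[0] or hi > blank.em[-1]:
        raise ValueError("Raman emission window lies outside the EEM emission grid")
    sel = (blank.em > lo) & (blank.em < hi)
    if sel.sum() < 2:
        raise ValueError("Raman emission window covers fewer than two grid points")
    # integrate over the exact window: interpolate the endpoints onto it
    em_pts = np.concatenate([[lo], blank.em[sel], [hi]])
    vals = np.interp(em_pts, blank.em, blank.intensity[:, j])
    area = float(np.trapezoid(vals, em_pts))
    if area == 0.0:
        warnings.warn("Raman area is zero; normalization would divide by zero")
    return area


def raman_normalize(eem: EEM, area: float) -> EEM:
    """Convert an EEM to Raman units by dividing by the blank's Raman area."""
    if not area > 0:
        raise ValueError("Raman area must be positive")
    if eem.raman_normalized:
        raise ValueError("EEM is already Raman normalized")
    return eem.copy_with(intensity=eem.intensity / area, raman_normalized=True)


def ife_correct(eem: EEM, spectrum: AbsorbanceSpectrum,
                warn_threshold: float = 1.5) -> EEM:
    """Inner-filter-effect correction by the absorbance (ABA) method.

    Each cell is multiplied by ``10**((A_ex + A_em)/2)`` where A is the
    decadic absorbance at the cell's excitation and emission wavelengths,
    rescaled to a 1 cm path. Warns when total absorbance A_ex + A_em
    exceeds ``warn_threshold`` anywhere (the multiplicative correction is
    unreliable for strongly absorbing samples).
    """
    if eem.ife_corrected:
        raise ValueError("EEM is already IFE corrected")
    try:
        a_ex = np.asarray(spectrum.absorbance_1cm(eem.ex), dtype=float)
        a_em = np.asarray(spectrum.absorbance_1cm(eem.em), dtype=float)
    except ValueError as err:
        raise ValueError(f"absorbance spectrum does not cover the EEM grids: {err}")
    total = a_em[:, None] + a_ex[None, :]
    if np.nanmax(total) > warn_threshold:
        warnings.warn(
            f"total absorbance exceeds {warn_threshold}; IFE correction may be unreliable"
        )
    factor = 10.0 ** (total / 2.0)
    return eem.copy_with(intensity=eem.intensity * factor, ife_corrected=True)


@dataclass(frozen=True)
class ScatterWidths:
    """Half-widths (nm) of the scatter bands excised before PARAFAC."""

    rayleigh1: float = 10.0
    rayleigh2: float = 15.0
    raman1: float = 10.0
    raman2: float = 0.0

    def __post_init__(self):
        for name in ("rayleigh1", "rayleigh2", "raman1", "raman2"):
            if getattr(self, name) < 0:
                raise ValueError(f"scatter width {name} must be >= 0")


def scatter_mask(ex: np.ndarray, em: np.ndarray,
                 widths: ScatterWidths) -> np.ndarray:
    """Boolean mask (n_em, n_ex), True where a cell falls in a scatter band."""
    EM = em[:, None]
    EX = ex[None, :]
    mask = np.zeros((em.size, ex.size), dtype=bool)
    if widths.rayleigh1 > 0:
        mask |= np.abs(EM - EX) <= widths.rayleigh1
    if widths.rayleigh2 > 0:
        mask |= np.abs(EM - 2.0 * EX) <= widths.rayleigh2
    if widths.raman1 > 0:
        mask |= np.abs(EM - raman_emission_wavelength(EX)) <= widths.raman1
    if widths.raman2 > 0:
        mask |= np.abs(EM - 2.0 * raman_emission_wavelength(EX)) <= widths.raman2
    return mask


def remove_scatter(eem: EEM, widths: ScatterWidths = ScatterWidths(),
                   interpolate: bool = False) -> EEM:
    """Blank out Rayleigh (1st/2nd order) and Raman scatter bands.

    Cells within each band are set to NaN; with ``interpolate=True`` they
    are then linearly interpolated along the emission axis (edge cells
    nearest-filled). The default leaves them missing, which the PARAFAC
    fit treats as unweighted cells.
    """
    mask = scatter_mask(eem.ex, eem.em, widths)
    intensity = eem.intensity.copy()
    intensity[mask] = np.nan
    if interpolate:
        for j in range(eem.ex.size):
            col = intensity[:, j]
            bad = np.isnan(col)
            if bad.all():
                continue
            if bad.any():
                col[bad] = np.interp(eem.em[bad], eem.em[~bad], col[~bad])
        # np.interp clamps at the ends: edge gaps become nearest-fill
    return eem.copy_with(intensity=intensity, scatter_removed=True)


# ---------------------------------------------------------------------------
# Absorbance indices
# ---------------------------------------------------------------------------

def absorption_coefficient(spectrum: AbsorbanceSpectrum,
                           wavelength: float = 254.0) -> float:
    """Napierian absorption coefficient a(lambda) = ln(10)*A(lambda)/path, in 1/m."""
    return LN10 * spectrum.value_at(wavelength) / spectrum.path_length


def suva254(spectrum: AbsorbanceSpectrum, doc: float) -> float:
    """Specific UV absorbance at 254 nm, L/(mg C*m).

    Decadic absorbance at 254 nm expressed per metre of path, divided by
    the DOC concentration (Weishaar convention). An aromaticity proxy.
    """
    if not doc > 0:
        raise ValueError("DOC concentration must be positive")
    return (spectrum.value_at(254.0) / spectrum.path_length) / doc


def spectral_slope(spectrum: AbsorbanceSpectrum,
                   window: tuple[float, float]) -> float:
    """Exponential spectral slope S (1/nm) over a wavelength window.

    Fits ``a(lambda) = a(lambda_ref) * exp(-S*(lambda - lambda_ref))`` by
    nonlinear least squares over the window (``lambda_ref`` = window
    start); S > 0 for the normal CDOM decrease with wavelength.
    """
    lo, hi = window
    sel = (spectrum.wavelength >= lo) & (spectrum.wavelength <= hi)
    if sel.sum() < 5:
        raise ValueError("spectral slope window must contain at least 5 points")
    lam = spectrum.wavelength[sel]
    a = LN10 * spectrum.absorbance[sel] / spectrum.path_length
    if np.any(a < 0):
        raise ValueError("negative absorbance in slope window")
    if np.all(a == a[0]):
        return 0.0
    if np.any(a <= 0):
        raise ValueError(
            "non-positive absorbance in slope window; cannot fit exponential decay"
        )
    lam0 = lam[0]
    # log-linear fit seeds the nonlinear one
    coeffs = np.polyfit(lam - lam0, np.log(a), 1)
    s0, a0 = -coeffs[0], float(np.exp(coeffs[1]))

    def model(x, a_ref, s):
        return a_ref * np.exp(-s * (x - lam0))

    popt, _ = curve_fit(model, lam, a, p0=(a0, s0), maxfev=10000)
    return float(popt[1])


def slope_ratio(s275_295: float, s350_400: float) -> float:
    """Spectral slope ratio S_R = S(275-295)/S(350-400); inversely related to DOM MW."""
    if s350_400 == 0:
        raise ValueError("S(350-400) is zero; slope ratio undefined")
    return s275_295 / s350_400


# ---------------------------------------------------------------------------
# Fluorescence indices
# ---------------------------------------------------------------------------

def fluorescence_index(eem: EEM, convention: str = "corrected") -> float:
    """Fluorescence index: emission intensity ratio at excitation 370 nm.

    ``convention='corrected'`` uses em 470/520 nm (corrected-instrument
    convention); ``'legacy'`` uses the original em 450/500 nm pair. Lower
    FI indicates more aromatic, terrestrially derived DOM.
    """
    pairs = {"corrected": (470.0, 520.0), "legacy": (450.0, 500.0)}
    try:
        em_num, em_den = pairs[convention]
    except KeyError:
        raise ValueError(f"unknown FI convention {convention!r}")
    j = _snap_index(eem.ex, 370.0)
    num = eem.intensity[_snap_index(eem.em, em_num), j]
    den = eem.intensity[_snap_index(eem.em, em_den), j]
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        warnings.warn("FI undefined: missing or zero intensity at reference cells")
        return float("nan")
    return float(num / den)


#: Coble peak definitions: excitation nm and emission nm (point or range).
PEAK_DEFINITIONS: dict[str, tuple[float, tuple[float, float] | float]] = {
    "B": (270.0, 310.0),            # tyrosine-like (protein)
    "T": (275.0, 340.0),            # tryptophan-like (protein)
    "A": (260.0, (380.0, 410.0)),   # humic-like (UVC)
    "M": (312.0, (380.0, 420.0)),   # marine/microbial humic-like
    "C": (350.0, (420.0, 480.0)),   # humic-like (UVA)
}


def pick_peaks(eem: EEM) -> dict[str, float]:
    """Read the classical fluorophore peaks B, T, A, M, C from a corrected EEM.

    B and T are read at single ex/em coordinates; A, M and C are the
    maximum over an emission range at fixed excitation. Windows that are
    entirely missing (NaN) yield NaN with a warning.
    """
    peaks: dict[str, float] = {}
    for name, (ex_nm, em_def) in PEAK_DEFINITIONS.items():
        j = _snap_index(eem.ex, ex_nm)
        if isinstance(em_def, tuple):
            lo, hi = em_def
            sel = (eem.em >= lo) & (eem.em <= hi)
            vals = eem.intensity[sel, j]
        else:
            vals = eem.intensity[[_snap_index(eem.em, em_def)], j]
        if vals.size == 0 or np.all(np.isnan(vals)):
            warnings.warn(f"peak {name}: window fully missing; value undefined")
            peaks[name] = float("nan")
        else:
            peaks[name] = float(np.nanmax(vals))
    return peaks


def peak_ratio(peaks: Mapping[str, float], num: str = "A", den: str = "T") -> float:
    """Ratio of two fluorophore peaks, e.g. A:T (recalcitrant:labile balance).

    A zero or missing denominator peak yields NaN with a warning rather
    than an infinite ratio.
    """
    a, t = peaks[num], peaks[den]
    if not np.isfinite(a) or not np.isfinite(t) or t == 0:
        warnings.warn(f"{num}:{den} ratio undefined (denominator zero or missing)")
        return float("nan")
    return a / t


def compute_indices(spectrum: AbsorbanceSpectrum, doc: float,
                    eem: EEM | None = None,
                    fi_convention: str = "corrected") -> OpticalIndices:
    """Compute the full optical-index set for one sample.

    Fluorescence-derived indices require ``eem`` (corrected, in Raman
    units); without one they are NaN.
    """
    s1 = spectral_slope(spectrum, (275.0, 295.0))
    s2 = spectral_slope(spectrum, (350.0, 400.0))
    if eem is not None:
        fi = fluorescence_index(eem, fi_convention)
        peaks = pick_peaks(eem)
        at = peak_ratio(peaks, "A", "T")
    else:
        fi, peaks, at = float("nan"), {k: float("nan") for k in PEAK_DEFINITIONS}, float("nan")
    return OpticalIndices(
        a254=absorption_coefficient(spectrum, 254.0),
        suva254=suva254(spectrum, doc),
        s275_295=s1,
        s350_400=s2,
        s_r=slope_ratio(s1, s2) if s2 != 0 else float("nan"),
        fi=fi,
        peaks=peaks,
        a_t_ratio=at,
    )
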