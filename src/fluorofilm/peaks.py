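"""Diffraction-peak analysis: shape fits, coherence length, hexagonal indexing.

A 2D hexagonal lattice with parameter a diffracts at in-plane positions
Q_10 = 4*pi / (sqrt(3) a), with higher orders at sqrt(3) and 2 times Q_10
(the (11) and (20) reflections). Indexing the first peak therefore gives

    a = 4*pi / (sqrt(3) Q_10),     area per molecule = (sqrt(3)/2) a^2.

The coherence length (the size of coherently diffracting crystalline
domains) is estimated as l_c = 2*pi / FWHM of the intrinsic peak width. For
measured spectra the instrument resolution D is removed in quadrature,
intrinsic = sqrt(FWHM^2 - D^2); when the measured width is at or below the
resolution only a lower bound l_c >= 2*pi / D can be stated.

Peaks are least-squares fitted as amplitude * S((Q - Q0)/w) plus a linear
baseline, with S Lorentzian (1/(1+x^2), typical of zero-pressure spectra) or
Gaussian (exp(-x^2/2), typical of compressed or simulated spectra).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .scatter import DiffractionSpectrum

__all__ = ["PeakFit", "HexagonalLattice", "CoherenceResult",
           "fit_peak", "coherence_length", "index_hexagonal", "peak_ratios",
           "HEX_RATIO_TOLERANCE"]

HEX_RATIO_TOLERANCE = 0.01  # relative; sqrt(2) (square lattice) is 8.6% off
_SQRT3 = math.sqrt(3.0)
_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 sigma


@dataclass
class PeakFit:
    """One fitted diffraction peak."""

    center: float                 # Q0, nm^-1
    fwhm: float                   # nm^-1
    amplitude: float
    baseline: tuple[float, float]  # (slope, intercept) of the linear baseline
    shape: str                    # "lorentzian" | "gaussian"
    fit_window: tuple[float, float]
    covariance: np.ndarray | None = None
    residual_norm: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "center_nm_inv": float(self.center),
            "fwhm_nm_inv": float(self.fwhm),
            "amplitude": float(self.amplitude),
            "baseline_slope": float(self.baseline[0]),
            "baseline_intercept": float(self.baseline[1]),
            "shape": self.shape,
            "fit_window": [float(v) for v in self.fit_window],
            "residual_norm": float(self.residual_norm),
        }


@dataclass
class HexagonalLattice:
    """2D hexagonal lattice derived from indexed peak positions."""

    a: float                      # lattice parameter, nm
    q10: float                    # (10) peak position, nm^-1
    q11: float | None = None      # (11), if supplied
    q20: float | None = None      # (20), if supplied
    area_per_molecule: float = field(init=False)

    def __post_init__(self) -> None:
        self.area_per_molecule = (_SQRT3 / 2.0) * self.a ** 2

    def to_dict(self) -> dict:
        return {
            "a_nm": float(self.a),
            "q10_nm_inv": float(self.q10),
            "q11_nm_inv": None if self.q11 is None else float(self.q11),
            "q20_nm_inv": None if self.q20 is None else float(self.q20),
            "area_per_molecule_nm2": float(self.area_per_molecule),
        }


@dataclass
class CoherenceResult:
    """Crystalline coherence length from a peak width."""

    l_c: float                    # nm
    is_lower_bound: bool
    intrinsic_fwhm: float         # nm^-1
    instrument_resolution: float  # nm^-1

    def to_dict(self) -> dict:
        return {
            "coherence_length_nm": float(self.l_c),
            "is_lower_bound": bool(self.is_lower_bound),
            "intrinsic_fwhm_nm_inv": float(self.intrinsic_fwhm),
            "instrument_resolution_nm_inv": float(self.instrument_resolution),
        }


class NotHexagonalError(ValueError):
    """Peak-position ratios incompatible with a 2D hexagonal lattice."""


def _lorentzian(q, amp, q0, w, slope, intercept):
    return amp / (1.0 + ((q - q0) / w) ** 2) + slope * q + intercept


def _gaussian(q, amp, q0, w, slope, intercept):
    return amp * np.exp(-0.5 * ((q - q0) / w) ** 2) + slope * q + intercept


def fit_peak(spectrum: DiffractionSpectrum,
             window: tuple[float, float],
             shape: str = "lorentzian") -> PeakFit:
    """Least-squares fit of one peak plus linear baseline inside ``window``.

    Initialised from the argmax and the half-height crossings; raises when
    the window holds no local maximum above its edges or the fit does not
    converge.
    """
    if shape not in ("lorentzian", "gaussian"):
        raise ValueError(f"unknown peak shape {shape!r}")
    lo, hi = window
    sub = spectrum.window(lo, hi)
    q, y = sub.q, sub.intensity
    if len(q) < 6:
        raise ValueError("fit window holds too few grid points")
    imax = int(np.argmax(y))
    edge = 0.5 * (y[0] + y[-1])
    if imax in (0, len(q) - 1) or y[imax] <= edge:
        raise ValueError("no local maximum above baseline in window")

    # initial guesses from argmax and half-height crossings
    base0 = float(min(y[0], y[-1]))
    amp0 = float(y[imax] - base0)
    half = base0 + amp0 / 2.0
    above = np.nonzero(y >= half)[0]
    width0 = max(float(q[above[-1]] - q[above[0]]), sub.dq)
    w0 = width0 / 2.0 if shape == "lorentzian" else width0 / _GAUSS_FWHM
    p0 = [amp0, float(q[imax]), w0, 0.0, base0]
    model = _lorentzian if shape == "lorentzian" else _gaussian
    try:
        popt, pcov = curve_fit(
            model, q, y, p0=p0, maxfev=500 * len(p0),
            bounds=([0.0, lo, sub.dq / 10.0, -np.inf, -np.inf],
                    [np.inf, hi, (hi - lo) * 2.0, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:
        raise RuntimeError(f"peak fit did not converge in window "
                           f"({lo}, {hi}): {exc}") from exc
    amp, q0, w, slope, intercept = popt
    fwhm = 2.0 * w if shape == "lorentzian" else _GAUSS_FWHM * w
    resid = y - model(q, *popt)
    return PeakFit(center=float(q0), fwhm=float(fwhm), amplitude=float(amp),
                   baseline=(float(slope), float(intercept)), shape=shape,
                   fit_window=(float(lo), float(hi)), covariance=pcov,
                   residual_norm=float(np.linalg.norm(resid)))


def coherence_length(fwhm: float, resolution: float = 0.0,
                     deconvolve: bool = True) -> CoherenceResult:
    """Coherence length l_c = 2*pi / (intrinsic FWHM).

    With ``deconvolve`` the instrument resolution is removed in quadrature;
    a measured width at or below the resolution yields a lower-bound result
    with l_c = 2*pi / resolution. Computed spectra carry no instrumental
    broadening: pass resolution 0 (or deconvolve=False).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if resolution < 0:
        raise ValueError("resolution must be non-negative")
    if not deconvolve or resolution == 0.0:
        return CoherenceResult(l_c=2.0 * math.pi / fwhm, is_lower_bound=False,
                               intrinsic_fwhm=fwhm,
                               instrument_resolution=resolution)
    if fwhm <= resolution * (1.0 + 1e-9):
        return CoherenceResult(l_c=2.0 * math.pi / resolution,
                               is_lower_bound=True, intrinsic_fwhm=0.0,
                               instrument_resolution=resolution)
    intrinsic = math.sqrt(fwhm ** 2 - resolution ** 2)
    return CoherenceResult(l_c=2.0 * math.pi / intrinsic, is_lower_bound=False,
                           intrinsic_fwhm=intrinsic,
                           instrument_resolution=resolution)


def index_hexagonal(peak_positions) -> HexagonalLattice:
    """Index 1-3 ascending peak positions on a 2D hexagonal lattice.

    The first position is assigned to the (10) reflection; additional
    positions must sit at sqrt(3) and 2 times the first (the (11) and (20)
    reflections) within 1%, otherwise the lattice is rejected with a
    diagnostic naming the offending ratio.
    """
    pos = [float(p) for p in np.atleast_1d(peak_positions)]
    if not 1 <= len(pos) <= 3:
        raise ValueError("give 1 to 3 peak positions")
    if any(p <= 0 for p in pos) or sorted(pos) != pos:
        raise ValueError("peak positions must be positive and ascending")
    q10 = pos[0]
    expected = {1: _SQRT3, 2: 2.0}
    names = {1: "(11)/(10)", 2: "(20)/(10)"}
    for k in range(1, len(pos)):
        ratio = pos[k] / q10
        if abs(ratio / expected[k] - 1.0) > HEX_RATIO_TOLERANCE:
            raise NotHexagonalError(
                f"not hexagonal: ratio {names[k]} = {ratio:.4f}, expected "
                f"{expected[k]:.4f} within {HEX_RATIO_TOLERANCE:.0%}")
    a = 4.0 * math.pi / (_SQRT3 * q10)
    return HexagonalLattice(a=a, q10=q10,
                            q11=pos[1] if len(pos) > 1 else None,
                            q20=pos[2] if len(pos) > 2 else None)


def peak_ratios(peak_positions) -> np.ndarray:
    """Each later peak position divided by the first, full precision."""
    pos = np.asarray(peak_positions, dtype=float)
    if pos.ndim != 1 or len(pos) < 2:
        raise ValueError("need at least two peak positions")
    if np.any(np.diff(pos) <= 0) or pos[0] <= 0:
        raise ValueError("positions must be positive and ascending")
    return pos[1:] / pos[0]
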