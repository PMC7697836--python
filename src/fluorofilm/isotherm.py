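"""Surface pressure - area isotherm analysis for Langmuir films.

A compression isotherm pi(A) of a condensed-phase-forming amphiphile shows a
long zero-pressure plateau (gas/condensed coexistence) down to the liftoff
area, then a steep quasi-linear rise. Two footprint measures are derived:

* liftoff area — the largest area at which the pressure rises measurably
  above zero and stays above it on further compression;
* limit area A0 — the extrapolation to pi = 0 of the linear (condensed)
  region of the isotherm before film collapse; the standard proxy for the
  condensed-phase area per molecule.

Internal units: area in nm^2/molecule, pressure in mN/m. CSV input may be in
Angstrom^2 (units="A2"); values are converted on read (1 nm^2 = 100 A^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Isotherm", "LimitAreaResult", "limit_area", "detect_liftoff",
           "generate_isotherm", "read_isotherm"]

DEFAULT_LIFTOFF_THRESHOLD = 0.2  # mN/m, just above typical noise floor


@dataclass
class Isotherm:
    """Paired (area per molecule, surface pressure) compression series."""

    area: np.ndarray       # nm^2/molecule
    pressure: np.ndarray   # mN/m
    temperature: float | None = None  # deg C, metadata

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.shape != self.pressure.shape or self.area.ndim != 1:
            raise ValueError("area and pressure must be equal-length 1D series")
        if np.any(self.area <= 0):
            raise ValueError("areas must be positive")
        if np.any(self.pressure < -0.5):
            raise ValueError("pressure below tolerated noise (-0.5 mN/m)")
        d = np.diff(self.area)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("area series must be strictly monotone")

    def descending(self) -> "Isotherm":
        """Compression order: areas from large to small."""
        if self.area[0] >= self.area[-1]:
            return self
        return Isotherm(self.area[::-1].copy(), self.pressure[::-1].copy(),
                        self.temperature)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"area_nm2": self.area, "pressure_mN_m": self.pressure}) \
            .to_csv(path, index=False)


@dataclass
class LimitAreaResult:
    """Zero-pressure extrapolation of the condensed linear branch."""

    A0: float                       # nm^2/molecule
    fit_slope: float                # mN/m per nm^2 (negative: compression)
    fit_window: tuple[float, float]  # area interval used
    liftoff_area: float | None = None

    def to_dict(self) -> dict:
        return {
            "A0_nm2": float(self.A0),
            "fit_slope_mN_m_per_nm2": float(self.fit_slope),
            "fit_window_nm2": [float(v) for v in self.fit_window],
            "liftoff_area_nm2": (None if self.liftoff_area is None
                                 else float(self.liftoff_area)),
        }


def read_isotherm(path: str | Path, units: str = "nm2",
                  temperature: float | None = None) -> Isotherm:
    """Read a two-column (area, pressure) CSV table; units "nm2" or "A2"."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (area, pressure)")
    area = df.iloc[:, 0].to_numpy(dtype=float)
    if units == "A2":
        area = area / 100.0
    elif units != "nm2":
        raise ValueError(f"unknown units {units!r} (use 'nm2' or 'A2')")
    return Isotherm(area, df.iloc[:, 1].to_numpy(dtype=float), temperature)


def detect_liftoff(isotherm: Isotherm,
                   pressure_threshold: float = DEFAULT_LIFTOFF_THRESHOLD) -> float:
    """Largest area at which the pressure exceeds the threshold and stays
    above it for all smaller areas."""
    iso = isotherm.descending()
    above = iso.pressure > pressure_threshold
    if not np.any(above):
        raise ValueError("no liftoff: pressure never exceeds threshold")
    # last index k such that every point from k to the end is above threshold
    below_idx = np.nonzero(~above)[0]
    start = below_idx[-1] + 1 if len(below_idx) else 0
    if start >= len(iso.area):
        raise ValueError("no liftoff: pressure drops below threshold at "
                         "the smallest areas")
    return float(iso.area[start])


def _auto_window(iso: Isotherm) -> np.ndarray:
    """Steepest contiguous quarter of the rising compression branch.

    The branch runs from where the pressure first exceeds the noise floor
    down to the collapse (the pressure maximum; beyond it the film buckles
    and dpi/dA changes sign). The zero-pressure coexistence plateau never
    enters the window.
    """
    a, p = iso.area, iso.pressure
    i_top = int(np.argmax(p))
    # rising branch starts where the pressure exceeds the noise floor and
    # STAYS above it (sporadic noise spikes on the plateau do not count)
    below = np.nonzero(p[:i_top + 1] <= DEFAULT_LIFTOFF_THRESHOLD)[0]
    idx0 = int(below[-1]) + 1 if len(below) else 0
    if idx0 > i_top:
        raise ValueError("collapse not identified: pressure never rises "
                         "above the noise floor")
    m = i_top + 1 - idx0
    k = max(int(round(m * 0.25)), 5)
    if m < k:
        raise ValueError("too few points on the compression branch for "
                         "an auto window")
    best, best_slope = None, 0.0
    for i in range(idx0, i_top + 2 - k):
        slope = np.polyfit(a[i:i + k], p[i:i + k], 1)[0]
        if slope < best_slope:
            best_slope = slope
            best = (i, i + k)
    if best is None:
        raise ValueError("no descending-slope segment found")
    return np.arange(best[0], best[1])


def limit_area(isotherm: Isotherm,
               fit_window: tuple[float, float] | str = "auto") -> LimitAreaResult:
    """Limit area A0 by zero-pressure extrapolation of the linear branch.

    ``fit_window`` is an (area_lo, area_hi) interval, or ``"auto"`` to select
    the steepest contiguous quarter of the compression branch before film
    collapse. Ordinary least squares of pi on A over the window; A0 is the
    area at pi = 0. The slope must be negative (pressure rises on
    compression) and the window must hold at least 5 points spanning at
    least 5 mN/m.
    """
    iso = isotherm.descending()
    if isinstance(fit_window, str):
        if fit_window != "auto":
            raise ValueError("fit_window must be (lo, hi) or 'auto'")
        idx = _auto_window(iso)
    else:
        lo, hi = fit_window
        idx = np.nonzero((iso.area >= lo) & (iso.area <= hi))[0]
    if len(idx) < 5:
        raise ValueError("fit window holds fewer than 5 points")
    p = iso.pressure[idx]
    if p.max() - p.min() < 5.0:
        raise ValueError("fit window spans less than 5 mN/m of pressure")
    slope, intercept = np.polyfit(iso.area[idx], p, 1)
    if slope >= 0:
        raise ValueError("positive slope in fit window: not a compression "
                         "branch")
    a0 = -intercept / slope
    try:
        liftoff = detect_liftoff(iso)
    except ValueError:
        liftoff = None
    return LimitAreaResult(A0=float(a0), fit_slope=float(slope),
                           fit_window=(float(iso.area[idx].min()),
                                       float(iso.area[idx].max())),
                           liftoff_area=liftoff)


def generate_isotherm(A0: float, liftoff: float, slope: float = 600.0,
                      plateau_extent: float = 1.0, noise_sigma: float = 0.0,
                      n_points: int = 400, seed: int = 0,
                      collapse_pressure: float | None = None,
                      temperature: float = 20.0) -> Isotherm:
    """Synthetic compression isotherm with known ground truth.

    Zero-pressure plateau for A > liftoff; a quadratic shoulder joining the
    plateau tangentially at the liftoff area; then a linear condensed branch
    of slope ``-slope`` whose zero-pressure extrapolation is exactly ``A0``.
    The tangent point sits at A_t = 2*A0 - liftoff, so liftoff >= A0 is
    required (equality gives a pure kink). Optional collapse: above
    ``collapse_pressure`` the slope flattens to a quarter. Seeded Gaussian
    noise of ``noise_sigma`` (mN/m) is added to the pressure.

    ``limit_area`` on the noise-free output recovers A0 exactly (the linear
    branch is genuinely linear).
    """
    if not (0 < A0 <= liftoff):
        raise ValueError("require liftoff >= A0 > 0")
    if slope <= 0:
        raise ValueError("slope must be positive (pi rises as A falls)")
    a_min = max(A0 - (A0 * 0.25), 1e-3)
    a_max = liftoff + plateau_extent
    area = np.linspace(a_max, a_min, n_points)  # compression order
    a_t = 2.0 * A0 - liftoff                    # tangent point
    pressure = np.zeros_like(area)
    if liftoff > A0:
        c = slope / (4.0 * (liftoff - A0))
        shoulder = (area <= liftoff) & (area > a_t)
        pressure[shoulder] = c * (liftoff - area[shoulder]) ** 2
    linear = area <= a_t
    pressure[linear] = slope * (A0 - area[linear])
    if collapse_pressure is not None:
        over = pressure > collapse_pressure
        pressure[over] = (collapse_pressure
                          + (pressure[over] - collapse_pressure) * 0.25)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sigma, len(pressure))
        pressure = np.maximum(pressure, -0.45)
    return Isotherm(area, pressure, temperature)
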