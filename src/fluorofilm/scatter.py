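"""Simulated in-plane (Q_xy) diffraction spectra from atomic coordinates.

Grazing-incidence diffraction of a monolayer probes in-plane order only, so
the computed estimator is the 2D analogue of the Debye scattering equation:
the orientational (azimuthal) average of the in-plane structure factor,

    I(Q) = < sum_j sum_k w_j w_k J0(Q d_jk) >_frames / sum_j w_j^2,

where d_jk is the in-plane (x, y) separation of the selected atoms, J0 the
zeroth-order cylindrical Bessel function, and w_j the atomic weights
(atomic number Z by default, approximating form-factor contrast). The j = k
self terms are included, so I(Q) >= 0 and a single atom gives a flat
spectrum of 1. Frames are finite aperiodic clusters: no periodic images
enter the pair sum by default, so peak widths reflect the true domain size.

For large frames the pair sum is evaluated through a fine distance histogram
(0.0005 nm bins); the phase error this introduces is below 0.01 rad at
Q = 30 nm^-1, far below any peak-position tolerance of interest.

No Q_z dependence is modelled; spectra correspond to Q_z-integrated
(rod-integrated) in-plane scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import j0

from .frames import ATOMIC_NUMBERS, MonolayerFrame

__all__ = ["DiffractionSpectrum", "compute_spectrum", "background_subtract",
           "read_spectrum", "DEFAULT_ATOM_FILTER"]

DEFAULT_ATOM_FILTER = ("C", "F")  # chain atoms: head group / water excluded
_EXACT_PATH_MAX_ATOMS = 300       # above this, use the distance histogram
_HIST_BIN_NM = 5e-4
_PAIR_CHUNK = 3000


@dataclass
class DiffractionSpectrum:
    """Intensity sampled on a uniform Q_xy grid (nm^-1)."""

    q: np.ndarray          # strictly increasing, constant step
    intensity: np.ndarray  # arbitrary units, per-atom normalised, >= 0
    n_frames: int = 1
    source: str = "computed"   # "computed" | "measured"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must be 1D and equal length")
        if len(self.q) > 1:
            steps = np.diff(self.q)
            if np.any(steps <= 0):
                raise ValueError("q grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("q grid step must be constant")

    @property
    def dq(self) -> float:
        return float(self.q[1] - self.q[0]) if len(self.q) > 1 else 0.0

    def window(self, q_lo: float, q_hi: float) -> "DiffractionSpectrum":
        sel = (self.q >= q_lo) & (self.q <= q_hi)
        return DiffractionSpectrum(self.q[sel], self.intensity[sel],
                                   self.n_frames, self.source)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"q_nm_inv": self.q, "intensity": self.intensity}) \
            .to_csv(path, index=False)


def read_spectrum(path: str | Path, source: str = "measured") -> DiffractionSpectrum:
    """Read a two-column (Q_xy in nm^-1, intensity) CSV table."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (q, intensity)")
    q = df.iloc[:, 0].to_numpy(dtype=float)
    i = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(q)
    return DiffractionSpectrum(q[order], i[order], n_frames=1, source=source)


def _select_atoms(frame: MonolayerFrame, atom_filter) -> np.ndarray:
    if atom_filter is None:
        return np.arange(frame.n_atoms)
    if callable(atom_filter):
        mask = np.asarray([bool(atom_filter(el)) for el in frame.elements])
        return np.nonzero(mask)[0]
    wanted = set(atom_filter)
    return np.nonzero(np.isin(frame.elements.astype(str), sorted(wanted)))[0]


def _weights(elements: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "unit":
        return np.ones(len(elements))
    if scheme == "Z":
        return np.array([float(ATOMIC_NUMBERS[el]) for el in elements])
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _frame_intensity(xy: np.ndarray, w: np.ndarray, q: np.ndarray,
                     box_xy: np.ndarray | None) -> np.ndarray:
    """Normalised I(q) for one frame's selected in-plane coordinates."""
    n = len(xy)
    w2 = float(w @ w)
    if n == 1:
        return np.ones_like(q)
    if n <= _EXACT_PATH_MAX_ATOMS:
        d = cdist(xy, xy)
        if box_xy is not None:
            dx = xy[:, 0][:, None] - xy[:, 0][None, :]
            dy = xy[:, 1][:, None] - xy[:, 1][None, :]
            dx -= box_xy[0] * np.round(dx / box_xy[0])
            dy -= box_xy[1] * np.round(dy / box_xy[1])
            d = np.hypot(dx, dy)
        iu, ju = np.triu_indices(n, k=1)
        dists = d[iu, ju]
        wprod = w[iu] * w[ju]
        cross = np.empty_like(q)
        for k0 in range(0, len(q), 256):
            qc = q[k0:k0 + 256]
            cross[k0:k0 + 256] = j0(qc[:, None] * dists[None, :]) @ wprod
        return (w2 + 2.0 * cross) / w2

    # histogram path
    dr = _HIST_BIN_NM
    if box_xy is not None:
        dmax = float(np.hypot(box_xy[0], box_xy[1])) / 2.0 + 2 * dr
    else:
        span = xy.max(axis=0) - xy.min(axis=0)
        dmax = float(np.hypot(span[0], span[1])) + 2 * dr
    nbins = int(math.ceil(dmax / dr)) + 2
    hist = np.zeros(nbins)
    starts = list(range(0, n, _PAIR_CHUNK))
    for ia, i0 in enumerate(starts):
        i1 = min(i0 + _PAIR_CHUNK, n)
        for j0_ in starts[ia:]:
            j1 = min(j0_ + _PAIR_CHUNK, n)
            dx = xy[i0:i1, 0][:, None] - xy[j0_:j1, 0][None, :]
            dy = xy[i0:i1, 1][:, None] - xy[j0_:j1, 1][None, :]
            if box_xy is not None:
                dx -= box_xy[0] * np.round(dx / box_xy[0])
                dy -= box_xy[1] * np.round(dy / box_xy[1])
            d = np.hypot(dx, dy)
            wp = np.outer(w[i0:i1], w[j0_:j1])
            if j0_ == i0:
                iu, ju = np.triu_indices(i1 - i0, k=1)
                d = d[iu, ju]
                wp = wp[iu, ju]
            idx = np.minimum((d / dr).astype(np.int64), nbins - 1)
            hist += np.bincount(idx.ravel(), weights=wp.ravel(),
                                minlength=nbins)
    nz = np.nonzero(hist)[0]
    centers = (nz + 0.5) * dr
    weights_nz = hist[nz]
    cross = np.empty_like(q)
    for k0 in range(0, len(q), 128):
        qc = q[k0:k0 + 128]
        cross[k0:k0 + 128] = j0(qc[:, None] * centers[None, :]) @ weights_nz
    intensity = (w2 + 2.0 * cross) / w2
    # binning can leave tiny negative residues in deep troughs; clamp
    return np.maximum(intensity, 0.0)


def compute_spectrum(frames: MonolayerFrame | list[MonolayerFrame],
                     q_min: float = 1.0, q_max: float = 30.0, dq: float = 0.02,
                     atom_filter=DEFAULT_ATOM_FILTER,
                     weight_scheme: str = "Z",
                     minimum_image: bool = False,
                     max_grid_points: int = 50_000) -> DiffractionSpectrum:
    """Frame-averaged in-plane diffraction spectrum of selected atoms.

    Parameters
    ----------
    frames : frame or list of frames
        Averaged with equal weight.
    q_min, q_max, dq : float
        Grid in nm^-1; the default 0.02 nm^-1 step matches typical
        synchrotron in-plane resolution.
    atom_filter : iterable of elements, callable, or None
        Which atoms scatter; default chain carbons and fluorines. None
        selects every atom.
    weight_scheme : "Z" or "unit"
        Atomic-number or equal weighting. Peak positions are insensitive to
        the choice.
    minimum_image : bool
        Apply in-plane minimum-image convention to pair separations
        (default off: frames are finite clusters).
    """
    if isinstance(frames, MonolayerFrame):
        frames = [frames]
    if not frames:
        raise ValueError("need at least one frame")
    if not (0 < q_min < q_max):
        raise ValueError("require 0 < q_min < q_max")
    if dq <= 0:
        raise ValueError("dq must be positive")
    n_grid = int(round((q_max - q_min) / dq)) + 1
    if n_grid > max_grid_points:
        raise ValueError(f"q grid of {n_grid} points exceeds cap "
                         f"{max_grid_points}")
    q = q_min + dq * np.arange(n_grid)

    total = np.zeros(n_grid)
    for f in frames:
        sel = _select_atoms(f, atom_filter)
        if len(sel) == 0:
            raise ValueError("atom filter selects no atoms")
        xy = f.positions[sel, :2]
        w = _weights(f.elements[sel], weight_scheme)
        box_xy = f.box[:2] if minimum_image else None
        total += _frame_intensity(xy, w, q, box_xy)
    return DiffractionSpectrum(q, total / len(frames),
                               n_frames=len(frames), source="computed")


def background_subtract(spectrum: DiffractionSpectrum,
                        method: str = "linear",
                        fit_windows: list[tuple[float, float]] | None = None,
                        clip_negative: bool = False) -> DiffractionSpectrum:
    """Subtract a smooth baseline fitted on peak-free windows.

    ``fit_windows`` is a list of (q_lo, q_hi) intervals that exclude the
    peaks; the baseline (linear or quadratic in Q) is least-squares fitted on
    the points inside them and subtracted everywhere. Needed before fitting
    peaks of computed spectra, whose baseline is the amorphous/self-
    scattering continuum.
    """
    if method not in ("linear", "poly2"):
        raise ValueError(f"unknown baseline method {method!r}")
    if not fit_windows:
        raise ValueError("fit_windows must list at least one interval")
    mask = np.zeros(len(spectrum.q), dtype=bool)
    for lo, hi in fit_windows:
        if hi <= lo:
            raise ValueError(f"bad window ({lo}, {hi})")
        inside = (spectrum.q >= lo) & (spectrum.q <= hi)
        if not np.any(inside):
            raise ValueError(f"window ({lo}, {hi}) outside the q grid")
        mask |= inside
    deg = 1 if method == "linear" else 2
    coeffs = np.polyfit(spectrum.q[mask], spectrum.intensity[mask], deg)
    baseline = np.polyval(coeffs, spectrum.q)
    resid = spectrum.intensity - baseline
    if clip_negative:
        resid = np.maximum(resid, 0.0)
    return DiffractionSpectrum(spectrum.q, resid, spectrum.n_frames,
                               spectrum.source)
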