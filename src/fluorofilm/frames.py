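"""Core in-memory containers for monolayer structures.

Coordinates are in nanometres throughout the package; the interface normal
is +z (the air-water interface sits near z = 0). A :class:`MonolayerFrame`
is one time point of a film; a :class:`ChainVectorSet` carries the
per-molecule head-to-tail vectors used by the alignment order parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MonolayerFrame", "ChainVectorSet", "ATOMIC_NUMBERS"]

# Atomic numbers for the elements that occur in fatty-alcohol films.
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "S": 16}


@dataclass
class MonolayerFrame:
    """One snapshot of a molecular film at the air-water interface.

    Parameters
    ----------
    positions : (N_atoms, 3) float array, nm
        Cartesian coordinates; x, y in-plane, z along the interface normal.
    elements : (N_atoms,) array of str
        Element symbols (``"C"``, ``"F"``, ...).
    molecule_index : (N_atoms,) int array
        0-based molecule membership; values are contiguous 0..N_mol-1.
    box : (3,) float array, nm
        Orthorhombic box lengths. In-plane coordinates are interpreted
        periodically in x and y; z is open.
    time_label : float or None
        Time stamp in ns, used for block averaging of trajectories.
    meta : dict
        Optional per-molecule bookkeeping written by the generators
        (species labels, ground-truth tilt angles, aggregate membership).
        Never required by any analysis routine.
    """

    positions: np.ndarray
    elements: np.ndarray
    molecule_index: np.ndarray
    box: np.ndarray
    time_label: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        n = len(self.positions)
        if len(self.elements) != n or len(self.molecule_index) != n:
            raise ValueError("elements/molecule_index length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        mols = np.unique(self.molecule_index)
        if len(mols) and not np.array_equal(mols, np.arange(len(mols))):
            raise ValueError("molecule_index values must be contiguous 0..N_mol-1")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_atoms else 0

    def wrap_xy(self) -> "MonolayerFrame":
        """Return a copy with x, y wrapped into [0, box); z untouched."""
        pos = self.positions.copy()
        pos[:, 0] %= self.box[0]
        pos[:, 1] %= self.box[1]
        return MonolayerFrame(pos, self.elements, self.molecule_index,
                              self.box.copy(), self.time_label, dict(self.meta))

    def centroids(self) -> np.ndarray:
        """Per-molecule centroid positions, (N_mol, 3)."""
        nm = self.n_molecules
        out = np.zeros((nm, 3))
        counts = np.bincount(self.molecule_index, minlength=nm).astype(float)
        for k in range(3):
            out[:, k] = np.bincount(self.molecule_index,
                                    weights=self.positions[:, k],
                                    minlength=nm) / counts
        return out


@dataclass
class ChainVectorSet:
    """Per-molecule end-to-end vectors: head carbon -> terminal chain carbon.

    The head is the carbon bonded to the hydroxyl oxygen; the tail is the
    terminal carbon of the hydrophobic chain. These vectors feed the pairwise
    alignment order parameter.
    """

    vectors: np.ndarray       # (N_mol, 3), nm
    centroids: np.ndarray     # (N_mol, 3), nm
    molecule_ids: np.ndarray  # (N_mol,), int

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.vectors.shape != self.centroids.shape:
            raise ValueError("vectors/centroids shape mismatch")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length chain vector")

    @property
    def n_molecules(self) -> int:
        return len(self.vectors)

    def unit_vectors(self) -> np.ndarray:
        return self.vectors / np.linalg.norm(self.vectors, axis=1, keepdims=True)
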