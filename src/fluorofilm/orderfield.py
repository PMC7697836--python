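"""Molecular alignment statistics of monolayer films.

The central quantity is the pairwise alignment order parameter

    OP = 2 / (N (N - 1)) * sum_{i<j} (r_i . r_j) / (|r_i| |r_j|),

the mean cosine between all pairs of molecular end-to-end vectors r_i (head
carbon -> terminal chain carbon). OP = 1 for perfectly parallel molecules;
an isotropic upper-hemisphere film gives OP -> 1/4 for large N; the lower
bound is -1/(N-1). Averaging OP over the frames of a trajectory gives the
time average, with uncertainties from block averaging (2 ns blocks by
default, the convention for equilibrated monolayer trajectories).

The module also provides tilt-angle distributions, an upright/lying
classifier, and single-linkage aggregate detection on in-plane centroid
distances with periodic x, y images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .frames import ChainVectorSet, MonolayerFrame
from .structio import extract_chain_vectors

__all__ = [
    "OPResult", "ClusterLabels",
    "compute_op", "compute_op_double_sum", "average_op",
    "tilt_angles", "classify_upright", "cluster_molecules",
    "DEFAULT_CLUSTER_CUTOFF", "DEFAULT_UPRIGHT_THRESHOLD",
]

# Single-linkage cutoff separating lattice neighbours (~0.575 nm) from gas.
DEFAULT_CLUSTER_CUTOFF = 0.70   # nm
DEFAULT_UPRIGHT_THRESHOLD = 45.0  # deg, midpoint convention


@dataclass
class OPResult:
    """Time-averaged order parameter of a trajectory."""

    op_per_frame: np.ndarray      # OP(t), one value per frame
    times: np.ndarray             # frame time labels, ns (nan if absent)
    op_mean: float                # mean over frames
    op_std: float                 # standard deviation of block means
    block_duration: float         # ns
    n_molecules: int

    def to_dict(self) -> dict:
        return {
            "op_per_frame": [float(v) for v in self.op_per_frame],
            "times_ns": [None if np.isnan(t) else float(t) for t in self.times],
            "op_mean": float(self.op_mean),
            "op_std": float(self.op_std),
            "block_duration_ns": float(self.block_duration),
            "n_molecules": int(self.n_molecules),
        }


@dataclass
class ClusterLabels:
    """Single-linkage aggregate labels; -1 marks unclustered singletons."""

    labels: np.ndarray
    cutoff: float

    def sizes(self) -> dict[int, int]:
        """Cluster label -> member count (singletons excluded)."""
        out: dict[int, int] = {}
        for lab in self.labels:
            if lab >= 0:
                out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def n_clusters(self) -> int:
        return len(self.sizes())


def compute_op(vectors: ChainVectorSet | np.ndarray) -> float:
    """Mean pairwise cosine between all molecular end-to-end vectors.

    Evaluated through the algebraic identity
    ``OP = (|sum_i u_i|^2 - N) / (N (N - 1))`` with u_i the unit vectors,
    which equals the explicit double sum to machine precision in O(N) time.
    """
    u = _unit_vectors(vectors)
    n = len(u)
    if n < 2:
        raise ValueError("order parameter needs at least two molecules")
    s = u.sum(axis=0)
    return float((s @ s - n) / (n * (n - 1)))


def compute_op_double_sum(vectors: ChainVectorSet | np.ndarray) -> float:
    """Literal double-sum evaluation; O(N^2), used for cross-checks."""
    u = _unit_vectors(vectors)
    n = len(u)
    if n < 2:
        raise ValueError("order parameter needs at least two molecules")
    total = 0.0
    for i in range(n - 1):
        total += float((u[i + 1:] @ u[i]).sum())
    return 2.0 * total / (n * (n - 1))


def _unit_vectors(vectors: ChainVectorSet | np.ndarray) -> np.ndarray:
    if isinstance(vectors, ChainVectorSet):
        return vectors.unit_vectors()
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length vector")
    return v / norms


def average_op(frames: list[MonolayerFrame],
               block_duration: float = 2.0,
               largest_cluster_only: bool = False,
               cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> OPResult:
    """Time-averaged order parameter with block-averaged uncertainty.

    Frames are grouped into consecutive, non-overlapping blocks of
    ``block_duration`` (ns) by their time labels; a truncated final block is
    dropped for the uncertainty (never for the mean). If the frames span less
    than one block (or carry no time labels) they form a single block and the
    reported std is 0. By default all N molecules enter the order parameter;
    ``largest_cluster_only`` restricts it to the largest aggregate, excluding
    gas-phase molecules.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    ops = []
    times = []
    for f in frames:
        vec = extract_chain_vectors(f)
        if largest_cluster_only:
            labels = cluster_molecules(f, cluster_cutoff).labels
            sizes = np.bincount(labels[labels >= 0]) if np.any(labels >= 0) else None
            if sizes is not None and len(sizes):
                keep = labels == int(np.argmax(sizes))
                vec = ChainVectorSet(vec.vectors[keep], vec.centroids[keep],
                                     vec.molecule_ids[keep])
        ops.append(compute_op(vec))
        times.append(np.nan if f.time_label is None else float(f.time_label))
    ops = np.asarray(ops)
    times = np.asarray(times)
    op_mean = float(ops.mean())

    if np.all(np.isnan(times)) or block_duration <= 0:
        block_means = np.array([op_mean])
    else:
        t0 = np.nanmin(times)
        span = np.nanmax(times) - t0
        # each frame represents one sampling interval; the final block is
        # complete when the last frame's interval reaches its end
        finite = np.sort(times[~np.isnan(times)])
        dt = float(np.median(np.diff(finite))) if len(finite) > 1 else 0.0
        if span + dt < block_duration:
            block_means = np.array([op_mean])
        else:
            idx = np.floor((times - t0) / block_duration).astype(int)
            n_complete = int(np.floor((span + dt + 1e-12) / block_duration))
            block_means = np.array([
                ops[idx == b].mean() for b in range(n_complete)
                if np.any(idx == b)
            ])
    op_std = float(block_means.std(ddof=1)) if len(block_means) > 1 else 0.0
    return OPResult(op_per_frame=ops, times=times, op_mean=op_mean,
                    op_std=op_std, block_duration=block_duration,
                    n_molecules=frames[0].n_molecules)


def tilt_angles(vectors: ChainVectorSet | np.ndarray) -> np.ndarray:
    """Angle of each chain vector to the interface normal +z, in degrees
    within [0, 180]."""
    u = _unit_vectors(vectors)
    return np.degrees(np.arccos(np.clip(u[:, 2], -1.0, 1.0)))


def classify_upright(vectors: ChainVectorSet | np.ndarray,
                     threshold_deg: float = DEFAULT_UPRIGHT_THRESHOLD) -> np.ndarray:
    """Boolean per molecule: upright iff tilt < threshold (default 45 deg)."""
    if not 0.0 < threshold_deg < 90.0:
        raise ValueError("threshold must be in (0, 90) degrees")
    return tilt_angles(vectors) < threshold_deg


def cluster_molecules(frame: MonolayerFrame,
                      cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> ClusterLabels:
    """Single-linkage clustering of molecules on in-plane centroid distance.

    Two molecules are linked when their centroid separation in x, y (under
    periodic images in the box) is below ``cutoff``; clusters are the
    transitive closure. Labels are deterministic, ordered by the smallest
    member molecule id; molecules in no pair are singletons labelled -1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cent = frame.centroids()[:, :2].copy()
    box = frame.box[:2]
    cent %= box
    n = len(cent)
    tree = cKDTree(cent, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return ClusterLabels(labels=-np.ones(n, dtype=int), cutoff=cutoff)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    labels = -np.ones(n, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    counts = np.bincount(comp)
    for m in range(n):
        c = comp[m]
        if counts[c] < 2:
            continue
        if c not in seen:
            seen[c] = next_label
            next_label += 1
        labels[m] = seen[c]
    return ClusterLabels(labels=labels, cutoff=cutoff)
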