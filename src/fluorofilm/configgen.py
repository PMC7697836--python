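"""Synthetic monolayer configurations of (per)fluorinated fatty alcohols.

Builds rigid helical fluorocarbon chains and flexible all-trans hydrogenated
chains from ideal internal coordinates, and places them at the air-water
interface in the arrangements a Langmuir film explores along its compression
isotherm: 2D-crystalline hexagonal domains, gas/aggregate coexistence,
liquid-like disordered films, and laterally segregated two-component films.

The generated frames stand in for molecular-dynamics trajectories of such
films: they reproduce the structural statistics (hexagonal packing near
a = 0.575 nm, upright chains, tunable tilt and positional disorder) without
any force field. Water is never instantiated — no statistic computed by this
package uses it; the interface is the z = 0 plane to which head groups are
anchored with a small vertical jitter.

Geometry: C-C 0.154 nm, C-C-C 114 deg; fluorocarbon backbones use a fixed
torsion of 163.5 deg (the ~15/7 helix, rise ~0.13 nm per carbon),
hydrogenated backbones are all-trans (180 deg). This reproduces the known
fully extended molecular lengths (~1.8 nm for F14OH, ~2.5 nm for F18OH)
without energy minimisation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .frames import MonolayerFrame

__all__ = [
    "MoleculeTemplate",
    "GeneratorSpec",
    "build_chain",
    "generate_hex_domain",
    "generate_gas_cluster",
    "generate_liquid_film",
    "generate_segregated_mixture",
    "generate",
]

# Bond lengths (nm) and angles (deg) for ideal chain construction.
BOND_CC = 0.154
BOND_CF = 0.135
BOND_CH = 0.109
BOND_CO = 0.143
BOND_OH = 0.096
ANGLE_CCC = 114.0
ANGLE_SUB = 109.47       # X-C-X substituent angle
TORSION_HELIX = 163.5    # fluorocarbon helical backbone torsion
TORSION_TRANS = 180.0    # hydrogenated all-trans backbone torsion

HEAD_Z_JITTER = 0.05     # nm, vertical jitter of the anchored head group
HARD_CORE_RADIUS = 0.40  # nm, in-plane exclusion for liquid/gas placement
MAX_INSERTION_TRIALS = 10_000

_SPECIES_RE = re.compile(r"^([FH])(\d+)OH$")


@dataclass
class MoleculeTemplate:
    """Reference conformation of one fatty-alcohol molecule.

    The template is built head-down/tail-up: the chain axis (head carbon ->
    terminal carbon) lies along +z with the head carbon at the origin, so
    generators only rotate and translate copies.
    """

    name: str
    element_sequence: np.ndarray          # (N,) element symbols
    positions: np.ndarray                 # (N, 3) reference coordinates, nm
    internal_coordinates: dict            # bond lengths / angles / torsions used
    head_atom_index: int                  # carbon bonded to the hydroxyl oxygen
    tail_atom_index: int                  # terminal chain carbon
    contour_length: float                 # |head -> tail| of this conformation, nm

    def __post_init__(self) -> None:
        self.element_sequence = np.asarray(self.element_sequence, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.head_atom_index == self.tail_atom_index:
            raise ValueError("head and tail must be distinct atoms")
        for idx in (self.head_atom_index, self.tail_atom_index):
            if self.element_sequence[idx] != "C":
                raise ValueError("head/tail must be carbon atoms")
        if self.contour_length <= 0:
            raise ValueError("contour_length must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.element_sequence)


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic film.

    ``lattice_parameter`` is the 2D hexagonal lattice constant a (nm);
    ``area_per_molecule`` is the nominal film area A (nm^2/molecule) used to
    size the box for gas and liquid arrangements; ``tilt_sigma`` (deg) and
    ``positional_sigma`` (nm) control orientational and positional disorder.
    """

    template: MoleculeTemplate
    n_molecules: int
    lattice_parameter: float = 0.575
    tilt_sigma: float = 0.0
    positional_sigma: float = 0.0
    area_per_molecule: float = 0.30
    arrangement: str = "hex_crystal"
    seed: int = 0
    aggregate_fraction: float = 0.75   # gas_cluster only
    hard_core: float = HARD_CORE_RADIUS

    def __post_init__(self) -> None:
        if self.lattice_parameter <= 0:
            raise ValueError("lattice parameter must be positive")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.tilt_sigma < 0 or self.positional_sigma < 0:
            raise ValueError("disorder sigmas must be non-negative")
        if self.arrangement not in (
            "hex_crystal", "liquid", "gas_cluster", "segregated_mixture"
        ):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NERF placement: position d with |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) as given."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-math.cos(ang),
                               math.cos(tor) * math.sin(ang),
                               math.sin(tor) * math.sin(ang)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _pair_substituents(center: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
                       bond: float) -> list[np.ndarray]:
    """Two substituents on a backbone carbon, symmetric about the plane of
    its two bonded neighbours."""
    d1 = nb1 - center
    d1 /= np.linalg.norm(d1)
    d2 = nb2 - center
    d2 /= np.linalg.norm(d2)
    bis = -(d1 + d2)
    bis /= np.linalg.norm(bis)
    nrm = np.cross(d1, d2)
    nrm /= np.linalg.norm(nrm)
    half = math.radians(ANGLE_SUB / 2.0)
    return [center + bond * (math.cos(half) * bis + s * math.sin(half) * nrm)
            for s in (+1.0, -1.0)]


def _terminal_substituents(center: np.ndarray, neighbour: np.ndarray,
                           reference: np.ndarray, bond: float) -> list[np.ndarray]:
    """Three substituents on the terminal carbon, staggered relative to the
    backbone (reference = second-to-last backbone atom)."""
    axis = center - neighbour
    axis /= np.linalg.norm(axis)
    ref = reference - neighbour
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = math.radians(180.0 - ANGLE_SUB)  # polar angle from +axis
    out = []
    for az_deg in (60.0, 180.0, 300.0):
        az = math.radians(az_deg)
        direction = (math.cos(theta) * axis
                     + math.sin(theta) * (math.cos(az) * e1 + math.sin(az) * e2))
        out.append(center + bond * direction)
    return out


def _build_alcohol(n_carbons: int, fluorinated: bool,
                   torsions: np.ndarray) -> tuple[list[str], np.ndarray, int, int]:
    """Build one 1H,1H-alcohol: O, hydroxyl H, then C1..Cn each followed by
    its substituents. Returns (elements, positions, head index, tail index).

    ``torsions`` are the backbone dihedral angles O-C1-C2-C3, C1-C2-C3-C4, ...
    (n_carbons - 2 values).
    """
    if n_carbons < 2:
        raise ValueError("chains need at least two carbons")
    # backbone: O, C1, C2 seeded in a plane, the rest by torsion placement
    ang_ocC = 109.5
    o = np.zeros(3)
    c1 = np.array([BOND_CO, 0.0, 0.0])
    a = math.radians(180.0 - ANGLE_CCC)
    c2 = c1 + BOND_CC * np.array([math.cos(a), math.sin(a), 0.0])
    backbone = [c1, c2]
    chain = [o, c1, c2]
    for k in range(n_carbons - 2):
        new = _place_atom(chain[-3], chain[-2], chain[-1],
                          BOND_CC, ANGLE_CCC, float(torsions[k]))
        backbone.append(new)
        chain.append(new)
    backbone = np.array(backbone)          # carbons C1..Cn
    # hydroxyl hydrogen, anti to C1
    h_o = _place_atom(backbone[1], backbone[0], o, BOND_OH, 108.0, 180.0)

    sub_el = "F" if fluorinated else "H"
    sub_bond = BOND_CF if fluorinated else BOND_CH

    elements: list[str] = ["O", "H"]
    coords: list[np.ndarray] = [o, h_o]
    head_idx = tail_idx = -1
    for i in range(n_carbons):
        if i == 0:
            head_idx = len(elements)
        if i == n_carbons - 1:
            tail_idx = len(elements)
        elements.append("C")
        coords.append(backbone[i])
        if i == n_carbons - 1:
            subs = _terminal_substituents(backbone[i], backbone[i - 1],
                                          backbone[i - 2] if n_carbons > 2 else o,
                                          sub_bond)
            el = sub_el
        else:
            prev = o if i == 0 else backbone[i - 1]
            subs = _pair_substituents(backbone[i], prev, backbone[i + 1], sub_bond)
            # C1 of a 1H,1H-perfluoro alcohol is a CH2 group
            el = "H" if (fluorinated and i == 0) else sub_el
        for s in subs:
            elements.append(el)
            coords.append(s)
    positions = np.array(coords)

    # orient: chain axis head -> tail along +z, head carbon at the origin
    axis = positions[tail_idx] - positions[head_idx]
    axis /= np.linalg.norm(axis)
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, target))
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        positions = positions @ rot.T
    elif c < 0:
        positions = positions * np.array([1.0, -1.0, -1.0])
    positions -= positions[head_idx]
    return elements, positions, head_idx, tail_idx


def build_chain(species: str, conformation: str | None = None) -> MoleculeTemplate:
    """Build the minimum-energy conformation template for one alcohol species.

    Parameters
    ----------
    species : str
        ``"F12OH"``..``"F18OH"`` (1H,1H-perfluorinated) or ``"H12OH"``..
        ``"H18OH"`` (hydrogenated), even carbon numbers 12-18.
    conformation : ``"helical"`` or ``"all_trans"``
        Defaults to helical for F-species and all-trans for H-species.
        Helical is only valid for fluorocarbons.
    """
    m = _SPECIES_RE.match(species)
    if not m:
        raise ValueError(f"unknown species {species!r}")
    fluorinated = m.group(1) == "F"
    n_c = int(m.group(2))
    if n_c not in (12, 14, 16, 18):
        raise ValueError(f"unsupported chain length in {species!r}")
    if conformation is None:
        conformation = "helical" if fluorinated else "all_trans"
    if conformation not in ("helical", "all_trans"):
        raise ValueError(f"unknown conformation {conformation!r}")
    if conformation == "helical" and not fluorinated:
        raise ValueError("helical conformation is only valid for fluorocarbons")
    torsion = TORSION_HELIX if conformation == "helical" else TORSION_TRANS
    torsions = np.full(n_c - 2, torsion)
    elements, positions, head, tail = _build_alcohol(n_c, fluorinated, torsions)
    contour = float(np.linalg.norm(positions[tail] - positions[head]))
    return MoleculeTemplate(
        name=species,
        element_sequence=np.array(elements, dtype=object),
        positions=positions,
        internal_coordinates={
            "bond_cc_nm": BOND_CC, "angle_ccc_deg": ANGLE_CCC,
            "backbone_torsion_deg": torsion, "conformation": conformation,
        },
        head_atom_index=head,
        tail_atom_index=tail,
        contour_length=contour,
    )


def _test_template(n_carbons: int = 2) -> MoleculeTemplate:
    """Tiny all-trans test species (not a physical alcohol); used in tests."""
    torsions = np.full(max(n_carbons - 2, 0), TORSION_TRANS)
    elements, positions, head, tail = _build_alcohol(n_carbons, False, torsions)
    contour = float(np.linalg.norm(positions[tail] - positions[head]))
    return MoleculeTemplate(
        name=f"H{n_carbons}OH-test",
        element_sequence=np.array(elements, dtype=object),
        positions=positions,
        internal_coordinates={"backbone_torsion_deg": TORSION_TRANS,
                              "conformation": "all_trans"},
        head_atom_index=head, tail_atom_index=tail, contour_length=contour,
    )


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _spiral_lattice_sites(n: int, a: float) -> np.ndarray:
    """First ``n`` sites of a triangular lattice, spiral-filled from a central
    site so any count yields a compact quasi-hexagonal patch. Distance ties
    are broken by lower azimuth."""
    rings = int(math.ceil(1.2 * math.sqrt(n))) + 2
    idx = np.arange(-rings, rings + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    x = a * (ii + jj / 2.0)
    y = a * (jj * math.sqrt(3.0) / 2.0)
    pts = np.column_stack([x.ravel(), y.ravel()])
    r = np.hypot(pts[:, 0], pts[:, 1])
    az = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * math.pi)
    order = np.lexsort((az, np.round(r / a, 9)))
    if len(order) < n:
        raise ValueError("lattice patch too small (internal)")
    return pts[order[:n]]


def _tilt_rotation(tilt_rad: float, azimuth_rad: float) -> np.ndarray:
    """Rotation tilting +z by ``tilt_rad`` towards in-plane azimuth."""
    axis = np.array([-math.sin(azimuth_rad), math.cos(azimuth_rad), 0.0])
    c, s = math.cos(tilt_rad), math.sin(tilt_rad)
    vx = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) + s * vx + (1 - c) * (vx @ vx)


def _spin_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _assemble(template: MoleculeTemplate, sites_xy: np.ndarray,
              spins: np.ndarray, tilts_deg: np.ndarray, tilt_az: np.ndarray,
              head_z: np.ndarray,
              mol_positions: list[np.ndarray] | None = None) -> np.ndarray:
    """Place one rotated copy of the template per site.

    Each molecule is spun about its own chain axis, tilted away from +z, then
    translated so its centroid sits over the site in-plane and its head
    carbon at head_z. Returns the (n*|mol|, 3) coordinate block.
    """
    blocks = []
    base = template.positions
    for k in range(len(sites_xy)):
        mol = base if mol_positions is None else mol_positions[k]
        rot = _tilt_rotation(math.radians(tilts_deg[k]), tilt_az[k]) @ _spin_z(spins[k])
        placed = mol @ rot.T
        shift = np.array([sites_xy[k, 0], sites_xy[k, 1], 0.0])
        centroid = placed.mean(axis=0)
        shift[:2] -= centroid[:2]
        shift[2] = head_z[k] - placed[template.head_atom_index, 2]
        blocks.append(placed + shift)
    return np.vstack(blocks)


def _frame_from_blocks(template: MoleculeTemplate, coords: np.ndarray,
                       n_mol: int, box: np.ndarray,
                       meta: dict | None = None) -> MonolayerFrame:
    n_at = template.n_atoms
    elements = np.tile(template.element_sequence, n_mol)
    mol_idx = np.repeat(np.arange(n_mol), n_at)
    return MonolayerFrame(coords, elements, mol_idx, box, meta=meta or {})


def _fit_box(coords: np.ndarray, margin: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Box enclosing coords with margin; returns (shifted coords, box)."""
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    shift = margin - lo
    shift[2] = -lo[2] + 0.5
    box = hi - lo + 2 * margin
    box[2] = hi[2] - lo[2] + 1.0
    return coords + shift, box


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_hex_domain(spec: GeneratorSpec) -> MonolayerFrame:
    """A 2D-crystalline domain: upright chains on a triangular lattice.

    With zero disorder every in-plane nearest-neighbour centroid distance
    equals the lattice parameter exactly and all chain vectors point along
    +z. ``tilt_sigma`` draws per-molecule tilt magnitudes from a half-normal
    law; ``positional_sigma`` jitters the lattice sites isotropically
    in-plane. Output is bit-identical for identical spec (including seed).
    """
    if spec.arrangement not in ("hex_crystal",):
        raise ValueError("spec.arrangement must be 'hex_crystal'")
    n = spec.n_molecules
    rng = np.random.default_rng(spec.seed)
    sites = _spiral_lattice_sites(n, spec.lattice_parameter)
    # fixed draw order: spin, tilt magnitude, tilt azimuth, xy jitter, z jitter
    spins = rng.uniform(0.0, 2.0 * math.pi, n)
    tilts = np.abs(rng.normal(0.0, spec.tilt_sigma, n)) if spec.tilt_sigma > 0 \
        else np.zeros(n)
    tilt_az = rng.uniform(0.0, 2.0 * math.pi, n)
    if spec.positional_sigma > 0:
        sites = sites + rng.normal(0.0, spec.positional_sigma, (n, 2))
    head_z = rng.normal(0.0, HEAD_Z_JITTER, n) if spec.positional_sigma > 0 \
        else np.zeros(n)
    coords = _assemble(spec.template, sites, spins, tilts, tilt_az, head_z)
    coords, box = _fit_box(coords)
    meta = {"species": np.array([spec.template.name] * n, dtype=object),
            "true_tilt_deg": tilts}
    return _frame_from_blocks(spec.template, coords, n, box, meta)


def generate_gas_cluster(spec: GeneratorSpec) -> MonolayerFrame:
    """Gas/aggregate coexistence: one crystalline aggregate plus free molecules.

    A fraction ``spec.aggregate_fraction`` of the molecules forms a single
    hexagonal aggregate at the box centre; the remainder are placed at
    uniformly random unoccupied in-plane positions with orientations uniform
    on the upper hemisphere (an upright-to-lying mixture). Free molecules are
    kept at least 0.75 nm in-plane from the aggregate and from one another so
    the aggregate is recoverable as a single cluster at the default cutoff.
    """
    f = spec.aggregate_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("aggregate fraction must be in [0, 1]")
    n = spec.n_molecules
    n_agg = int(round(f * n))
    n_gas = n - n_agg
    rng = np.random.default_rng(spec.seed)
    box_l = math.sqrt(n * spec.area_per_molecule)
    template = spec.template

    sites_list: list[np.ndarray] = []
    spins_list: list[float] = []
    tilts_list: list[float] = []
    tilt_az_list: list[float] = []

    if n_agg:
        agg_sites = _spiral_lattice_sites(n_agg, spec.lattice_parameter)
        agg_sites = agg_sites + box_l / 2.0
        spins_list += list(rng.uniform(0.0, 2.0 * math.pi, n_agg))
        agg_tilt = (np.abs(rng.normal(0.0, spec.tilt_sigma, n_agg))
                    if spec.tilt_sigma > 0 else np.zeros(n_agg))
        tilts_list += list(agg_tilt)
        tilt_az_list += list(rng.uniform(0.0, 2.0 * math.pi, n_agg))
        sites_list += list(agg_sites)

    gas_exclusion = 0.75  # nm; keeps free molecules outside the cluster cutoff
    occupied = list(sites_list)
    for _ in range(n_gas):
        placed = False
        for _trial in range(MAX_INSERTION_TRIALS):
            xy = rng.uniform(0.0, box_l, 2)
            if occupied:
                occ = np.asarray(occupied)
                d = occ - xy
                d -= box_l * np.round(d / box_l)
                if np.min(np.hypot(d[:, 0], d[:, 1])) < gas_exclusion:
                    continue
            occupied.append(xy)
            sites_list.append(xy)
            # orientation uniform on the upper hemisphere: cos(tilt) ~ U(0,1)
            uz = rng.uniform(0.0, 1.0)
            tilts_list.append(math.degrees(math.acos(uz)))
            tilt_az_list.append(rng.uniform(0.0, 2.0 * math.pi))
            spins_list.append(rng.uniform(0.0, 2.0 * math.pi))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place gas molecule: box too crowded")

    sites = np.asarray(sites_list)
    spins = np.asarray(spins_list)
    tilts = np.asarray(tilts_list)
    tilt_az = np.asarray(tilt_az_list)
    coords = _assemble(template, sites, spins, tilts, tilt_az, np.zeros(n))
    box = np.array([box_l, box_l, template.contour_length + 2.0])
    coords[:, 2] -= coords[:, 2].min() - 0.5
    meta = {
        "species": np.array([template.name] * n, dtype=object),
        "true_tilt_deg": tilts,
        "aggregate_mask": np.arange(n) < n_agg,
    }
    return _frame_from_blocks(template, coords, n, box, meta)


def generate_liquid_film(spec: GeneratorSpec) -> MonolayerFrame:
    """Liquid-like disordered film: random sequential insertion of centroids
    with a hard-core exclusion, broad orientational disorder, and torsional
    noise on the backbone (flexible hydrogenated chains).

    The result is amorphous: its computed in-plane diffraction spectrum has
    no sharp Bragg peak and its alignment order parameter falls well below
    that of a crystalline film of equal size.
    """
    n = spec.n_molecules
    rng = np.random.default_rng(spec.seed)
    box_l = math.sqrt(n * spec.area_per_molecule)
    hard_core = spec.hard_core
    # RSA of hard disks jams near 55% coverage; disk radius is hard_core/2
    if hard_core > 0 and n * math.pi * (hard_core / 2.0)**2 > 0.50 * box_l**2:
        raise ValueError("packing density infeasible for hard-core radius")

    sites = np.empty((n, 2))
    placed = 0
    while placed < n:
        ok = False
        for _trial in range(MAX_INSERTION_TRIALS):
            xy = rng.uniform(0.0, box_l, 2)
            if placed and hard_core > 0:
                d = sites[:placed] - xy
                d -= box_l * np.round(d / box_l)
                if np.min(np.hypot(d[:, 0], d[:, 1])) < hard_core:
                    continue
            sites[placed] = xy
            ok = True
            break
        if not ok:
            raise RuntimeError("random sequential insertion failed: too dense")
        placed += 1

    spins = rng.uniform(0.0, 2.0 * math.pi, n)
    tilt_sigma = spec.tilt_sigma if spec.tilt_sigma > 0 else 35.0
    tilts = np.minimum(np.abs(rng.normal(0.0, tilt_sigma, n)), 89.0)
    tilt_az = rng.uniform(0.0, 2.0 * math.pi, n)
    head_z = rng.normal(0.0, HEAD_Z_JITTER, n)

    # flexible chains: rebuild each backbone with torsional noise
    tmpl = spec.template
    conf = tmpl.internal_coordinates.get("conformation", "all_trans")
    base_torsion = tmpl.internal_coordinates.get(
        "backbone_torsion_deg",
        TORSION_HELIX if conf == "helical" else TORSION_TRANS)
    m = _SPECIES_RE.match(tmpl.name)
    mol_positions = None
    if m:
        n_c = int(m.group(2))
        fluorinated = m.group(1) == "F"
        torsion_noise = 12.0  # deg; gauche-forming flexibility
        mol_positions = []
        for _ in range(n):
            tors = base_torsion + rng.normal(0.0, torsion_noise, n_c - 2)
            _, pos, _, _ = _build_alcohol(n_c, fluorinated, tors)
            mol_positions.append(pos)

    coords = _assemble(tmpl, sites, spins, tilts, tilt_az, head_z, mol_positions)
    box = np.array([box_l, box_l, tmpl.contour_length + 2.0])
    coords[:, 2] -= coords[:, 2].min() - 0.5
    meta = {"species": np.array([tmpl.name] * n, dtype=object),
            "true_tilt_deg": tilts}
    return _frame_from_blocks(tmpl, coords, n, box, meta)


def generate_segregated_mixture(spec_a: GeneratorSpec, spec_b: GeneratorSpec,
                                mixing_ratio: float) -> MonolayerFrame:
    """Two-component film with laterally segregated, species-pure domains.

    ``mixing_ratio`` is the molar fraction of species A in the film; the
    total molecule count is ``spec_a.n_molecules + spec_b.n_molecules``.
    Species B condenses as a compact hexagonal domain, species A as a
    thread-like two-row strip, the two separated by a gap wider than any
    clustering cutoff — emulating the separate 2D crystallisation of the two
    alcohols in a mixed film.
    """
    if not 0.0 < mixing_ratio < 1.0:
        raise ValueError("mixing_ratio must be in (0, 1)")
    n_total = spec_a.n_molecules + spec_b.n_molecules
    n_a = int(round(mixing_ratio * n_total))
    n_b = n_total - n_a
    if n_a < 1 or n_b < 1:
        raise ValueError("mixing_ratio leaves one species empty")
    rng = np.random.default_rng(spec_a.seed)

    # compact domain of B
    sites_b = _spiral_lattice_sites(n_b, spec_b.lattice_parameter)
    # thread of A: two-row strip on its own lattice
    a_par = spec_a.lattice_parameter
    n_cols = (n_a + 1) // 2
    strip = []
    for k in range(n_a):
        col, row = divmod(k, 2)
        strip.append([col * a_par + row * a_par / 2.0,
                      row * a_par * math.sqrt(3.0) / 2.0])
    sites_a = np.asarray(strip)
    # place the strip above the B domain with a 2.5 nm gap, centred in x
    gap = 2.5
    sites_a[:, 0] += sites_b[:, 0].mean() - sites_a[:, 0].mean()
    sites_a[:, 1] += sites_b[:, 1].max() + gap - sites_a[:, 1].min()

    def _draws(nk, sigma):
        spins = rng.uniform(0.0, 2.0 * math.pi, nk)
        tilts = np.abs(rng.normal(0.0, sigma, nk)) if sigma > 0 else np.zeros(nk)
        t_az = rng.uniform(0.0, 2.0 * math.pi, nk)
        return spins, tilts, t_az

    spins_b, tilts_b, az_b = _draws(n_b, spec_b.tilt_sigma)
    spins_a, tilts_a, az_a = _draws(n_a, spec_a.tilt_sigma)
    coords_b = _assemble(spec_b.template, sites_b, spins_b, tilts_b, az_b,
                         np.zeros(n_b))
    coords_a = _assemble(spec_a.template, sites_a, spins_a, tilts_a, az_a,
                         np.zeros(n_a))
    coords = np.vstack([coords_b, coords_a])
    coords, box = _fit_box(coords)

    elements = np.concatenate([
        np.tile(spec_b.template.element_sequence, n_b),
        np.tile(spec_a.template.element_sequence, n_a),
    ])
    mol_idx = np.concatenate([
        np.repeat(np.arange(n_b), spec_b.template.n_atoms),
        np.repeat(n_b + np.arange(n_a), spec_a.template.n_atoms),
    ])
    species = np.array([spec_b.template.name] * n_b
                       + [spec_a.template.name] * n_a, dtype=object)
    meta = {"species": species,
            "true_tilt_deg": np.concatenate([tilts_b, tilts_a])}
    return MonolayerFrame(coords, elements, mol_idx, box, meta=meta)


def generate(spec: GeneratorSpec) -> MonolayerFrame:
    """Dispatch on ``spec.arrangement`` (single-species arrangements)."""
    if spec.arrangement == "hex_crystal":
        return generate_hex_domain(spec)
    if spec.arrangement == "gas_cluster":
        return generate_gas_cluster(spec)
    if spec.arrangement == "liquid":
        return generate_liquid_film(spec)
    raise ValueError(f"use generate_segregated_mixture for {spec.arrangement!r}")
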