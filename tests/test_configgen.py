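"""Chain builder and film generators: geometry, composition, determinism."""

import math

import numpy as np
import pytest
from scipy.spatial import Voronoi
from scipy.spatial.distance import pdist, squareform

from fluorofilm import (GeneratorSpec, build_chain, compute_op,
                        extract_chain_vectors, generate_gas_cluster,
                        generate_hex_domain, generate_liquid_film,
                        generate_segregated_mixture)
from fluorofilm.configgen import BOND_CC, _test_template


class TestBuildChain:
    @pytest.mark.parametrize("species,quoted_length", [
        ("F14OH", 1.8),   # fully extended molecular length, nm
        ("F18OH", 2.5),
    ])
    def test_contour_length_matches_extended_molecule(self, species,
                                                      quoted_length):
        t = build_chain(species, "helical")
        assert abs(t.contour_length - quoted_length) / quoted_length < 0.15

    def test_two_carbon_all_trans_head_tail_is_one_bond(self):
        # single C-C bond: head-tail distance is the bond length itself
        t = _test_template(2)
        assert t.contour_length == pytest.approx(BOND_CC, abs=1e-12)

    def test_reference_conformation_is_upright(self, f18):
        v = f18.positions[f18.tail_atom_index] - f18.positions[f18.head_atom_index]
        assert v[0] == pytest.approx(0.0, abs=1e-9)
        assert v[1] == pytest.approx(0.0, abs=1e-9)
        assert v[2] > 0

    def test_fluorinated_composition(self, f14):
        els = list(f14.element_sequence)
        # CF3(CF2)12CH2OH: 14 C, 27 F, 1 O, 3 H (2 on C1 + hydroxyl)
        assert els.count("C") == 14
        assert els.count("F") == 27
        assert els.count("O") == 1
        assert els.count("H") == 3

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            build_chain("F13OH")
        with pytest.raises(ValueError):
            build_chain("X14OH")

    def test_helical_invalid_for_hydrogenated(self):
        with pytest.raises(ValueError):
            build_chain("H14OH", "helical")


class TestHexDomain:
    def test_zero_disorder_nearest_neighbour_distance(self, hex61):
        d = squareform(pdist(hex61.centroids()[:, :2]))
        np.fill_diagonal(d, np.inf)
        assert d.min(axis=1) == pytest.approx(0.575, abs=1e-9)

    def test_interior_voronoi_area_is_hexagonal_cell(self, hex61):
        cents = hex61.centroids()[:, :2]
        vor = Voronoi(cents)
        central = int(np.argmin(np.linalg.norm(cents - cents.mean(axis=0),
                                               axis=1)))
        region = vor.regions[vor.point_region[central]]
        assert -1 not in region
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        assert area == pytest.approx(math.sqrt(3) / 2 * 0.575**2, rel=1e-6)

    def test_zero_tilt_order_parameter_is_one(self, hex61):
        vec = extract_chain_vectors(hex61)
        assert compute_op(vec) == pytest.approx(1.0, abs=1e-12)

    def test_seed_reproducibility(self, f14):
        spec = GeneratorSpec(template=f14, n_molecules=37, tilt_sigma=8.0,
                             positional_sigma=0.02, seed=11)
        a = generate_hex_domain(spec)
        b = generate_hex_domain(spec)
        assert np.array_equal(a.positions, b.positions)
        c = generate_hex_domain(GeneratorSpec(template=f14, n_molecules=37,
                                              tilt_sigma=8.0,
                                              positional_sigma=0.02, seed=12))
        assert not np.array_equal(a.positions, c.positions)

    def test_negative_sigma_rejected(self, f14):
        with pytest.raises(ValueError):
            GeneratorSpec(template=f14, n_molecules=10, tilt_sigma=-1.0)

    def test_op_nonincreasing_in_tilt_disorder(self, f14):
        # averaged over 5 seeds, OP falls monotonically with tilt_sigma
        sigmas = [0.0, 10.0, 25.0, 45.0, 60.0]
        means = []
        for sigma in sigmas:
            ops = []
            for seed in range(5):
                spec = GeneratorSpec(template=f14, n_molecules=64,
                                     tilt_sigma=sigma, seed=seed)
                ops.append(compute_op(extract_chain_vectors(
                    generate_hex_domain(spec))))
            means.append(np.mean(ops))
        assert np.all(np.diff(means) <= 1e-9)


class TestGasCluster:
    def test_aggregate_plus_singletons_by_construction(self, gas_48_16):
        from fluorofilm import cluster_molecules
        labels = cluster_molecules(gas_48_16).labels
        sizes = np.bincount(labels[labels >= 0])
        assert list(sizes) == [48]
        assert int((labels == -1).sum()) == 16

    def test_fraction_one_is_a_crystal(self, f14):
        spec = GeneratorSpec(template=f14, n_molecules=61,
                             arrangement="gas_cluster", aggregate_fraction=1.0,
                             area_per_molecule=1.29, seed=4)
        frame = generate_gas_cluster(spec)
        d = squareform(pdist(frame.centroids()[:, :2]))
        np.fill_diagonal(d, np.inf)
        assert d.min(axis=1) == pytest.approx(spec.lattice_parameter, abs=1e-9)
        assert compute_op(extract_chain_vectors(frame)) == pytest.approx(
            1.0, abs=1e-12)

    def test_gas_only_orientations_are_hemisphere_isotropic(self, f14):
        # |E[u]|^2 = 1/4 for orientations uniform on the upper hemisphere
        spec = GeneratorSpec(template=f14, n_molecules=1200,
                             arrangement="gas_cluster", aggregate_fraction=0.0,
                             area_per_molecule=4.0, seed=9)
        frame = generate_gas_cluster(spec)
        op = compute_op(extract_chain_vectors(frame))
        assert op == pytest.approx(0.25, abs=0.03)

    def test_bad_fraction_rejected(self, f14):
        spec = GeneratorSpec(template=f14, n_molecules=10,
                             arrangement="gas_cluster", aggregate_fraction=1.5)
        with pytest.raises(ValueError):
            generate_gas_cluster(spec)


class TestLiquidFilm:
    def test_less_ordered_than_crystal(self, h18, f18):
        n = 200
        liq = generate_liquid_film(GeneratorSpec(
            template=h18, n_molecules=n, arrangement="liquid",
            area_per_molecule=0.60, seed=1))
        hexf = generate_hex_domain(GeneratorSpec(
            template=f18, n_molecules=n, tilt_sigma=5.0, seed=1))
        op_liq = compute_op(extract_chain_vectors(liq))
        op_hex = compute_op(extract_chain_vectors(hexf))
        assert op_liq < op_hex

    def test_single_molecule_zero_core_is_valid(self, h18):
        spec = GeneratorSpec(template=h18, n_molecules=1, arrangement="liquid",
                             area_per_molecule=1.0, hard_core=0.0, seed=0)
        frame = generate_liquid_film(spec)
        assert frame.n_molecules == 1
        assert np.all(np.isfinite(frame.positions))

    def test_centroid_pair_correlation_is_liquid_like(self, h18):
        # g(r) ~ 1 beyond a few molecular diameters: no long-range order
        spec = GeneratorSpec(template=h18, n_molecules=400,
                             arrangement="liquid", area_per_molecule=0.60,
                             seed=2)
        frame = generate_liquid_film(spec)
        xy = frame.centroids()[:, :2] % frame.box[:2]
        box = frame.box[:2]
        delta = xy[:, None, :] - xy[None, :, :]
        delta -= box * np.round(delta / box)
        r = np.hypot(delta[..., 0], delta[..., 1])
        iu = np.triu_indices(len(xy), k=1)
        r = r[iu]
        rho = len(xy) / (box[0] * box[1])
        edges = np.arange(3.0, min(box) / 2, 0.25)
        counts, _ = np.histogram(r, bins=edges)
        shell = math.pi * (edges[1:]**2 - edges[:-1]**2)
        g = counts / (0.5 * len(xy) * rho * shell)
        assert np.all(np.abs(g - 1.0) < 0.2)

    def test_infeasible_density_rejected(self, h18):
        spec = GeneratorSpec(template=h18, n_molecules=500,
                             arrangement="liquid", area_per_molecule=0.10,
                             hard_core=0.40, seed=0)
        with pytest.raises(ValueError):
            generate_liquid_film(spec)


@pytest.fixture(scope="module")
def mixture(f14, f18):
    sa = GeneratorSpec(template=f14, n_molecules=20, seed=5)
    sb = GeneratorSpec(template=f18, n_molecules=80, seed=5)
    return generate_segregated_mixture(sa, sb, 0.2)


class TestSegregatedMixture:

    def test_composition_matches_mixing_ratio(self, mixture):
        species = mixture.meta["species"]
        assert int((species == "F14OH").sum()) == 20
        assert int((species == "F18OH").sum()) == 80

    def test_clusters_are_species_pure(self, mixture):
        from fluorofilm import cluster_molecules
        labels = cluster_molecules(mixture).labels
        species = mixture.meta["species"]
        for lab in set(labels[labels >= 0]):
            assert len(set(species[labels == lab])) == 1

    def test_counts_conserved_through_file_round_trip(self, mixture, tmp_path):
        from fluorofilm import read_frames, write_frames
        path = tmp_path / "mix.gro"
        write_frames(mixture, path)
        back = read_frames(path)[0]
        assert back.n_molecules == mixture.n_molecules
        assert back.n_atoms == mixture.n_atoms

    def test_bad_ratio_rejected(self, f14, f18):
        sa = GeneratorSpec(template=f14, n_molecules=10)
        sb = GeneratorSpec(template=f18, n_molecules=10)
        with pytest.raises(ValueError):
            generate_segregated_mixture(sa, sb, 1.2)
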