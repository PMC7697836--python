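import math

import numpy as np
import pytest

from fluorofilm import (GeneratorSpec, MonolayerFrame, build_chain,
                        generate_gas_cluster, generate_hex_domain)


@pytest.fixture(scope="session")
def f14():
    return build_chain("F14OH")


@pytest.fixture(scope="session")
def f18():
    return build_chain("F18OH")


@pytest.fixture(scope="session")
def h18():
    return build_chain("H18OH")


@pytest.fixture(scope="session")
def hex61(f14):
    """Zero-disorder 61-molecule hexagonal domain, a = 0.575 nm."""
    spec = GeneratorSpec(template=f14, n_molecules=61,
                         lattice_parameter=0.575, seed=1)
    return generate_hex_domain(spec)


@pytest.fixture(scope="session")
def gas_48_16(f14):
    """64 molecules, one 48-molecule aggregate + 16 free molecules."""
    spec = GeneratorSpec(template=f14, n_molecules=64,
                         arrangement="gas_cluster", area_per_molecule=1.29,
                         aggregate_fraction=0.75, seed=3)
    return generate_gas_cluster(spec)


def minimal_chain_frame(directions, length=0.15):
    """Frame of 3-atom (O-C-C) stand-in molecules whose chain vectors point
    along the given unit directions; used to exercise order-parameter
    statistics with hand-chosen geometry."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    positions, elements, mol = [], [], []
    for m, d in enumerate(directions):
        d = d / np.linalg.norm(d)
        origin = np.array([2.0 * m + 1.0, 1.0, 1.0])
        head = origin
        tail = origin + length * d
        oxy = origin - 0.14 * d
        positions += [oxy, head, tail]
        elements += ["O", "C", "C"]
        mol += [m, m, m]
    positions = np.asarray(positions)
    box = positions.max(axis=0) + 2.0
    return MonolayerFrame(positions, np.array(elements, dtype=object),
                          np.asarray(mol), box)


def hex_q10(a):
    """First Bragg position of a 2D hexagonal lattice with parameter a."""
    return 4.0 * math.pi / (math.sqrt(3.0) * a)
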