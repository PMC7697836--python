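"""In-plane diffraction from coordinates, peak fitting, hexagonal indexing.

Computes the Q_xy spectrum of a generated crystalline monolayer via the 2D
Debye sum, fits the first three peaks, verifies the 1 : sqrt(3) : 2
hexagonal sequence, and recovers the lattice parameter and area per
molecule.
"""

import math

from fluorofilm import (GeneratorSpec, build_chain, compute_spectrum,
                        fit_peak, generate_hex_domain, index_hexagonal,
                        peak_ratios)

spec = GeneratorSpec(template=build_chain("F14OH"), n_molecules=169,
                     lattice_parameter=0.575, seed=1)
frame = generate_hex_domain(spec)
spectrum = compute_spectrum(frame, q_min=8.0, q_max=28.0, dq=0.02,
                            atom_filter=("C",))

p1 = fit_peak(spectrum, (10.0, 16.0), shape="gaussian")
p2 = fit_peak(spectrum, (20.0, 24.0), shape="gaussian")
p3 = fit_peak(spectrum, (24.0, 26.5), shape="gaussian")
print(f"fitted peaks: {p1.center:.2f}, {p2.center:.2f}, {p3.center:.2f} "
      f"nm^-1 (FWHM of first: {p1.fwhm:.2f} nm^-1)")

r = peak_ratios([p1.center, p2.center, p3.center])
print(f"position ratios {r[0]:.3f}, {r[1]:.3f} vs sqrt(3) = "
      f"{math.sqrt(3):.3f} and 2 — a hexagonal lattice")

lattice = index_hexagonal([p1.center, p2.center, p3.center])
print(f"indexed (10) peak: a = {lattice.a:.3f} nm, area per molecule = "
      f"{lattice.area_per_molecule:.3f} nm^2 (input lattice was 0.575 nm)")
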