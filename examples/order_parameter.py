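"""Chain-alignment order parameter of crystalline vs liquid-like films.

The order parameter is the mean cosine between all pairs of molecular
end-to-end vectors: 1 for perfect parallel alignment, ~0.25 for orientations
uniform on the upper hemisphere. Rigid fluorocarbon films stay near 1 even
with a few degrees of tilt disorder; flexible hydrogenated films fall well
below.
"""

import numpy as np

from fluorofilm import (GeneratorSpec, build_chain, compute_op,
                        extract_chain_vectors, generate_hex_domain,
                        generate_liquid_film, tilt_angles)

n = 200

f18 = GeneratorSpec(template=build_chain("F18OH"), n_molecules=n,
                    tilt_sigma=5.0, seed=1)
crystal = generate_hex_domain(f18)
vec_c = extract_chain_vectors(crystal)
print(f"F18OH crystalline domain (5 deg tilt disorder): "
      f"OP = {compute_op(vec_c):.3f}, median tilt "
      f"{np.median(tilt_angles(vec_c)):.1f} deg")

h18 = GeneratorSpec(template=build_chain("H18OH"), n_molecules=n,
                    arrangement="liquid", area_per_molecule=0.60, seed=1)
liquid = generate_liquid_film(h18)
vec_l = extract_chain_vectors(liquid)
print(f"H18OH liquid-like film: OP = {compute_op(vec_l):.3f}, median tilt "
      f"{np.median(tilt_angles(vec_l)):.1f} deg")

print("the fluorinated film is far more aligned than the hydrogenated one "
      "at equal size — the signature of rigid helical chains")
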