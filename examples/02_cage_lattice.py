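"""Generate the parametric trussed cage and export it.

Builds the default PLIF-class strut lattice (25 x 10 x 11 mm box, 0.6 mm
struts, crossing diagonals, posterior screw-insertion block with enlarged
effective strut diameter) and writes it as a plain-text node/strut file
plus a VTK file for visualisation.
"""

import numpy as np

import trusscage as tc

lattice = tc.generate_cage(tc.CageParams(), seed=0)
print(f"nodes:  {len(lattice.nodes)}")
print(f"struts: {len(lattice.struts)}")
print(f"lateral strut surface: {lattice.lateral_surface_area():.1f} mm^2")

block = lattice.sets["screw_block"]
diams = sorted({d for _, _, d in lattice.struts})
print(f"strut diameters (free, block): {diams} mm")
print(f"screw-block nodes: {len(block)} of {len(lattice.nodes)}")

# bilateral mirror symmetry about the midsagittal plane (y = 0)
ys = np.sort(lattice.nodes[:, 1])
print(f"mirror symmetric in y: {np.allclose(ys, -ys[::-1], atol=1e-9)}")

tc.write_lattice_txt(lattice, "cage.txt")
tc.write_lattice_vtk(lattice, "cage.vtk")
print("wrote cage.txt and cage.vtk")
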