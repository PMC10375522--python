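"""Solvent-cage difference scattering from an RDF library.

Builds a coarse (r12, r23, alpha) library of synthetic radial
distribution functions for acetonitrile, then evaluates the cage term
(cross + displaced volume) for a geometry off the grid nodes via
trilinear interpolation, and reports the first-solvation-shell radius.
"""

import numpy as np

from trixs import SoluteGeometry, get_solvent
from trixs.cage import (
    CageGridSpec,
    CageModel,
    ShellParams,
    build_library,
    first_shell_radius,
    synth_rdf,
)

acn = get_solvent("acetonitrile")
grid = CageGridSpec.coarse()
lib = build_library(grid, acn, ShellParams(), r=np.linspace(0, 12, 241))
print(f"library: {lib.node_count} structural nodes, types {lib.types}")

q = np.round(np.arange(0.5, 4.5 + 1e-9, 0.02), 10)
cage = CageModel(lib, acn, q)
es = SoluteGeometry(3.08, 5.23, 1.05)  # off-node geometry
diff = cage.difference(es, acn.gs_geometry)
print(f"cage difference at q=1.0: {diff[np.argmin(np.abs(q-1.0))]:.3f} e.u.")
print(f"cage difference at q=2.0: {diff[np.argmin(np.abs(q-2.0))]:.3f} e.u.")

r = np.linspace(0, 12, 961)
g = synth_rdf(acn.gs_geometry, acn, ShellParams(), r)[(0, "C")]
print(f"first solvation shell at {first_shell_radius(r, g):.2f} A")
# the shell radius is the cage size seen by the dissociating I fragment
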