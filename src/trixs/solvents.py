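"""Built-in solvent descriptions.

Each solvent carries the triiodide ground-state geometry refined from MD
in that solvent (bond lengths in Angstrom, angle in degrees converted to
radians), the number densities of its non-hydrogen atom types (used in
the solute-solvent cross term), its mean electron density (used in the
displaced-volume term), and the position of its main diffraction peak
(used to place the synthetic heating reference).

Ground-state structures:

    solvent       R(I2-)  R(I2- - I)  alpha
    acetonitrile  2.95    3.06        172 deg
    water         2.92    3.14        170 deg
    ethanol       2.94    3.07        171 deg
    methanol      2.94    3.09        172 deg

Number densities are derived from the liquid mass densities at ambient
conditions (e.g. water 0.997 g/cm^3 -> 0.0334 molecules/A^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scattering import SoluteGeometry

__all__ = ["SolventSpec", "SOLVENTS", "get_solvent"]


@dataclass(frozen=True)
class SolventSpec:
    """Solvent parameters needed by the cage and heating terms."""

    name: str
    #: non-hydrogen atom types -> number density in atoms/A^3
    atom_densities: dict[str, float]
    #: element of the nearest non-hydrogen contact atom (O, or C for MeCN)
    contact_element: str
    gs_geometry: SoluteGeometry
    #: mean electron density of the bulk liquid, e-/A^3
    electron_density: float
    #: q-position of the main diffraction peak, 1/A (heating-curve center)
    main_peak_q: float

    def __post_init__(self):
        if any(rho <= 0 for rho in self.atom_densities.values()):
            raise ValueError("atom number densities must be positive")
        if self.electron_density <= 0:
            raise ValueError("electron density must be positive")


def _geom(r12: float, r23: float, alpha_deg: float) -> SoluteGeometry:
    return SoluteGeometry(r12, r23, np.deg2rad(alpha_deg))


SOLVENTS: dict[str, SolventSpec] = {
    "acetonitrile": SolventSpec(
        name="acetonitrile",
        atom_densities={"C": 0.02306, "N": 0.01153},
        contact_element="C",
        gs_geometry=_geom(2.95, 3.06, 172.0),
        electron_density=0.254,
        main_peak_q=1.6,
    ),
    "water": SolventSpec(
        name="water",
        atom_densities={"O": 0.03340},
        contact_element="O",
        gs_geometry=_geom(2.92, 3.14, 170.0),
        electron_density=0.334,
        main_peak_q=2.0,
    ),
    "ethanol": SolventSpec(
        name="ethanol",
        atom_densities={"O": 0.01031, "C": 0.02062},
        contact_element="O",
        gs_geometry=_geom(2.94, 3.07, 171.0),
        electron_density=0.268,
        main_peak_q=1.5,
    ),
    "methanol": SolventSpec(
        name="methanol",
        atom_densities={"O": 0.01489, "C": 0.01489},
        contact_element="O",
        gs_geometry=_geom(2.94, 3.09, 172.0),
        electron_density=0.268,
        main_peak_q=1.7,
    ),
}


def get_solvent(name: str) -> SolventSpec:
    try:
        return SOLVENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown solvent {name!r}; available: {sorted(SOLVENTS)}"
        ) from None
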