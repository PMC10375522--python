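"""Solute scattering for the three-iodine system.

The solute is described by two bond lengths and the I-I-I angle
(:class:`SoluteGeometry`). Isotropic scattering follows the Debye
equation -- the orientational average of the coherent scattering of a
rigid molecule,

    S0(q) = sum_i sum_j Fi(q) Fj(q) sinc(q d_ij),

with disorder-damped atomic form factors. The anisotropic component
created by photoselection with linearly polarized light is

    S2(q) = c2 * sum_{i != j} Fi(q) Fj(q) P2(cos zeta_ij) j2(q d_ij),

where zeta_ij is the angle between the i-j interatomic vector and the
transition dipole, P2 the second Legendre polynomial and j2 the
second-order spherical Bessel function. Self-terms carry no orientation
dependence and are excluded from S2.

Sign convention: S2 is evaluated with a positive overall prefactor, so a
positive anisotropy amplitude with the transition dipole along the long
molecular axis produces a positive S2 where P2(cos zeta) j2(q d) > 0.
The same convention is used by the synthetic-data generator and the
azimuthal decomposition, so the pipeline is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formfactors import dw_form_factor

__all__ = [
    "SoluteGeometry",
    "DWParams",
    "DipoleConvention",
    "ScatteringCurve",
    "debye_scattering",
    "debye_scattering_atoms",
    "anisotropic_scattering",
    "difference_solute",
    "sinc_qd",
    "sph_j2",
]

_MIN_SEPARATION = 1e-6  # Angstrom; below this two atoms are "coincident"


@dataclass(frozen=True)
class SoluteGeometry:
    """Triiodide geometry: I1-I2 bond, I2-I3 bond, I1-I2-I3 angle.

    Atom 2 is the central iodine. ``r12`` is the bond forming the I2-
    fragment after dissociation, ``r23`` the (breaking) interfragment
    distance, and ``alpha`` the bond angle in radians.
    """

    r12: float
    r23: float
    alpha: float

    def __post_init__(self):
        if not (self.r12 > 0 and self.r23 > 0):
            raise ValueError("bond lengths must be positive")
        if not (0.0 <= self.alpha <= np.pi):
            raise ValueError("alpha must lie in [0, pi] rad")

    @property
    def d13(self) -> float:
        """Terminal-terminal distance by the law of cosines."""
        return float(
            np.sqrt(
                self.r12**2
                + self.r23**2
                - 2.0 * self.r12 * self.r23 * np.cos(self.alpha)
            )
        )

    def positions(self) -> np.ndarray:
        """Cartesian coordinates (3, 3), molecule in the xy-plane.

        I2 at the origin, I1 on the +x axis, I3 at angle alpha from the
        I2->I1 bond. For alpha = pi the molecule is linear along x.
        """
        return np.array(
            [
                [self.r12, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [self.r23 * np.cos(self.alpha), self.r23 * np.sin(self.alpha), 0.0],
            ]
        )

    def distances(self) -> np.ndarray:
        """Pairwise distance matrix (3, 3)."""
        p = self.positions()
        return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)


@dataclass(frozen=True)
class DWParams:
    """Per-atom positional rmsd (Angstrom) for Debye-Waller-like damping."""

    sigma: tuple[float, float, float] = (0.5, 0.5, 0.7)

    def __post_init__(self):
        if len(self.sigma) != 3 or any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be three non-negative values")


@dataclass(frozen=True)
class DipoleConvention:
    """Unit transition-dipole direction in the molecular frame.

    ``axis=None`` selects the default: the end-to-end I1->I3 direction of
    the (nearly linear) ion, the conventional polarization of the 400 nm
    transition.
    """

    axis: tuple[float, float, float] | None = None

    def unit_vector(self, geometry: SoluteGeometry) -> np.ndarray:
        if self.axis is None:
            p = geometry.positions()
            v = p[2] - p[0]
        else:
            v = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError("transition dipole has zero norm")
        return v / n


@dataclass
class ScatteringCurve:
    """Scattering values on a strictly increasing q-grid.

    Units: q in 1/Angstrom, values in electron units per solute molecule.
    """

    q: np.ndarray
    values: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.values.shape:
            raise ValueError("q and values must be matching 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __sub__(self, other: "ScatteringCurve") -> "ScatteringCurve":
        if not np.array_equal(self.q, other.q):
            raise ValueError("q-grids do not match")
        return ScatteringCurve(self.q, self.values - other.values)

    def __mul__(self, a: float) -> "ScatteringCurve":
        return ScatteringCurve(self.q, self.values * a)

    __rmul__ = __mul__


def sinc_qd(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the series limit at small argument."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def sph_j2(x) -> np.ndarray:
    """Spherical Bessel function j2, stable at small argument.

    j2(x) = (3/x^2 - 1) sin(x)/x - 3 cos(x)/x^2; below |x| = 1e-3 the
    Taylor series x^2/15 - x^4/210 is used (relative error < 1e-13).
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)  # avoid 0/0 in the masked lanes
    exact = (3.0 / xs**2 - 1.0) * np.sin(xs) / xs - 3.0 * np.cos(xs) / xs**2
    series = x**2 / 15.0 - x**4 / 210.0
    return np.where(small, series, exact)


def _dw_factors(q: np.ndarray, dw: DWParams, elements=("I", "I", "I")) -> np.ndarray:
    return np.array([dw_form_factor(q, s, el) for s, el in zip(dw.sigma, elements)])


def debye_scattering_atoms(
    positions: np.ndarray, sigmas, q, elements=None
) -> ScatteringCurve:
    """Debye scattering of an arbitrary small cluster of atoms.

    ``positions`` is (n, 3) in Angstrom; ``sigmas`` per-atom rmsd values.
    The double sum runs over all (i, j) including self-terms (sinc -> 1).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    q = np.asarray(q, dtype=float)
    n = positions.shape[0]
    if elements is None:
        elements = ["I"] * n
    F = np.array([dw_form_factor(q, s, el) for s, el in zip(sigmas, elements)])
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    s = np.zeros_like(q)
    for i in range(n):
        for j in range(n):
            s = s + F[i] * F[j] * sinc_qd(q * d[i, j])
    return ScatteringCurve(q, s)


def debye_scattering(
    geometry: SoluteGeometry, dw: DWParams, q
) -> ScatteringCurve:
    """Isotropic solute scattering S0(q) of the three-iodine arrangement."""
    q = np.asarray(q, dtype=float)
    d = geometry.distances()
    off = d[~np.eye(3, dtype=bool)]
    if np.any(off < _MIN_SEPARATION):
        raise ValueError("degenerate geometry: coincident atoms")
    F = _dw_factors(q, dw)
    s = np.zeros_like(q)
    for i in range(3):
        for j in range(3):
            s = s + F[i] * F[j] * sinc_qd(q * d[i, j])
    return ScatteringCurve(q, s)


def anisotropic_scattering(
    geometry: SoluteGeometry,
    dw: DWParams,
    dipole: DipoleConvention,
    c2: float,
    q,
) -> ScatteringCurve:
    """Anisotropic solute scattering S2(q); self-terms excluded."""
    q = np.asarray(q, dtype=float)
    p = geometry.positions()
    mu = dipole.unit_vector(geometry)
    F = _dw_factors(q, dw)
    s = np.zeros_like(q)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            v = p[i] - p[j]
            dij = np.linalg.norm(v)
            if dij < _MIN_SEPARATION:
                raise ValueError("degenerate geometry: coincident atoms")
            cz = np.dot(v, mu) / dij
            p2 = 0.5 * (3.0 * cz**2 - 1.0)
            s = s + F[i] * F[j] * p2 * sph_j2(q * dij)
    return ScatteringCurve(q, c2 * s)


def difference_solute(
    g_es: SoluteGeometry, g_gs: SoluteGeometry, dw: DWParams, q
) -> ScatteringCurve:
    """Difference solute scattering: S0(excited) - S0(ground)."""
    return debye_scattering(g_es, dw, q) - debye_scattering(g_gs, dw, q)
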