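"""Composite forward model of the time-resolved difference scattering.

Two laser-induced species are modeled at every time point: the geminate
pair (GP), with refinable geometry (r12, r23, alpha), and the solvent-
separated nongeminate pair (NG), with the same I2- bond length but a
fixed interfragment distance of 100 A and alpha = pi. The isotropic
difference signal is

    dS0 = A_iso [ A_GP dS0_GP + (1 - A_GP) dS0_NG ] + A_heat dS_heat,

where each species term is its solute difference (excited minus ground)
plus its cage difference, and dS_heat is the solvent heating reference.
The anisotropic signal contains solute terms only,

    dS2 = A_ani [ A_GP S2_GP + (1 - A_GP) S2_NG ];

the unexcited ground state is isotropic, so its S2 vanishes and the
species anisotropy is the excited-structure S2 alone. The photoselection
prefactor c2 is absorbed into the time-dependent amplitude A_ani(t).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cage import CageModel, RDFLibrary
from .formfactors import dw_form_factor
from .scattering import (
    DipoleConvention,
    DWParams,
    ScatteringCurve,
    SoluteGeometry,
    sinc_qd,
    sph_j2,
)
from .solvents import SolventSpec

__all__ = ["ParameterVector", "NGConvention", "ForwardModel", "model_iso", "model_aniso"]


@dataclass(frozen=True)
class ParameterVector:
    """Refinable per-timepoint state x = (r12, r23, alpha, A_iso, A_GP, A_heat, A_ani)."""

    r12: float
    r23: float
    alpha: float
    A_iso: float
    A_GP: float
    A_heat: float
    A_ani: float

    def __post_init__(self):
        if not (0.0 <= self.A_GP <= 1.0):
            raise ValueError("A_GP must lie in [0, 1]")
        if self.A_iso < 0:
            raise ValueError("A_iso must be non-negative")
        SoluteGeometry(self.r12, self.r23, self.alpha)  # validate geometry

    @property
    def geometry(self) -> SoluteGeometry:
        return SoluteGeometry(self.r12, self.r23, self.alpha)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.r12, self.r23, self.alpha, self.A_iso, self.A_GP, self.A_heat, self.A_ani]
        )

    @classmethod
    def from_array(cls, a) -> "ParameterVector":
        return cls(*(float(v) for v in a))


PARAM_NAMES = ("r12", "r23", "alpha", "A_iso", "A_GP", "A_heat", "A_ani")


@dataclass(frozen=True)
class NGConvention:
    """Fixed structural convention for the solvent-separated pair."""

    r23: float = 100.0
    alpha: float = np.pi


class ForwardModel:
    """Evaluates dS0(x) and dS2(x) on a fixed q-grid.

    Caches the disorder-damped form factors, the ground-state curves and
    the cage node interpolant so that per-timepoint evaluation stays
    cheap inside the refinement loop.
    """

    def __init__(
        self,
        solvent: SolventSpec,
        q,
        library: RDFLibrary | None = None,
        heating: ScatteringCurve | None = None,
        dw: DWParams = DWParams(),
        dipole: DipoleConvention = DipoleConvention(),
        ng: NGConvention = NGConvention(),
        gs: SoluteGeometry | None = None,
    ):
        self.q = np.asarray(q, dtype=float)
        self.solvent = solvent
        self.gs = gs if gs is not None else solvent.gs_geometry
        self.dw = dw
        self.dipole = dipole
        self.ng = ng
        self._F = np.array([dw_form_factor(self.q, s) for s in dw.sigma])
        # cached form-factor products for the fast evaluation path
        self._Fself = self._F[0] ** 2 + self._F[1] ** 2 + self._F[2] ** 2
        self._F01 = 2.0 * self._F[0] * self._F[1]
        self._F12 = 2.0 * self._F[1] * self._F[2]
        self._F02 = 2.0 * self._F[0] * self._F[2]
        self.cage = (
            CageModel(library, solvent, self.q) if library is not None else None
        )
        if self.cage is not None:
            from .cage import gaussian_sphere_amplitude

            fdv = gaussian_sphere_amplitude(
                self.q, self.cage.excluded_radius, solvent.electron_density
            )
            self._fdv2 = fdv * fdv
        else:
            self._fdv2 = np.zeros_like(self.q)
        if heating is not None and not np.array_equal(
            np.asarray(heating.q), self.q
        ):
            raise ValueError("heating reference is not on the model q-grid")
        self.heating = heating
        self._s0_gs = self._s0(self.gs)
        self._cross_gs = self.cage.cross(self.gs) if self.cage else 0.0
        self._dv_gs = self.cage.dv(self.gs) if self.cage else 0.0

    # -- solute terms -------------------------------------------------
    def _s0(self, geom: SoluteGeometry) -> np.ndarray:
        d = geom.distances()
        F = self._F
        s = F[0] ** 2 + F[1] ** 2 + F[2] ** 2
        for i, j in ((0, 1), (0, 2), (1, 2)):
            s = s + 2.0 * F[i] * F[j] * sinc_qd(self.q * d[i, j])
        return s

    def _s2(self, geom: SoluteGeometry) -> np.ndarray:
        p = geom.positions()
        mu = self.dipole.unit_vector(geom)
        F = self._F
        s = np.zeros_like(self.q)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            v = p[i] - p[j]
            dij = float(np.linalg.norm(v))
            cz = float(np.dot(v, mu)) / dij
            p2 = 0.5 * (3.0 * cz**2 - 1.0)
            s = s + 2.0 * F[i] * F[j] * p2 * sph_j2(self.q * dij)
        return s

    def _cage_difference(self, geom: SoluteGeometry) -> np.ndarray:
        if self.cage is None:
            return np.zeros_like(self.q)
        grid = self.cage.library.grid
        clamped = SoluteGeometry(
            min(max(geom.r12, grid.r12[0]), grid.r12[-1]),
            min(max(geom.r23, grid.r23[0]), grid.r23[-1]),
            min(max(geom.alpha, grid.alpha[0]), grid.alpha[-1]),
        )
        return (self.cage.cross(clamped) - self._cross_gs) + (
            self.cage.dv(geom) - self._dv_gs
        )

    def ng_geometry(self, r12: float) -> SoluteGeometry:
        return SoluteGeometry(r12, self.ng.r23, self.ng.alpha)

    def species_iso(self, geom: SoluteGeometry) -> np.ndarray:
        """dS0 of one species: solute difference plus cage difference."""
        return (self._s0(geom) - self._s0_gs) + self._cage_difference(geom)

    # -- composite model ----------------------------------------------
    def iso(self, x: ParameterVector) -> np.ndarray:
        return self.iso_array(x.to_array())

    def aniso(self, x: ParameterVector) -> np.ndarray:
        return self.aniso_array(x.to_array())

    # -- fast array path (hot loop of the refinement) ------------------
    def _distances(self, r12: float, r23: float, alpha: float):
        d13 = np.sqrt(
            r12 * r12 + r23 * r23 - 2.0 * r12 * r23 * np.cos(alpha)
        )
        return r12, r23, d13

    def _species_iso_fast(self, r12: float, r23: float, alpha: float):
        d12, d23, d13 = self._distances(r12, r23, alpha)
        s01 = sinc_qd(self.q * d12)
        s12 = sinc_qd(self.q * d23)
        s02 = sinc_qd(self.q * d13)
        out = (
            self._Fself
            + self._F01 * s01
            + self._F12 * s12
            + self._F02 * s02
            - self._s0_gs
        )
        if self.cage is not None:
            out = out + self.cage.cross_clamped(r12, r23, alpha) - self._cross_gs
            dv = self._fdv2 * (3.0 + 2.0 * (s01 + s12 + s02))
            out = out + dv - self._dv_gs
        return out

    def _species_aniso_fast(self, r12: float, r23: float, alpha: float):
        ca, sa = np.cos(alpha), np.sin(alpha)
        p0 = np.array([r12, 0.0])
        p2 = np.array([r23 * ca, r23 * sa])
        if self.dipole.axis is None:
            mu = p2 - p0
            mu = mu / np.linalg.norm(mu)
        else:
            ax = np.asarray(self.dipole.axis, dtype=float)
            mu = ax[:2] / np.linalg.norm(ax)
        s = np.zeros_like(self.q)
        for (v, d, fprod) in (
            (p0, r12, self._F01),
            (-p2, r23, self._F12),
            (p0 - p2, None, self._F02),
        ):
            dij = float(np.linalg.norm(v)) if d is None else d
            cz = float(np.dot(v, mu)) / dij
            p2leg = 0.5 * (3.0 * cz * cz - 1.0)
            s = s + fprod * p2leg * sph_j2(self.q * dij)
        return s

    def iso_array(self, x: np.ndarray) -> np.ndarray:
        """dS0 from a raw parameter array (no validation; hot path)."""
        if self.heating is None:
            raise ValueError("no heating reference configured")
        r12, r23, alpha, a_iso, a_gp, a_heat, _ = x
        gp = self._species_iso_fast(r12, r23, alpha)
        ng = self._species_iso_fast(r12, self.ng.r23, self.ng.alpha)
        return a_iso * (a_gp * gp + (1.0 - a_gp) * ng) + a_heat * self.heating.values

    def aniso_array(self, x: np.ndarray) -> np.ndarray:
        """dS2 from a raw parameter array (no validation; hot path)."""
        r12, r23, alpha, _, a_gp, _, a_ani = x
        gp = self._species_aniso_fast(r12, r23, alpha)
        ng = self._species_aniso_fast(r12, self.ng.r23, self.ng.alpha)
        return a_ani * (a_gp * gp + (1.0 - a_gp) * ng)


def model_iso(
    x: ParameterVector,
    gs: SoluteGeometry,
    library: RDFLibrary | None,
    solvent: SolventSpec,
    q,
    heating: ScatteringCurve,
    dw: DWParams = DWParams(),
) -> ScatteringCurve:
    """Total modeled isotropic difference scattering dS0(q; x)."""
    fm = ForwardModel(solvent, q, library=library, heating=heating, dw=dw, gs=gs)
    return ScatteringCurve(fm.q, fm.iso(x))


def model_aniso(
    x: ParameterVector,
    gs: SoluteGeometry,
    solvent: SolventSpec,
    q,
    dipole: DipoleConvention = DipoleConvention(),
    dw: DWParams = DWParams(),
) -> ScatteringCurve:
    """Total modeled anisotropic difference scattering dS2(q; x)."""
    fm = ForwardModel(solvent, q, dipole=dipole, dw=dw, gs=gs)
    return ScatteringCurve(fm.q, fm.aniso(x))
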