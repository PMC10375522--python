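"""Solvent-cage difference scattering.

The cage contribution to the difference signal has two parts:

* a solute-solvent *cross term* computed from radial distribution
  functions g_Iv(r) of solvent atoms of type v around each iodine,

      S_cross(q) = sum_i sum_v F_I(q) F_v(q) 4 pi rho_v
                   Integral r^2 (g_iv(r) - 1) sinc(q r) dr,

* a *displaced-volume* (DV) term: the scattering of the bulk solvent
  excluded by the solute, modeled as one Gaussian dummy-solvent sphere
  per iodine site.

RDFs live in a library indexed on a regular (r12, r23, alpha) grid of
solute geometries; off-node geometries are evaluated by per-q trilinear
interpolation between the eight enclosing nodes. The library emulates
the frozen-solute MD construction with a parametric RDF model: an
excluded core, a Gaussian first solvation shell, and a bulk tail. The
shell position can optionally track the solute geometry through a linear
coupling; the default coupling of zero gives geometry-independent
shells, the simplest testable stand-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formfactors import atomic_form_factor
from .scattering import ScatteringCurve, SoluteGeometry, sinc_qd
from .solvents import SolventSpec

__all__ = [
    "CageGridSpec",
    "ShellParams",
    "RDFLibrary",
    "synth_rdf",
    "build_library",
    "cage_cross_term",
    "displaced_volume_term",
    "interpolate_cage",
    "trilinear_weights",
    "cage_difference",
    "first_shell_radius",
    "CageModel",
]

#: van der Waals radius of iodine, Angstrom (default DV excluded radius)
IODINE_VDW_RADIUS = 1.98


def _uniform_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class CageGridSpec:
    """Regular structural grid of the RDF library."""

    r12: np.ndarray = field(
        default_factory=lambda: _uniform_axis(2.6, 5.0, 0.2)
    )
    r23: np.ndarray = field(
        default_factory=lambda: _uniform_axis(2.6, 13.8, 0.2)
    )
    alpha: np.ndarray = field(
        default_factory=lambda: _uniform_axis(0.0, np.pi, 0.131)[
            : int(np.floor(np.pi / 0.131)) + 1
        ]
    )

    def __post_init__(self):
        for name in ("r12", "r23", "alpha"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.ndim != 1 or len(ax) < 2:
                raise ValueError(f"{name} axis needs >= 2 nodes")
            steps = np.diff(ax)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError(f"{name} axis must be uniform and increasing")

    @property
    def node_count(self) -> int:
        return len(self.r12) * len(self.r23) * len(self.alpha)

    @classmethod
    def coarse(cls, n12=5, n23=7, na=5) -> "CageGridSpec":
        """Small grid for desk-scale tests and the default scenario."""
        return cls(
            r12=np.linspace(2.6, 3.6, n12),
            r23=np.linspace(2.6, 6.2, n23),
            alpha=np.linspace(0.5, np.pi, na),
        )


@dataclass(frozen=True)
class ShellParams:
    """Parametric first-solvation-shell model for synthetic RDFs."""

    peak_radius: float = 3.6  # Angstrom, first-shell position
    width: float = 0.45  # Gaussian shell width
    amplitude: float = 0.9  # peak height above bulk (g_max = 1 + amplitude)
    core_radius: float = 2.8  # hard core: g = 0 below
    #: linear coupling of the terminal-atom shell position to that atom's
    #: nearest-neighbor distance change; 0 = geometry-independent shells
    geometry_coupling: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("shell width must be positive")
        if self.core_radius < 0 or self.peak_radius <= 0:
            raise ValueError("radii must be positive")


def synth_rdf(
    geometry: SoluteGeometry,
    solvent: SolventSpec,
    shell: ShellParams = ShellParams(),
    r: np.ndarray | None = None,
) -> dict[tuple[int, str], np.ndarray]:
    """Synthetic g_Iv(r) around each of the three iodine atoms.

    Returns a dict keyed by (atom index 0..2, solvent atom type). The
    terminal-atom shells (atoms 0 and 2) shift with the solute geometry
    by ``geometry_coupling`` times the change of that atom's nearest-
    neighbor distance relative to a 3.0 A reference; the central atom's
    shell is fixed.
    """
    if r is None:
        r = np.linspace(0.0, 12.0, 481)
    r = np.asarray(r, dtype=float)
    d = geometry.distances()
    nn = [min(d[0, 1], d[0, 2]), min(d[0, 1], d[1, 2]), min(d[1, 2], d[0, 2])]
    out: dict[tuple[int, str], np.ndarray] = {}
    for i in range(3):
        shift = 0.0
        if i != 1:
            shift = shell.geometry_coupling * (nn[i] - 3.0)
        peak = shell.peak_radius + shift
        g = 1.0 + shell.amplitude * np.exp(-0.5 * ((r - peak) / shell.width) ** 2)
        g[r < shell.core_radius] = 0.0
        for v in solvent.atom_densities:
            out[(i, v)] = g.copy()
    return out


@dataclass
class RDFLibrary:
    """RDF curves on the structural grid.

    ``g`` has shape (n12, n23, nalpha, 3 atoms, ntypes, nr); ``types``
    orders the solvent atom types along the 5th axis.
    """

    grid: CageGridSpec
    r: np.ndarray
    g: np.ndarray
    types: tuple[str, ...]
    solvent_name: str = ""

    def __post_init__(self):
        expect = (
            len(self.grid.r12),
            len(self.grid.r23),
            len(self.grid.alpha),
            3,
            len(self.types),
            len(self.r),
        )
        if self.g.shape != expect:
            raise ValueError(f"g has shape {self.g.shape}, expected {expect}")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def node_count(self) -> int:
        return self.grid.node_count


def build_library(
    grid: CageGridSpec,
    solvent: SolventSpec,
    shell: ShellParams = ShellParams(),
    r: np.ndarray | None = None,
) -> RDFLibrary:
    """Populate an RDF library over the full structural grid.

    Deterministic given (grid, solvent, shell). The node count is
    reported by ``RDFLibrary.node_count``.
    """
    if r is None:
        r = np.linspace(0.0, 12.0, 481)
    types = tuple(solvent.atom_densities)
    g = np.empty(
        (len(grid.r12), len(grid.r23), len(grid.alpha), 3, len(types), len(r))
    )
    for a, r12 in enumerate(grid.r12):
        for b, r23 in enumerate(grid.r23):
            for c, alpha in enumerate(grid.alpha):
                try:
                    geom = SoluteGeometry(r12, r23, float(alpha))
                except ValueError:
                    geom = SoluteGeometry(r12, r23, np.pi)
                rdfs = synth_rdf(geom, solvent, shell, r)
                for i in range(3):
                    for k, v in enumerate(types):
                        g[a, b, c, i, k] = rdfs[(i, v)]
    return RDFLibrary(grid=grid, r=r, g=g, types=types, solvent_name=solvent.name)


def _taper(gm1: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Cosine taper of (g-1) over the last 10% of the radial grid."""
    r0 = r[-1] - 0.1 * (r[-1] - r[0])
    w = np.ones_like(r)
    tail = r > r0
    w[tail] = 0.5 * (1.0 + np.cos(np.pi * (r[tail] - r0) / (r[-1] - r0)))
    return gm1 * w


def cage_cross_term(
    rdfs: dict[tuple[int, str], np.ndarray],
    solvent: SolventSpec,
    q,
    r: np.ndarray | None = None,
    taper: bool = True,
    tol: float = 5e-2,
) -> ScatteringCurve:
    """Solute-solvent cross term from per-atom RDFs.

    Trapezoidal quadrature on the radial grid; (g - 1) is tapered by a
    cosine window over the last 10% of r to suppress truncation ringing.
    A warning is raised if any RDF has not converged to 1 at the edge.
    """
    if r is None:
        r = np.linspace(0.0, 12.0, 481)
    q = np.asarray(q, dtype=float)
    f_i = atomic_form_factor(q, "I")
    qr = np.outer(q, r)
    kernel = r**2 * sinc_qd(qr)  # (nq, nr)
    s = np.zeros_like(q)
    for (i, v), g in rdfs.items():
        gm1 = np.asarray(g, dtype=float) - 1.0
        if abs(gm1[-1]) > tol:
            warnings.warn(
                f"RDF for atom {i}, type {v} not converged to bulk at the "
                "radial grid edge; tapering applied",
                stacklevel=2,
            )
        if taper:
            gm1 = _taper(gm1, r)
        integral = np.trapezoid(kernel * gm1, r, axis=1)
        rho = solvent.atom_densities[v]
        s = s + f_i * atomic_form_factor(q, v) * 4.0 * np.pi * rho * integral
    return ScatteringCurve(q, s)


def gaussian_sphere_amplitude(
    q, radius: float, electron_density: float
) -> np.ndarray:
    """Scattering amplitude of a Gaussian dummy-solvent sphere.

    The sphere carries rho_e * V electrons with the standard Gaussian
    profile of equal volume: f(q) = rho_e V exp(-q^2 V^(2/3) / (4 pi)).
    """
    if radius < 0:
        raise ValueError("excluded radius must be non-negative")
    q = np.asarray(q, dtype=float)
    vol = 4.0 / 3.0 * np.pi * radius**3
    return electron_density * vol * np.exp(-(q**2) * vol ** (2.0 / 3.0) / (4.0 * np.pi))


def displaced_volume_term(
    geometry: SoluteGeometry,
    solvent: SolventSpec,
    q,
    excluded_radius: float = IODINE_VDW_RADIUS,
) -> ScatteringCurve:
    """Scattering of the solvent volume displaced by the solute.

    One Gaussian sphere per iodine site, summed coherently and
    orientationally averaged (Debye sum over the three sites).
    """
    q = np.asarray(q, dtype=float)
    f = gaussian_sphere_amplitude(q, excluded_radius, solvent.electron_density)
    d = geometry.distances()
    s = np.zeros_like(q)
    for i in range(3):
        for j in range(3):
            s = s + f * f * sinc_qd(q * d[i, j])
    return ScatteringCurve(q, s)


def trilinear_weights(axes, point):
    """Cell indices and corner weights for trilinear interpolation.

    Returns (idx, frac) with idx the lower corner along each axis and
    frac the fractional position in [0, 1] within the cell. Points
    outside the hull are clamped with a warning.
    """
    idx = []
    frac = []
    clamped = False
    for ax, x in zip(axes, point):
        ax = np.asarray(ax)
        if x < ax[0] or x > ax[-1]:
            clamped = True
            x = min(max(x, ax[0]), ax[-1])
        k = int(np.searchsorted(ax, x, side="right") - 1)
        k = min(max(k, 0), len(ax) - 2)
        idx.append(k)
        frac.append((x - ax[k]) / (ax[k + 1] - ax[k]))
    if clamped:
        warnings.warn("geometry outside the library hull; clamped", stacklevel=2)
    return tuple(idx), tuple(frac)


def interpolate_cage(
    geometry: SoluteGeometry, grid: CageGridSpec, node_curves: np.ndarray
) -> np.ndarray:
    """Per-q trilinear interpolation of node curves at a geometry.

    ``node_curves`` has shape (n12, n23, nalpha, nq).
    """
    axes = (grid.r12, grid.r23, grid.alpha)
    point = (geometry.r12, geometry.r23, geometry.alpha)
    (i, j, k), (u, v, w) = trilinear_weights(axes, point)
    c = node_curves
    out = (
        c[i, j, k] * (1 - u) * (1 - v) * (1 - w)
        + c[i + 1, j, k] * u * (1 - v) * (1 - w)
        + c[i, j + 1, k] * (1 - u) * v * (1 - w)
        + c[i, j, k + 1] * (1 - u) * (1 - v) * w
        + c[i + 1, j + 1, k] * u * v * (1 - w)
        + c[i + 1, j, k + 1] * u * (1 - v) * w
        + c[i, j + 1, k + 1] * (1 - u) * v * w
        + c[i + 1, j + 1, k + 1] * u * v * w
    )
    return out


class CageModel:
    """Cage difference scattering with precomputed node cross terms.

    Precomputes S_cross at every library node on the working q-grid so
    that per-geometry evaluation reduces to a trilinear interpolation
    plus the closed-form DV term.
    """

    def __init__(
        self,
        library: RDFLibrary,
        solvent: SolventSpec,
        q,
        excluded_radius: float = IODINE_VDW_RADIUS,
    ):
        self.library = library
        self.solvent = solvent
        self.q = np.asarray(q, dtype=float)
        self.excluded_radius = excluded_radius
        grid = library.grid
        n1, n2, n3 = len(grid.r12), len(grid.r23), len(grid.alpha)
        self.cross_nodes = np.empty((n1, n2, n3, len(self.q)))
        types = library.types
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a in range(n1):
                for b in range(n2):
                    for c in range(n3):
                        rdfs = {
                            (i, v): library.g[a, b, c, i, k]
                            for i in range(3)
                            for k, v in enumerate(types)
                        }
                        self.cross_nodes[a, b, c] = cage_cross_term(
                            rdfs, solvent, self.q, r=library.r
                        ).values

    def cross(self, geometry: SoluteGeometry) -> np.ndarray:
        return interpolate_cage(geometry, self.library.grid, self.cross_nodes)

    def cross_clamped(self, r12: float, r23: float, alpha: float) -> np.ndarray:
        """Trilinear cross-term lookup with silent clamping (hot path)."""
        grid = self.library.grid
        c = self.cross_nodes
        idx = []
        frac = []
        for ax, x in (
            (grid.r12, r12), (grid.r23, r23), (grid.alpha, alpha)
        ):
            if x <= ax[0]:
                idx.append(0)
                frac.append(0.0)
                continue
            if x >= ax[-1]:
                idx.append(len(ax) - 2)
                frac.append(1.0)
                continue
            k = int(np.searchsorted(ax, x, side="right") - 1)
            k = min(k, len(ax) - 2)
            idx.append(k)
            frac.append((x - ax[k]) / (ax[k + 1] - ax[k]))
        (i, j, k), (u, v, w) = idx, frac
        return (
            c[i, j, k] * (1 - u) * (1 - v) * (1 - w)
            + c[i + 1, j, k] * u * (1 - v) * (1 - w)
            + c[i, j + 1, k] * (1 - u) * v * (1 - w)
            + c[i, j, k + 1] * (1 - u) * (1 - v) * w
            + c[i + 1, j + 1, k] * u * v * (1 - w)
            + c[i + 1, j, k + 1] * u * (1 - v) * w
            + c[i, j + 1, k + 1] * (1 - u) * v * w
            + c[i + 1, j + 1, k + 1] * u * v * w
        )

    def dv(self, geometry: SoluteGeometry) -> np.ndarray:
        return displaced_volume_term(
            geometry, self.solvent, self.q, self.excluded_radius
        ).values

    def difference(
        self, g_es: SoluteGeometry, g_gs: SoluteGeometry
    ) -> np.ndarray:
        """dS_cage = [S_cross(es) - S_cross(gs)] + [S_DV(es) - S_DV(gs)]."""
        return (self.cross(g_es) - self.cross(g_gs)) + (
            self.dv(g_es) - self.dv(g_gs)
        )


def cage_difference(
    g_es: SoluteGeometry,
    g_gs: SoluteGeometry,
    library: RDFLibrary,
    solvent: SolventSpec,
    q,
    excluded_radius: float = IODINE_VDW_RADIUS,
) -> ScatteringCurve:
    """One-shot cage difference curve (builds a CageModel internally)."""
    model = CageModel(library, solvent, q, excluded_radius)
    return ScatteringCurve(np.asarray(q, dtype=float), model.difference(g_es, g_gs))


def first_shell_radius(
    r: np.ndarray, g: np.ndarray, smooth_window: int = 0,
    prominence: float = 0.05,
) -> float:
    """Radius of the first local maximum of g(r) above the bulk level.

    Only maxima exceeding 1 + ``prominence`` count as shell peaks, which
    guards against rounding-level wiggles of the bulk tail.
    ``smooth_window`` > 1 applies a moving-average of that many bins
    before peak picking (odd windows keep the grid registration).
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, kernel, mode="same")
    interior = (
        (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:]) & (g[1:-1] > 1.0 + prominence)
    )
    idx = np.nonzero(interior)[0]
    if len(idx) == 0:
        raise ValueError("no first-shell peak found in g(r)")
    return float(r[idx[0] + 1])
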