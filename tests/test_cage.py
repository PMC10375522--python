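"""Solvent-cage terms: RDFs, cross term, displaced volume, interpolation."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from trixs import SoluteGeometry, get_solvent
from trixs.cage import (
    CageGridSpec,
    CageModel,
    ShellParams,
    build_library,
    cage_cross_term,
    displaced_volume_term,
    first_shell_radius,
    gaussian_sphere_amplitude,
    interpolate_cage,
    synth_rdf,
    trilinear_weights,
)
from trixs.formfactors import atomic_form_factor


@pytest.fixture(scope="module")
def acn():
    return get_solvent("acetonitrile")


@pytest.fixture(scope="module")
def coarse_grid():
    return CageGridSpec.coarse()


class TestSynthRDF:
    def test_bulk_limit_core_and_peak(self, acn):
        r = np.linspace(0.0, 12.0, 961)
        shell = ShellParams(peak_radius=3.5)
        rdfs = synth_rdf(acn.gs_geometry, acn, shell, r)
        g = rdfs[(0, "C")]
        assert np.all(g[r < shell.core_radius] == 0.0)
        far = r > 8.0
        assert np.max(np.abs(g[far] - 1.0)) < 1e-3
        assert r[np.argmax(g)] == pytest.approx(3.5, abs=r[1] - r[0])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            ShellParams(width=0.0)

    def test_library_deterministic_and_counts_nodes(self, acn, coarse_grid):
        r = np.linspace(0.0, 12.0, 121)
        lib1 = build_library(coarse_grid, acn, ShellParams(), r)
        lib2 = build_library(coarse_grid, acn, ShellParams(), r)
        assert np.array_equal(lib1.g, lib2.g)
        assert lib1.node_count == 5 * 7 * 5


class TestCrossTerm:
    def test_unstructured_solvent_gives_zero(self, acn, q_coarse):
        r = np.linspace(0.0, 12.0, 481)
        rdfs = {(i, v): np.ones_like(r) for i in range(3) for v in ("C", "N")}
        s = cage_cross_term(rdfs, acn, q_coarse, r)
        assert np.allclose(s.values, 0.0)

    def test_linear_in_density(self, acn, q_coarse):
        r = np.linspace(0.0, 12.0, 481)
        g = 1.0 + 0.8 * np.exp(-0.5 * ((r - 3.5) / 0.4) ** 2)
        rdfs = {(0, "C"): g}
        base = cage_cross_term(rdfs, acn, q_coarse, r).values
        doubled = get_solvent("acetonitrile")
        dbl = type(doubled)(
            name="x2",
            atom_densities={"C": 2 * acn.atom_densities["C"]},
            contact_element="C",
            gs_geometry=acn.gs_geometry,
            electron_density=acn.electron_density,
            main_peak_q=acn.main_peak_q,
        )
        twice = cage_cross_term(rdfs, dbl, q_coarse, r).values
        assert np.allclose(twice, 2 * base)

    def test_matches_fine_grid_quadrature_oracle(self, acn):
        """Gaussian-peak RDF vs adaptive quadrature of the same integral."""
        r = np.linspace(0.0, 12.0, 2401)
        peak, width, amp = 3.5, 0.4, 0.8
        g = 1.0 + amp * np.exp(-0.5 * ((r - peak) / width) ** 2)
        rdfs = {(0, "C"): g}
        qv = np.array([0.5, 1.1, 2.3, 3.3, 4.5])
        got = cage_cross_term(rdfs, acn, qv, r, taper=False).values
        rho = acn.atom_densities["C"]

        def oracle(q):
            integrand = lambda rr: (
                rr**2
                * amp * np.exp(-0.5 * ((rr - peak) / width) ** 2)
                * np.sinc(q * rr / np.pi)
            )
            val, _ = quad(integrand, 0.0, 12.0, limit=400, epsabs=1e-13)
            return (
                atomic_form_factor(q, "I")
                * atomic_form_factor(q, "C")
                * 4 * np.pi * rho * val
            )

        expected = np.array([oracle(q) for q in qv])
        scale = np.max(np.abs(expected))
        assert np.max(np.abs(got - expected)) / scale < 1e-6

    def test_riemann_lebesgue_decay(self, acn):
        r = np.linspace(0.0, 12.0, 961)
        g = 1.0 + 0.8 * np.exp(-0.5 * ((r - 3.5) / 0.4) ** 2)
        rdfs = {(0, "C"): g}
        q = np.array([0.05, 4.5])
        s = cage_cross_term(rdfs, acn, q, r).values
        assert abs(s[-1]) < abs(s[0])

    def test_unconverged_rdf_warns(self, acn, q_coarse):
        r = np.linspace(0.0, 5.0, 201)
        g = 1.0 + 0.8 * np.exp(-0.5 * ((r - 4.8) / 0.4) ** 2)  # peak at edge
        with pytest.warns(UserWarning, match="not converged"):
            cage_cross_term({(0, "C"): g}, acn, q_coarse, r)


class TestDisplacedVolume:
    def test_zero_radius_gives_zero(self, acn, q_coarse):
        s = displaced_volume_term(acn.gs_geometry, acn, q_coarse, 0.0)
        assert np.allclose(s.values, 0.0)

    def test_negative_radius_rejected(self, acn, q_coarse):
        with pytest.raises(ValueError):
            displaced_volume_term(acn.gs_geometry, acn, q_coarse, -1.0)

    def test_identical_geometries_difference_is_zero(self, acn, q_coarse):
        a = displaced_volume_term(acn.gs_geometry, acn, q_coarse).values
        b = displaced_volume_term(acn.gs_geometry, acn, q_coarse).values
        assert np.allclose(a - b, 0.0)

    def test_single_sphere_closed_form(self, acn, q_coarse):
        radius = 1.98
        f = gaussian_sphere_amplitude(q_coarse, radius, acn.electron_density)
        vol = 4 / 3 * np.pi * radius**3
        expected = (
            acn.electron_density * vol
            * np.exp(-(q_coarse**2) * vol ** (2 / 3) / (4 * np.pi))
        )
        assert np.allclose(f, expected, rtol=1e-12)


def oracle_trilinear(axes, point, values):
    """Independent trilinear formula via explicit corner enumeration."""
    idx = []
    fr = []
    for ax, x in zip(axes, point):
        k = int(np.clip(np.searchsorted(ax, x, side="right") - 1, 0, len(ax) - 2))
        idx.append(k)
        fr.append((x - ax[k]) / (ax[k + 1] - ax[k]))
    out = 0.0
    for corner in itertools.product((0, 1), repeat=3):
        w = 1.0
        for c, f in zip(corner, fr):
            w *= f if c else (1 - f)
        out = out + w * values[tuple(i + c for i, c in zip(idx, corner))]
    return out


class TestInterpolation:
    def _node_curves(self, grid, rng, nq=11):
        return rng.normal(
            size=(len(grid.r12), len(grid.r23), len(grid.alpha), nq)
        )

    def test_exact_at_nodes(self, coarse_grid):
        rng = np.random.default_rng(0)
        curves = self._node_curves(coarse_grid, rng)
        for (i, j, k) in [(0, 0, 0), (2, 3, 1), (4, 6, 4)]:
            g = SoluteGeometry(
                coarse_grid.r12[i], coarse_grid.r23[j], coarse_grid.alpha[k]
            )
            got = interpolate_cage(g, coarse_grid, curves)
            assert np.max(np.abs(got - curves[i, j, k])) < 1e-12

    def test_exact_for_linear_fields(self, coarse_grid):
        a, b, c = 1.3, -0.7, 2.1
        curves = (
            a * coarse_grid.r12[:, None, None, None]
            + b * coarse_grid.r23[None, :, None, None]
            + c * coarse_grid.alpha[None, None, :, None]
        ) * np.ones((1, 1, 1, 4))
        g = SoluteGeometry(3.03, 4.31, 2.2)
        got = interpolate_cage(g, coarse_grid, curves)
        assert np.allclose(got, a * 3.03 + b * 4.31 + c * 2.2, atol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        r12=st.floats(2.61, 3.59),
        r23=st.floats(2.61, 6.19),
        alpha=st.floats(0.51, 3.13),
    )
    def test_matches_weight_formula_oracle(self, r12, r23, alpha):
        grid = CageGridSpec.coarse()
        rng = np.random.default_rng(5)
        curves = self._node_curves(grid, rng, nq=3)
        g = SoluteGeometry(r12, r23, alpha)
        got = interpolate_cage(g, grid, curves)
        axes = (grid.r12, grid.r23, grid.alpha)
        expected = np.array(
            [
                oracle_trilinear(axes, (r12, r23, alpha), curves[..., m])
                for m in range(3)
            ]
        )
        assert np.allclose(got, expected, atol=1e-12)

    def test_continuous_across_cell_faces(self, coarse_grid):
        rng = np.random.default_rng(1)
        curves = self._node_curves(coarse_grid, rng)
        face = coarse_grid.r23[3]
        lo = interpolate_cage(
            SoluteGeometry(3.0, face - 1e-11, 2.0), coarse_grid, curves
        )
        hi = interpolate_cage(
            SoluteGeometry(3.0, face + 1e-11, 2.0), coarse_grid, curves
        )
        assert np.max(np.abs(hi - lo)) < 1e-10

    def test_outside_hull_clamps_with_warning(self, coarse_grid):
        rng = np.random.default_rng(2)
        curves = self._node_curves(coarse_grid, rng)
        with pytest.warns(UserWarning, match="clamped"):
            far = interpolate_cage(
                SoluteGeometry(3.0, 100.0, np.pi), coarse_grid, curves
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edge = interpolate_cage(
                SoluteGeometry(3.0, coarse_grid.r23[-1], np.pi),
                coarse_grid, curves,
            )
        assert np.allclose(far, edge)


class TestCageModel:
    def test_difference_antisymmetric_and_zero_on_identity(self, acn, q_coarse):
        lib = build_library(
            CageGridSpec.coarse(3, 4, 3), acn, ShellParams(geometry_coupling=0.1),
            r=np.linspace(0.0, 12.0, 121),
        )
        cm = CageModel(lib, acn, q_coarse)
        gs = acn.gs_geometry
        es = SoluteGeometry(3.1, 4.8, 2.0)
        assert np.allclose(cm.difference(gs, gs), 0.0)
        assert np.allclose(cm.difference(es, gs), -cm.difference(gs, es))

    def test_node_evaluation_matches_direct(self, acn, q_coarse):
        grid = CageGridSpec.coarse(3, 4, 3)
        lib = build_library(
            grid, acn, ShellParams(geometry_coupling=0.1),
            r=np.linspace(0.0, 12.0, 121),
        )
        cm = CageModel(lib, acn, q_coarse)
        g = SoluteGeometry(grid.r12[1], grid.r23[2], grid.alpha[1])
        direct = cage_cross_term(
            {
                (i, v): lib.g[1, 2, 1, i, k]
                for i in range(3)
                for k, v in enumerate(lib.types)
            },
            acn, q_coarse, lib.r,
        ).values
        assert np.allclose(cm.cross(g), direct, atol=1e-12)

    def test_fast_clamped_path_matches_public_interpolation(self, acn, q_coarse):
        lib = build_library(
            CageGridSpec.coarse(3, 4, 3), acn, ShellParams(geometry_coupling=0.1),
            r=np.linspace(0.0, 12.0, 121),
        )
        cm = CageModel(lib, acn, q_coarse)
        g = SoluteGeometry(3.05, 4.11, 1.7)
        assert np.allclose(cm.cross(g), cm.cross_clamped(3.05, 4.11, 1.7))


class TestFirstShell:
    def test_peak_location(self):
        r = np.linspace(0, 10, 1001)
        g = 1 + 0.9 * np.exp(-0.5 * ((r - 3.5) / 0.4) ** 2)
        assert first_shell_radius(r, g) == pytest.approx(3.5, abs=0.01)

    def test_first_of_two_peaks(self):
        r = np.linspace(0, 10, 1001)
        g = (
            1
            + 0.9 * np.exp(-0.5 * ((r - 3.5) / 0.4) ** 2)
            + 0.5 * np.exp(-0.5 * ((r - 6.0) / 0.5) ** 2)
        )
        assert first_shell_radius(r, g) == pytest.approx(3.5, abs=0.01)

    def test_noisy_recovery_with_smoothing(self):
        r = np.linspace(0, 10, 501)
        rng = np.random.default_rng(11)
        g = 1 + 0.9 * np.exp(-0.5 * ((r - 3.5) / 0.4) ** 2) + rng.normal(0, 0.02, r.shape)
        got = first_shell_radius(r, g, smooth_window=7)
        assert abs(got - 3.5) <= 0.5 * (r[1] - r[0]) * 7  # within the window span

    def test_featureless_rdf_rejected(self):
        r = np.linspace(0, 10, 101)
        with pytest.raises(ValueError, match="no first-shell peak"):
            first_shell_radius(r, np.ones_like(r))
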