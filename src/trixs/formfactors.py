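"""Atomic X-ray form factors and disorder damping.

Form factors use the standard four-Gaussian Cromer-Mann parameterization

    f(q) = sum_k a_k exp(-b_k (q / 4 pi)^2) + c

with coefficients from the International Tables for Crystallography
(Vol. C) for the neutral atoms. Only the elements appearing in the
triiodide/solvent problem are tabulated (I, C, N, O, H). The solute is
treated with neutral-iodine form factors; the -1 excess charge of I3- is
bookkeeping for the solvation layer, not a form-factor correction.

Conformational heterogeneity of the solute enters as a Debye-Waller-like
Gaussian damping of the *atomic* form factor,

    F^DW(q) = f(q) exp(-q^2 sigma^2 / 2),

with sigma the rms deviation of the atomic position in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CROMER_MANN", "atomic_form_factor", "dw_form_factor"]

# element -> (a1..a4, b1..b4, c); q in 1/Angstrom, f in electrons
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "I": (
        (20.1472, 18.9949, 7.5138, 2.2735),
        (4.3470, 0.3814, 27.7660, 66.8776),
        4.0712,
    ),
    "C": (
        (2.3100, 1.0200, 1.5886, 0.8650),
        (20.8439, 10.2075, 0.5687, 51.6512),
        0.2156,
    ),
    "N": (
        (12.2126, 3.1322, 2.0125, 1.1663),
        (0.0057, 9.8933, 28.9975, 0.5826),
        -11.5290,
    ),
    "O": (
        (3.0485, 2.2868, 1.5463, 0.8670),
        (13.2771, 5.7011, 0.3239, 32.9089),
        0.2508,
    ),
    "H": (
        (0.489918, 0.262003, 0.196767, 0.049879),
        (20.6593, 7.74039, 49.5519, 2.20159),
        0.001305,
    ),
}


def atomic_form_factor(q, element: str = "I") -> np.ndarray:
    """Cromer-Mann atomic form factor f(q), in electrons.

    Parameters
    ----------
    q : array_like
        Momentum transfer in 1/Angstrom, q >= 0.
    element : str
        Element symbol; must be in :data:`CROMER_MANN`.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    try:
        a, b, c = CROMER_MANN[element]
    except KeyError:
        raise KeyError(
            f"no Cromer-Mann coefficients tabulated for {element!r}"
        ) from None
    s2 = (q / (4.0 * np.pi)) ** 2
    f = np.full_like(q, c, dtype=float)
    for ak, bk in zip(a, b):
        f = f + ak * np.exp(-bk * s2)
    return f


def dw_form_factor(q, sigma: float, element: str = "I") -> np.ndarray:
    """Form factor damped by positional disorder of rmsd ``sigma`` (Angstrom).

    Returns f(q) * exp(-q^2 sigma^2 / 2).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    q = np.asarray(q, dtype=float)
    return atomic_form_factor(q, element) * np.exp(-0.5 * (q * sigma) ** 2)
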