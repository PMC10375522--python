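"""Canonical end-to-end synthetic scenario.

Bundles the default study conditions used throughout the tests,
examples and the reproduction script: the acetonitrile reaction scheme,
the experimental q-range (0.5-4.5 1/A, 201 points), 41 time delays from
-0.1 to 500 ps, a coarse RDF library, the synthetic heating reference
and 1% Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cage import CageGridSpec, ShellParams, build_library
from .io import AnisoDataset
from .model import ForwardModel, ParameterVector
from .simulate import (
    ReactionSchemeParams,
    default_q_grid,
    default_time_grid,
    simulate_dataset,
    simulate_heating_reference,
    simulate_trajectory,
)
from .solvents import get_solvent

__all__ = ["Scenario", "default_scenario", "standard_forward_model"]


def standard_forward_model(solvent_name: str, q) -> ForwardModel:
    """Forward model with the standard coarse library and heating curve."""
    solvent = get_solvent(solvent_name)
    library = build_library(
        CageGridSpec.coarse(), solvent, ShellParams(),
        r=np.linspace(0.0, 12.0, 241),
    )
    heating = simulate_heating_reference(solvent, q)
    return ForwardModel(solvent, np.asarray(q, dtype=float), library=library,
                        heating=heating)


@dataclass
class Scenario:
    params: ReactionSchemeParams
    q: np.ndarray
    t: np.ndarray
    fm: ForwardModel
    truth: list[ParameterVector]
    dataset: AnisoDataset

    @property
    def truth_array(self) -> np.ndarray:
        return np.array([x.to_array() for x in self.truth])


def default_scenario(
    seed: int = 0,
    noise_level: float = 0.01,
    solvent_name: str = "acetonitrile",
    params: ReactionSchemeParams | None = None,
    t: np.ndarray | None = None,
    q: np.ndarray | None = None,
) -> Scenario:
    """Build the default synthetic scenario (truth + noisy dataset)."""
    solvent = get_solvent(solvent_name)
    if params is None:
        params = ReactionSchemeParams()
    if q is None:
        q = default_q_grid()
    if t is None:
        t = default_time_grid()
    fm = standard_forward_model(solvent_name, q)
    truth = simulate_trajectory(params, t, fm.gs)
    dataset = simulate_dataset(truth, t, fm, noise_level=noise_level, seed=seed)
    return Scenario(params=params, q=q, t=t, fm=fm, truth=truth, dataset=dataset)
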