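"""Regularized per-timepoint structural refinement.

Each time point is fit by minimizing

    chi2(x) + f(x),   f = lambda * sum_k w_k (x_k - x_prev,k)^2,

where chi2 sums the squared, uncertainty-weighted residuals of both the
isotropic and anisotropic channels and f penalizes jumps of the
parameter vector relative to the previously refined time point
(time-sequential regularization; the first time point is unregularized).
The minimization is repeated from several random starting guesses drawn
in physically feasible ranges, plus a warm start at the previous
solution when regularizing; the lowest objective wins, ties broken by
the earliest restart.

Bounded parameters are handled by smooth reparameterization: logistic
transforms map the geometry parameters and A_GP onto finite intervals
and a softplus keeps A_iso non-negative, so the local optimizer runs
unconstrained. Parameter uncertainties come from one-dimensional
sensitivity scans of chi2 + f: the interval where the objective stays
within a configurable increase (default 1) of its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .io import AnisoDataset
from .model import PARAM_NAMES, ForwardModel, ParameterVector

__all__ = [
    "RefinementConfig",
    "TimepointResult",
    "RefinementResult",
    "chi2",
    "regularization_penalty",
    "refine_timepoint",
    "refine_series",
    "parameter_uncertainty",
]


def chi2(data0, model0, err0, data2=None, model2=None, err2=None) -> float:
    """Uncertainty-weighted sum of squared residuals over both channels."""
    data0 = np.asarray(data0, dtype=float)
    err0 = np.asarray(err0, dtype=float)
    if np.any(err0 <= 0):
        raise ValueError("uncertainties must be strictly positive")
    total = float(np.sum(((data0 - model0) / err0) ** 2))
    if data2 is not None:
        err2 = np.asarray(err2, dtype=float)
        if np.any(err2 <= 0):
            raise ValueError("uncertainties must be strictly positive")
        total += float(np.sum(((np.asarray(data2) - model2) / err2) ** 2))
    return total


def regularization_penalty(x, x_prev, lam: float, weights=None) -> float:
    """f = lambda * sum_k w_k (x_k - x_prev,k)^2."""
    if x_prev is None or lam == 0:
        return 0.0
    x = np.asarray(x, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    return float(lam * np.sum(w * (x - x_prev) ** 2))


# parameter transforms: logistic onto [lo, hi], softplus, or identity
_LOGISTIC, _SOFTPLUS, _IDENTITY = 0, 1, 2


@dataclass(frozen=True)
class RefinementConfig:
    """Settings of the regularized refinement."""

    lam: float = 50.0
    restarts: int = 10
    seed: int = 0
    maxiter: int = 400
    delta_objective: float = 1.0
    #: per-parameter penalty scale weights (1/A^2 for distances, 1/rad^2
    #: for the angle, 1 for amplitudes)
    weights: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    #: physically feasible ranges used to draw random starting guesses
    start_ranges: tuple = (
        (2.7, 3.5),  # r12
        (2.8, 6.0),  # r23
        (0.8, 3.1),  # alpha
        (0.005, 0.3),  # A_iso
        (0.05, 0.95),  # A_GP
        (0.0, 1.5),  # A_heat
        (-0.5, 0.5),  # A_ani
    )
    #: hard transform bounds for the logistic parameters
    bounds: tuple = (
        (2.6, 3.6),  # r12
        (2.6, 6.2),  # r23
        (0.35, np.pi),  # alpha
        None,  # A_iso: softplus >= 0
        (0.0, 1.0),  # A_GP
        None,  # A_heat: free
        None,  # A_ani: free
    )

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.restarts < 1:
            raise ValueError("need at least one restart")


_KINDS = (_LOGISTIC, _LOGISTIC, _LOGISTIC, _SOFTPLUS, _LOGISTIC, _IDENTITY, _IDENTITY)


def _to_internal(x: np.ndarray, cfg: RefinementConfig) -> np.ndarray:
    u = np.empty(7)
    for k in range(7):
        if _KINDS[k] == _LOGISTIC:
            lo, hi = cfg.bounds[k]
            p = np.clip((x[k] - lo) / (hi - lo), 1e-9, 1 - 1e-9)
            u[k] = np.log(p / (1 - p))
        elif _KINDS[k] == _SOFTPLUS:
            v = max(x[k], 1e-9)
            u[k] = v + np.log(-np.expm1(-v)) if v < 30 else v
        else:
            u[k] = x[k]
    return u


def _from_internal(u: np.ndarray, cfg: RefinementConfig) -> np.ndarray:
    x = np.empty(7)
    for k in range(7):
        if _KINDS[k] == _LOGISTIC:
            lo, hi = cfg.bounds[k]
            x[k] = lo + (hi - lo) * expit(u[k])
        elif _KINDS[k] == _SOFTPLUS:
            x[k] = np.logaddexp(0.0, u[k])
        else:
            x[k] = u[k]
    return x


@dataclass
class TimepointResult:
    x: np.ndarray
    objective: float
    chi2: float
    restart_objectives: list
    converged: bool

    @property
    def parameters(self) -> ParameterVector:
        return ParameterVector.from_array(self.x)


def _objective_factory(fm: ForwardModel, data_t, cfg: RefinementConfig, x_prev):
    d0, d2, e0, e2 = data_t

    def objective_x(x: np.ndarray) -> float:
        c = chi2(d0, fm.iso_array(x), e0, d2, fm.aniso_array(x), e2)
        return c + regularization_penalty(x, x_prev, cfg.lam, cfg.weights)

    return objective_x


def refine_timepoint(
    fm: ForwardModel,
    data_t,
    x_prev: np.ndarray | None,
    cfg: RefinementConfig,
    rng: np.random.Generator | None = None,
) -> TimepointResult:
    """Multi-start local minimization of chi2 + f for one time point.

    ``data_t`` is the tuple (dS0, dS2, err0, err2) of 1-D arrays on the
    model q-grid. The returned objective is <= each restart's objective.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    objective_x = _objective_factory(fm, data_t, cfg, x_prev)

    def objective_u(u):
        return objective_x(_from_internal(u, cfg))

    starts = []
    if x_prev is not None and cfg.lam > 0:
        starts.append(np.asarray(x_prev, dtype=float))
    for _ in range(cfg.restarts):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in cfg.start_ranges])
        )

    best = None
    restart_objectives = []
    any_converged = False
    for x0 in starts:
        sol = minimize(
            objective_u,
            _to_internal(x0, cfg),
            method="L-BFGS-B",
            options={"maxiter": cfg.maxiter},
        )
        restart_objectives.append(float(sol.fun))
        any_converged = any_converged or bool(sol.success)
        if best is None or sol.fun < best.fun:
            best = sol
    x_opt = _from_internal(best.x, cfg)
    pv = ParameterVector.from_array(x_opt)
    d0, d2, e0, e2 = data_t
    c = chi2(d0, fm.iso(pv), e0, d2, fm.aniso(pv), e2)
    return TimepointResult(
        x=x_opt,
        objective=float(best.fun),
        chi2=c,
        restart_objectives=restart_objectives,
        converged=any_converged,
    )


@dataclass
class RefinementResult:
    """Per-timepoint refined parameters and diagnostics."""

    t: np.ndarray
    x: np.ndarray  # (nt, 7), columns ordered as PARAM_NAMES
    chi2: np.ndarray
    objective: np.ndarray
    converged: np.ndarray
    config: RefinementConfig
    ci: np.ndarray | None = None  # (nt, 7, 2) confidence bounds
    param_names: tuple = PARAM_NAMES

    def column(self, name: str) -> np.ndarray:
        return self.x[:, PARAM_NAMES.index(name)]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=self.t)
            fh.create_dataset("x", data=self.x)
            fh.create_dataset("chi2", data=self.chi2)
            fh.create_dataset("objective", data=self.objective)
            fh.create_dataset("converged", data=self.converged.astype(np.int8))
            if self.ci is not None:
                fh.create_dataset("ci", data=self.ci)
            fh.attrs["lam"] = self.config.lam
            fh.attrs["restarts"] = self.config.restarts
            fh.attrs["seed"] = self.config.seed


def load_result(path) -> RefinementResult:
    import h5py

    with h5py.File(path, "r") as fh:
        for name in ("t", "x", "chi2", "objective", "converged"):
            if name not in fh:
                raise KeyError(f"malformed result file {path!s}: missing /{name}")
        cfg = RefinementConfig(
            lam=float(fh.attrs.get("lam", 0.0)),
            restarts=int(fh.attrs.get("restarts", 1)),
            seed=int(fh.attrs.get("seed", 0)),
        )
        return RefinementResult(
            t=fh["t"][()],
            x=fh["x"][()],
            chi2=fh["chi2"][()],
            objective=fh["objective"][()],
            converged=fh["converged"][()].astype(bool),
            config=cfg,
            ci=fh["ci"][()] if "ci" in fh else None,
        )


def refine_series(
    dataset: AnisoDataset,
    fm: ForwardModel,
    cfg: RefinementConfig = RefinementConfig(),
    uncertainties: bool = False,
    progress=None,
) -> RefinementResult:
    """Sequential refinement over the time axis.

    Time points are processed in increasing order; each is regularized
    against the previously optimized parameter vector (the first is
    unregularized). Random starts for time point i are drawn from a
    generator seeded with (cfg.seed, i), so with lambda = 0 the series
    result equals independent per-timepoint refinement.
    """
    nt = dataset.n_timepoints
    xs = np.empty((nt, 7))
    c2 = np.empty(nt)
    obj = np.empty(nt)
    conv = np.empty(nt, dtype=bool)
    cis = np.empty((nt, 7, 2)) if uncertainties else None
    x_prev = None
    for i in range(nt):
        data_t = (
            dataset.dS0[i], dataset.dS2[i], dataset.err0[i], dataset.err2[i]
        )
        rng = np.random.default_rng([cfg.seed, i])
        res = refine_timepoint(fm, data_t, x_prev, cfg, rng)
        xs[i] = res.x
        c2[i] = res.chi2
        obj[i] = res.objective
        conv[i] = res.converged
        if uncertainties:
            cis[i] = parameter_uncertainty(fm, data_t, res.x, cfg, x_prev)[0]
        x_prev = res.x
        if progress is not None:
            progress(i, nt, res)
    return RefinementResult(
        t=np.asarray(dataset.t, dtype=float),
        x=xs, chi2=c2, objective=obj, converged=conv, config=cfg, ci=cis,
    )


_SCAN_SCALES = (0.5, 1.5, 1.0, 0.2, 0.6, 0.8, 0.8)
_VALID_LO = (1e-3, 1e-3, 0.0, 0.0, 0.0, -np.inf, -np.inf)
_VALID_HI = (np.inf, np.inf, np.pi, np.inf, 1.0, np.inf, np.inf)


def parameter_uncertainty(
    fm: ForwardModel,
    data_t,
    x_opt: np.ndarray,
    cfg: RefinementConfig,
    x_prev: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Sensitivity-scan confidence intervals around a refined minimum.

    Each parameter is scanned one-dimensionally (others held fixed)
    until chi2 + f increases by ``cfg.delta_objective``; the crossing is
    located by bisection. Directions with no crossing inside the scan
    range are flagged flat and reported as infinite.

    Returns (bounds, flat_flags): bounds is (7, 2) with the lower and
    upper interval edges; flat_flags lists (parameter name, direction)
    pairs for unbounded directions.
    """
    objective_x = _objective_factory(fm, data_t, cfg, x_prev)
    x_opt = np.asarray(x_opt, dtype=float)
    f0 = objective_x(x_opt)
    target = f0 + cfg.delta_objective
    bounds = np.empty((7, 2))
    flat: list = []
    for k in range(7):
        for s, side in ((-1.0, 0), (+1.0, 1)):
            edge = x_opt[k] + s * _SCAN_SCALES[k]
            edge = float(np.clip(edge, _VALID_LO[k], _VALID_HI[k]))

            def f_at(v):
                x = x_opt.copy()
                x[k] = v
                return objective_x(x)

            if abs(edge - x_opt[k]) < 1e-12 or f_at(edge) < target:
                bounds[k, side] = s * np.inf
                flat.append((PARAM_NAMES[k], "lower" if s < 0 else "upper"))
                continue
            lo, hi = x_opt[k], edge
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if f_at(mid) < target:
                    lo = mid
                else:
                    hi = mid
                if abs(hi - lo) < 1e-10:
                    break
            bounds[k, side] = 0.5 * (lo + hi)
    return bounds, flat
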