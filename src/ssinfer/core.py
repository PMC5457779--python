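"""Power-law (S-System) ODE networks: representation, simulation, slopes.

An S-System describes the concentration dynamics of ``N`` dependent
biochemical components by one production and one degradation power-law
term per component::

    dX_i/dt = alpha_i * prod_j X_j^g_ij  -  beta_i * prod_j X_j^h_ij

where the product runs over all ``M >= N`` variables (dependent components
first, then optional independent variables held at constant, strictly
positive values such as enzyme activities).  The real exponents
(*kinetic orders*) ``g_ij``/``h_ij`` encode the network topology: a zero
exponent means variable ``j`` does not influence term ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SSystem",
    "Trajectory",
    "SlopeSet",
    "SimulationError",
    "evaluate_rhs",
    "simulate",
    "five_point_slopes",
    "analytic_slopes",
]


class SimulationError(RuntimeError):
    """Raised when an integrated trajectory leaves the positive orthant.

    Attributes ``component`` (1-based index) and ``time`` identify where
    positivity was lost.
    """

    def __init__(self, message: str, component: int | None = None, time: float | None = None):
        super().__init__(message)
        self.component = component
        self.time = time


@dataclass(frozen=True)
class SSystem:
    """Full parameterization of a power-law reaction network.

    Parameters
    ----------
    alpha, beta
        Length-``N`` strictly positive rate constants of the production and
        degradation terms.
    G, H
        ``N x M`` kinetic-order matrices (production / degradation exponents).
    fixed_vars
        Length ``M - N`` vector of constant, positive independent-variable
        values (empty for fully dependent systems).
    """

    alpha: np.ndarray
    beta: np.ndarray
    G: np.ndarray
    H: np.ndarray
    fixed_vars: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        for name in ("alpha", "beta", "G", "H", "fixed_vars"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.alpha.shape[0]
        if self.beta.shape != (n,):
            raise ValueError("alpha and beta must have the same length")
        if self.G.shape != self.H.shape or self.G.shape[0] != n:
            raise ValueError("G and H must both be N x M")
        m = self.G.shape[1]
        if m < n or m != n + self.fixed_vars.shape[0]:
            raise ValueError("need G.shape[1] == n_dep + len(fixed_vars)")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("rate constants must be strictly positive")
        if np.any(self.fixed_vars <= 0):
            raise ValueError("independent variables must be strictly positive")
        if not (np.isfinite(self.G).all() and np.isfinite(self.H).all()):
            raise ValueError("kinetic orders must be finite")

    @property
    def n_dep(self) -> int:
        """Number of dependent components ``N``."""
        return self.alpha.shape[0]

    @property
    def n_vars(self) -> int:
        """Total variable count ``M`` (dependent + independent)."""
        return self.G.shape[1]

    def full_state(self, x_dep: np.ndarray) -> np.ndarray:
        """Append the fixed independent variables to a dependent state."""
        x_dep = np.asarray(x_dep, dtype=float)
        return np.concatenate([x_dep, self.fixed_vars])


@dataclass(frozen=True)
class Trajectory:
    """Sampled concentrations of the dependent components.

    ``times`` is strictly increasing with ``values`` of shape ``(T, N)``;
    concentrations must be strictly positive (power laws with real
    exponents are undefined otherwise).
    """

    times: np.ndarray
    values: np.ndarray
    condition_id: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise ValueError("times must be 1-D and values 2-D")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values must have one row per time point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValueError("trajectory contains NaN/Inf")
        if np.any(self.values <= 0):
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SlopeSet:
    """Estimated time derivatives, same shape as the trajectory they derive from.

    ``provenance`` records how the slopes were obtained: ``"five_point"``
    (finite differences on data) or ``"analytic"`` (exact model right-hand
    side, used as a testing oracle).
    """

    values: np.ndarray
    provenance: str
    condition_id: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.provenance not in ("five_point", "analytic"):
            raise ValueError("provenance must be 'five_point' or 'analytic'")


def evaluate_rhs(model: SSystem, x: np.ndarray) -> np.ndarray:
    """Evaluate the S-System right-hand side at a positive state.

    ``x`` may have length ``M`` (full state) or length ``N``, in which case
    the model's fixed independent variables are appended.
    """
    x = np.asarray(x, dtype=float)
    if x.shape == (model.n_dep,) and model.n_vars > model.n_dep:
        x = model.full_state(x)
    if x.shape != (model.n_vars,):
        raise ValueError(f"state must have length {model.n_vars} (or {model.n_dep})")
    if np.any(x <= 0):
        raise ValueError("state must be strictly positive")
    logx = np.log(x)
    prod = np.exp(model.G @ logx)
    degr = np.exp(model.H @ logx)
    return model.alpha * prod - model.beta * degr


def simulate(
    model: SSystem,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    condition_id: str = "0",
) -> Trajectory:
    """Integrate the S-System from ``x0`` and sample it on ``times``.

    Uses an adaptive explicit Runge-Kutta scheme (RK45) with dense output
    evaluated at the requested grid; deterministic given its inputs.
    Raises :class:`SimulationError` if any component leaves the positive
    orthant (power-law dynamics are only defined there).
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if x0.shape != (model.n_dep,):
        raise ValueError(f"x0 must have length {model.n_dep}")
    if np.any(x0 <= 0):
        raise ValueError("x0 must be strictly positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    fixed = model.fixed_vars

    def rhs(t, y):
        yfull = np.concatenate([y, fixed]) if fixed.size else y
        # guard the log against transient non-positive excursions of the solver
        logx = np.log(np.maximum(yfull, 1e-300))
        return model.alpha * np.exp(model.G @ logx) - model.beta * np.exp(model.H @ logx)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        x0,
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    vals = sol.y.T
    bad = np.argwhere(vals <= 0)
    if bad.size:
        k, i = bad[0]
        raise SimulationError(
            f"component X{i + 1} became non-positive at t={times[k]:g}",
            component=int(i) + 1,
            time=float(times[k]),
        )
    return Trajectory(times=times, values=vals, condition_id=condition_id)


# 5-point stencil weights (divide by 12*dt); rows: offsets 0..4 from the
# left edge for the first two points, central, and mirrored for the last two.
_W_EDGE0 = np.array([-25.0, 48.0, -36.0, 16.0, -3.0])
_W_EDGE1 = np.array([-3.0, -10.0, 18.0, -6.0, 1.0])
_W_CENTRAL = np.array([1.0, -8.0, 0.0, 8.0, -1.0])


def five_point_slopes(traj: Trajectory) -> SlopeSet:
    """Estimate derivatives with the five-point finite-difference formula.

    Interior points use the central stencil
    ``(-f[k+2] + 8 f[k+1] - 8 f[k-1] + f[k-2]) / (12 dt)``; the two points
    at each boundary use one-sided five-point stencils of the same
    (fourth) order.  Requires a uniform grid with at least five samples;
    exact for polynomials of degree <= 4.
    """
    t, f = traj.times, traj.values
    T = t.shape[0]
    if T < 5:
        raise ValueError("five-point slopes need at least 5 time points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise ValueError("five-point slopes require a uniform time grid")
    h = dt[0]

    s = np.empty_like(f)
    s[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / (12 * h)
    s[0] = _W_EDGE0 @ f[:5] / (12 * h)
    s[1] = _W_EDGE1 @ f[:5] / (12 * h)
    s[-2] = -(_W_EDGE1 @ f[-1:-6:-1]) / (12 * h)
    s[-1] = -(_W_EDGE0 @ f[-1:-6:-1]) / (12 * h)
    return SlopeSet(values=s, provenance="five_point", condition_id=traj.condition_id)


def analytic_slopes(model: SSystem, traj: Trajectory) -> SlopeSet:
    """Exact derivatives: the model right-hand side at each sampled state.

    A testing oracle — with these slopes the decoupled fitting error of the
    true parameters is exactly zero.
    """
    if traj.n_components != model.n_dep:
        raise ValueError("trajectory dimension does not match the model")
    s = np.vstack([evaluate_rhs(model, row) for row in traj.values])
    return SlopeSet(values=s, provenance="analytic", condition_id=traj.condition_id)
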