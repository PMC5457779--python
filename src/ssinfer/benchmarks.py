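"""Benchmark systems and synthetic time-course data generation.

Two standard test systems are provided:

* ``make_s1`` — a 5-component artificial gene-network S-System widely used
  to benchmark S-System inference (13 of the 50 kinetic orders nonzero).
* ``make_s2`` — the anaerobic yeast fermentation pathway: glucose (X1),
  glucose-6-phosphate (X2), fructose-1,6-diphosphate (X3),
  phosphoenolpyruvate (X4) and ATP (X5), driven by eight independent
  variables (enzyme activities / fluxes, in mM/min) held at their
  steady-state values.

``generate_dataset`` simulates a model from random initial conditions,
samples it on a uniform grid and attaches five-point slope estimates —
the inputs of the decoupled inference problem.  ``add_noise`` applies
multiplicative Gaussian measurement noise and recomputes the slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    SSystem,
    SimulationError,
    Trajectory,
    SlopeSet,
    analytic_slopes,
    five_point_slopes,
    simulate,
)

__all__ = ["Dataset", "make_s1", "make_s2", "generate_dataset", "add_noise", "exogenous_factors"]


@dataclass(frozen=True)
class Dataset:
    """Multi-condition time courses plus derived slope estimates.

    ``exo_prod``/``exo_deg`` are known per-equation constant multipliers
    contributed by independent variables (enzyme activities) that are part
    of the experimental setup rather than of the inference problem; they
    are all 1 for fully dependent systems.
    """

    trajectories: tuple[Trajectory, ...]
    slopes: tuple[SlopeSet, ...]
    noise_rate: float = 0.0
    seed: int | None = None
    source_model: SSystem | None = None
    exo_prod: np.ndarray | None = None
    exo_deg: np.ndarray | None = None

    def __post_init__(self):
        if len(self.trajectories) != len(self.slopes):
            raise ValueError("need one SlopeSet per trajectory")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        n = self.n_components
        t0 = self.trajectories[0].times
        for traj in self.trajectories:
            if traj.n_components != n or not np.array_equal(traj.times, t0):
                raise ValueError("all trajectories must share one time grid and N")
        object.__setattr__(self, "trajectories", tuple(self.trajectories))
        object.__setattr__(self, "slopes", tuple(self.slopes))
        if self.exo_prod is None:
            object.__setattr__(self, "exo_prod", np.ones(n))
        if self.exo_deg is None:
            object.__setattr__(self, "exo_deg", np.ones(n))

    @property
    def n_components(self) -> int:
        return self.trajectories[0].n_components

    @property
    def n_conditions(self) -> int:
        return len(self.trajectories)

    def stacked_values(self) -> np.ndarray:
        """All observed concentrations, conditions stacked: shape (C*T, N)."""
        return np.vstack([t.values for t in self.trajectories])

    def stacked_log_values(self) -> np.ndarray:
        """log of observations, guarded at 1e-12 so candidate scoring stays total."""
        return np.log(np.clip(self.stacked_values(), 1e-12, None))

    def stacked_slopes(self) -> np.ndarray:
        return np.vstack([s.values for s in self.slopes])


def make_s1() -> SSystem:
    """The 5-component artificial benchmark network."""
    alpha = np.array([5.0, 10.0, 10.0, 8.0, 10.0])
    beta = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
    G = np.zeros((5, 5))
    H = np.zeros((5, 5))
    G[0, 2] = 1.0
    G[0, 4] = -1.0
    G[1, 0] = 2.0
    G[2, 1] = -1.0
    G[3, 2] = 2.0
    G[3, 4] = -1.0
    G[4, 3] = 2.0
    H[0, 0] = 2.0
    H[1, 1] = 2.0
    H[2, 1] = -1.0
    H[2, 2] = 2.0
    H[3, 3] = 2.0
    H[4, 4] = 2.0
    return SSystem(alpha=alpha, beta=beta, G=G, H=H)


def make_s2() -> SSystem:
    """The yeast fermentation pathway: 5 dependent + 8 independent variables.

    Variables without a printed exponent in the source model carry exponent 1
    (this reading is also recorded in the shipped ``data/s2.model`` file).
    """
    alpha = np.array([1.0006, 1.6497, 0.4536, 0.2365, 1.4060])
    beta = np.array([1.6497, 0.5793, 0.2456, 2.0892, 2.9437])
    G = np.zeros((5, 13))
    H = np.zeros((5, 13))
    # dependent-variable kinetic orders (columns 0..4 = X1..X5)
    G[0, 1] = -0.0492
    G[1, 0] = 0.5582
    G[1, 4] = 0.0465
    G[2, 1] = 0.4407
    G[2, 4] = -0.2665
    G[3, 2] = 0.5285
    G[3, 4] = 0.0994
    G[4, 2] = 0.2605
    G[4, 3] = 0.1520
    G[4, 4] = 0.0739
    H[0, 0] = 0.5582
    H[0, 4] = 0.0456
    H[1, 1] = 0.5097
    H[1, 4] = -0.2218
    H[2, 2] = 0.4506
    H[2, 3] = 0.0441
    H[2, 4] = 0.0920
    H[3, 2] = -0.0075
    H[3, 3] = 0.3040
    H[3, 4] = 0.0484
    H[4, 0] = 0.1962
    H[4, 1] = 0.1791
    H[4, 4] = 0.2354
    # independent-variable kinetic orders (columns 5..12 = X6..X13)
    G[0, 5] = 1.0   # glucose uptake
    G[1, 6] = 1.0   # hexokinase
    G[2, 7] = 1.0   # phosphofructokinase
    G[3, 8] = 1.0   # GAPDH
    G[4, 8] = 0.5
    G[4, 9] = 0.5   # pyruvate kinase
    H[0, 6] = 1.0
    H[1, 7] = 0.8322
    H[1, 10] = 0.1678  # polysaccharide storage
    H[2, 8] = 0.8547
    H[2, 11] = 0.1453  # glycerol production
    H[3, 9] = 1.0
    H[4, 6] = 0.3514
    H[4, 7] = 0.2925
    H[4, 10] = 0.0589
    H[4, 12] = 0.2970  # ATPase
    fixed = np.array([47.5, 24.1, 53.9, 91.4, 18.1, 82.9, 92.4, 1.0])
    return SSystem(alpha=alpha, beta=beta, G=G, H=H, fixed_vars=fixed)


def exogenous_factors(model: SSystem) -> tuple[np.ndarray, np.ndarray]:
    """Per-equation constant multipliers from the independent variables.

    ``K_prod_i = prod_j fv_j^g_ij`` and ``K_deg_i = prod_j fv_j^h_ij`` over the
    independent columns.  These enter candidate scoring as known constants,
    so inferred rate constants stay on the scale of the printed model.
    """
    n = model.n_dep
    if model.fixed_vars.size == 0:
        return np.ones(n), np.ones(n)
    logfv = np.log(model.fixed_vars)
    return np.exp(model.G[:, n:] @ logfv), np.exp(model.H[:, n:] @ logfv)


def generate_dataset(
    model: SSystem,
    n_conditions: int,
    n_times: int,
    t_span: tuple[float, float],
    init_range: tuple[float, float],
    seed: int,
    slope_method: str = "five_point",
) -> Dataset:
    """Simulate noise-free time courses from uniformly drawn initial conditions.

    Initial concentrations are drawn i.i.d. per component from
    ``U(init_range)``; each condition is integrated and sampled at
    ``n_times`` uniform points over ``t_span``, and slopes are estimated
    (``slope_method``: "five_point" for data-driven estimates, "analytic"
    for the exact-RHS oracle).  Reproducible given ``seed``.
    """
    if n_times < 5:
        raise ValueError("need at least 5 time points")
    lo, hi = init_range
    if lo <= 0 or hi <= lo:
        raise ValueError("init_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    times = np.linspace(t_span[0], t_span[1], n_times)
    x0s = rng.uniform(lo, hi, size=(n_conditions, model.n_dep))
    trajs, slopes = [], []
    for c, x0 in enumerate(x0s):
        try:
            traj = simulate(model, x0, times, condition_id=str(c))
        except SimulationError as exc:
            raise SimulationError(f"condition {c}: {exc}") from exc
        trajs.append(traj)
        if slope_method == "analytic":
            slopes.append(analytic_slopes(model, traj))
        elif slope_method == "five_point":
            slopes.append(five_point_slopes(traj))
        else:
            raise ValueError("slope_method must be 'five_point' or 'analytic'")
    kp, kd = exogenous_factors(model)
    return Dataset(
        trajectories=tuple(trajs),
        slopes=tuple(slopes),
        noise_rate=0.0,
        seed=seed,
        source_model=model,
        exo_prod=kp,
        exo_deg=kd,
    )


def add_noise(ds: Dataset, rate: float, seed: int) -> Dataset:
    """Apply multiplicative Gaussian noise ``X * (1 + eps)``, eps ~ N(0, rate^2).

    Noise is independent per observation; noisy values are clipped below at
    1e-6 to preserve positivity, and slopes are recomputed from the noisy
    trajectories with the five-point formula.  ``rate = 0`` is the identity.
    """
    if rate < 0:
        raise ValueError("noise rate must be >= 0")
    if rate == 0:
        return replace(ds)
    rng = np.random.default_rng(seed)
    trajs, slopes = [], []
    for traj in ds.trajectories:
        eps = rng.normal(0.0, rate, size=traj.values.shape)
        noisy = np.clip(traj.values * (1.0 + eps), 1e-6, None)
        ntraj = Trajectory(times=traj.times, values=noisy, condition_id=traj.condition_id)
        trajs.append(ntraj)
        slopes.append(five_point_slopes(ntraj))
    return replace(
        ds,
        trajectories=tuple(trajs),
        slopes=tuple(slopes),
        noise_rate=rate,
        seed=seed,
    )
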