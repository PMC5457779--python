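"""The decoupled biobjective model for one S-System equation.

Decoupling replaces the coupled ODE fit by per-equation slope matching:
candidate right-hand sides are evaluated at the *observed* concentrations
(other components enter as data, never integrated), which makes candidate
evaluation cheap enough for population-based search.

A candidate equation ``i`` is a :class:`MixedSolution` ``(bx, rx)``:

* ``bx`` — ``2N`` bits, connection indicators for ``g_i1..g_iN, h_i1..h_iN``;
* ``rx`` — ``2N + 2`` reals: candidate kinetic orders followed by the rate
  constants ``alpha_i, beta_i``.

The kinetic orders decode as ``g_ij = bx_j * rx_j`` and
``h_ij = bx_{N+j} * rx_{N+j}``, so the sparsity objective is simply the
popcount of ``bx`` — no magnitude threshold is ever needed to prune
connections.  The two minimized objectives are the squared slope-fitting
error and this L0 connection count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmarks import Dataset

__all__ = [
    "Bounds",
    "MixedSolution",
    "Front",
    "decode",
    "fitting_error",
    "l0",
    "dominates",
    "nondominated_filter",
    "batch_errors",
]


@dataclass(frozen=True)
class Bounds:
    """Search ranges: ``kinetic_range`` for g,h and ``rate_range`` for alpha,beta."""

    kinetic_range: tuple[float, float] = (-3.0, 3.0)
    rate_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self):
        if self.rate_range[0] < 0:
            raise ValueError("rate constants cannot be negative")
        for lo, hi in (self.kinetic_range, self.rate_range):
            if hi <= lo:
                raise ValueError("bounds must be increasing intervals")

    @classmethod
    def s1(cls) -> "Bounds":
        return cls(kinetic_range=(-3.0, 3.0), rate_range=(0.0, 10.0))

    @classmethod
    def s2(cls) -> "Bounds":
        return cls(kinetic_range=(-1.0, 1.0), rate_range=(0.0, 3.0))

    def lower(self, n: int) -> np.ndarray:
        return np.array([self.kinetic_range[0]] * (2 * n) + [self.rate_range[0]] * 2)

    def upper(self, n: int) -> np.ndarray:
        return np.array([self.kinetic_range[1]] * (2 * n) + [self.rate_range[1]] * 2)


@dataclass(frozen=True)
class MixedSolution:
    """One candidate configuration of equation ``eq_index`` with cached objectives."""

    bx: np.ndarray
    rx: np.ndarray
    err: float | None = None
    l0: int | None = None
    eq_index: int = 0

    def __post_init__(self):
        bx = np.asarray(self.bx, dtype=np.uint8)
        rx = np.asarray(self.rx, dtype=float)
        if rx.shape[0] != bx.shape[0] + 2:
            raise ValueError("rx must have length len(bx) + 2")
        object.__setattr__(self, "bx", bx)
        object.__setattr__(self, "rx", rx)
        if self.l0 is None:
            object.__setattr__(self, "l0", int(bx.sum()))

    @property
    def n(self) -> int:
        return self.bx.shape[0] // 2


def decode(sol: MixedSolution) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Return ``(g, h, alpha_i, beta_i)``: bits mask the reals, rates pass through."""
    n = sol.n
    g = sol.bx[:n] * sol.rx[:n]
    h = sol.bx[n : 2 * n] * sol.rx[n : 2 * n]
    return g, h, float(sol.rx[2 * n]), float(sol.rx[2 * n + 1])


def batch_errors(
    logX: np.ndarray,
    s_i: np.ndarray,
    G: np.ndarray,
    H: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    kp: float = 1.0,
    kd: float = 1.0,
) -> np.ndarray:
    """Vectorized fitting errors for a batch of candidate equations.

    ``logX``: (R, N) log observations (all conditions stacked); ``s_i``: (R,)
    slope estimates of the target component; ``G``, ``H``: (B, N) decoded
    kinetic orders; ``a``, ``b``: (B,) rate constants; ``kp``/``kd``: known
    exogenous multipliers.  Returns (B,) sums of squared residuals.
    """
    prod = np.exp(logX @ G.T)
    degr = np.exp(logX @ H.T)
    shat = (kp * a) * prod - (kd * b) * degr
    d = shat - s_i[:, None]
    return np.einsum("rb,rb->b", d, d)


def fitting_error(sol: MixedSolution, ds: Dataset) -> float:
    """Squared slope-fitting error of one candidate equation over all data.

    ``err_i = sum_{c,t} (S_i - Shat_i)^2`` with
    ``Shat_i = K_prod*alpha_i*prod_j X_j^g_j - K_deg*beta_i*prod_j X_j^h_j``
    evaluated at the observed concentrations.
    """
    i = sol.eq_index
    if not 0 <= i < ds.n_components:
        raise ValueError(f"eq_index {i} out of range")
    g, h, a, b = decode(sol)
    err = batch_errors(
        ds.stacked_log_values(),
        ds.stacked_slopes()[:, i],
        g[None, :],
        h[None, :],
        np.array([a]),
        np.array([b]),
        kp=float(ds.exo_prod[i]),
        kd=float(ds.exo_deg[i]),
    )
    return float(err[0])


def l0(sol: MixedSolution) -> int:
    """Connection count of the candidate: popcount of the bit vector."""
    return int(np.sum(sol.bx))


def dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Pareto dominance for minimization: a <= b componentwise, < somewhere."""
    return a[0] <= b[0] and a[1] <= b[1] and (a[0] < b[0] or a[1] < b[1])


@dataclass(frozen=True)
class Front:
    """Mutually nondominated solutions of one equation, ascending in L0.

    Holds at most one member per distinct connection count (ties resolved
    toward lower fitting error), so its errors are strictly decreasing.
    """

    eq_index: int
    solutions: tuple[MixedSolution, ...]

    def objectives(self) -> np.ndarray:
        return np.array([[s.err, s.l0] for s in self.solutions])

    def __len__(self) -> int:
        return len(self.solutions)


def nondominated_filter(solutions: list[MixedSolution]) -> Front:
    """Reduce any solution set to a Front (best err per L0, then nondominated)."""
    if not solutions:
        return Front(eq_index=0, solutions=())
    eq = solutions[0].eq_index
    if any(s.eq_index != eq for s in solutions):
        raise ValueError("all solutions must describe the same equation")
    best: dict[int, MixedSolution] = {}
    for s in solutions:
        cur = best.get(s.l0)
        if cur is None or s.err < cur.err:
            best[s.l0] = s
    kept = []
    best_err = np.inf
    for k in sorted(best):
        if best[k].err < best_err:
            kept.append(best[k])
            best_err = best[k].err
    return Front(eq_index=eq, solutions=tuple(kept))
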