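"""Automatic selection of one solution per equation from the fronts.

The per-equation fronts trade fitting error against connection count, so
one configuration must be chosen per equation without a user-set
threshold.  The procedure:

1. normalize both objectives of each front by their maxima (scores in
   [0, 1]);
2. for each weight ``lambda`` on a uniform grid, pick per equation the
   member minimizing the aggregation product
   ``Score1^lambda * Score2^(1-lambda)`` (the linear aggregation sum is
   implemented for comparison but systematically over-sparsifies);
3. sum the selected scores over equations into one "sum vector" per
   lambda — collectively a normalized front in the objective plane;
4. pick the sum vector with the maximum tradeoff (bend) angle — the knee —
   and assemble the network from any lambda mapping to it.

Because sparsity is counted by an L0 norm, long runs of lambda values
collapse onto the same network, which is what makes the knee choice
robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SSystem
from .objectives import Front, MixedSolution, decode

__all__ = [
    "ScoredFront",
    "SweepPoint",
    "InferenceResult",
    "normalize",
    "las_score",
    "ap_score",
    "select_equation_result",
    "sweep_lambda",
    "distinct_networks",
    "knee_select",
    "asp",
]


@dataclass(frozen=True)
class ScoredFront:
    """A front with both objectives normalized by their front maxima.

    The empty configuration (zero connections) is dropped before
    normalization: its sparsity score would be exactly 0, making its
    aggregation product 0 for every ``lambda < 1`` and hijacking the
    selection regardless of fit.  It remains a legitimate front member;
    it is just never a candidate final result.
    """

    front: Front
    score1: np.ndarray  # err / max err
    score2: np.ndarray  # l0 / max l0

    def __len__(self) -> int:
        return len(self.front)


def normalize(front: Front) -> ScoredFront:
    """Divide each objective by its maximum over the front (0/0 -> 0),
    after discarding the degenerate zero-connection member (if any other
    members exist)."""
    if len(front) == 0:
        raise ValueError("cannot normalize an empty front")
    members = [s for s in front.solutions if s.l0 > 0] or list(front.solutions)
    front = Front(eq_index=front.eq_index, solutions=tuple(members))
    obj = front.objectives()
    max_err = obj[:, 0].max()
    max_l0 = obj[:, 1].max()
    s1 = obj[:, 0] / max_err if max_err > 0 else np.zeros(len(front))
    s2 = obj[:, 1] / max_l0 if max_l0 > 0 else np.zeros(len(front))
    return ScoredFront(front=front, score1=s1, score2=s2)


def _check_lam(lam: float) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return float(lam)


def las_score(s1, s2, lam: float):
    """Linear aggregation sum ``lam*s1 + (1-lam)*s2``."""
    lam = _check_lam(lam)
    return lam * np.asarray(s1) + (1.0 - lam) * np.asarray(s2)


def ap_score(s1, s2, lam: float):
    """Aggregation product ``s1^lam * s2^(1-lam)`` (with x^0 == 1, even at 0)."""
    lam = _check_lam(lam)
    return np.asarray(s1, dtype=float) ** lam * np.asarray(s2, dtype=float) ** (1.0 - lam)


def select_equation_result(sf: ScoredFront, lam: float) -> int:
    """Index of the front member minimizing the aggregation product at ``lam``.

    Fronts are ordered by ascending connection count, so ``argmin`` breaks
    exact ties toward the sparser member.
    """
    if len(sf) == 0:
        raise ValueError("empty scored front")
    return int(np.argmin(ap_score(sf.score1, sf.score2, lam)))


@dataclass(frozen=True)
class SweepPoint:
    """Selections at one lambda: chosen member per equation, the sum vector
    of their normalized scores, and the assembled network."""

    lam: float
    indices: tuple[int, ...]
    vec: np.ndarray
    system: SSystem


def _assemble(solutions: list[MixedSolution], exo=None) -> SSystem:
    """Build an S-System from per-equation decoded solutions.

    ``exo`` optionally gives known exogenous multipliers ``(kp, kd)`` per
    equation, which are folded into the rate constants so the assembled
    system is directly simulable against a ground truth that carries
    independent variables.  Rates are floored at 1e-12 (degenerate
    candidates with a zero rate constant are otherwise unrepresentable).
    """
    n = len(solutions)
    if any(sol.n != n for sol in solutions):
        raise ValueError("need one solution per component to assemble a network")
    kp = np.ones(n) if exo is None else np.asarray(exo[0], dtype=float)
    kd = np.ones(n) if exo is None else np.asarray(exo[1], dtype=float)
    G = np.zeros((n, n))
    H = np.zeros((n, n))
    alpha = np.empty(n)
    beta = np.empty(n)
    for i, sol in enumerate(solutions):
        g, h, a, b = decode(sol)
        G[i], H[i] = g, h
        alpha[i] = max(a * kp[i], 1e-12)
        beta[i] = max(b * kd[i], 1e-12)
    return SSystem(alpha=alpha, beta=beta, G=G, H=H)


def sweep_lambda(scored_fronts: list[ScoredFront], grid_size: int = 101, exo=None) -> list[SweepPoint]:
    """Per-equation selections, sum vectors and assembled networks over a
    uniform lambda grid including both endpoints."""
    points = []
    for lam in np.linspace(0.0, 1.0, grid_size):
        idx = tuple(select_equation_result(sf, lam) for sf in scored_fronts)
        vec = np.array(
            [
                sum(sf.score1[k] for sf, k in zip(scored_fronts, idx)),
                sum(sf.score2[k] for sf, k in zip(scored_fronts, idx)),
            ]
        )
        sols = [sf.front.solutions[k] for sf, k in zip(scored_fronts, idx)]
        points.append(SweepPoint(lam=float(lam), indices=idx, vec=vec, system=_assemble(sols, exo)))
    return points


def distinct_networks(points: list[SweepPoint]) -> list[SweepPoint]:
    """One representative sweep point (lowest lambda) per distinct
    per-equation selection; long runs of lambda collapse onto few networks."""
    seen: dict[tuple[int, ...], SweepPoint] = {}
    for p in points:
        seen.setdefault(p.indices, p)
    return list(seen.values())


def _distinct_nondominated(vecs: np.ndarray) -> np.ndarray:
    """Unique sum vectors, sorted by first component, reduced to the
    nondominated subset (strictly decreasing second component)."""
    uniq = np.unique(np.round(vecs, 12), axis=0)  # lexicographic sort
    kept = []
    best2 = np.inf
    for v in uniq:
        if v[1] < best2:
            kept.append(v)
            best2 = v[1]
    return np.array(kept)


def tradeoff_angle(prev: np.ndarray, p: np.ndarray, nxt: np.ndarray) -> float:
    """Bend angle at ``p``: pi minus the interior angle between the edges to
    its neighbours.  Zero on a straight line, large at a sharp knee."""
    u = prev - p
    v = nxt - p
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.pi - np.arccos(c))


def knee_select(points: list[SweepPoint]) -> tuple[np.ndarray, list[float]]:
    """Locate the knee among the distinct nondominated sum vectors.

    Endpoints have no two neighbours and are excluded from candidacy; ties
    in the tradeoff angle (e.g. collinear runs) break toward the smaller
    second component (sparser network).  With exactly two distinct vectors
    the one with smaller summed fitting score is chosen (documented
    fallback).  Returns the chosen vector and every lambda mapping to it.
    """
    vecs = np.array([p.vec for p in points])
    nd = _distinct_nondominated(vecs)
    if len(nd) < 2:
        raise ValueError("need at least 2 distinct sum vectors to locate a knee")
    if len(nd) == 2:
        chosen = nd[int(np.argmin(nd[:, 0]))]
    else:
        angles = np.array(
            [tradeoff_angle(nd[k - 1], nd[k], nd[k + 1]) for k in range(1, len(nd) - 1)]
        )
        cand = np.flatnonzero(angles >= angles.max() - 1e-12) + 1
        chosen = nd[cand[int(np.argmin(nd[cand, 1]))]]
    lams = [p.lam for p in points if np.allclose(p.vec, chosen, atol=1e-9)]
    return chosen, lams


@dataclass
class InferenceResult:
    """Final assembled network with its selection provenance."""

    system: SSystem
    solutions: list[MixedSolution]
    raw_alpha: np.ndarray
    raw_beta: np.ndarray
    lam: float
    lam_interval: tuple[float, float]
    knee_vec: np.ndarray
    sweep: list[SweepPoint]
    fronts: list[Front]
    confusion: object = None
    roc: object = None
    extras: dict = field(default_factory=dict)


def asp(fronts: list[Front], grid_size: int = 101, exo=None) -> InferenceResult:
    """The automatic selection procedure: normalize, sweep, knee, assemble.

    The reported lambda is the midpoint of the (closed) interval of grid
    values achieving the knee vector; the network is assembled from the
    sweep point at the grid lambda nearest that midpoint.
    """
    scored = [normalize(f) for f in sorted(fronts, key=lambda f: f.eq_index)]
    points = sweep_lambda(scored, grid_size, exo)
    vecs = np.array([p.vec for p in points])
    if len(_distinct_nondominated(vecs)) < 2:
        chosen, lams = points[0].vec, [p.lam for p in points]
    else:
        chosen, lams = knee_select(points)
    lam_mid = 0.5 * (min(lams) + max(lams))
    in_set = [p for p in points if p.lam in lams]
    pick = min(in_set, key=lambda p: abs(p.lam - lam_mid))
    sols = [sf.front.solutions[k] for sf, k in zip(scored, pick.indices)]
    raw = np.array([[decode(s)[2], decode(s)[3]] for s in sols])
    return InferenceResult(
        system=pick.system,
        solutions=sols,
        raw_alpha=raw[:, 0],
        raw_beta=raw[:, 1],
        lam=float(pick.lam),
        lam_interval=(float(min(lams)), float(max(lams))),
        knee_vec=chosen,
        sweep=points,
        fronts=list(fronts),
    )
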