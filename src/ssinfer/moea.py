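"""Mixed-variable multiobjective evolutionary algorithm (one equation at a time).

The search space of one decoupled equation couples ``2N`` connection bits
with ``2N + 2`` bounded reals.  The algorithm evolves a population ``Pop``
with three auxiliary structures:

* ``OldPop`` — the previous generation, used as a parent source to slow
  down premature convergence of the binary search;
* ``Arc`` — an archive of promising topologies, kept diverse by a
  hamming-distance-aware replacement rule (duplicated bit-strings are
  evicted first);
* ``Pool_i`` — one pool of real vectors per population slot, which feeds
  extra difference vectors to the real-parameter (differential evolution)
  variation and drives local exploitation.

Each generation: offspring are produced by a three-parent binary
recombination plus DE/rand/1 with binomial crossover on the reals;
parents come from ``Pop``/``OldPop`` with probability ``p1`` and from the
archive otherwise, and the DE difference pair comes from the parents with
probability ``p2`` and from ``Pool_i`` otherwise.  Parents and offspring
are merged, ranked by dominance depth (ties: ascending connection count),
and the best ``pop_size`` survive; the remainder update the archive.  A
``gbest`` individual is tracked (population with probability ``p3``, else
archive) for instrumentation.

All randomness flows through one ``numpy`` Generator, so runs are
bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmarks import Dataset
from .objectives import (
    Bounds,
    Front,
    MixedSolution,
    batch_errors,
    nondominated_filter,
)

__all__ = [
    "EAConfig",
    "EAState",
    "initialize",
    "step",
    "binary_recombine",
    "real_recombine",
    "make_offspring",
    "rank_and_truncate",
    "update_archive",
    "update_pools",
    "run_equation",
    "merge_runs",
    "infer_equation",
    "spawn_seed",
]


@dataclass
class EAConfig:
    """Algorithm settings.

    ``p1``/``p2``/``p3`` are the parent-source, DE-source and gbest-source
    probabilities; ``F`` and ``CR`` the DE scale and crossover rate;
    ``bin_inherit`` and ``bin_flip`` the two rates of the binary
    recombination (``bin_flip`` defaults to ``0.5 * CR``).

    ``polish_every`` controls the memetic refinement: every that many
    generations (and once at the end) the per-L0 incumbent solutions are
    refined by bounded least squares over their unmasked reals and fed
    back into the archive, sharpening the real-variable exploitation that
    pure DE variation provides only slowly for dense topologies (0
    disables).
    """

    pop_size: int = 100
    iterations: int = 2000
    n_runs: int = 10
    p1: float = 0.8
    p2: float = 0.7
    p3: float = 0.8
    F: float = 0.5
    CR: float = 0.9
    bin_inherit: float = 0.9
    bin_flip: float | None = None
    polish_every: int = 250
    bounds: Bounds = field(default_factory=Bounds.s1)
    seed: int = 0

    def __post_init__(self):
        for p in (self.p1, self.p2, self.p3, self.CR, self.bin_inherit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.F <= 0:
            raise ValueError("F must be positive")
        if self.bin_flip is None:
            self.bin_flip = 0.5 * self.CR


def spawn_seed(base: int, *key: int) -> np.random.SeedSequence:
    """Deterministic child seed: one global seed fans out by integer path."""
    return np.random.SeedSequence([int(base), *[int(k) for k in key]])


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection (preserves diversity
    better than clipping, which piles mass onto the bounds)."""
    span = hi - lo
    t = np.mod(x - lo, 2 * span)
    return lo + np.where(t > span, 2 * span - t, t)


def binary_recombine(b1, b2, b3, rng, inherit: float = 0.9, flip: float = 0.45):
    """Three-parent bit recombination.

    Where ``b2`` and ``b3`` agree, the offspring takes ``b1``'s bit with
    probability ``inherit`` and the agreed value otherwise; where they
    disagree, ``b1``'s bit is flipped with probability ``flip``.
    Shape-agnostic (works on single bit-strings or stacked batches).
    """
    b1, b2, b3 = (np.asarray(b, dtype=np.uint8) for b in (b1, b2, b3))
    if not (b1.shape == b2.shape == b3.shape):
        raise ValueError("parent bit-strings must have equal shapes")
    u = rng.random(b1.shape)
    agree = b2 == b3
    off_agree = np.where(u < inherit, b1, b2)
    off_dis = np.where(u < flip, 1 - b1, b1)
    return np.where(agree, off_agree, off_dis).astype(np.uint8)


def _de_recombine(r1, r2, r3, F, CR, lo, hi, rng):
    """DE/rand/1 mutant + binomial crossover against r1, reflected into bounds."""
    v = r1 + F * (r2 - r3)
    cross = rng.random(r1.shape) < CR
    jrand = rng.integers(r1.shape[-1], size=r1.shape[:-1])
    np.put_along_axis(cross, jrand[..., None], True, axis=-1)
    return _reflect(np.where(cross, v, r1), lo, hi)


def real_recombine(r1, r2, r3, cfg: EAConfig, rng) -> np.ndarray:
    """DE/rand/1 mutation with binomial crossover for one real vector."""
    r1, r2, r3 = (np.asarray(r, dtype=float) for r in (r1, r2, r3))
    n = (r1.shape[-1] - 2) // 2
    lo, hi = cfg.bounds.lower(n), cfg.bounds.upper(n)
    return _de_recombine(r1, r2, r3, cfg.F, cfg.CR, lo, hi, rng)


class _Archive:
    """Fixed-size topology archive with hamming-aware replacement."""

    def __init__(self, B, R, err):
        self.B = B
        self.R = R
        self.err = err
        self.l0 = B.sum(axis=1).astype(np.int64)
        self._pow2 = 1 << np.arange(B.shape[1], dtype=np.int64)
        self.keys = (B.astype(np.int64) @ self._pow2)
        self.counts: dict[int, int] = {}
        for k in self.keys:
            self.counts[int(k)] = self.counts.get(int(k), 0) + 1
        self.member_count = np.array([self.counts[int(k)] for k in self.keys])

    def update(self, b, r, e) -> bool:
        key = int(b.astype(np.int64) @ self._pow2)
        if self.counts.get(key, 0) > 0:
            # bit-string already archived: challenge the worst of its copies
            idxs = np.flatnonzero(self.keys == key)
            w = idxs[np.argmax(self.err[idxs])]
            if e < self.err[w]:
                self.B[w] = b
                self.R[w] = r
                self.err[w] = e
                return True
            return False
        dup = np.flatnonzero(self.member_count > 1)
        w = dup[np.argmax(self.err[dup])] if dup.size else int(np.argmax(self.err))
        if e >= self.err[w]:
            return False
        old = int(self.keys[w])
        self.counts[old] -= 1
        if self.counts[old] == 0:
            del self.counts[old]
        else:
            self.member_count[self.keys == old] = self.counts[old]
        self.B[w] = b
        self.R[w] = r
        self.err[w] = e
        self.keys[w] = key
        self.l0[w] = int(b.sum())
        self.counts[key] = 1
        self.member_count[w] = 1
        return True


@dataclass
class _EvalCtx:
    """Precomputed data for cheap candidate scoring of one equation."""

    logX: np.ndarray
    s_i: np.ndarray
    kp: float
    kd: float
    lo: np.ndarray
    hi: np.ndarray
    n: int
    eq_index: int

    @classmethod
    def from_dataset(cls, ds: Dataset, eq_index: int, bounds: Bounds) -> "_EvalCtx":
        n = ds.n_components
        if not 0 <= eq_index < n:
            raise ValueError(f"eq_index {eq_index} out of range")
        return cls(
            logX=ds.stacked_log_values(),
            s_i=ds.stacked_slopes()[:, eq_index],
            kp=float(ds.exo_prod[eq_index]),
            kd=float(ds.exo_deg[eq_index]),
            lo=bounds.lower(n),
            hi=bounds.upper(n),
            n=n,
            eq_index=eq_index,
        )

    def evaluate(self, B: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        G = B[:, :n] * R[:, :n]
        H = B[:, n : 2 * n] * R[:, n : 2 * n]
        with np.errstate(over="ignore", invalid="ignore"):
            err = batch_errors(self.logX, self.s_i, G, H, R[:, 2 * n], R[:, 2 * n + 1],
                               kp=self.kp, kd=self.kd)
        err = np.where(np.isfinite(err), err, np.inf)
        return err, B.sum(axis=1).astype(np.int64)


@dataclass
class EAState:
    """Mutable algorithm state: population, previous generation, archive,
    per-slot real-vector pools, gbest and the RNG.

    ``elite_*`` is a per-L0 register of the best solution ever evaluated at
    each connection count.  The population drifts sparse (ascending-L0
    truncation) and the archive evicts by error alone, so without this
    register the best solution at intermediate connection counts can be
    lost late in a run; the register guarantees the returned front never
    worsens at any L0 level.
    """

    ctx: _EvalCtx
    rng: np.random.Generator
    B: np.ndarray
    R: np.ndarray
    err: np.ndarray
    l0: np.ndarray
    Bold: np.ndarray
    Rold: np.ndarray
    arc: _Archive
    pools: np.ndarray      # (P, P, 2N+2)
    pool_err: np.ndarray   # (P, P), scored under B[i]'s bit-string
    gbest_b: np.ndarray
    gbest_r: np.ndarray
    elite_err: np.ndarray = None  # (2N+1,)
    elite_B: np.ndarray = None
    elite_R: np.ndarray = None
    generation: int = 0

    def register_elite(self, B, R, err, l0v) -> None:
        better = np.flatnonzero(err < self.elite_err[l0v])
        for k in better:
            kl = l0v[k]
            if err[k] < self.elite_err[kl]:
                self.elite_err[kl] = err[k]
                self.elite_B[kl] = B[k]
                self.elite_R[kl] = R[k]

    def elite_solutions(self) -> list[MixedSolution]:
        return [
            MixedSolution(bx=self.elite_B[k].copy(), rx=self.elite_R[k].copy(),
                          err=float(self.elite_err[k]), eq_index=self.ctx.eq_index)
            for k in np.flatnonzero(np.isfinite(self.elite_err))
        ]

    def solutions(self, which: str = "pop") -> list[MixedSolution]:
        if which == "pop":
            B, R, err = self.B, self.R, self.err
        elif which == "arc":
            B, R, err = self.arc.B, self.arc.R, self.arc.err
        else:
            raise ValueError("which must be 'pop' or 'arc'")
        return [
            MixedSolution(bx=B[i].copy(), rx=R[i].copy(), err=float(err[i]),
                          eq_index=self.ctx.eq_index)
            for i in range(B.shape[0])
        ]


def _pool_errors(ctx: _EvalCtx, bits: np.ndarray, pools: np.ndarray) -> np.ndarray:
    """Score every pool vector under its slot's bit-string; bits (r, 2N), pools (r, P, D)."""
    r, P, D = pools.shape
    Bflat = np.repeat(bits, P, axis=0)
    Rflat = pools.reshape(r * P, D)
    err, _ = ctx.evaluate(Bflat, Rflat)
    return err.reshape(r, P)


def initialize(cfg: EAConfig, ds: Dataset, eq_index: int, seed=None) -> EAState:
    """Draw and evaluate Pop/OldPop/Arc and the per-slot real pools.

    Bits are Bernoulli(1/2), reals uniform within bounds; each ``Pool_i``
    is scored under slot ``i``'s bit-string; gbest starts as a uniformly
    drawn population member.
    """
    ctx = _EvalCtx.from_dataset(ds, eq_index, cfg.bounds)
    P, n = cfg.pop_size, ctx.n
    if P <= 2 * n + 1:
        raise ValueError("pop_size must exceed 2N + 1")
    n2, D = 2 * n, 2 * n + 2
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)

    def draw():
        B = (rng.random((P, n2)) < 0.5).astype(np.uint8)
        R = rng.uniform(ctx.lo, ctx.hi, size=(P, D))
        return B, R

    B, R = draw()
    err, l0v = ctx.evaluate(B, R)
    Bold, Rold = draw()
    ctx.evaluate(Bold, Rold)
    Barc, Rarc = draw()
    err_arc, _ = ctx.evaluate(Barc, Rarc)
    pools = rng.uniform(ctx.lo, ctx.hi, size=(P, P, D))
    pool_err = _pool_errors(ctx, B, pools)
    gi = int(rng.integers(P))
    state = EAState(
        ctx=ctx,
        rng=rng,
        B=B,
        R=R,
        err=err,
        l0=l0v,
        Bold=Bold,
        Rold=Rold,
        arc=_Archive(Barc, Rarc, err_arc),
        pools=pools,
        pool_err=pool_err,
        gbest_b=B[gi].copy(),
        gbest_r=R[gi].copy(),
    )
    state.elite_err = np.full(n2 + 1, np.inf)
    state.elite_B = np.zeros((n2 + 1, n2), dtype=np.uint8)
    state.elite_R = np.zeros((n2 + 1, D))
    state.register_elite(B, R, err, l0v)
    state.register_elite(Barc, Rarc, err_arc, Barc.sum(axis=1))
    pb = np.repeat(B, P, axis=0)
    state.register_elite(pb, pools.reshape(P * P, D), pool_err.ravel(),
                         pb.sum(axis=1))
    return state


def _offspring_batch(state: EAState, cfg: EAConfig):
    ctx, rng = state.ctx, state.rng
    P = cfg.pop_size
    use_pop = rng.random(P) < cfg.p1
    i1, i2, i3 = (rng.integers(P, size=P) for _ in range(3))
    j1, j2, j3 = (rng.integers(state.arc.B.shape[0], size=P) for _ in range(3))
    m = use_pop[:, None]
    B1 = np.where(m, state.B[i1], state.arc.B[j1])
    B2 = np.where(m, state.Bold[i2], state.arc.B[j2])
    B3 = np.where(m, state.B[i3], state.arc.B[j3])
    R1 = np.where(m, state.R[i1], state.arc.R[j1])
    R2 = np.where(m, state.Rold[i2], state.arc.R[j2])
    R3 = np.where(m, state.R[i3], state.arc.R[j3])
    Boff = binary_recombine(B1, B2, B3, rng, cfg.bin_inherit, cfg.bin_flip)
    use_parents = rng.random(P) < cfg.p2
    pa, pb = rng.integers(P, size=P), rng.integers(P, size=P)
    rows = np.arange(P)
    mp = use_parents[:, None]
    r2 = np.where(mp, R2, state.pools[rows, pa])
    r3 = np.where(mp, R3, state.pools[rows, pb])
    Roff = _de_recombine(R1, r2, r3, cfg.F, cfg.CR, ctx.lo, ctx.hi, rng)
    err_off, l0_off = ctx.evaluate(Boff, Roff)
    return Boff, Roff, err_off, l0_off


def make_offspring(state: EAState, i: int, cfg: EAConfig) -> MixedSolution:
    """Produce one evaluated offspring for population slot ``i``.

    Parent sourcing (Pop/OldPop with probability ``p1``, archive otherwise)
    and DE-pair sourcing (parents with probability ``p2``, ``Pool_i``
    otherwise) follow the generational rule; provided for inspection and
    testing — the run loop uses the batched equivalent.
    """
    ctx, rng = state.ctx, state.rng
    P = cfg.pop_size
    if rng.random() < cfg.p1:
        i1, i3 = rng.integers(P), rng.integers(P)
        i2 = rng.integers(P)
        b1, b2, b3 = state.B[i1], state.Bold[i2], state.B[i3]
        r1, r2, r3 = state.R[i1], state.Rold[i2], state.R[i3]
    else:
        j1, j2, j3 = rng.integers(state.arc.B.shape[0], size=3)
        b1, b2, b3 = state.arc.B[j1], state.arc.B[j2], state.arc.B[j3]
        r1, r2, r3 = state.arc.R[j1], state.arc.R[j2], state.arc.R[j3]
    boff = binary_recombine(b1, b2, b3, rng, cfg.bin_inherit, cfg.bin_flip)
    if rng.random() >= cfg.p2:
        pa, pb = rng.integers(P), rng.integers(P)
        r2, r3 = state.pools[i, pa], state.pools[i, pb]
    roff = _de_recombine(r1[None, :], r2[None, :], r3[None, :],
                         cfg.F, cfg.CR, ctx.lo, ctx.hi, rng)[0]
    err, _ = ctx.evaluate(boff[None, :], roff[None, :])
    return MixedSolution(bx=boff, rx=roff, err=float(err[0]), eq_index=ctx.eq_index)


def _dominance_ranks(err: np.ndarray, l0v: np.ndarray) -> np.ndarray:
    """Dominance depth (fast nondominated sorting) for two minimized objectives."""
    e1, e2 = err[:, None], err[None, :]
    k1, k2 = l0v[:, None], l0v[None, :]
    dominated_by = (e2 <= e1) & (k2 <= k1) & ((e2 < e1) | (k2 < k1))
    nsol = err.shape[0]
    ranks = np.full(nsol, -1, dtype=np.int64)
    remaining = np.ones(nsol, dtype=bool)
    r = 0
    while remaining.any():
        front = remaining & ~(dominated_by & remaining[None, :]).any(axis=1)
        ranks[front] = r
        remaining &= ~front
        r += 1
    return ranks


def _truncation_order(err, l0v) -> np.ndarray:
    ranks = _dominance_ranks(err, l0v)
    return np.lexsort((np.arange(err.shape[0]), err, l0v, ranks))


def rank_and_truncate(solutions: list[MixedSolution], pop_size: int):
    """Nondominated-sort a merged population and split survivors from leftovers.

    Within a rank, solutions are ordered by ascending connection count,
    then lower error, then insertion order; the first ``pop_size`` form the
    next population and the rest are handed to the archive.
    """
    err = np.array([s.err for s in solutions])
    l0v = np.array([s.l0 for s in solutions])
    order = _truncation_order(err, l0v)
    new_pop = [solutions[k] for k in order[:pop_size]]
    leftovers = [solutions[k] for k in order[pop_size:]]
    return new_pop, leftovers


def update_archive(arc: list[MixedSolution], candidate: MixedSolution) -> list[MixedSolution]:
    """Apply the hamming-aware archive replacement rule to a solution list.

    New bit-strings challenge the worst-error member among duplicated
    bit-strings (or the overall worst if all are unique); already-present
    bit-strings challenge the worst of their own copies.  Archive size is
    invariant.
    """
    B = np.array([s.bx for s in arc], dtype=np.uint8)
    R = np.array([s.rx for s in arc], dtype=float)
    err = np.array([s.err for s in arc], dtype=float)
    a = _Archive(B, R, err)
    a.update(candidate.bx, candidate.rx, candidate.err)
    eq = arc[0].eq_index
    return [
        MixedSolution(bx=a.B[i].copy(), rx=a.R[i].copy(), err=float(a.err[i]), eq_index=eq)
        for i in range(len(arc))
    ]


def update_pools(pool_err: np.ndarray, off_err: np.ndarray):
    """Replace-worst decisions for the per-slot pools.

    Returns ``(rows, worst_idx)`` where ``rows`` are the slots whose worst
    pool member is beaten by their offspring's fitting error.
    """
    worst_idx = pool_err.argmax(axis=1)
    worst = pool_err[np.arange(pool_err.shape[0]), worst_idx]
    rows = np.flatnonzero(off_err < worst)
    return rows, worst_idx


def step(state: EAState, cfg: EAConfig) -> None:
    """Advance one generation in place."""
    ctx = state.ctx
    P = cfg.pop_size
    Boff, Roff, err_off, l0_off = _offspring_batch(state, cfg)
    state.register_elite(Boff, Roff, err_off, l0_off)

    Bi = np.vstack([state.B, Boff])
    Ri = np.vstack([state.R, Roff])
    erri = np.concatenate([state.err, err_off])
    l0i = np.concatenate([state.l0, l0_off])
    order = _truncation_order(erri, l0i)
    sel, rest = order[:P], order[P:]

    # pool replacement decisions use the offspring errors (own bit-strings)
    repl_rows, worst_idx = update_pools(state.pool_err, err_off)

    # Survivors are assigned to population slots so that a slot keeps its
    # bit-string whenever some survivor carries it: pools are per-slot local
    # searchers, and stable slots avoid needless pool re-scoring.
    old_keys = state.B.astype(np.int64) @ state.arc._pow2
    new_keys_unordered = Bi[sel].astype(np.int64) @ state.arc._pow2
    slots_by_key: dict[int, list[int]] = {}
    for i, k in enumerate(old_keys):
        slots_by_key.setdefault(int(k), []).append(i)
    assign = np.full(P, -1, dtype=np.int64)  # slot -> index into sel
    unmatched = []
    for j, k in enumerate(new_keys_unordered):
        lst = slots_by_key.get(int(k))
        if lst:
            assign[lst.pop()] = j
        else:
            unmatched.append(j)
    free = np.flatnonzero(assign < 0)
    assign[free] = unmatched
    perm = sel[assign]

    state.Bold, state.Rold = state.B, state.R
    state.B, state.R = Bi[perm].copy(), Ri[perm].copy()
    state.err, state.l0 = erri[perm].copy(), l0i[perm].copy()
    changed = free

    state.pools[repl_rows, worst_idx[repl_rows]] = Roff[repl_rows]
    if changed.size:
        state.pool_err[changed] = _pool_errors(ctx, state.B[changed], state.pools[changed])
        nch, Ppool, D = state.pools[changed].shape
        pb = np.repeat(state.B[changed], Ppool, axis=0)
        state.register_elite(pb, state.pools[changed].reshape(nch * Ppool, D),
                             state.pool_err[changed].ravel(), pb.sum(axis=1))
    fresh = np.setdiff1d(repl_rows, changed, assume_unique=False)
    if fresh.size:
        # re-score just-inserted vectors under their slot's (unchanged) bits
        err, _ = ctx.evaluate(state.B[fresh], state.pools[fresh, worst_idx[fresh]])
        state.pool_err[fresh, worst_idx[fresh]] = err

    for k in rest:
        state.arc.update(Bi[k], Ri[k], erri[k])

    if state.rng.random() < cfg.p3:
        gi = int(state.rng.integers(P))
        state.gbest_b, state.gbest_r = state.B[gi].copy(), state.R[gi].copy()
    else:
        gi = int(state.rng.integers(state.arc.B.shape[0]))
        state.gbest_b, state.gbest_r = state.arc.B[gi].copy(), state.arc.R[gi].copy()
    state.generation += 1


def _ls_refine(ctx: _EvalCtx, b: np.ndarray, rx: np.ndarray):
    """Bounded least-squares fit of the unmasked reals of topology ``b``,
    started from ``rx``.  Returns ``(err, rx_refined)`` or ``None``."""
    from scipy.optimize import least_squares

    n = ctx.n
    rx = np.clip(rx, ctx.lo, ctx.hi)
    gm = b[:n].astype(bool)
    hm = b[n : 2 * n].astype(bool)
    ng, nf = int(gm.sum()), int(gm.sum() + hm.sum())
    if nf == 0:
        return None

    def resid(theta):
        g = np.zeros(n)
        h = np.zeros(n)
        g[gm] = theta[:ng]
        h[hm] = theta[ng:nf]
        a, bb = theta[-2:]
        with np.errstate(over="ignore"):
            shat = ctx.kp * a * np.exp(ctx.logX @ g) - ctx.kd * bb * np.exp(ctx.logX @ h)
        return shat - ctx.s_i

    x0 = np.concatenate([rx[:n][gm], rx[n : 2 * n][hm], rx[2 * n :]])
    lo = np.concatenate([ctx.lo[:n][gm], ctx.lo[n : 2 * n][hm], ctx.lo[2 * n :]])
    hi = np.concatenate([ctx.hi[:n][gm], ctx.hi[n : 2 * n][hm], ctx.hi[2 * n :]])
    try:
        fit = least_squares(resid, x0, bounds=(lo, hi), max_nfev=60 * (nf + 2))
    except Exception:
        return None
    err = float(2 * fit.cost)
    if not np.isfinite(err):
        return None
    rx_new = rx.copy()
    rx_new[np.flatnonzero(gm)] = fit.x[:ng]
    rx_new[n + np.flatnonzero(hm)] = fit.x[ng:nf]
    rx_new[2 * n :] = fit.x[-2:]
    return err, rx_new


def polish_elites(state: EAState) -> None:
    """Memetic refinement of the per-L0 incumbents.

    Each incumbent's reals are refined by bounded least squares with its
    topology fixed; from the refined solution a pruned child — same
    topology minus the connection with the smallest decoded magnitude —
    is refined as well, cascading good dense solutions down the sparsity
    ladder where the evolutionary variation alone discovers exact sparse
    supports only slowly.  Improvements re-enter the elite register and
    the archive.  Deterministic."""
    ctx = state.ctx
    n = ctx.n
    for k in range(state.elite_err.shape[0] - 1, 0, -1):
        if not np.isfinite(state.elite_err[k]):
            continue
        b = state.elite_B[k]
        out = _ls_refine(ctx, b, state.elite_R[k])
        if out is None:
            continue
        err, rx_new = out
        if err < state.elite_err[k]:
            state.elite_err[k] = err
            state.elite_R[k] = rx_new
            state.arc.update(b.copy(), rx_new.copy(), err)
        if k < 2:
            continue
        # prune each connection of the refined solution in turn: exact sparse
        # supports are found as one-bit drops of easily-found supersets
        rx_best = state.elite_R[k].copy()
        for drop in np.flatnonzero(b):
            child = b.copy()
            child[drop] = 0
            out = _ls_refine(ctx, child, rx_best)
            if out is None:
                continue
            cerr, crx = out
            if cerr < state.elite_err[k - 1]:
                state.elite_err[k - 1] = cerr
                state.elite_B[k - 1] = child
                state.elite_R[k - 1] = crx
                state.arc.update(child.copy(), crx.copy(), cerr)


def run_equation(ds: Dataset, eq_index: int, cfg: EAConfig, seed=None) -> Front:
    """Run the generational loop and return the nondominated front of the
    final population, archive and per-L0 elite register.  Deterministic
    given the seed."""
    state = initialize(cfg, ds, eq_index, seed=seed)
    for it in range(cfg.iterations):
        step(state, cfg)
        if cfg.polish_every and (it + 1) % cfg.polish_every == 0:
            polish_elites(state)
    if cfg.polish_every and cfg.iterations % cfg.polish_every != 0:
        polish_elites(state)
    return front_from_state(state)


def front_from_state(state: EAState) -> Front:
    return nondominated_filter(
        state.solutions("pop") + state.solutions("arc") + state.elite_solutions()
    )


def merge_runs(fronts: list[Front]) -> Front:
    """Nondominated union of independent-run fronts of one equation."""
    eqs = {f.eq_index for f in fronts}
    if len(eqs) != 1:
        raise ValueError("all fronts must describe the same equation")
    return nondominated_filter([s for f in fronts for s in f.solutions])


def infer_equation(ds: Dataset, eq_index: int, cfg: EAConfig, base_seed=None) -> Front:
    """Independent restarts merged into one front (``cfg.n_runs`` runs).

    Child seeds derive deterministically from ``(base_seed, eq_index, run)``
    so any single run can be reproduced in isolation.
    """
    base = cfg.seed if base_seed is None else base_seed
    fronts = [
        run_equation(ds, eq_index, cfg, seed=spawn_seed(base, eq_index, r))
        for r in range(cfg.n_runs)
    ]
    return merge_runs(fronts)
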