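"""Variation operators, ranking, archive/pool updating, and recovery runs."""

import numpy as np
import pytest

import ssinfer as si
from ssinfer import moea
from conftest import true_solution


@pytest.fixture()
def small_cfg():
    return si.EAConfig(pop_size=20, iterations=30, n_runs=1, seed=0)


@pytest.fixture()
def state(small_cfg, s1_data_analytic):
    return moea.initialize(small_cfg, s1_data_analytic, 1, seed=3)


class TestBinaryRecombine:
    def test_identical_parents_deviation_rate(self):
        # with b1 == b2 == b3 every draw returns the common bits
        rng = np.random.default_rng(0)
        b = rng.integers(0, 2, 50).astype(np.uint8)
        out = moea.binary_recombine(np.tile(b, (200, 1)), np.tile(b, (200, 1)),
                                    np.tile(b, (200, 1)), rng)
        assert (out == b).all()

    def test_disagreement_flip_rate(self):
        # b2 != b3 everywhere: b1's bit flips with probability 0.45
        rng = np.random.default_rng(1)
        n = 10_000
        b1 = np.zeros((n, 1), np.uint8)
        b2 = np.zeros((n, 1), np.uint8)
        b3 = np.ones((n, 1), np.uint8)
        out = moea.binary_recombine(b1, b2, b3, rng, flip=0.45)
        rate = out.mean()
        assert abs(rate - 0.45) < 3 * np.sqrt(0.45 * 0.55 / n)

    def test_agreement_law(self):
        # b2 == b3 == 1, b1 == 0: offspring bit is 0 w.p. inherit, else 1
        rng = np.random.default_rng(2)
        n = 10_000
        out = moea.binary_recombine(np.zeros((n, 1), np.uint8),
                                    np.ones((n, 1), np.uint8),
                                    np.ones((n, 1), np.uint8), rng, inherit=0.9)
        assert abs(out.mean() - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            moea.binary_recombine(np.zeros(4, np.uint8), np.zeros(5, np.uint8),
                                  np.zeros(5, np.uint8), rng)


class TestRealRecombine:
    def test_zero_difference_vector(self):
        cfg = si.EAConfig(CR=1.0, bounds=si.Bounds(kinetic_range=(-3, 3), rate_range=(0, 10)))
        rng = np.random.default_rng(0)
        r = np.r_[1.0, -1.0, 2.0, 3.0]  # n = 1 -> length 4
        out = moea.real_recombine(r, np.r_[2.0, 0, 1, 1], np.r_[2.0, 0, 1, 1], cfg, rng)
        np.testing.assert_allclose(out, r)

    def test_direct_formula(self):
        # v = r1 + 0.5 * (r2 - r3); CR = 1 takes every mutant component
        cfg = si.EAConfig(F=0.5, CR=1.0, bounds=si.Bounds(kinetic_range=(-3, 3), rate_range=(0, 10)))
        rng = np.random.default_rng(0)
        r1 = np.r_[1.0, 1.0, 1.0, 1.0]
        r2 = np.r_[2.0, 0.0, 2.0, 0.0]
        r3 = np.r_[0.0, 0.0, 0.0, 0.0]
        out = moea.real_recombine(r1, r2, r3, cfg, rng)
        np.testing.assert_allclose(out, [2.0, 1.0, 2.0, 1.0])

    def test_reflection_keeps_bounds(self):
        cfg = si.EAConfig(F=2.5, bounds=si.Bounds(kinetic_range=(-1, 1), rate_range=(0, 3)))
        rng = np.random.default_rng(4)
        lo, hi = cfg.bounds.lower(1), cfg.bounds.upper(1)
        for _ in range(50):
            r1, r2, r3 = (rng.uniform(lo, hi) for _ in range(3))
            out = moea.real_recombine(r1, r2, r3, cfg, rng)
            assert (out >= lo).all() and (out <= hi).all()


class TestRankAndTruncate:
    @staticmethod
    def _depth_oracle(objs):
        # dominance depth by repeated peeling of nondominated layers
        objs = list(objs)
        depth = {}
        remaining = set(range(len(objs)))
        d = 0
        while remaining:
            layer = {
                i for i in remaining
                if not any(si.dominates(objs[j], objs[i]) for j in remaining if j != i)
            }
            for i in layer:
                depth[i] = d
            remaining -= layer
            d += 1
        return [depth[i] for i in range(len(objs))]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_depth_oracle(self, seed):
        rng = np.random.default_rng(seed)
        err = rng.random(40)
        l0v = rng.integers(0, 11, 40)
        ranks = moea._dominance_ranks(err, l0v)
        oracle = self._depth_oracle(list(zip(err, l0v)))
        np.testing.assert_array_equal(ranks, oracle)

    def test_truncation_contract(self):
        rng = np.random.default_rng(7)
        sols = [
            si.MixedSolution(bx=rng.integers(0, 2, 10).astype(np.uint8),
                             rx=rng.uniform(-3, 3, 12), err=float(rng.random()))
            for _ in range(30)
        ]
        pop, rest = moea.rank_and_truncate(sols, 12)
        assert len(pop) == 12 and len(rest) == 18
        ranks = moea._dominance_ranks(np.array([s.err for s in sols]),
                                      np.array([s.l0 for s in sols]))
        by_id = {id(s): r for s, r in zip(sols, ranks)}
        worst_kept = max(by_id[id(s)] for s in pop)
        best_dropped = min(by_id[id(s)] for s in rest)
        assert worst_kept <= best_dropped

    def test_small_nondominated_set_is_identity(self):
        sols = [
            si.MixedSolution(bx=np.zeros(10, np.uint8), rx=np.zeros(12), err=3.0),
            si.MixedSolution(bx=np.r_[1, np.zeros(9)].astype(np.uint8),
                             rx=np.zeros(12), err=1.0),
        ]
        pop, rest = moea.rank_and_truncate(sols, 5)
        assert {id(s) for s in pop} == {id(s) for s in sols} and not rest


class TestUpdateArchive:
    @staticmethod
    def _arc(bits_list, errs):
        return [
            si.MixedSolution(bx=np.array(b, np.uint8), rx=np.zeros(len(b) + 2), err=e)
            for b, e in zip(bits_list, errs)
        ]

    def test_worse_candidate_with_new_bits_leaves_archive_unchanged(self):
        arc = self._arc([[1, 0], [0, 1]], [1.0, 2.0])
        cand = si.MixedSolution(bx=np.array([1, 1], np.uint8), rx=np.zeros(4), err=9.0)
        out = moea.update_archive(arc, cand)
        assert [s.err for s in out] == [1.0, 2.0]

    def test_duplicate_bits_replaced_by_better_same_bits(self):
        arc = self._arc([[1, 0]] * 3, [1.0, 2.0, 3.0])
        cand = si.MixedSolution(bx=np.array([1, 0], np.uint8), rx=np.ones(4), err=0.5)
        out = moea.update_archive(arc, cand)
        assert sorted(s.err for s in out) == [0.5, 1.0, 2.0]

    def test_new_bits_evict_worst_duplicate_first(self):
        arc = self._arc([[1, 0], [1, 0], [0, 1]], [1.0, 2.0, 9.0])
        cand = si.MixedSolution(bx=np.array([1, 1], np.uint8), rx=np.ones(4), err=0.5)
        out = moea.update_archive(arc, cand)
        # the duplicated (1,0) at err 2.0 goes, not the unique worst (0,1)
        assert sorted(s.err for s in out) == [0.5, 1.0, 9.0]
        assert len(out) == len(arc)


class TestStateAndStep:
    def test_initialize_contracts(self, state, small_cfg, s1_data_analytic):
        P = small_cfg.pop_size
        assert state.B.shape == (P, 10) and state.arc.B.shape == (P, 10)
        assert state.pools.shape == (P, P, 12)
        # cached errors match re-evaluation
        err, l0v = state.ctx.evaluate(state.B, state.R)
        np.testing.assert_array_equal(err, state.err)
        np.testing.assert_array_equal(l0v, state.l0)

    def test_initialize_deterministic(self, small_cfg, s1_data_analytic):
        a = moea.initialize(small_cfg, s1_data_analytic, 1, seed=5)
        b = moea.initialize(small_cfg, s1_data_analytic, 1, seed=5)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.pools, b.pools)

    def test_make_offspring_within_bounds(self, state, small_cfg):
        lo, hi = state.ctx.lo, state.ctx.hi
        for i in range(5):
            off = moea.make_offspring(state, i, small_cfg)
            assert (off.rx >= lo).all() and (off.rx <= hi).all()
            assert off.err is not None

    def test_pool_worst_error_non_increasing(self, state, small_cfg):
        worst_before = state.pool_err.max(axis=1).copy()
        keys_before = state.B.astype(np.int64) @ state.arc._pow2
        for _ in range(10):
            moea.step(state, small_cfg)
        keys_after = state.B.astype(np.int64) @ state.arc._pow2
        stable = keys_after == keys_before
        # for slots whose topology never changed, the pool can only improve
        assert (state.pool_err.max(axis=1)[stable] <= worst_before[stable] + 1e-12).all()

    def test_archive_size_invariant(self, state, small_cfg):
        for _ in range(5):
            moea.step(state, small_cfg)
        assert state.arc.B.shape[0] == small_cfg.pop_size

    def test_elitism_per_l0_never_worsens(self, state, small_cfg):
        snapshots = []
        for _ in range(15):
            moea.step(state, small_cfg)
            snapshots.append(state.elite_err.copy())
        for a, b in zip(snapshots, snapshots[1:]):
            assert (b <= a + 1e-12).all()


class TestRunEquation:
    def test_seeded_determinism(self, s1_data_analytic):
        cfg = si.EAConfig(pop_size=20, iterations=40, seed=0)
        f1 = si.run_equation(s1_data_analytic, 1, cfg, seed=9)
        f2 = si.run_equation(s1_data_analytic, 1, cfg, seed=9)
        assert len(f1) == len(f2)
        for a, b in zip(f1.solutions, f2.solutions):
            np.testing.assert_array_equal(a.bx, b.bx)
            np.testing.assert_array_equal(a.rx, b.rx)
            assert a.err == b.err

    def test_front_internally_nondominated(self, s1_data_analytic):
        cfg = si.EAConfig(pop_size=20, iterations=40, seed=0)
        front = si.run_equation(s1_data_analytic, 0, cfg, seed=2)
        objs = [(s.err, s.l0) for s in front.solutions]
        for a in objs:
            assert not any(si.dominates(b, a) for b in objs if b is not a)

    def test_recovers_s1_equation2_topology(self, s1, s1_data_analytic):
        # with exact slopes the true (g21, h22) pair is identifiable at l0=2
        cfg = si.EAConfig(pop_size=60, iterations=150, seed=0)
        truth = true_solution(s1, 1)
        hits = 0
        for seed in range(10):
            front = si.run_equation(s1_data_analytic, 1, cfg, seed=seed)
            for s in front.solutions:
                if s.l0 == 2 and s.err < 1e-4 and np.array_equal(s.bx, truth.bx):
                    hits += 1
                    break
        assert hits >= 9


class TestMergeRuns:
    def test_idempotent(self, s1_data_analytic):
        cfg = si.EAConfig(pop_size=20, iterations=30, seed=0)
        f = si.run_equation(s1_data_analytic, 2, cfg, seed=1)
        m = si.merge_runs([f, f])
        assert [(s.err, s.l0) for s in m.solutions] == [(s.err, s.l0) for s in f.solutions]

    def test_merge_dominates_inputs(self, s1_data_analytic):
        cfg = si.EAConfig(pop_size=20, iterations=30, seed=0)
        fronts = [si.run_equation(s1_data_analytic, 2, cfg, seed=s) for s in (1, 2)]
        merged = si.merge_runs(fronts)
        best = {s.l0: s.err for s in merged.solutions}
        for f in fronts:
            for s in f.solutions:
                assert best.get(s.l0, np.inf) <= s.err or any(
                    k <= s.l0 and e <= s.err for k, e in best.items()
                )

    def test_mixed_equations_rejected(self, s1_data_analytic):
        cfg = si.EAConfig(pop_size=20, iterations=10, seed=0)
        f1 = si.run_equation(s1_data_analytic, 0, cfg, seed=1)
        f2 = si.run_equation(s1_data_analytic, 1, cfg, seed=1)
        with pytest.raises(ValueError):
            si.merge_runs([f1, f2])
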