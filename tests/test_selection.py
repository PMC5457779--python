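"""Score normalization, aggregation selection, lambda sweep and knee location."""

import numpy as np
import pytest

import ssinfer as si
from ssinfer.selection import SweepPoint, tradeoff_angle, _distinct_nondominated


def _front(errs, l0s, eq_index=0, n=5):
    rng = np.random.default_rng(0)
    sols = []
    for e, k in zip(errs, l0s):
        bx = np.zeros(2 * n, np.uint8)
        bx[rng.permutation(2 * n)[:k]] = 1
        sols.append(si.MixedSolution(bx=bx, rx=rng.uniform(0.1, 2, 2 * n + 2),
                                     err=float(e), eq_index=eq_index))
    return si.Front(eq_index=eq_index, solutions=tuple(sols))


class TestNormalize:
    def test_division_by_maximum(self):
        sf = si.normalize(_front([4.0, 1.0, 0.2], [1, 2, 3]))
        np.testing.assert_allclose(sf.score1, [1.0, 0.25, 0.05])
        np.testing.assert_allclose(sf.score2, [1 / 3, 2 / 3, 1.0])

    def test_single_member(self):
        sf = si.normalize(_front([2.0], [3]))
        assert sf.score1[0] == 1.0 and sf.score2[0] == 1.0

    def test_empty_topology_member_is_dropped(self):
        sf = si.normalize(_front([9.0, 4.0, 1.0], [0, 1, 2]))
        assert len(sf) == 2
        np.testing.assert_allclose(sf.score2, [0.5, 1.0])

    def test_ordering_preserved(self):
        front = _front([5.0, 3.0, 1.0], [1, 2, 3])
        sf = si.normalize(front)
        assert np.argsort(sf.score1).tolist() == [2, 1, 0]

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            si.normalize(si.Front(eq_index=0, solutions=()))


class TestScores:
    def test_las_endpoints_and_midpoint(self):
        assert si.las_score(0.3, 0.8, 1.0) == pytest.approx(0.3)
        assert si.las_score(0.3, 0.8, 0.0) == pytest.approx(0.8)
        assert si.las_score(0.2, 0.6, 0.5) == pytest.approx(0.4)

    def test_ap_spot_values(self):
        assert si.ap_score(0.7, 0.2, 1.0) == pytest.approx(0.7)
        assert si.ap_score(0.04, 0.25, 0.5) == pytest.approx(0.1)
        assert si.ap_score(0.0, 0.5, 0.7) == 0.0
        assert si.ap_score(0.0, 0.5, 0.0) == pytest.approx(0.5)  # x^0 == 1

    @pytest.mark.parametrize("fn", [si.las_score, si.ap_score])
    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_lambda_out_of_range(self, fn, lam):
        with pytest.raises(ValueError):
            fn(0.5, 0.5, lam)


class TestSelectEquationResult:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_argmin(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 9)
        errs = np.sort(rng.random(m))[::-1] + 1e-3
        front = _front(errs, np.arange(1, m + 1))
        sf = si.normalize(front)
        lam = float(rng.random())
        k = si.select_equation_result(sf, lam)
        scores = [si.ap_score(sf.score1[j], sf.score2[j], lam) for j in range(m)]
        assert scores[k] == min(scores)

    def test_extreme_lambdas(self):
        sf = si.normalize(_front([8.0, 2.0, 0.5], [1, 2, 4]))
        assert sf.front.solutions[si.select_equation_result(sf, 0.0)].l0 == 1
        k = si.select_equation_result(sf, 1.0)
        assert sf.score1[k] == sf.score1.min()


class TestSweep:
    def test_grid_endpoints_and_vector_range(self):
        fronts = [_front([5.0, 1.0, 0.1], [1, 2, 3], eq_index=i) for i in range(5)]
        pts = si.sweep_lambda([si.normalize(f) for f in fronts], grid_size=21)
        assert pts[0].lam == 0.0 and pts[-1].lam == 1.0 and len(pts) == 21
        for p in pts:
            assert (0 <= p.vec).all() and (p.vec <= 5).all()

    def test_selected_l0_non_decreasing_in_lambda(self):
        fronts = [_front([7.0, 2.0, 0.4, 0.05], [1, 2, 3, 5], eq_index=i) for i in range(5)]
        pts = si.sweep_lambda([si.normalize(f) for f in fronts], grid_size=51)
        tot = [sum(p.indices) for p in pts]
        assert (np.diff(tot) >= 0).all()


class TestKneeSelect:
    @staticmethod
    def _points(vecs):
        sys = si.make_s1()
        return [SweepPoint(lam=i / (len(vecs) - 1), indices=(0,), vec=np.asarray(v, float),
                           system=sys) for i, v in enumerate(vecs)]

    def test_toy_knee(self):
        # explicit oracle: the bend angle of the middle point is largest
        pts = self._points([(0, 1), (0.05, 0.1), (1, 0)])
        chosen, lams = si.knee_select(pts)
        np.testing.assert_allclose(chosen, [0.05, 0.1])
        assert lams == [0.5]

    def test_angle_oracle_values(self):
        a = tradeoff_angle(np.r_[0.0, 1.0], np.r_[0.05, 0.1], np.r_[1.0, 0.0])
        straight = tradeoff_angle(np.r_[0.0, 1.0], np.r_[0.5, 0.5], np.r_[1.0, 0.0])
        assert a > 1.0          # sharp corner, large bend
        assert straight == pytest.approx(0.0, abs=1e-6)

    def test_collinear_tie_breaks_sparse(self):
        pts = self._points([(0, 3), (1, 2), (2, 1), (3, 0)])
        chosen, _ = si.knee_select(pts)
        np.testing.assert_allclose(chosen, [2, 1])  # smaller second component

    def test_reorder_invariance(self):
        vecs = [(0, 1), (0.05, 0.1), (1, 0), (0.3, 0.05)]
        a, _ = si.knee_select(self._points(vecs))
        b, _ = si.knee_select(self._points(vecs[::-1]))
        np.testing.assert_allclose(a, b)

    def test_two_point_fallback(self):
        chosen, _ = si.knee_select(self._points([(0.1, 1.0), (0.9, 0.2)]))
        np.testing.assert_allclose(chosen, [0.1, 1.0])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            si.knee_select(self._points([(0.5, 0.5), (0.5, 0.5)]))

    def test_chosen_point_is_nondominated(self):
        rng = np.random.default_rng(3)
        vecs = rng.random((30, 2)) * 3
        pts = self._points(vecs.tolist())
        chosen, _ = si.knee_select(pts)
        nd = _distinct_nondominated(np.array([p.vec for p in pts]))
        assert any(np.allclose(chosen, v) for v in nd)


class TestAsp:
    def test_deterministic_and_decodable(self):
        rng = np.random.default_rng(0)
        fronts = []
        for i in range(5):
            m = 4
            errs = np.sort(rng.random(m))[::-1] + 0.01
            fronts.append(_front(errs, [1, 2, 3, 5], eq_index=i))
        r1 = si.asp(fronts)
        r2 = si.asp(fronts)
        assert r1.lam == r2.lam
        np.testing.assert_array_equal(r1.system.G, r2.system.G)
        # the assembled system decodes exactly from the chosen solutions
        for i, sol in enumerate(r1.solutions):
            g, h, a, b = si.decode(sol)
            np.testing.assert_array_equal(r1.system.G[i], g)
            assert r1.system.alpha[i] == pytest.approx(max(a, 1e-12))
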