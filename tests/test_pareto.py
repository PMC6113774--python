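"""Monte Carlo Pareto machinery: sampling, objectives, dominance, selection."""

import numpy as np
import pytest

from dermadyn import pareto
from dermadyn.datasets import FitSolution, KineticParameters
from dermadyn.pareto import (
    ParetoCandidate,
    ParetoFront,
    SamplingRanges,
    default_ranges,
    fit,
    mse_pair,
    pareto_front,
    sample_candidate,
    select_solution,
)
from dermadyn.synthetic import NoiseModel, synth_maturation


def collapsed_ranges(solution):
    b = {}
    for name, v in zip(("beta", "k2", "km2", "k3", "k4", "k6", "k7"), solution.params.as_tuple()):
        b[name] = (v, v, "linear" if name == "beta" else "log")
    b["pf0"] = (solution.pf0, solution.pf0, "linear")
    b["qf0"] = (solution.qf0, solution.qf0, "linear")
    return SamplingRanges(b)


class TestSampling:
    def test_draws_within_bounds(self, rng):
        ranges = default_ranges()
        lo, hi, _ = ranges.arrays()
        draws = np.array(
            [
                [*sample_candidate(rng, ranges).params.as_tuple(),
                 sample_candidate(rng, ranges).pf0]
                for _ in range(200)
            ]
        )
        assert np.all(draws[:, :7] >= lo[:7] - 1e-12)
        assert np.all(draws[:, :7] <= hi[:7] + 1e-12)

    def test_same_seed_identical(self):
        a = sample_candidate(np.random.default_rng(7))
        b = sample_candidate(np.random.default_rng(7))
        assert a == b

    def test_default_ranges_contain_published(self, published):
        lo, hi, _ = default_ranges().arrays()
        vec = np.array([*published.params.as_tuple(), published.pf0, published.qf0])
        assert np.all(vec >= lo) and np.all(vec <= hi)

    def test_invalid_ranges(self):
        b = default_ranges().bounds.copy()
        b["k2"] = (1.0, 0.5, "log")
        with pytest.raises(ValueError):
            SamplingRanges(b)
        b = default_ranges().bounds.copy()
        b["k2"] = (-1.0, 0.5, "log")
        with pytest.raises(ValueError):
            SamplingRanges(b)


class TestMsePair:
    def test_perfect_fit_on_own_synthetic_data(self, published):
        pf_ds, ecm_ds = synth_maturation(published, noise=NoiseModel(mode="fixed_sd", sd=0.0))
        mp, me = mse_pair(published, pf_ds, ecm_ds)
        assert mp < 1e-8 and me < 1e-8

    def test_constant_offset_algebra(self, published):
        # adding c to every PF% observation changes msePF by c^2 when the
        # model fit was exact
        pf_ds, ecm_ds = synth_maturation(published, noise=NoiseModel(mode="fixed_sd", sd=0.0))
        c = 3.0
        shifted = type(pf_ds)(
            "pf_percent", tuple((t, min(v + c, 100.0), s) for t, v, s in pf_ds.records)
        )
        assert all(v + c <= 100 for _, v, _ in pf_ds.records[:5])
        mp, _ = mse_pair(published, shifted, ecm_ds)
        assert mp == pytest.approx(c**2, rel=1e-6)

    def test_published_regression_pair(self, published, pf_data, ecm_data, published_mse):
        mp, me = mse_pair(published, pf_data, ecm_data)
        assert mp == pytest.approx(published_mse[0], rel=1e-5)
        assert me == pytest.approx(published_mse[1], rel=1e-5)

    def test_batch_evaluator_matches_adaptive(self, published, pf_data, ecm_data, published_mse):
        vals = np.array([[*published.params.as_tuple(), published.pf0, published.qf0]])
        y0 = np.array([[published.pf0, published.qf0, 0.0]])
        mp, me, ok = pareto._batch_objectives(vals, y0, pf_data, ecm_data, 10.5)
        assert ok[0]
        assert mp[0] == pytest.approx(published_mse[0], rel=1e-3)
        assert me[0] == pytest.approx(published_mse[1], rel=1e-3)


def brute_force_front(pairs):
    out = []
    for i, (a1, a2) in enumerate(pairs):
        dominated = any(
            (b1 <= a1 and b2 <= a2 and (b1 < a1 or b2 < a2)) for j, (b1, b2) in enumerate(pairs) if j != i
        )
        if not dominated:
            out.append(i)
    return sorted(out, key=lambda i: (pairs[i][0], pairs[i][1]))


class TestParetoFront:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(1, 1), (2, 2)], [(1, 1)]),
            ([(1, 2), (2, 1), (3, 3)], [(1, 2), (2, 1)]),
            ([], []),
        ],
    )
    def test_small_cases(self, pairs, expected):
        idx = pareto_front(pairs)
        assert [tuple(pairs[i]) for i in idx] == expected

    def test_matches_brute_force_oracle(self, rng):
        pairs = [tuple(p) for p in rng.uniform(0, 10, size=(200, 2))]
        assert set(pareto_front(pairs)) == set(brute_force_front(pairs))

    def test_duplicates_are_kept(self):
        pairs = [(1.0, 1.0), (1.0, 1.0), (2.0, 0.5)]
        assert set(pareto_front(pairs)) == {0, 1, 2}

    def test_monotone_under_extension(self, rng):
        # adding candidates never re-admits a dominated point
        pairs = [tuple(p) for p in rng.uniform(0, 10, size=(60, 2))]
        f1 = {tuple(pairs[i]) for i in pareto_front(pairs)}
        extra = pairs + [tuple(p) for p in rng.uniform(0, 10, size=(60, 2))]
        f2 = {tuple(extra[i]) for i in pareto_front(extra)}
        assert {p for p in f1 if p in f2} == f1 & f2


def _candidate(solution, mp, me):
    return ParetoCandidate(solution=solution, mse_pf=mp, mse_ecm=me, stable=True)


class TestSelection:
    def test_single_member(self, published):
        front = ParetoFront((_candidate(published, 1.0, 2.0),), 1, 1, 0)
        assert select_solution(front).mse_pf == 1.0

    def test_balanced_dominant_knee(self, published):
        members = tuple(
            _candidate(published, a, b) for a, b in [(0.0, 1.0), (1.0, 0.0), (0.1, 0.1)]
        )
        front = ParetoFront(members, 3, 3, 0)
        chosen = select_solution(front)
        assert (chosen.mse_pf, chosen.mse_ecm) == (0.1, 0.1)
        chosen = select_solution(front, policy="knee")
        assert (chosen.mse_pf, chosen.mse_ecm) == (0.1, 0.1)

    def test_permutation_invariance(self, published, rng):
        pairs = [(0.5, 3.0), (1.0, 1.2), (2.0, 0.4), (0.2, 5.0)]
        members = [
            _candidate(
                FitSolution(params=published.params, pf0=published.pf0 + 0.001 * i, qf0=published.qf0),
                a,
                b,
            )
            for i, (a, b) in enumerate(pairs)
        ]
        baseline = select_solution(ParetoFront(tuple(members), 4, 4, 0))
        for _ in range(5):
            perm = [members[i] for i in rng.permutation(4)]
            again = select_solution(ParetoFront(tuple(perm), 4, 4, 0))
            assert (again.mse_pf, again.mse_ecm) == (baseline.mse_pf, baseline.mse_ecm)

    def test_empty_front_errors(self):
        with pytest.raises(ValueError):
            select_solution(ParetoFront((), 0, 0, 0))


class TestFit:
    def test_zero_iterations_error(self, pf_data, ecm_data):
        with pytest.raises(ValueError):
            fit(pf_data, ecm_data, n_iter=0, seed=1)

    def test_collapsed_ranges_recover_published(self, published, pf_data, ecm_data, published_mse):
        res = fit(pf_data, ecm_data, n_iter=40, seed=3, ranges=collapsed_ranges(published))
        assert len(res.front.members) == 1
        sel = res.selected
        assert sel.solution.params == published.params
        assert sel.mse_pf == pytest.approx(published_mse[0], rel=1e-3)
        assert sel.mse_ecm == pytest.approx(published_mse[1], rel=1e-3)

    def test_reproducible_and_mutually_nondominated(self, pf_data, ecm_data):
        r1 = fit(pf_data, ecm_data, n_iter=3000, seed=11)
        r2 = fit(pf_data, ecm_data, n_iter=3000, seed=11)
        p1 = [(m.mse_pf, m.mse_ecm) for m in r1.front.members]
        p2 = [(m.mse_pf, m.mse_ecm) for m in r2.front.members]
        assert p1 == p2
        assert brute_force_front(p1) == list(range(len(p1)))
        assert all(m.stable for m in r1.front.members)

    def test_front_members_pass_stability_filter(self, pf_data, ecm_data):
        from dermadyn.maturation import is_stable

        res = fit(pf_data, ecm_data, n_iter=2000, seed=4)
        for m in res.front.members:
            assert is_stable(m.solution.params)[0]

    def test_bookkeeping(self, pf_data, ecm_data):
        res = fit(pf_data, ecm_data, n_iter=1500, seed=9)
        f = res.front
        assert f.n_sampled == 1500
        assert 0 < f.n_stable <= 1500
        assert f.seed == 9
        assert not f.is_empty
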