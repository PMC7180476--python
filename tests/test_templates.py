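"""Template-library construction: the five strategies and their helpers."""

import itertools

import numpy as np
import pytest
import scipy.stats

import gaitdtw as g
from gaitdtw.templates import resample_linear

from conftest import random_series


def make_collection(rng, lengths, prefix="s"):
    return g.StepCollection(
        steps=[random_series(rng, n) for n in lengths],
        ids=[f"{prefix}{i:02d}" for i in range(len(lengths))],
    )


class TestMedianLength:
    def test_odd_count(self, rng):
        assert g.median_length(make_collection(rng, [60, 63, 70])) == 63

    def test_even_count_lower_middle(self, rng):
        assert g.median_length(make_collection(rng, [60, 64])) == 60

    def test_matches_sort_recomputation_on_cohort(self, small_cohort):
        coll = g.merge_collections(
            [g.extract_steps(sig, anns) for sig, anns in small_cohort.trials]
        )
        lengths = sorted(len(s) for s in coll.steps)
        assert g.median_length(coll) == lengths[(len(lengths) - 1) // 2]


class TestRandomSelection:
    def test_full_collection(self, rng):
        coll = make_collection(rng, [10, 11, 12])
        lib = g.strategy_random(coll, n=3, seed=0)
        assert sorted(t.source for t in lib) == coll.ids

    def test_reproducible(self, rng):
        coll = make_collection(rng, [10] * 8 + [12] * 2)
        a = g.strategy_random(coll, n=3, seed=42)
        b = g.strategy_random(coll, n=3, seed=42)
        assert [t.source for t in a] == [t.source for t in b]

    def test_n_too_large(self, rng):
        with pytest.raises(g.ValidationError):
            g.strategy_random(make_collection(rng, [10, 10]), n=3, seed=0)

    def test_selection_uniformity(self, rng):
        coll = make_collection(rng, [10] * 10)
        counts = {sid: 0 for sid in coll.ids}
        for seed in range(2000):
            (t,) = g.strategy_random(coll, n=1, seed=seed).templates
            counts[t.source] += 1
        chi = scipy.stats.chisquare(list(counts.values()))
        assert chi.pvalue > 1e-3


class TestDtwMedoid:
    def test_singleton(self, rng):
        coll = make_collection(rng, [8])
        assert g.strategy_dtw_medoid(coll, None).source == coll.ids[0]

    def test_duplicate_pair_beats_outlier(self, rng):
        u = random_series(rng, 7)
        coll = g.StepCollection(steps=[u, 2.0 * u + 1.0, random_series(rng, 7)],
                                ids=["a", "b", "c"])
        # DTW(a, b) = 0 by affine invariance, so a (lowest id) is the medoid
        assert g.strategy_dtw_medoid(coll, None).source == "a"

    def test_matches_bruteforce_row_sums(self, rng):
        coll = make_collection(rng, [5, 6, 7, 8, 6, 7, 5, 8])
        sums = [
            sum(g.dtw_bruteforce(coll.steps[i], s, None) for s in coll.steps)
            for i in range(len(coll))
        ]
        expected = coll.ids[int(np.argmin(sums))]
        assert g.strategy_dtw_medoid(coll, None).source == expected

    def test_order_invariant(self, rng):
        coll = make_collection(rng, [6, 7, 8, 6, 7])
        perm = [3, 1, 4, 0, 2]
        shuffled = g.StepCollection(steps=[coll.steps[i] for i in perm],
                                    ids=[coll.ids[i] for i in perm])
        assert g.strategy_dtw_medoid(coll, None).source == g.strategy_dtw_medoid(shuffled, None).source

    def test_infeasible_pair_named(self, rng):
        coll = make_collection(rng, [5, 30])
        with pytest.raises(g.BandInfeasibleError, match="s0"):
            g.strategy_dtw_medoid(coll, maxsamp=3)


class TestLinearFusion:
    def test_identical_copies_return_znormed_step(self, rng):
        step = random_series(rng, 20)
        coll = g.StepCollection(steps=[step.copy() for _ in range(4)],
                                ids=list("abcd"))
        t = g.strategy_linear_fusion(coll)
        assert t.strategy == "S3"
        assert np.allclose(t.samples, g.znorm(step), atol=1e-12)

    def test_mirror_images_degenerate(self, rng):
        u = g.znorm(random_series(rng, 15))
        coll = g.StepCollection(steps=[u, -u], ids=["a", "b"])
        with pytest.raises(g.DegenerateSeriesError):
            g.strategy_linear_fusion(coll)

    def test_linear_ramp_resampling_closed_form(self):
        # resampling a ramp of length 10 to 5 keeps it a ramp: x_i = 9 i / 4
        out = resample_linear(np.arange(10.0), 5)
        assert np.allclose(out, [0.0, 2.25, 4.5, 6.75, 9.0], atol=1e-12)

    def test_output_has_median_length(self, rng):
        coll = make_collection(rng, [18, 20, 22, 24, 20])
        assert len(g.strategy_linear_fusion(coll)) == 20


def _enumerate_paths(zu, zv):
    """Test-local oracle: exhaustively enumerate unconstrained paths."""
    nu, nv = len(zu), len(zv)

    def walk(i, j, acc, cost):
        if (i, j) == (nu - 1, nv - 1):
            yield cost, acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < nu and nj < nv:
                yield from walk(ni, nj, acc + [(ni, nj)], cost + (zu[ni] - zv[nj]) ** 2)

    start_cost = (zu[0] - zv[0]) ** 2
    return list(walk(0, 0, [(0, 0)], start_cost))


class TestAlignToCalibration:
    def test_identity(self, rng):
        s = random_series(rng, 10)
        assert np.allclose(g.align_to_calibration(s, s, None), s, atol=1e-12)

    def test_band_zero_forces_diagonal(self, rng):
        s, c = random_series(rng, 3), random_series(rng, 3)
        assert np.allclose(g.align_to_calibration(s, c, 0), s, atol=1e-12)

    def test_one_to_many_averaging_matches_enumeration(self, rng):
        # with a 6-sample step on a 4-sample calibration, every path has at
        # least one calibration sample matched to several step samples
        checked = 0
        for _ in range(50):
            cal = random_series(rng, 4)
            step = random_series(rng, 6)
            paths = _enumerate_paths(g.znorm(cal), g.znorm(step))
            best = min(c for c, _ in paths)
            optimal = [p for c, p in paths if c <= best + 1e-12]
            if len(optimal) != 1:
                continue  # averaging is only pinned down for a unique optimum
            (path,) = optimal
            expected = np.array([
                np.mean([step[j] for i, j in path if i == k]) for k in range(4)
            ])
            got = g.align_to_calibration(step, cal, None)
            assert np.allclose(got, expected, atol=1e-9)
            assert max(sum(1 for i, _ in path if i == k) for k in range(4)) >= 2
            checked += 1
            if checked >= 5:
                break
        assert checked >= 5


class TestNonlinearFusion:
    def test_identical_copies(self, rng):
        step = random_series(rng, 12)
        coll = g.StepCollection(steps=[step.copy() for _ in range(3)], ids=list("abc"))
        t = g.strategy_nonlinear_fusion(coll, None)
        assert t.strategy == "S4"
        assert np.allclose(t.samples, g.znorm(step), atol=1e-12)

    def test_output_length_is_median(self, rng):
        coll = make_collection(rng, [10, 12, 14, 12, 16, 12])
        assert len(g.strategy_nonlinear_fusion(coll, None)) == 12

    def test_matches_scripted_recomputation(self, rng):
        coll = make_collection(rng, [6, 7, 7, 8, 7, 9])
        got = g.strategy_nonlinear_fusion(coll, maxsamp=5)

        # step-by-step independent recomputation
        normed = [(s - s.mean()) / s.std() for s in coll.steps]
        lengths = sorted(s.size for s in coll.steps)
        med = lengths[(len(lengths) - 1) // 2]
        cands = [i for i, s in enumerate(coll.steps) if s.size == med]
        means = [np.mean([g.dtw_distance(normed[i], t, 5) for t in normed]) for i in cands]
        cal = normed[cands[int(np.argmin(means))]]
        aligned = []
        for s in normed:
            res = g.dtw(cal, s, 5)
            out = np.zeros(med)
            cnt = np.zeros(med)
            for i, j in res.path.pairs:
                out[i] += s[j]
                cnt[i] += 1
            aligned.append(out / cnt)
        expected = np.mean(aligned, axis=0)
        assert len(got) == med
        assert np.allclose(got.samples, expected, atol=1e-10)


class TestPiecewise:
    def test_central_plateau_value(self, s5_template):
        assert g.piecewise_step_function(30.0) == pytest.approx(0.8, abs=1e-12)
        xs = np.arange(16, 45)
        assert all(g.piecewise_step_function(float(x)) == pytest.approx(0.8, abs=1e-12) for x in xs)

    def test_default_length(self, s5_template):
        assert len(s5_template) == 63
        assert s5_template.samples[29] == pytest.approx(0.8)

    def test_breakpoint_continuity(self):
        branches = [(1, 3, 0.3, -0.7), (3, 5, -0.8, 2.6), (5, 16, 0.2, -2.4),
                    (16, 44, 0.0, 0.8), (44, 54, -0.34, 15.76), (54, 63, 0.2, -13.4)]
        for (l0, h0, a0, b0), (l1, h1, a1, b1) in itertools.pairwise(branches):
            x = h0
            assert a0 * x + b0 == pytest.approx(a1 * x + b1, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(g.ValidationError):
            g.strategy_piecewise(5)

    def test_rescaled_abscissa_keeps_endpoints(self):
        t = g.strategy_piecewise(32)
        assert len(t) == 32
        assert t.samples[0] == pytest.approx(g.piecewise_step_function(1.0))
        assert t.samples[-1] == pytest.approx(g.piecewise_step_function(63.0))
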