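import numpy as np
import pytest

from treesweep import (
    SelectionModel,
    TreeHMM,
    bayes_trajectory,
    empirical_threshold,
    likelihood_ratio_surface,
    logLR_test,
    mle,
    posterior_trajectory,
    soft_vs_hard_statistic,
)
from treesweep.inference import LikelihoodSurface

from conftest import SEED, make_toy_replicate


@pytest.fixture(scope="module")
def toy_hmms(cache):
    hmms = []
    for k in range(3):
        rng = np.random.default_rng([SEED, 900 + k])
        rep, cond = make_toy_replicate(rng, d=20, K=8, n_der=5, n_anc=3, N=800.0)
        hmms.append(TreeHMM(rep.counts, cond.demography, cond.fg, cache))
    return hmms


S_GRID = np.array([0.0, 0.001, 0.01, 0.05, 0.2])


class TestSurface:
    def test_neutral_point_is_exactly_zero(self, toy_hmms):
        surf = likelihood_ratio_surface(toy_hmms, S_GRID)
        assert surf.loglr[0] == 0.0

    def test_single_tree_reduces_to_its_weight(self, toy_hmms):
        h = toy_hmms[0]
        surf = likelihood_ratio_surface([h], S_GRID)
        for s, lr in zip(surf.s_values, surf.loglr):
            assert lr == pytest.approx(h.log_weight(SelectionModel(s)), abs=1e-12)

    def test_ess_bounds(self, toy_hmms):
        surf = likelihood_ratio_surface(toy_hmms, S_GRID)
        finite = np.isfinite(surf.loglr)
        assert np.all(surf.ess[finite] >= 1.0 - 1e-9)
        assert np.all(surf.ess[finite] <= len(toy_hmms) + 1e-9)
        assert surf.ess[0] == pytest.approx(len(toy_hmms))

    def test_requires_neutral_point_and_range(self, toy_hmms):
        with pytest.raises(ValueError, match="include the neutral"):
            likelihood_ratio_surface(toy_hmms, [0.01, 0.05])
        with pytest.raises(ValueError, match="0, 0.5"):
            likelihood_ratio_surface(toy_hmms, [0.0, 0.7])
        with pytest.raises(ValueError, match="at least one"):
            likelihood_ratio_surface([], S_GRID)

    def test_two_dimensional_nesting(self, toy_hmms):
        surf = likelihood_ratio_surface(
            toy_hmms, S_GRID[:4], ts_grid=[100.0, 1000.0, np.inf]
        )
        assert surf.loglr.max() >= surf.hard_sweep_max() - 1e-12
        assert soft_vs_hard_statistic(surf) >= 0.0


class TestMle:
    def test_monotone_decreasing_surface_returns_null(self):
        surf = LikelihoodSurface(
            np.array([0.0, 0.01, 0.1]), np.array([0.0, -3.0, -9.0]), np.ones(3)
        )
        s_hat, _, best = mle(surf)
        assert s_hat == 0.0 and best == 0.0

    def test_ties_break_toward_smaller_s(self):
        surf = LikelihoodSurface(
            np.array([0.0, 0.01, 0.1]), np.array([0.0, 5.0, 5.0]), np.ones(3)
        )
        s_hat, _, _ = mle(surf)
        assert s_hat == 0.01

    def test_golden_refinement_finds_interior_peak(self):
        # synthetic smooth surface peaked at s* = 0.027, off the grid
        peak = 0.027
        f = lambda s: -((np.log(s + 1e-4) - np.log(peak)) ** 2)
        grid = np.array([0.0, 0.001, 0.01, 0.05, 0.2])
        surf = LikelihoodSurface(grid, f(grid) - f(0.0), np.ones(grid.size))
        s_hat, _, best = mle(surf, evaluator=lambda s: f(s) - f(0.0))
        assert abs(s_hat - peak) / peak < 0.1
        assert best >= surf.loglr.max()

    def test_two_dimensional_grid_argmax(self):
        lr = np.array([[0.0, 0.0], [1.0, 4.0], [2.0, 1.0]])
        surf = LikelihoodSurface(
            np.array([0.0, 0.01, 0.1]), lr, np.ones_like(lr),
            ts_values=np.array([100.0, np.inf]),
        )
        s_hat, ts_hat, best = mle(surf)
        assert (s_hat, ts_hat, best) == (0.01, np.inf, 4.0)


class TestSoftVsHard:
    def test_degenerate_grid_is_zero(self, toy_hmms):
        surf = likelihood_ratio_surface(toy_hmms[:1], [0.0], ts_grid=[np.inf])
        assert soft_vs_hard_statistic(surf) == 0.0

    def test_missing_hard_limit_rejected(self, toy_hmms):
        surf = likelihood_ratio_surface(toy_hmms[:1], S_GRID[:2], ts_grid=[100.0])
        with pytest.raises(ValueError, match="hard-sweep limit"):
            surf.hard_sweep_max()


class TestTrajectories:
    def test_single_tree_neutral_matches_raw_posterior(self, toy_hmms):
        h = toy_hmms[0]
        traj = posterior_trajectory([h], SelectionModel.neutral())
        assert np.allclose(traj.distribution, h.posterior(SelectionModel.neutral()))

    def test_present_epoch_mean_near_sample_frequency(self, cache):
        # with an informative sample (40 lineages) the epoch-0 posterior mean
        # must track the sample frequency
        rng = np.random.default_rng([SEED, 940])
        rep, cond = make_toy_replicate(rng, d=40, K=10, n_der=25, n_anc=15,
                                       N=2000.0)
        h = TreeHMM(rep.counts, cond.demography, cond.fg, cache)
        traj = posterior_trajectory([h], SelectionModel.neutral())
        assert abs(traj.mean[0] - 25 / 40) < 0.08

    def test_distributions_normalized_and_band_ordered(self, toy_hmms):
        traj = posterior_trajectory(toy_hmms, SelectionModel(0.01))
        assert np.allclose(traj.distribution.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(traj.quantiles[0.25] <= traj.quantiles[0.75])
        assert np.all((traj.mean >= 0) & (traj.mean <= 1))

    def test_bayes_average_close_to_mle_fix_when_peaked(self, toy_hmms, cache):
        # a strongly selected replicate: the surface peaks sharply enough
        # that averaging over s barely differs from fixing the MLE
        rng = np.random.default_rng([SEED, 950])
        rep, cond = make_toy_replicate(rng, d=30, K=12, n_der=12, n_anc=4,
                                       N=2000.0, s=0.05)
        h = TreeHMM(rep.counts, cond.demography, cond.fg, cache)
        grid = np.concatenate([[0.0], np.geomspace(1e-3, 0.3, 9)])
        surf = likelihood_ratio_surface([h], grid)
        s_hat, _, _ = mle(surf)
        fixed = posterior_trajectory([h], SelectionModel(s_hat))
        avg = bayes_trajectory([h], grid)
        assert np.max(np.abs(fixed.mean - avg.mean)) < 0.1

    def test_bayes_flat_surface_is_unweighted_average(self, cache):
        # two s values with identical likelihoods: weights follow the
        # trapezoid rule only
        rng = np.random.default_rng([SEED, 960])
        rep, cond = make_toy_replicate(rng, d=12, K=6)
        h = TreeHMM(rep.counts, cond.demography, cond.fg, cache)
        traj = bayes_trajectory([h], [0.0, 1e-7])  # s ~ 0 twice: flat
        ref = posterior_trajectory([h], SelectionModel.neutral())
        assert np.allclose(traj.distribution, ref.distribution, atol=1e-6)


class TestSignificance:
    def test_zero_loglr_never_rejects(self):
        thr = empirical_threshold(np.zeros(100), 0.01)
        assert not logLR_test(0.0, thr)

    def test_threshold_is_upper_quantile(self):
        null = np.arange(100, dtype=float)
        thr = empirical_threshold(null, 0.01)
        assert thr == 99.0
        assert logLR_test(99.5, thr)
        assert not logLR_test(98.0, thr)
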