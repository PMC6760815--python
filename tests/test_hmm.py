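import math

import numpy as np
import pytest

from treesweep import (
    DemographicModel,
    FrequencyGrid,
    SelectionModel,
    TimeGrid,
    TransitionCache,
    TreeHMM,
)
from treesweep.freq import TransitionSet, present_day_init
from treesweep.hmm import (
    LikelihoodZeroError,
    backward_recursion,
    emission_log_matrix,
    forward_recursion,
    posterior_marginals,
    tree_loglik,
)
from treesweep.lod import lod_exact

from conftest import SEED, enumerate_joint, make_toy_replicate


def toy_components(rep, cond, s=0.0):
    tset = TransitionSet(cond.fg, cond.demography.grid, cond.demography,
                         SelectionModel(s))
    E = emission_log_matrix(rep.counts, cond.demography, cond.fg)
    init = present_day_init(cond.n_der, cond.n_der + cond.n_anc, cond.fg)
    return E, tset, init


class TestEmissions:
    def test_absent_state_impossible_with_multiple_derived_lineages(self):
        rng = np.random.default_rng(SEED)
        rep, cond = make_toy_replicate(rng, n_der=4, n_anc=2)
        E = emission_log_matrix(rep.counts, cond.demography, cond.fg)
        multi = np.nonzero(rep.counts.c_der[:-1] > 1)[0]
        assert np.all(E[multi, 0] == -np.inf)

    def test_no_event_short_epoch_has_probability_near_one(self):
        grid = TimeGrid((0.0, 1.0, 1e6))
        demog = DemographicModel.constant(1e4, grid)
        fg = FrequencyGrid.default(6)
        from treesweep.genealogy import CountSeries

        cs = CountSeries(grid, [2, 2, 1], [2, 2, 1], [3, 3, 1], n_der=2, n_anc=2)
        E = emission_log_matrix(cs, demog, fg)
        j = fg.nearest_bin(0.5)
        assert E[0, j] == pytest.approx(0.0, abs=1e-3)

    def test_two_lineage_coalescence_closed_form(self):
        # derived pair coalescing within the epoch at x=0.5: log(1 - e^{-dtau})
        grid = TimeGrid((0.0, 5000.0, 1e6))
        demog = DemographicModel.constant(1e4, grid)
        fg = FrequencyGrid.default(6)
        from treesweep.genealogy import CountSeries

        cs = CountSeries(grid, [2, 1, 1], [1, 1, 1], [2, 2, 1], n_der=2, n_anc=1)
        E = emission_log_matrix(cs, demog, fg)
        j = fg.nearest_bin(0.5)
        x = fg.x[j]
        expect = math.log(-math.expm1(-5000.0 / (2 * 1e4 * x)))
        assert E[0, j] == pytest.approx(expect, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        grid = TimeGrid((0.0, 10.0, 1e6))
        demog = DemographicModel.constant(1e4, grid)
        fg = FrequencyGrid.default(6)
        from treesweep.genealogy import CountSeries

        cs = CountSeries(grid, [2, 3, 1], [1, 1, 1], [2, 2, 1], n_der=2, n_anc=1)
        with pytest.raises(ValueError, match="increase"):
            emission_log_matrix(cs, demog, fg)


class TestRecursionsAgainstEnumeration:
    """The forward/backward recursions must equal the explicit trajectory sum."""

    @pytest.mark.parametrize("case", range(6))
    def test_loglik_and_posterior_match_brute_force(self, case):
        rng = np.random.default_rng([SEED, case])
        d = int(rng.integers(4, 7))
        K = int(rng.integers(3, 5))
        rep, cond = make_toy_replicate(rng, d=d, K=K,
                                       n_der=int(rng.integers(2, 4)),
                                       n_anc=int(rng.integers(2, 4)))
        s_eval = float(rng.choice([0.0, 0.005, 0.05]))
        E, tset, init = toy_components(rep, cond, s_eval)
        total, marg = enumerate_joint(E, tset.matrices, init)
        ll = tree_loglik(rep.counts, tset, init, E)
        assert ll == pytest.approx(math.log(total), rel=1e-10)
        post = posterior_marginals(rep.counts, tset, init, E)
        expect = marg / total
        assert np.allclose(post, expect, atol=1e-10)

    def test_forward_backward_consistency_at_every_epoch(self):
        rng = np.random.default_rng([SEED, 77])
        rep, cond = make_toy_replicate(rng)
        E, tset, init = toy_components(rep, cond, 0.01)
        b = backward_recursion(E, tset)
        f = forward_recursion(E, tset, init)
        from scipy.special import logsumexp

        per_epoch = [logsumexp(f[i] + b[i]) for i in range(E.shape[0])]
        assert np.allclose(per_epoch, per_epoch[0], rtol=1e-10)

    def test_forward_starts_from_initialization(self):
        rng = np.random.default_rng([SEED, 78])
        rep, cond = make_toy_replicate(rng)
        E, tset, init = toy_components(rep, cond)
        f = forward_recursion(E, tset, init)
        with np.errstate(divide="ignore"):
            assert np.allclose(f[0], np.log(init), equal_nan=False)

    def test_posterior_rows_normalized_and_absorbed_at_depth(self):
        rng = np.random.default_rng([SEED, 79])
        rep, cond = make_toy_replicate(rng)
        E, tset, init = toy_components(rep, cond)
        post = posterior_marginals(rep.counts, tset, init, E)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert post[-1, 0] == pytest.approx(1.0)  # origination certain by t_K


class TestTreeLoglik:
    def test_two_epoch_model_is_explicit_weighted_sum(self):
        # smallest non-degenerate model: segregate in epoch 0, originate by
        # epoch 1; the likelihood is a single hand-writable sum
        grid = TimeGrid((0.0, 500.0, 60000.0))
        demog = DemographicModel.constant(300.0, grid)
        fg = FrequencyGrid.default(5)
        from treesweep.genealogy import CountSeries

        cs = CountSeries(grid, [1, 1, 1], [1, 1, 1], [2, 2, 1], n_der=1, n_anc=1)
        tset = TransitionSet(fg, grid, demog, SelectionModel.neutral())
        E = emission_log_matrix(cs, demog, fg)
        init = present_day_init(1, 2, fg)
        expect = sum(
            init[x] * math.exp(E[0, x]) * tset[0][x, 0] * math.exp(E[1, 0])
            for x in range(1, fg.d)
        )
        ll = tree_loglik(cs, tset, init, E)
        assert ll == pytest.approx(math.log(expect), rel=1e-12)

    def test_zero_likelihood_raises_with_epoch_context(self):
        grid = TimeGrid((0.0, 10.0, 1e6))
        demog = DemographicModel.constant(1e4, grid)
        fg = FrequencyGrid.default(6)
        from treesweep.genealogy import CountSeries

        # full coalescence of 3 mixed lineages is required instantly while
        # 2 derived lineages still exist: impossible in every state
        cs = CountSeries(grid, [2, 1, 1], [1, 1, 1], [3, 2, 1], n_der=2, n_anc=1)
        E = emission_log_matrix(cs, demog, fg)
        E[:, 1:] = -np.inf  # knock out segregating states
        tset = TransitionSet(fg, grid, demog, SelectionModel.neutral())
        with pytest.raises(LikelihoodZeroError, match="epoch"):
            backward_recursion(E, tset)

    def test_rapid_derived_coalescence_favors_selection(self, cache):
        # counts simulated under strong selection: the likelihood at a
        # moderate s must beat neutrality in most replicates
        wins = 0
        n = 12
        for k in range(n):
            rng = np.random.default_rng([SEED, 200 + k])
            rep, cond = make_toy_replicate(rng, d=40, K=14, n_der=10, n_anc=6,
                                           N=2000.0, s=0.05)
            hmm = TreeHMM(rep.counts, cond.demography, cond.fg, cache)
            if hmm.loglik(SelectionModel(0.02)) > hmm.loglik(SelectionModel(0.0)):
                wins += 1
        assert wins > n / 2

    def test_epoch_specific_sizes_matter(self, cache):
        # permuting per-epoch population sizes must change the likelihood:
        # the model is genuinely time-inhomogeneous
        rng = np.random.default_rng([SEED, 300])
        rep, cond = make_toy_replicate(rng, d=8, K=4)
        grid = cond.demography.grid
        sizes = np.array([200.0, 900.0, 400.0, 2500.0])
        d1 = DemographicModel(grid, tuple(sizes))
        d2 = DemographicModel(grid, tuple(sizes[::-1]))
        fg = cond.fg
        h1 = TreeHMM(rep.counts, d1, fg, cache)
        h2 = TreeHMM(rep.counts, d2, fg, cache)
        assert h1.loglik(SelectionModel.neutral()) != pytest.approx(
            h2.loglik(SelectionModel.neutral()), abs=1e-6
        )

    def test_log_likelihood_ratio_at_neutral_is_exactly_zero(self, cache):
        rng = np.random.default_rng([SEED, 400])
        rep, cond = make_toy_replicate(rng)
        hmm = TreeHMM(rep.counts, cond.demography, cond.fg, cache)
        assert hmm.log_weight(SelectionModel.neutral()) == 0.0

    def test_refinement_stability(self, cache):
        # splitting an event-free epoch perturbs the likelihood only mildly
        rng = np.random.default_rng([SEED, 500])
        rep, cond = make_toy_replicate(rng, d=30, K=10, N=1000.0)
        grid = cond.demography.grid
        from treesweep.genealogy import extract_counts

        ll = TreeHMM(rep.counts, cond.demography, cond.fg, cache).loglik(
            SelectionModel.neutral()
        )
        mid = 0.5 * (grid.times[-2] + grid.times[-1])
        fine = grid.refine_with([mid])
        demog2 = DemographicModel.from_epochs(
            grid.times[:-1], cond.demography.sizes, fine
        )
        counts2 = extract_counts(rep.genealogy, fine)
        ll2 = TreeHMM(counts2, demog2, cond.fg, cache).loglik(SelectionModel.neutral())
        assert ll2 == pytest.approx(ll, abs=0.05)
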