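"""Likelihood-ratio surfaces, MLEs, and trajectory estimates from sampled trees.

Genealogies sampled from the posterior under neutrality are reweighted to
estimate the likelihood ratio at arbitrary selection parameters:

    LR(s) ~= (1/M) sum_m Omega_m(s),   Omega_m(s) = P(C_m | s) / P(C_m | 0)

so a single set of trees yields the whole surface.  The same self-normalized
weights turn per-tree posterior marginals of the hidden frequency into a
trajectory estimate.  Significance is always assessed against a matched
empirical null (same demography, sample size, and present-day frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import SelectionModel
from .hmm import TreeHMM

__all__ = [
    "LikelihoodSurface",
    "PosteriorTrajectory",
    "likelihood_ratio_surface",
    "mle",
    "soft_vs_hard_statistic",
    "posterior_trajectory",
    "bayes_trajectory",
    "empirical_threshold",
    "logLR_test",
]

_INF = float("inf")


@dataclass
class LikelihoodSurface:
    """log LR over an s grid (1-D) or an (s, t_s) grid (2-D), with per-point ESS."""

    s_values: np.ndarray
    loglr: np.ndarray
    ess: np.ndarray
    ts_values: np.ndarray | None = None
    n_trees: int = 0

    @property
    def is_2d(self) -> bool:
        return self.ts_values is not None

    def argmax(self):
        """Grid argmax with ties broken toward smaller s, then smaller t_s."""
        if not self.is_2d:
            j = int(np.flatnonzero(self.loglr >= self.loglr.max() - 1e-12)[0])
            return j, float(self.s_values[j]), float(self.loglr[j])
        flat = np.argwhere(self.loglr >= self.loglr.max() - 1e-12)
        # rows ordered by (s index, ts index); smallest wins
        i, j = (int(v) for v in flat[0])
        return (i, j), (float(self.s_values[i]), float(self.ts_values[j])), float(
            self.loglr[i, j]
        )

    def hard_sweep_max(self) -> float:
        """Maximum over the hard-sweep slice (t_s = inf) of a 2-D surface."""
        if not self.is_2d:
            return float(self.loglr.max())
        cols = np.isinf(self.ts_values)
        if not np.any(cols):
            raise ValueError("t_s grid does not include the hard-sweep limit (inf)")
        return float(self.loglr[:, cols].max())


def _surface_point(hmms, model: SelectionModel):
    logw = np.array([h.log_weight(model) for h in hmms])
    M = len(logw)
    lse = logsumexp(logw)
    if not np.isfinite(lse):
        return -np.inf, 0.0
    loglr = float(lse - math.log(M))
    ess = float(np.exp(2.0 * lse - logsumexp(2.0 * logw)))
    return loglr, ess


def likelihood_ratio_surface(
    hmms: list, s_grid, ts_grid=None
) -> LikelihoodSurface:
    """Importance-sampling estimate of the likelihood-ratio surface.

    ``hmms`` are the per-tree HMMs (trees sampled under the neutral posterior,
    or true trees).  With ``ts_grid`` the selection model is the SSV step
    function and the surface is two-dimensional.
    """
    if not hmms:
        raise ValueError("need at least one genealogy")
    s_grid = np.asarray(sorted(set(float(s) for s in s_grid)))
    if np.any((s_grid < 0) | (s_grid > 0.5)):
        raise ValueError("selection coefficients must lie in [0, 0.5]")
    if 0.0 not in s_grid:
        raise ValueError("the s grid must include the neutral point 0")
    if ts_grid is None:
        loglr = np.empty(s_grid.size)
        ess = np.empty(s_grid.size)
        for j, s in enumerate(s_grid):
            loglr[j], ess[j] = _surface_point(hmms, SelectionModel(s))
        return LikelihoodSurface(s_grid, loglr, ess, None, len(hmms))
    ts_grid = np.asarray(sorted(set(float(t) for t in ts_grid)))
    loglr = np.empty((s_grid.size, ts_grid.size))
    ess = np.empty_like(loglr)
    for i, s in enumerate(s_grid):
        for j, ts in enumerate(ts_grid):
            model = SelectionModel(s, ts) if s > 0 else SelectionModel(0.0)
            loglr[i, j], ess[i, j] = _surface_point(hmms, model)
    return LikelihoodSurface(s_grid, loglr, ess, ts_grid, len(hmms))


def _golden_refine(evaluator, lo, hi, f_best, s_best, max_iter=16, rel_tol=0.02):
    """Golden-section maximization of the log-LR over the bracket [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = evaluator(c), evaluator(d)
    for _ in range(max_iter):
        if (b - a) <= rel_tol * max(abs(a), abs(b), 1e-6):
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = evaluator(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = evaluator(d)
    for s, f in ((c, fc), (d, fd)):
        if f > f_best or (f == f_best and s < s_best):
            f_best, s_best = f, s
    return s_best, f_best


def mle(surface: LikelihoodSurface, evaluator=None):
    """Maximum-likelihood selection parameters from the surface.

    1-D surfaces are refined by golden-section search between the grid
    neighbours of the argmax when an ``evaluator`` (callable s -> log LR) is
    supplied; 2-D surfaces return the grid argmax.  Ties break toward the
    null (smaller s, then smaller t_s).
    """
    if surface.is_2d:
        _, (s_hat, ts_hat), best = surface.argmax()
        return s_hat, ts_hat, best
    j, s_hat, best = surface.argmax()
    if evaluator is not None and best > surface.loglr[0]:
        lo = surface.s_values[max(j - 1, 0)]
        hi = surface.s_values[min(j + 1, surface.s_values.size - 1)]
        if hi > lo:
            s_hat, best = _golden_refine(evaluator, lo, hi, best, s_hat)
    return s_hat, None, best


def soft_vs_hard_statistic(surface: LikelihoodSurface) -> float:
    """log max over all (s, t_s) minus log max over hard sweeps (t_s = inf).

    Non-negative whenever the hard-sweep slice is nested in the search grid;
    large values indicate a recent change in the strength of selection (a
    sweep from standing variation) fits the genealogy better than any
    constant-s model.
    """
    if not surface.is_2d:
        raise ValueError("soft-vs-hard statistic needs a 2-D (s, t_s) surface")
    return float(surface.loglr.max() - surface.hard_sweep_max())


@dataclass
class PosteriorTrajectory:
    """Per-epoch posterior of the allele frequency, with mean and quantile bands."""

    epoch_starts: np.ndarray
    epoch_ends: np.ndarray
    bin_values: np.ndarray
    distribution: np.ndarray  # (K, d)
    mean: np.ndarray
    quantiles: dict

    def to_tsv(self, fh) -> None:
        qkeys = sorted(self.quantiles)
        fh.write("epoch_start_gen\tepoch_end_gen\tpost_mean\t"
                 + "\t".join(f"q{int(100 * q)}" for q in qkeys) + "\n")
        for i in range(self.mean.size):
            row = [f"{self.epoch_starts[i]:.10g}", f"{self.epoch_ends[i]:.10g}",
                   f"{self.mean[i]:.6g}"]
            row += [f"{self.quantiles[q][i]:.6g}" for q in qkeys]
            fh.write("\t".join(row) + "\n")


def _pmf_quantile(pmf: np.ndarray, values: np.ndarray, q: float) -> float:
    cdf = np.cumsum(pmf)
    idx = int(np.searchsorted(cdf, q, side="left"))
    return float(values[min(idx, values.size - 1)])


def _mixture_to_trajectory(mix, hmm0, quantiles) -> PosteriorTrajectory:
    grid = hmm0.counts.grid
    x = hmm0.fg.x
    mean = mix @ x
    qs = {q: np.array([_pmf_quantile(mix[i], x, q) for i in range(mix.shape[0])])
          for q in quantiles}
    return PosteriorTrajectory(
        epoch_starts=grid.times[:-1],
        epoch_ends=grid.times[1:],
        bin_values=x,
        distribution=mix,
        mean=mean,
        quantiles=qs,
    )


def posterior_trajectory(
    hmms: list, model: SelectionModel, quantiles=(0.25, 0.75)
) -> PosteriorTrajectory:
    """Importance-weighted mixture of per-tree posterior marginals of X_i.

    In practice the model is fixed at the MLE; the mixture weights are the
    self-normalized importance weights Omega_m(model).
    """
    logw = np.array([h.log_weight(model) for h in hmms])
    if not np.any(np.isfinite(logw)):
        raise ValueError("all importance weights are zero under this model")
    w = np.exp(logw - logsumexp(logw))
    mix = sum(wi * h.posterior(model) for wi, h in zip(w, hmms))
    return _mixture_to_trajectory(mix, hmms[0], quantiles)


def bayes_trajectory(
    hmms: list, s_grid, quantiles=(0.25, 0.75)
) -> PosteriorTrajectory:
    """Trajectory averaged over s with a uniform prior (trapezoid weights).

    The posterior over s on the grid is proportional to LR(s) times the
    trapezoid integration weight; each s contributes its importance-weighted
    posterior mixture.
    """
    s_grid = np.asarray(sorted(set(float(s) for s in s_grid)))
    surf = likelihood_ratio_surface(hmms, s_grid)
    if s_grid.size > 1:
        trap = np.zeros(s_grid.size)
        trap[:-1] += 0.5 * np.diff(s_grid)
        trap[1:] += 0.5 * np.diff(s_grid)
    else:
        trap = np.ones(1)
    logwt = surf.loglr + np.log(trap)
    wt = np.exp(logwt - logsumexp(logwt))
    mix = None
    for w_s, s in zip(wt, s_grid):
        traj = posterior_trajectory(hmms, SelectionModel(s), quantiles)
        mix = w_s * traj.distribution if mix is None else mix + w_s * traj.distribution
    return _mixture_to_trajectory(mix, hmms[0], quantiles)


def empirical_threshold(null_stats, level: float = 0.01) -> float:
    """Significance cutoff: the (1 - level) quantile of matched null statistics."""
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("no null replicates available for calibration")
    return float(np.quantile(null_stats, 1.0 - level, method="higher"))


def logLR_test(loglr: float, threshold: float) -> bool:
    """Reject neutrality iff the observed max log LR exceeds the empirical cutoff."""
    return bool(loglr > threshold)
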