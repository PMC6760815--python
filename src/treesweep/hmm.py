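"""The coalescent HMM: emissions, recursions, tree likelihood, posteriors.

Hidden states are the allele frequencies ``X_0 .. X_{K-1}`` (one per epoch,
``X_i`` in force over ``(t_i, t_{i+1}]``), observed states are the lineage
counts at the epoch boundaries.  While the derived allele exists (``X_i > 0``)
the derived and ancestral classes coalesce independently given ``X_i``; once
it does not (``X_i = 0``, only reachable after the mutation going backward)
the mixed process takes over.  The emission therefore couples the mutation to
the counts: the absent state is impossible unless the derived class has
already collapsed to its single root lineage.

The chain is anchored at the present by the sample-frequency initialization
and terminated by the requirement that the allele has originated (X = 0) by
the final epoch; with the recommended horizon of ~100 x 2N generations that
terminal constraint is essentially free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import DemographicModel, FrequencyGrid, SelectionModel
from .freq import TransitionCache, TransitionSet, present_day_init
from .genealogy import CountSeries
from .lod import DEFAULT_POLICY, LodPolicy, lod_logpmf

__all__ = [
    "LikelihoodZeroError",
    "emission_log_matrix",
    "backward_recursion",
    "forward_recursion",
    "tree_loglik",
    "posterior_marginals",
    "TreeHMM",
]


class LikelihoodZeroError(ValueError):
    """Every frequency state has zero probability at some epoch."""


def emission_log_matrix(
    counts: CountSeries,
    demography: DemographicModel,
    fg: FrequencyGrid,
    policy: LodPolicy = DEFAULT_POLICY,
) -> np.ndarray:
    """(K, d) matrix of log P(C_{i+1} | C_i, X_i = x, N_i).

    For ``x > 0``: independent lines-of-descent transitions of the derived
    class (size ``N x``) and the ancestral class (size ``N (1 - x)``).  For
    ``x = 0``: the mixed process (size ``N``), permitted only when the derived
    class is already down to its single root lineage (the mutation can occur
    only on one surviving lineage).  Ancient leaves entering during an epoch
    are added to that epoch's start count.
    """
    grid = counts.grid
    K = grid.K
    E = np.full((K, fg.d), -np.inf)
    x_int = fg.x[1:]
    N = demography.sizes
    dts = grid.durations
    for i in range(K):
        dt = dts[i]
        a_der = int(counts.c_der[i] + counts.entrants_der[i])
        a_anc = int(counts.c_anc[i] + counts.entrants_anc[i])
        b_der = int(counts.c_der[i + 1])
        b_anc = int(counts.c_anc[i + 1])
        if b_der > a_der or b_anc > a_anc:
            raise ValueError(
                f"lineage counts increase across epoch {i} without an ancient sample"
            )
        ld = lod_logpmf(a_der, b_der, dt, N[i] * x_int, policy)
        la = lod_logpmf(a_anc, b_anc, dt, N[i] * (1.0 - x_int), policy)
        E[i, 1:] = ld + la
        if counts.c_der[i] == 1:
            a_mix = int(counts.c_mix[i] + counts.entrants_der[i] + counts.entrants_anc[i])
            b_mix = int(counts.c_mix[i + 1])
            if b_mix <= a_mix:
                E[i, 0] = lod_logpmf(a_mix, b_mix, dt, np.array([N[i]]), policy)[0]
    return E


def _check_epoch(v: np.ndarray, i: int, what: str) -> None:
    if not np.any(np.isfinite(v)):
        raise LikelihoodZeroError(
            f"likelihood is zero under this model: no admissible frequency state "
            f"in epoch {i} ({what} recursion)"
        )


def backward_recursion(E: np.ndarray, tset: TransitionSet) -> np.ndarray:
    """Log-domain tables b_i(x) = P(C_{i+1:K}, origination by t_K | X_i = x)."""
    K, d = E.shape
    b = np.full((K, d), -np.inf)
    b[K - 1, 0] = E[K - 1, 0]
    _check_epoch(b[K - 1], K - 1, "backward")
    for i in range(K - 2, -1, -1):
        m = np.max(b[i + 1])
        with np.errstate(divide="ignore"):
            w = tset[i] @ np.exp(b[i + 1] - m)
            b[i] = E[i] + np.log(w) + m
        _check_epoch(b[i], i, "backward")
    return b


def forward_recursion(E: np.ndarray, tset: TransitionSet, init: np.ndarray) -> np.ndarray:
    """Log-domain tables f_i(x) = P(C_{1:i}, X_i = x), f_0 = the initialization."""
    K, d = E.shape
    f = np.full((K, d), -np.inf)
    with np.errstate(divide="ignore"):
        f[0] = np.log(init)
    _check_epoch(f[0], 0, "forward")
    for i in range(K - 1):
        v = f[i] + E[i]
        m = np.max(v)
        if not np.isfinite(m):
            raise LikelihoodZeroError(
                f"likelihood is zero under this model: epoch {i} emits no mass"
            )
        with np.errstate(divide="ignore"):
            w = np.exp(v - m) @ tset[i]
            f[i + 1] = np.log(w) + m
        _check_epoch(f[i + 1], i + 1, "forward")
    return f


def tree_loglik(
    counts: CountSeries,
    tset: TransitionSet,
    init: np.ndarray,
    E: np.ndarray | None = None,
    policy: LodPolicy = DEFAULT_POLICY,
) -> float:
    """log P(C | selection model) by marginalizing the hidden trajectory."""
    if E is None:
        E = emission_log_matrix(counts, tset.demography, tset.fg, policy)
    b = backward_recursion(E, tset)
    with np.errstate(divide="ignore"):
        return float(logsumexp(np.log(init) + b[0]))


def posterior_marginals(
    counts: CountSeries,
    tset: TransitionSet,
    init: np.ndarray,
    E: np.ndarray | None = None,
    policy: LodPolicy = DEFAULT_POLICY,
) -> np.ndarray:
    """(K, d) posterior P(X_i = x | C, model) via the forward-backward identity."""
    if E is None:
        E = emission_log_matrix(counts, tset.demography, tset.fg, policy)
    b = backward_recursion(E, tset)
    f = forward_recursion(E, tset, init)
    post = f + b
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


@dataclass
class TreeHMM:
    """One genealogy's HMM with cached emissions, evaluable at any selection model.

    The emission matrix does not depend on the selection model (selection only
    enters the trajectory prior), so it is computed once per tree; transition
    sets are shared across trees through a :class:`TransitionCache`.
    """

    counts: CountSeries
    demography: DemographicModel
    fg: FrequencyGrid
    cache: TransitionCache
    policy: LodPolicy = DEFAULT_POLICY
    reference: str = "sojourn"

    def __post_init__(self):
        self.E = emission_log_matrix(self.counts, self.demography, self.fg, self.policy)
        self.init = present_day_init(
            self.counts.n_der,
            self.counts.n_der + self.counts.n_anc,
            self.fg,
            self.reference,
        )
        self._loglik_memo: dict = {}

    def _tset(self, model: SelectionModel) -> TransitionSet:
        return self.cache.get(
            self.fg, self.counts.grid, self.demography, model, self.reference
        )

    def loglik(self, model: SelectionModel) -> float:
        """log P(C | model); -inf when the likelihood underflows to zero.

        At strong selection the prior mass of trajectories old enough to
        explain a deep derived MRCA can vanish below double precision; such
        models get -inf (they are simply impossible for this tree) instead of
        the :class:`LikelihoodZeroError` the low-level recursions raise.
        """
        key = model.key()
        if key not in self._loglik_memo:
            try:
                self._loglik_memo[key] = tree_loglik(
                    self.counts, self._tset(model), self.init, self.E
                )
            except LikelihoodZeroError:
                self._loglik_memo[key] = -np.inf
        return self._loglik_memo[key]

    def log_weight(self, model: SelectionModel) -> float:
        """log Omega(model) = log P(C | model) - log P(C | neutral)."""
        return self.loglik(model) - self.loglik(SelectionModel.neutral())

    def posterior(self, model: SelectionModel) -> np.ndarray:
        return posterior_marginals(self.counts, self._tset(model), self.init, self.E)
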