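"""Hidden allele-frequency transitions: the trajectory prior P(X | s).

The derived-allele frequency is modelled as a Wright-Fisher chain with additive
viability selection, discretized on a :class:`~treesweep.core.FrequencyGrid`.
Forward (past -> present) dynamics over a short block of ``tau`` generations
are locally Gaussian: the mean follows the deterministic selection map
``x -> x + s x (1 - x) / (1 + 2 s x)`` iterated ``tau`` times and the variance
accumulates ``x_t (1 - x_t) / (2 N)`` along that path.  The block length is
chosen so that the Gaussian is at least as wide as a grid bin (``tau`` of
order ``2 N pi^2 / d^2``); a strictly one-generation kernel on a ~100-bin grid
would be far narrower than a bin and the discretized chain would badly distort
the diffusion.

The HMM runs backward in time, so each block kernel is time-reversed under a
reference measure ``pi`` before composition.  The default ``pi`` is the
classic neutral sojourn measure of a new mutant, ``pi(x) dx = 2 dx / x``
generations spent in ``(x, x + dx)``, with unit mass on the absent state 0;
mutants enter the population at the lowest interior bin.  Under this measure
the weight of origination (backward absorption into 0) is parameter-free: the
per-generation mutation flux cancels between the forward entry probability and
the interior sojourn mass.

Epoch-level backward transition matrices are compositions of reversed block
kernels, so the trajectory prior used by the HMM is *exactly* the law of the
backward chain that the simulator samples.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr

from .core import DemographicModel, FrequencyGrid, SelectionModel, TimeGrid

__all__ = [
    "wf_forward_step",
    "forward_block_kernel",
    "backward_block_kernel",
    "backward_transition_matrix",
    "present_day_init",
    "TransitionSet",
    "TransitionCache",
    "block_length",
]

# per-generation mutation flux used only as an internal bookkeeping constant;
# it cancels exactly in the time reversal (see backward_block_kernel)
_MUT_FLUX = 1.0e-12

# block length safety factor: sigma(block) >= sqrt(SAFETY) * bin width
_BLOCK_SAFETY = 2.0


def block_length(N: float, d: int, s: float = 0.0, max_len: int | None = None) -> int:
    """Number of generations per locally-Gaussian block for a d-bin grid.

    Capped so the deterministic logit drift per block stays below one unit
    (``s * tau <= 1``): longer blocks under strong selection would leap over
    grid bins and leave them unreachable.
    """
    tau = int(np.ceil(_BLOCK_SAFETY * 2.0 * N * np.pi**2 / d**2))
    if s > 0:
        tau = min(tau, max(1, int(np.floor(1.0 / s))))
    tau = max(1, tau)
    if max_len is not None:
        tau = min(tau, max(1, int(max_len)))
    return tau


def _drift_and_var(x: np.ndarray, s: float, N: float, tau: int):
    """Deterministic selection path over tau generations and accumulated variance."""
    y = np.asarray(x, dtype=float).copy()
    if s == 0.0:
        return y, tau * y * (1.0 - y) / (2.0 * N)
    var = np.zeros_like(y)
    for _ in range(tau):
        var += y * (1.0 - y) / (2.0 * N)
        y = y + s * y * (1.0 - y) / (1.0 + 2.0 * s * y)
    return y, var


def forward_block_kernel(
    fg: FrequencyGrid, N: float, s: float, tau: int, mut_flux: float = _MUT_FLUX
) -> np.ndarray:
    """Row-stochastic forward kernel over ``tau`` generations.

    Rows index the source (older) bin, columns the destination (younger) bin.
    Row 0 is the absent state: it persists except for a mutation flux
    ``mut_flux * tau`` into the lowest interior bin.  Interior rows are
    bin-integrated Gaussians; spillover below the first interior edge is
    absorbed at 0, spillover above the top edge is held at the top interior
    bin (1 is deliberately off-grid).
    """
    x = fg.x
    d = fg.d
    K = np.zeros((d, d))
    u = mut_flux * tau
    # a mutant entering during the block drifts/diffuses for about half of it
    e_mean, e_var = _drift_and_var(np.array([x[1]]), s, N, max(1, tau // 2))
    e_sd = np.sqrt(e_var[0])
    e_cdf = ndtr((fg.edges[1:-1] - e_mean[0]) / e_sd)
    entry = np.concatenate([[e_cdf[0]], np.diff(e_cdf), [1.0 - e_cdf[-1]]])
    K[0, :] = u * entry
    K[0, 0] += 1.0 - u
    mean, var = _drift_and_var(x[1:], s, N, tau)
    sd = np.sqrt(var)
    edges = fg.edges
    # interior edges 1..d-1 separate bin 0 | bin 1 | ... | bin d-1
    zvals = (edges[None, 1:-1] - mean[:, None]) / sd[:, None]
    cdf = ndtr(zvals)
    K[1:, 0] = cdf[:, 0]
    K[1:, 1:-1] = np.diff(cdf, axis=1)
    K[1:, -1] = 1.0 - cdf[:, -1]
    return K


def wf_forward_step(x: float, s: float, N: float, fg: FrequencyGrid) -> np.ndarray:
    """One-generation forward Wright-Fisher update, as a distribution over bins."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("frequency must lie in [0, 1]")
    if x == 0.0:
        out = np.zeros(fg.d)
        out[0] = 1.0
        return out
    K = forward_block_kernel(fg, N, s, 1, mut_flux=0.0)
    return K[fg.nearest_bin(x)]


def _sojourn_measure(fg: FrequencyGrid) -> np.ndarray:
    """Reference measure over interior bins: 2 * width / x generations."""
    x = fg.x
    w = fg.widths
    m = np.zeros(fg.d)
    m[1:] = 2.0 * w[1:] / x[1:]
    return m


def backward_block_kernel(
    fg: FrequencyGrid, N: float, s: float, tau: int, reference: str = "sojourn"
) -> np.ndarray:
    """Time reversal of the forward block kernel under the reference measure.

    ``B[j, y] = P(past state y | current state j)`` proportional to
    ``F[y, j] * pi(y)``; the absent state's weight divides out the mutation
    flux, making origination probabilities flux-independent.  State 0 is
    absorbing backward in time.
    """
    F = forward_block_kernel(fg, N, s, tau)
    if reference == "sojourn":
        pi = _sojourn_measure(fg)
    elif reference == "uniform":
        pi = np.concatenate([[0.0], fg.widths[1:]])
    else:
        raise ValueError(f"unknown reference measure {reference!r}")
    W = F.T * pi[None, :]
    W[:, 0] = F[0, :] / _MUT_FLUX
    W[0, :] = 0.0
    W[0, 0] = 1.0
    rows = W.sum(axis=1)
    if np.any(rows <= 0):
        bad = int(np.nonzero(rows <= 0)[0][0])
        raise ValueError(
            f"frequency bin {fg.x[bad]:.4g} is unreachable from any past state"
        )
    return W / rows[:, None]


def _mat_pow(M: np.ndarray, n: int) -> np.ndarray:
    """M**n by binary squaring (n >= 0)."""
    result = np.eye(M.shape[0])
    base = M
    while n > 0:
        if n & 1:
            result = result @ base
        base = base @ base
        n >>= 1
    return result


def _compose_blocks(
    fg: FrequencyGrid, N: float, s: float, gens: int, reference: str
) -> np.ndarray:
    """Backward kernel over ``gens`` generations built from repeated blocks."""
    if gens <= 0:
        return np.eye(fg.d)
    tau = block_length(N, fg.d, s, max_len=gens)
    q, r = divmod(int(gens), tau)
    B = _mat_pow(backward_block_kernel(fg, N, s, tau, reference), q)
    if r:
        B = B @ backward_block_kernel(fg, N, s, r, reference)
    return B


def backward_transition_matrix(
    fg: FrequencyGrid,
    dt: float,
    N: float,
    model: SelectionModel,
    epoch_start: float,
    reference: str = "sojourn",
) -> np.ndarray:
    """Backward transition matrix for one epoch ``(epoch_start, epoch_start + dt]``.

    Rows give ``P(X_{i+1} = x' | X_i = x)`` where ``i+1`` is the older epoch.
    Selection applies only to the portion of the epoch younger than the onset
    time ``t_s``; with a finite onset inside the epoch the selected (young)
    blocks are applied before the neutral (old) ones.
    """
    gens = int(round(dt))
    if gens < 1:
        raise ValueError("epoch must span at least one generation")
    sel_gens = int(round(np.clip(model.t_s - epoch_start, 0.0, gens))) if model.s else 0
    if not np.isfinite(model.t_s):
        sel_gens = gens if model.s else 0
    neu_gens = gens - sel_gens
    B = np.eye(fg.d)
    if sel_gens:
        B = B @ _compose_blocks(fg, N, model.s, sel_gens, reference)
    if neu_gens:
        B = B @ _compose_blocks(fg, N, 0.0, neu_gens, reference)
    return B


def present_day_init(
    n_der: int, n_total: int, fg: FrequencyGrid, reference: str = "sojourn"
) -> np.ndarray:
    """Distribution of the present-day population frequency given sample counts.

    Bin weights are proportional to the binomial likelihood of observing
    ``n_der`` derived lineages among ``n_total`` times the reference measure.
    The site must segregate in the sample.
    """
    if not (0 < n_der < n_total):
        raise ValueError("site must segregate: need 0 < n_der < n_total")
    x = fg.x
    if reference == "sojourn":
        pi = _sojourn_measure(fg)
    else:
        pi = np.concatenate([[0.0], fg.widths[1:]])
    logw = np.full(fg.d, -np.inf)
    xi = x[1:]
    logbin = (
        gammaln(n_total + 1) - gammaln(n_der + 1) - gammaln(n_total - n_der + 1)
        + n_der * np.log(xi)
        + (n_total - n_der) * np.log1p(-xi)
    )
    logw[1:] = logbin + np.log(pi[1:])
    w = np.exp(logw - logw.max())
    return w / w.sum()


@dataclass
class TransitionSet:
    """Backward transition matrices for every epoch under one selection model."""

    fg: FrequencyGrid
    grid: TimeGrid
    demography: DemographicModel
    model: SelectionModel
    reference: str = "sojourn"

    def __post_init__(self):
        times = self.grid.times
        self.matrices = [
            backward_transition_matrix(
                self.fg,
                self.grid.durations[i],
                self.demography.Ne[i],
                self.model,
                epoch_start=times[i],
                reference=self.reference,
            )
            for i in range(self.grid.K - 1)
        ]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.matrices[i]


class TransitionCache:
    """Bounded LRU cache of :class:`TransitionSet` keyed by model/grid identity."""

    def __init__(self, maxsize: int = 256):
        self.maxsize = maxsize
        self._store: OrderedDict = OrderedDict()

    def get(
        self,
        fg: FrequencyGrid,
        grid: TimeGrid,
        demography: DemographicModel,
        model: SelectionModel,
        reference: str = "sojourn",
    ) -> TransitionSet:
        key = (fg.key(), demography.key(), model.key(), reference)
        if key in self._store:
            self._store.move_to_end(key)
            return self._store[key]
        tset = TransitionSet(fg, grid, demography, model, reference)
        self._store[key] = tset
        if len(self._store) > self.maxsize:
            self._store.popitem(last=False)
        return tset
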