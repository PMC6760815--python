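"""Lines-of-descent transition probabilities within an allelic class.

Given ``a`` lineages in a class of (expected) size ``z`` diploid individuals,
the number of distinct ancestral lineages ``b`` remaining after ``dt``
generations follows Tavare's exact distribution for the discrete coalescent,
with the pairwise rate ``1/(2 z)`` per generation.  The exact alternating sum
is numerically unstable for large ``a`` or tiny scaled durations
``dtau = dt / (2 z)``; in that regime the count is asymptotically normal
(Griffiths' approximation) and we switch over automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr

__all__ = [
    "LodPolicy",
    "LodDistribution",
    "class_size",
    "lod_exact",
    "lod_normal",
    "lod_auto",
    "lod_logpmf",
]


@dataclass(frozen=True)
class LodPolicy:
    """Switching rule between the exact sum and the normal approximation.

    The normal approximation is used when the start count exceeds ``a_max`` or
    when the class is large relative to the interval (``z / dt > z_over_dt``,
    the "large recent Ne / short epoch" regime).  Independently, the exact sum
    falls back to the approximation wherever cancellation destroys more than
    ``-log10(cancellation_tol)`` orders of magnitude.
    """

    a_max: int = 40
    z_over_dt: float = 1.0e4
    cancellation_tol: float = 1.0e-10

    def use_normal(self, a: int, dt: float, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (a > self.a_max) | (z / dt > self.z_over_dt)


DEFAULT_POLICY = LodPolicy()


@dataclass
class LodDistribution:
    """Probability mass over end counts ``b in {1..a}`` (index 0 <-> b=1)."""

    a: int
    dt: float
    z: float
    pmf: np.ndarray
    method: str = "exact"

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.a + 1)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def prob(self, b: int) -> float:
        if b < 1 or b > self.a:
            return 0.0
        return float(self.pmf[b - 1])

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.support, p=self.pmf))


def class_size(x: float, N: float, klass: str) -> float:
    """Expected number of diploid individuals carrying the class at frequency x.

    ``der`` -> N*x, ``anc`` -> N*(1-x), ``mix`` -> N.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError("frequency must lie in [0, 1]")
    if N <= 0:
        raise ValueError("population size must be positive")
    if klass == "der":
        return N * x
    if klass == "anc":
        return N * (1.0 - x)
    if klass == "mix":
        return float(N)
    raise ValueError(f"unknown allelic class {klass!r}")


def _exact_coefficients(a: int, b: int):
    """Signed log-coefficients of Tavare's sum for fixed (a, b), k = b..a."""
    k = np.arange(b, a + 1, dtype=float)
    logc = (
        np.log(2.0 * k - 1.0)
        + gammaln(b + k - 1.0) - gammaln(b)          # rising factorial b^(k-1)
        + gammaln(a + 1.0) - gammaln(a - k + 1.0)    # falling factorial a_[k]
        + gammaln(a) - gammaln(a + k)                # 1 / rising factorial a^(k)
        - gammaln(b + 1.0) - gammaln(k - b + 1.0)    # 1 / (b! (k-b)!)
    )
    sign = np.where((k - b) % 2 == 0, 1.0, -1.0)
    return k, logc, sign


def _exact_logpmf_vec(a: int, b: int, dtau: np.ndarray, tol: float):
    """log P(b | a) for an array of scaled durations; also a stability mask.

    Terms are summed in log space with sign tracking after shifting by the
    largest term; a result is flagged unstable when the alternating sum cancels
    below ``tol`` of the leading term or turns negative.
    """
    k, logc, sign = _exact_coefficients(a, b)
    rates = k * (k - 1.0) / 2.0
    logterms = logc[None, :] - np.outer(dtau, rates)
    m = np.max(logterms, axis=1)
    with np.errstate(under="ignore"):
        ssum = np.einsum("ij,j->i", np.exp(logterms - m[:, None]), sign)
    stable = np.isfinite(m) & (ssum > tol)
    out = np.full(dtau.shape, -np.inf)
    ok = stable & (ssum > 0)
    with np.errstate(divide="ignore"):
        out[ok] = np.minimum(m[ok] + np.log(ssum[ok]), 0.0)
    # dtau = +inf means certain full coalescence
    inf_mask = ~np.isfinite(dtau)
    if np.any(inf_mask):
        out[inf_mask] = 0.0 if b == 1 else -np.inf
        stable[inf_mask] = True
    return out, stable


def _griffiths_moments(a: int, dtau: np.ndarray):
    """Mean and variance of the normal approximation to the end count."""
    dtau = np.asarray(dtau, dtype=float)
    alpha = a * dtau / 2.0
    beta = -dtau / 2.0
    with np.errstate(over="ignore", invalid="ignore", under="ignore", divide="ignore"):
        denom = alpha * np.expm1(beta) + beta * np.exp(beta)
        eta = np.where(denom != 0, alpha * beta / denom, np.nan)
        mean = 2.0 * eta / dtau
        factor = (
            1.0
            + eta / (eta + beta)
            - eta / alpha
            - eta / (alpha + beta)
            - 2.0 * eta
        )
        var = mean * (eta + beta) ** 2 / beta**2 * factor
    # limits: dtau -> 0 keeps all a lineages; dtau -> inf coalesces fully
    mean = np.where(np.isfinite(mean), mean, np.where(dtau > 1.0, 1.0, float(a)))
    var = np.where(np.isfinite(var) & (var > 0), var, 0.0)
    return np.clip(mean, 1.0, float(a)), var


def _normal_logpmf_vec(a: int, b: int, dtau: np.ndarray):
    """log of the bin-integrated, truncated-to-{1..a} normal mass at b."""
    mean, var = _griffiths_moments(a, np.asarray(dtau, dtype=float))
    sd = np.sqrt(var)
    out = np.full(mean.shape, -np.inf)
    degen = sd <= 0
    if np.any(degen):
        point = np.clip(np.rint(mean[degen]), 1, a).astype(int)
        out[degen] = np.where(point == b, 0.0, -np.inf)
    ok = ~degen
    if np.any(ok):
        lo = ndtr((b - 0.5 - mean[ok]) / sd[ok])
        hi = ndtr((b + 0.5 - mean[ok]) / sd[ok])
        total = ndtr((a + 0.5 - mean[ok]) / sd[ok]) - ndtr((0.5 - mean[ok]) / sd[ok])
        mass = np.where(total > 0, (hi - lo) / np.where(total > 0, total, 1.0), 0.0)
        sub = np.full(mass.shape, -np.inf)
        pos = mass > 0
        with np.errstate(divide="ignore"):
            sub[pos] = np.minimum(np.log(mass[pos]), 0.0)
        # zero-width normal window (total underflow): fall back to a point mass
        bad = total <= 0
        if np.any(bad):
            point = np.clip(np.rint(mean[ok][bad]), 1, a).astype(int)
            sub[bad] = np.where(point == b, 0.0, -np.inf)
        out[ok] = sub
    return out


def lod_logpmf(a: int, b: int, dt: float, z, policy: LodPolicy = DEFAULT_POLICY):
    """Vectorized log P(end count = b | start count = a) over class sizes ``z``.

    This is the emission workhorse: for one epoch the counts (a, b) and the
    duration are fixed while ``z`` varies across frequency bins.  ``z <= 0`` is
    only legal when the class holds a single lineage (which then persists).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if a < 1:
        raise ValueError("start count must be >= 1")
    out = np.full(z.shape, -np.inf)
    if b < 1 or b > a:
        return out
    zero = z <= 0
    if np.any(zero):
        if a == 1 and b == 1:
            out[zero] = 0.0
        elif a > 1 and b == 1:
            out[zero] = 0.0  # vanishing class: remaining lineages coalesce at once
    live = ~zero
    if not np.any(live):
        return out
    if a == 1:
        out[live] = 0.0 if b == 1 else -np.inf
        return out
    dtau = dt / (2.0 * z[live])
    use_norm = policy.use_normal(a, dt, z[live])
    vals = np.full(dtau.shape, -np.inf)
    exact_idx = ~use_norm
    if np.any(exact_idx):
        ex, stable = _exact_logpmf_vec(a, b, dtau[exact_idx], policy.cancellation_tol)
        need_fb = ~stable
        if np.any(need_fb):
            ex[need_fb] = _normal_logpmf_vec(a, b, dtau[exact_idx][need_fb])
        vals[exact_idx] = ex
    if np.any(use_norm):
        vals[use_norm] = _normal_logpmf_vec(a, b, dtau[use_norm])
    out[live] = vals
    return out


def lod_exact(a: int, dt: float, z: float, policy: LodPolicy = DEFAULT_POLICY) -> LodDistribution:
    """Tavare's exact end-count distribution, stabilized; raises if unusable.

    The alternating series is evaluated in log space with sign tracking; bins
    where cancellation exceeds the policy tolerance are filled from the normal
    approximation (the prescribed fallback).
    """
    if a < 1:
        raise ValueError("start count must be >= 1")
    if dt <= 0:
        raise ValueError("duration must be positive")
    if z <= 0:
        if a == 1:
            return LodDistribution(a, dt, z, np.array([1.0]), "exact")
        raise ValueError("class size must be positive for more than one lineage")
    if a == 1:
        return LodDistribution(a, dt, z, np.array([1.0]), "exact")
    dtau = np.array([dt / (2.0 * z)])
    pmf = np.zeros(a)
    for b in range(1, a + 1):
        lp, stable = _exact_logpmf_vec(a, b, dtau, policy.cancellation_tol)
        if not stable[0]:
            lp = _normal_logpmf_vec(a, b, dtau)
        pmf[b - 1] = np.exp(lp[0])
    pmf = np.clip(pmf, 0.0, 1.0)
    total = pmf.sum()
    if total <= 0:
        raise FloatingPointError("exact lines-of-descent sum fully cancelled")
    return LodDistribution(a, dt, z, pmf / total, "exact")


def lod_normal(a: int, dt: float, z: float) -> LodDistribution:
    """Griffiths' normal approximation discretized onto {1..a} and renormalized."""
    if a < 1:
        raise ValueError("start count must be >= 1")
    if a == 1 or z <= 0 and a == 1:
        return LodDistribution(a, dt, z, np.array([1.0]), "normal")
    if z <= 0:
        pmf = np.zeros(a)
        pmf[0] = 1.0
        return LodDistribution(a, dt, z, pmf, "normal")
    dtau = np.array([dt / (2.0 * z)])
    mean, var = _griffiths_moments(a, dtau)
    mean, sd = mean[0], float(np.sqrt(var[0]))
    bs = np.arange(1, a + 1)
    if sd <= 0:
        pmf = np.zeros(a)
        pmf[int(np.clip(np.rint(mean), 1, a)) - 1] = 1.0
        return LodDistribution(a, dt, z, pmf, "normal")
    hi = ndtr((bs + 0.5 - mean) / sd)
    lo = ndtr((bs - 0.5 - mean) / sd)
    pmf = np.clip(hi - lo, 0.0, None)
    total = pmf.sum()
    if total <= 0:
        pmf = np.zeros(a)
        pmf[int(np.clip(np.rint(mean), 1, a)) - 1] = 1.0
        return LodDistribution(a, dt, z, pmf, "normal")
    return LodDistribution(a, dt, z, pmf / total, "normal")


def lod_auto(a: int, dt: float, z: float, policy: LodPolicy = DEFAULT_POLICY) -> LodDistribution:
    """Dispatch between the exact formula and the normal approximation."""
    if a == 1:
        return LodDistribution(a, dt, z, np.array([1.0]), "exact")
    if z <= 0:
        pmf = np.zeros(a)
        pmf[0] = 1.0
        return LodDistribution(a, dt, z, pmf, "exact")
    if bool(policy.use_normal(a, dt, np.array([z]))[0]):
        return lod_normal(a, dt, z)
    try:
        return lod_exact(a, dt, z, policy)
    except FloatingPointError:
        return lod_normal(a, dt, z)
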