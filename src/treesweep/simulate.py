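"""Ground-truth generator: conditional trajectories, genealogies, experiments.

Trajectories are simulated backward in time from a fixed present-day frequency
by sampling the same time-reversed Wright-Fisher chain whose composition forms
the HMM's trajectory prior, so simulated data come exactly from the model the
likelihood marginalizes.  For time-varying population size, whole trajectories
are rejected with probability ``1 - N(t_origin) / max(N)`` so that the chance
of the mutation arising in an epoch scales with its population size.

Given a trajectory, the genealogy follows the structured coalescent: within
each epoch the derived and ancestral classes coalesce independently with class
sizes ``N x`` and ``N (1 - x)``; the trajectory's origination epoch must leave
exactly one derived lineage (else the pair is resimulated jointly), after
which the surviving lineages coalesce freely as the mixed class.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DemographicModel,
    FrequencyGrid,
    SelectionModel,
    TimeGrid,
    Trajectory,
    build_time_grid,
)
from .freq import TransitionCache, backward_block_kernel, block_length
from .genealogy import CountSeries, LabeledGenealogy, read_labeled_newick
from .hmm import TreeHMM
from .inference import (
    empirical_threshold,
    likelihood_ratio_surface,
    mle,
    posterior_trajectory,
    soft_vs_hard_statistic,
)
from .lod import DEFAULT_POLICY, LodPolicy, lod_auto

__all__ = [
    "SimCondition",
    "Replicate",
    "simulate_trajectory",
    "simulate_genealogy",
    "simulate_replicate",
    "AnalysisSettings",
    "analyze_counts",
    "run_experiment",
    "power_at",
    "ceu_demography",
]


@dataclass(frozen=True)
class SimCondition:
    """One simulation design point: demography, sampling, and selection truth."""

    demography: DemographicModel
    fg: FrequencyGrid
    x0: float
    model: SelectionModel
    n_der: int
    n_anc: int
    max_retries: int = 2000

    def __post_init__(self):
        if not (0.0 < self.x0 < 1.0):
            raise ValueError("present-day frequency must segregate (0 < x0 < 1)")
        if self.n_der < 1 or self.n_anc < 1:
            raise ValueError("need at least one lineage of each allelic class")


@functools.lru_cache(maxsize=256)
def _sampling_rows(fg_key, N, s, tau, reference):
    fg = FrequencyGrid(fg_key)
    B = backward_block_kernel(fg, N, s, tau, reference)
    return np.cumsum(B, axis=1)


def _epoch_phases(model: SelectionModel, t_start: float, gens: int):
    """(s, generations) pieces of one epoch, youngest first."""
    if model.s == 0.0:
        return [(0.0, gens)]
    if not np.isfinite(model.t_s):
        return [(model.s, gens)]
    sel = int(round(np.clip(model.t_s - t_start, 0.0, gens)))
    out = []
    if sel:
        out.append((model.s, sel))
    if gens - sel:
        out.append((0.0, gens - sel))
    return out


def simulate_trajectory(
    cond: SimCondition, rng: np.random.Generator, reference: str = "sojourn"
):
    """Sample one conditional trajectory backward from x0 until origination.

    Returns ``(Trajectory, origination_time_gen, n_rejected)``.  Rejection
    enforces both absorption within the horizon and, for varying population
    size, the linear scaling of the mutation's origination probability with
    the size at origination.
    """
    grid = cond.demography.grid
    fgk = cond.fg.key()
    maxN = cond.demography.max_size
    j0 = cond.fg.nearest_bin(cond.x0)
    if j0 == 0:
        raise ValueError("present-day frequency maps to the absent state")
    rejected = 0
    for _ in range(cond.max_retries):
        x = np.zeros(grid.K)
        j = j0
        t = 0.0
        origin = None
        for i in range(grid.K):
            x[i] = cond.fg.x[j]
            if j == 0:
                break
            gens = int(round(grid.durations[i]))
            N = cond.demography.Ne[i]
            for s_phase, g in _epoch_phases(cond.model, grid.times[i], gens):
                tau = block_length(N, cond.fg.d, s_phase, max_len=g)
                q, r = divmod(g, tau)
                rows = _sampling_rows(fgk, N, s_phase, tau, reference)
                for blocks, rows_b in (((q, rows)), ((1, None) if r else (0, None))):
                    if rows_b is None and blocks:
                        rows_b = _sampling_rows(fgk, N, s_phase, r, reference)
                    for _b in range(blocks):
                        j = int(np.searchsorted(rows_b[j], rng.random(), side="right"))
                        t += tau if rows_b is rows else r
                        if j == 0:
                            origin = t
                            break
                    if j == 0:
                        break
                if j == 0:
                    break
            t = grid.times[i + 1]
        if origin is None and j != 0:
            rejected += 1
            continue  # not absorbed within the horizon
        accept = cond.demography.Ne[grid.epoch_of(origin)] / maxN
        if rng.random() <= accept:
            return Trajectory(grid, cond.fg, x), float(origin), rejected
        rejected += 1
    raise RuntimeError(
        "trajectory simulation failed to originate within the horizon/retry "
        "budget; use a longer time grid"
    )


class _Lineage:
    __slots__ = ("name", "age", "children", "parent_age")

    def __init__(self, name, age, children=()):
        self.name = name
        self.age = age
        self.children = list(children)


def _newick(node: _Lineage) -> str:
    def rec(nd, parent_age):
        bl = parent_age - nd.age
        if not nd.children:
            return f"{nd.name}:{bl:.17g}"
        inner = ",".join(rec(ch, nd.age) for ch in nd.children)
        return f"({inner}):{bl:.17g}"

    inner = ",".join(rec(ch, node.age) for ch in node.children)
    return f"({inner});"


def _sample_lod(a, dt, z, rng, policy):
    if a == 1:
        return 1
    return lod_auto(a, dt, z, policy).sample(rng)


def _merge(active, n_events, t_lo, t_hi, rng):
    """Merge random pairs at sorted uniform times within (t_lo, t_hi)."""
    times = np.sort(rng.uniform(t_lo, t_hi, size=n_events))
    for tm in times:
        i, k = rng.choice(len(active), size=2, replace=False)
        i, k = (int(i), int(k)) if i < k else (int(k), int(i))
        parent = _Lineage(None, float(tm), [active[i], active[k]])
        active[i] = parent
        del active[k]
    return active


def simulate_genealogy(
    traj: Trajectory,
    cond: SimCondition,
    rng: np.random.Generator,
    policy: LodPolicy = DEFAULT_POLICY,
):
    """Draw a genealogy conditional on the trajectory; None if incompatible.

    Incompatibility means the derived class failed to collapse to its single
    root lineage by the end of the origination epoch, or the sample failed to
    fully coalesce by the horizon; callers resimulate the trajectory/genealogy
    pair jointly.
    """
    grid = cond.demography.grid
    K = grid.K
    istar = traj.istar
    der = [_Lineage(f"d{i}", 0.0) for i in range(cond.n_der)]
    anc = [_Lineage(f"a{i}", 0.0) for i in range(cond.n_anc)]
    c_der = np.ones(K + 1, dtype=int)
    c_anc = np.ones(K + 1, dtype=int)
    c_mix = np.ones(K + 1, dtype=int)
    c_der[0], c_anc[0], c_mix[0] = cond.n_der, cond.n_anc, cond.n_anc + 1

    for i in range(istar + 1):
        dt = grid.durations[i]
        N = cond.demography.Ne[i]
        x = traj.x[i]
        bd = _sample_lod(len(der), dt, N * x, rng, policy)
        ba = _sample_lod(len(anc), dt, N * (1.0 - x), rng, policy)
        if i == istar and bd != 1:
            return None
        der = _merge(der, len(der) - bd, grid.times[i], grid.times[i + 1], rng)
        anc = _merge(anc, len(anc) - ba, grid.times[i], grid.times[i + 1], rng)
        c_der[i + 1], c_anc[i + 1], c_mix[i + 1] = bd, ba, ba + 1

    droot = der[0]
    mix = anc + [droot]
    for i in range(istar + 1, K):
        dt = grid.durations[i]
        N = cond.demography.Ne[i]
        bm = _sample_lod(len(mix), dt, N, rng, policy)
        mix = _merge(mix, len(mix) - bm, grid.times[i], grid.times[i + 1], rng)
        merged = not any(ln is droot for ln in mix)
        c_mix[i + 1] = bm
        c_anc[i + 1] = bm if merged else bm - 1
        c_der[i + 1] = 1
    if len(mix) != 1:
        return None

    nwk = _newick(mix[0])
    labels = {f"d{i}": "derived" for i in range(cond.n_der)}
    labels.update({f"a{i}": "ancestral" for i in range(cond.n_anc)})
    gen = read_labeled_newick(nwk, labels)
    counts = CountSeries(
        grid, c_der, c_anc, c_mix,
        n_der=cond.n_der, n_anc=cond.n_anc,
        derived_mrca_age=gen.derived_mrca_age,
    )
    return gen, counts


@dataclass
class Replicate:
    trajectory: Trajectory
    genealogy: LabeledGenealogy
    counts: CountSeries
    origination_gen: float
    rejections: int


def simulate_replicate(
    cond: SimCondition,
    rng: np.random.Generator,
    policy: LodPolicy = DEFAULT_POLICY,
    reference: str = "sojourn",
) -> Replicate:
    """Jointly sample a compatible (trajectory, genealogy) pair."""
    rejections = 0
    for _ in range(cond.max_retries):
        traj, origin, rej = simulate_trajectory(cond, rng, reference)
        rejections += rej
        out = simulate_genealogy(traj, cond, rng, policy)
        if out is not None:
            gen, counts = out
            return Replicate(traj, gen, counts, origin, rejections)
        rejections += 1
    raise RuntimeError(
        "could not draw a genealogy compatible with the trajectory within the "
        "retry budget"
    )


@dataclass
class AnalysisSettings:
    """Inference settings shared by the experiment drivers."""

    s_grid: np.ndarray
    ts_grid: np.ndarray | None = None
    refine: bool = True
    quantiles: tuple = (0.25, 0.75)
    policy: LodPolicy = DEFAULT_POLICY
    reference: str = "sojourn"
    compute_trajectory: bool = False

    @staticmethod
    def default_s_grid(n: int = 31, s_min: float = 1e-4, s_max: float = 0.5):
        return np.concatenate([[0.0], np.geomspace(s_min, s_max, n - 1)])

    @staticmethod
    def default_ts_grid():
        return np.array([50.0, 100.0, 200.0, 500.0, 1000.0, np.inf])


def analyze_counts(
    counts: CountSeries,
    demography: DemographicModel,
    fg: FrequencyGrid,
    settings: AnalysisSettings,
    cache: TransitionCache,
) -> dict:
    """Surface, MLE, and (optionally) trajectory summaries for one replicate."""
    hmm = TreeHMM(counts, demography, fg, cache, settings.policy, settings.reference)
    surface = likelihood_ratio_surface([hmm], settings.s_grid, settings.ts_grid)
    out = {}
    if settings.ts_grid is None:
        evaluator = (
            (lambda s: hmm.log_weight(SelectionModel(s))) if settings.refine else None
        )
        s_hat, _, best = mle(surface, evaluator)
        out.update(s_hat=s_hat, ts_hat=np.inf, loglr=best)
    else:
        s_hat, ts_hat, best = mle(surface)
        out.update(
            s_hat=s_hat,
            ts_hat=ts_hat,
            loglr=best,
            soft_hard=soft_vs_hard_statistic(surface),
        )
    jmax = surface.argmax()[0]
    out["ess"] = float(surface.ess[jmax] if not surface.is_2d else surface.ess[jmax])
    out["_hmm"] = hmm
    out["_surface"] = surface
    if settings.compute_trajectory:
        model = (
            SelectionModel(out["s_hat"])
            if settings.ts_grid is None
            else (SelectionModel(out["s_hat"], out["ts_hat"]) if out["s_hat"] > 0
                  else SelectionModel(0.0))
        )
        out["_trajectory"] = posterior_trajectory([hmm], model, settings.quantiles)
    return out


def run_experiment(
    conditions: dict,
    settings: AnalysisSettings,
    n_reps: int,
    seed: int,
    progress=None,
) -> pd.DataFrame:
    """Simulate and analyze ``n_reps`` replicates per named condition.

    Returns a tidy frame with one row per replicate carrying the truth
    (s, t_s, x0, origination time), the estimates (s_hat, t_s_hat, max log
    LR, ESS, soft-vs-hard statistic where applicable), and the 25-75% band
    coverage of the true trajectory when trajectories are requested.
    Fully reproducible given (conditions, settings, seed).
    """
    cache = TransitionCache()
    rows = []
    for ci, (name, cond) in enumerate(sorted(conditions.items())):
        ss = np.random.SeedSequence([seed, ci])
        child_seeds = ss.spawn(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng(child_seeds[rep])
            replicate = simulate_replicate(cond, rng, settings.policy,
                                           settings.reference)
            res = analyze_counts(replicate.counts, cond.demography, cond.fg,
                                 settings, cache)
            row = {
                "condition": name,
                "rep": rep,
                "s_true": cond.model.s,
                "ts_true": cond.model.t_s,
                "x0": cond.x0,
                "n_der": cond.n_der,
                "n_anc": cond.n_anc,
                "origination_gen": replicate.origination_gen,
                "rejections": replicate.rejections,
                "s_hat": res["s_hat"],
                "ts_hat": res["ts_hat"],
                "loglr": res["loglr"],
                "ess": res["ess"],
            }
            if "soft_hard" in res:
                row["soft_hard"] = res["soft_hard"]
            if settings.compute_trajectory:
                traj = res["_trajectory"]
                truth = replicate.trajectory.x
                lo_q, hi_q = min(settings.quantiles), max(settings.quantiles)
                alive = truth > 0
                lo = traj.quantiles[lo_q][alive]
                hi = traj.quantiles[hi_q][alive]
                row["coverage"] = float(
                    np.mean((truth[alive] >= lo) & (truth[alive] <= hi))
                )
            rows.append(row)
            if progress is not None:
                progress(name, rep)
    return pd.DataFrame(rows)


def power_at(alt_stats, null_stats, level: float = 0.01) -> float:
    """Fraction of alternative statistics above the matched empirical cutoff."""
    thr = empirical_threshold(null_stats, level)
    return float(np.mean(np.asarray(alt_stats, dtype=float) > thr))


def ceu_demography(grid: TimeGrid) -> DemographicModel:
    """European-like piecewise-constant demography mapped onto ``grid``.

    Harmonic-mean sizes of a Tennessen-style European history: explosive
    recent growth, growth after the second (out-of-Africa-era) bottleneck at
    ~920-2040 generations ago, an ancestral expansion, and a deep ancestral
    size.  Values are stored in ``data/ceu_demography.tsv``.
    """
    import importlib.resources as ir

    text = (ir.files("treesweep") / "data" / "ceu_demography.tsv").read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    starts = np.array([float(r[0]) for r in rows])
    sizes = np.array([float(r[1]) for r in rows])
    return DemographicModel.from_epochs(starts, sizes, grid)
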