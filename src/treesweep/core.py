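"""Shared discretizations: time grid, demography, frequency grid, selection model.

All times are expressed in generations before present, all rates per generation,
and effective sizes are diploid counts of individuals.  The pairwise coalescence
rate within an allelic class holding ``z`` individuals is ``1 / (2 z)`` per
generation, so a class of size ``z`` with ``k`` lineages coalesces at total rate
``k (k - 1) / (4 z)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "DemographicModel",
    "FrequencyGrid",
    "SelectionModel",
    "Trajectory",
    "build_time_grid",
    "selection_at",
]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered coalescent observation times ``t_0 = 0 < t_1 < ... < t_K``.

    The genealogy and the hidden allele frequency are observed only at these
    K+1 times; epoch ``i`` is the half-open interval ``(t_i, t_{i+1}]``.  The
    horizon ``t_K`` should be large enough that any sample has coalesced with
    near certainty before it.
    """

    boundaries: tuple

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("time grid needs at least two boundaries")
        if b[0] != 0.0:
            raise ValueError("time grid must start at t_0 = 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("time grid boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def K(self) -> int:
        """Number of epochs."""
        return len(self.boundaries) - 1

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.boundaries, dtype=float)

    @property
    def durations(self) -> np.ndarray:
        """Epoch lengths in generations."""
        return np.diff(self.times)

    @property
    def horizon(self) -> float:
        return self.boundaries[-1]

    def epoch_of(self, t: float) -> int:
        """Index of the epoch whose interval ``(t_i, t_{i+1}]`` contains t (t=0 -> 0)."""
        if t < 0 or t > self.horizon:
            raise ValueError(f"time {t} outside grid [0, {self.horizon}]")
        if t == 0:
            return 0
        return int(np.searchsorted(self.times, t, side="left")) - 1

    def refine_with(self, extra_times) -> "TimeGrid":
        """Return a grid with additional boundaries inserted (duplicates dropped)."""
        extra = [t for t in extra_times if np.isfinite(t) and 0.0 < t < self.horizon]
        merged = np.unique(np.concatenate([self.times, np.asarray(extra, dtype=float)]))
        return TimeGrid(tuple(merged))


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant diploid effective sizes aligned to a :class:`TimeGrid`.

    ``N(t) = Ne[i]`` for ``t`` in epoch ``i = (t_i, t_{i+1}]``.
    """

    grid: TimeGrid
    Ne: tuple

    def __post_init__(self):
        n = np.asarray(self.Ne, dtype=float)
        if n.size != self.grid.K:
            raise ValueError(
                f"need one Ne per epoch: got {n.size} sizes for {self.grid.K} epochs"
            )
        if np.any(n <= 0):
            raise ValueError("effective sizes must be positive")
        object.__setattr__(self, "Ne", tuple(float(x) for x in n))

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.Ne, dtype=float)

    @property
    def max_size(self) -> float:
        return max(self.Ne)

    def size_at(self, t: float) -> float:
        return self.Ne[self.grid.epoch_of(t)]

    def key(self) -> tuple:
        """Hashable identity used for transition-matrix caching."""
        return (self.grid.boundaries, self.Ne)

    @classmethod
    def constant(cls, N: float, grid: TimeGrid) -> "DemographicModel":
        return cls(grid, tuple([float(N)] * grid.K))

    @classmethod
    def from_epochs(cls, starts, sizes, grid: TimeGrid) -> "DemographicModel":
        """Map a coarse piecewise model (epoch start times, sizes) onto ``grid``.

        Each analysis epoch takes the size in force at its young boundary.
        """
        starts = np.asarray(starts, dtype=float)
        sizes = np.asarray(sizes, dtype=float)
        if starts[0] != 0:
            raise ValueError("first epoch must start at 0")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("epoch starts must be strictly increasing")
        idx = np.searchsorted(starts, grid.times[:-1], side="right") - 1
        return cls(grid, tuple(sizes[idx]))


def read_demography(path: str, grid: TimeGrid) -> DemographicModel:
    """Read a piecewise-constant demographic model from TSV or JSON.

    TSV format: header ``epoch_start_gen<TAB>Ne``, first row starting at 0.
    JSON format: ``{"boundaries": [...], "Ne": [...]}`` (one more boundary than size,
    or boundaries interpreted as epoch starts when lengths match).
    """
    text = open(path).read()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        bounds = np.asarray(obj["boundaries"], dtype=float)
        sizes = np.asarray(obj["Ne"], dtype=float)
        starts = bounds[:-1] if bounds.size == sizes.size + 1 else bounds
        return DemographicModel.from_epochs(starts, sizes, grid)
    rows = [ln.split("\t") for ln in text.strip().splitlines()]
    if rows and not _is_number(rows[0][0]):
        rows = rows[1:]
    starts = np.array([float(r[0]) for r in rows])
    sizes = np.array([float(r[1]) for r in rows])
    return DemographicModel.from_epochs(starts, sizes, grid)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class FrequencyGrid:
    """Discrete allele-frequency state space including the absorbing state 0.

    The default placement puts the interior points at quantiles of a
    Beta(1/2, 1/2) distribution, ``x_j = sin^2(pi j / (2 d))`` for
    ``j = 1..d-1``, which is denser near the boundaries where trajectory
    resolution matters most; 1 is deliberately excluded so that a segregating
    allele has a single absorbing state (origination at 0).
    """

    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v[0] != 0.0:
            raise ValueError("frequency grid must contain 0 as its first value")
        if np.any(np.diff(v) <= 0):
            raise ValueError("frequency grid values must be strictly increasing")
        if v[-1] > 1.0 or np.any(v < 0):
            raise ValueError("frequency grid values must lie in [0, 1]")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def default(cls, d: int = 200) -> "FrequencyGrid":
        if d < 3:
            raise ValueError("need at least 3 frequency bins")
        j = np.arange(1, d)
        interior = np.sin(np.pi * j / (2.0 * d)) ** 2
        return cls((0.0,) + tuple(interior))

    @property
    def d(self) -> int:
        return len(self.values)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def edges(self) -> np.ndarray:
        """Bin edges: midpoints between grid values, closed below at 0, above at 1."""
        v = self.x
        return np.concatenate([[0.0], 0.5 * (v[1:] + v[:-1]), [1.0]])

    @property
    def widths(self) -> np.ndarray:
        e = self.edges
        return e[1:] - e[:-1]

    def nearest_bin(self, x: float) -> int:
        return int(np.argmin(np.abs(self.x - x)))

    def key(self) -> tuple:
        return self.values


_INF = float("inf")


@dataclass(frozen=True)
class SelectionModel:
    """Additive (genic) selection of strength ``s``, switched on ``t_s`` generations ago.

    ``t_s = inf`` is a hard sweep: ``s`` applies throughout the allele's history.
    Finite ``t_s`` is the sweep-from-standing-variation (SSV) model: neutral
    drift for ``t > t_s``, coefficient ``s`` from ``t_s`` to the present.
    """

    s: float
    t_s: float = _INF

    def __post_init__(self):
        if not (0.0 <= self.s <= 0.5):
            raise ValueError("selection coefficient must satisfy 0 <= s <= 0.5")
        if self.t_s < 0:
            raise ValueError("onset time must be non-negative (or inf)")

    @property
    def is_hard(self) -> bool:
        return math.isinf(self.t_s)

    def key(self) -> tuple:
        return (self.s, self.t_s)

    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls(0.0)


def selection_at(model: SelectionModel, t: float) -> float:
    """Effective selection coefficient ``t`` generations before present."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return model.s if t <= model.t_s else 0.0


@dataclass
class Trajectory:
    """Per-epoch allele frequencies on a grid, with the origination epoch ``i*``.

    ``x[i]`` is the population frequency of the derived allele during epoch i
    (most natural reading: the frequency at the epoch's young boundary ``t_i``).
    The allele segregates at present (``x[0] > 0``) and is absent for all epochs
    older than the origination epoch ``i* = max{i : x[i] > 0}``.
    """

    grid: TimeGrid
    freq_grid: FrequencyGrid
    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size != self.grid.K:
            raise ValueError("need one frequency per epoch")
        if self.x[0] <= 0:
            raise ValueError("allele must segregate at present (x_0 > 0)")
        pos = np.nonzero(self.x > 0)[0]
        istar = int(pos.max())
        if np.any(self.x[: istar + 1] <= 0):
            raise ValueError("frequencies must be positive up to the origination epoch")

    @property
    def istar(self) -> int:
        """Origination epoch: the most ancient epoch with x > 0."""
        return int(np.nonzero(self.x > 0)[0].max())


def build_time_grid(
    horizon: float | None = None,
    K: int = 32,
    spacing: str | list | tuple | np.ndarray = "log",
    demography_max_N: float | None = None,
    t_first: float = 10.0,
) -> TimeGrid:
    """Construct a time discretization.

    Parameters
    ----------
    horizon : terminal time t_K in generations; defaults to ``100 * 2 * max(Ne)``
        when ``demography_max_N`` is given.
    K : number of epochs (ignored when an explicit boundary list is passed).
    spacing : "log" for log-spaced boundaries (finer recent resolution), or an
        explicit list of boundaries returned verbatim.
    t_first : first positive boundary for log spacing.
    """
    if not isinstance(spacing, str):
        return TimeGrid(tuple(float(t) for t in spacing))
    if spacing != "log":
        raise ValueError(f"unknown spacing policy {spacing!r}")
    if horizon is None:
        if demography_max_N is None:
            raise ValueError("need a horizon or a demography to derive one")
        horizon = 100.0 * 2.0 * float(demography_max_N)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return TimeGrid((0.0, float(horizon)))
    inner = np.geomspace(t_first, horizon, K)
    inner = np.unique(np.round(inner))
    return TimeGrid((0.0,) + tuple(inner))
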