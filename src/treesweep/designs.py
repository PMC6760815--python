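"""Canonical desk-scale experiment designs for power, bias, and calibration.

Two study designs drive the validation experiments:

* ``equilibrium_design`` — constant diploid size ``N = 10^4``, 25 diploid
  individuals (50 sampled lineages), derived allele conditioned to segregate
  at 75% today, hard sweeps with s in {0, 0.003, 0.01}.  Used for estimator
  bias, likelihood-ratio power against the matched neutral null, and
  calibration.
* ``standing_variation_design`` — European-like demography, 50 diploids
  (100 lineages), present-day frequency 50%, selection switching on 100
  generations ago (sweep from standing variation) versus hard sweeps of the
  same strength; the soft-vs-hard likelihood-ratio statistic discriminates
  the two.

Analyses run on the true simulated genealogies; each replicate contributes a
single tree (M = 1), the best case for the importance-sampling estimator.
"""

from __future__ import annotations

import numpy as np

from .core import DemographicModel, FrequencyGrid, SelectionModel, build_time_grid
from .simulate import AnalysisSettings, SimCondition, ceu_demography

__all__ = ["equilibrium_design", "standing_variation_design"]


def equilibrium_design(
    s_values=(0.0, 0.003, 0.01),
    N: float = 1.0e4,
    x0: float = 0.75,
    n_lineages: int = 50,
    d: int = 100,
    K: int = 32,
    extra_null: bool = False,
):
    """Constant-size bias/power design; returns (conditions, settings).

    Condition names are ``s=<value>``; with ``extra_null`` a second,
    independent neutral batch ``s=0#2`` is added for honest calibration
    checks (testing a null batch against a threshold derived from itself is
    calibrated by construction).
    """
    grid = build_time_grid(demography_max_N=N, K=K)
    demog = DemographicModel.constant(N, grid)
    fg = FrequencyGrid.default(d)
    n_der = int(round(n_lineages * x0))
    n_anc = n_lineages - n_der
    conditions = {
        f"s={s:g}": SimCondition(demog, fg, x0, SelectionModel(float(s)), n_der, n_anc)
        for s in s_values
    }
    if extra_null:
        conditions["s=0#2"] = SimCondition(
            demog, fg, x0, SelectionModel(0.0), n_der, n_anc
        )
    settings = AnalysisSettings(
        s_grid=AnalysisSettings.default_s_grid(),
        refine=True,
        compute_trajectory=True,
    )
    return conditions, settings


def standing_variation_design(
    s_values=(0.01, 0.03),
    onset: float = 100.0,
    x0: float = 0.5,
    n_lineages: int = 100,
    d: int = 100,
    K: int = 32,
):
    """European-demography soft-vs-hard design; returns (conditions, settings).

    For every strength the design pairs a sweep from standing variation
    (``ssv s=<value>``, neutral before the onset) with a matched hard sweep
    (``hard s=<value>``) serving as its empirical null.
    """
    ts_grid = AnalysisSettings.default_ts_grid()
    grid = build_time_grid(demography_max_N=164500.0, K=K).refine_with(
        [onset] + [t for t in ts_grid if np.isfinite(t)]
    )
    demog = ceu_demography(grid)
    fg = FrequencyGrid.default(d)
    n_der = int(round(n_lineages * x0))
    n_anc = n_lineages - n_der
    conditions = {}
    for s in s_values:
        conditions[f"ssv s={s:g}"] = SimCondition(
            demog, fg, x0, SelectionModel(float(s), onset), n_der, n_anc
        )
        conditions[f"hard s={s:g}"] = SimCondition(
            demog, fg, x0, SelectionModel(float(s)), n_der, n_anc
        )
    settings = AnalysisSettings(
        s_grid=np.concatenate([[0.0], np.geomspace(1e-3, 0.3, 11)]),
        ts_grid=ts_grid,
        refine=False,
    )
    return conditions, settings
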