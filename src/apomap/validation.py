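"""Holdout model-adequacy check: remove 20% of the space-time cube, refit,
and compare posterior predictions with the held-out observations.

The sampling unit is the (area, period, outcome) cell, drawn uniformly
without replacement from the observed cells (optionally stratified by
outcome).  The refit sees the held-out cells as unobserved; predictions are
posterior-predictive binomial draws at those cells, summarized by the
median and central 95% interval.  Interval coverage and mean absolute error
on the rate scale are this package's comparison metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PanelData
from .mcmc import PosteriorSamples


@dataclass
class HoldoutReport:
    cells: list[tuple[int, int, int]]
    table: pd.DataFrame          # per-cell observed / predicted / interval
    coverage: float              # NaN if no cells
    mae_rate: float              # mean |obs - pred| / n (rate scale)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def holdout_split(data: PanelData, fraction: float = 0.2, seed: int = 0,
                  stratify_by_outcome: bool = False
                  ) -> tuple[PanelData, list[tuple[int, int, int]]]:
    """Uniformly hold out a fraction of the observed cells.

    Returns the training panel (held-out cells masked unobserved; counts
    retained for later comparison) and the held-out cell list.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(data.observed_mask & (data.n[:, :, None] > 0))
    cells: list[tuple[int, int, int]] = []
    if stratify_by_outcome:
        for k in range(data.n_outcomes):
            sub = obs[obs[:, 2] == k]
            m = int(round(fraction * len(sub)))
            pick = rng.choice(len(sub), size=m, replace=False)
            cells.extend(map(tuple, sub[np.sort(pick)]))
    else:
        m = int(round(fraction * len(obs)))
        pick = rng.choice(len(obs), size=m, replace=False)
        cells = [tuple(c) for c in obs[np.sort(pick)]]
    train = data.mask_cells(cells)
    remaining = train.observed_mask.sum(axis=(0, 1))
    if np.any(remaining == 0):
        bad = [data.outcomes[k] for k in np.nonzero(remaining == 0)[0]]
        raise ValueError(f"holdout left no observed cells for outcome(s) {bad}")
    return train, cells


def posterior_predictive_compare(samples: PosteriorSamples, data: PanelData,
                                 heldout, seed: int = 0) -> HoldoutReport:
    """Posterior-predictive check at the held-out cells.

    For each cell, binomial replicates Y* ~ Binomial(n, pi) are drawn at
    every retained posterior draw of pi; the report carries the predictive
    median, the central 95% interval, interval coverage of the observed
    counts, and the mean absolute error on the rate scale.
    """
    cells = [tuple(c) for c in heldout]
    keep, dropped = [], 0
    for (i, j, k) in cells:
        if data.n[i, j] > 0:
            keep.append((i, j, k))
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"excluded {dropped} held-out cells with zero denominator")
    if not keep:
        return HoldoutReport([], pd.DataFrame(), np.nan, np.nan)
    idx = np.asarray(keep)
    ii, jj, kk = idx[:, 0], idx[:, 1], idx[:, 2]
    pi = samples.pi_draws(data)[:, :, ii, jj, kk]       # (C, D, M)
    pi = pi.reshape(-1, len(keep))                      # (draws, M)
    rng = np.random.default_rng(seed)
    n_cell = data.n[ii, jj]
    ystar = rng.binomial(n_cell[None, :], pi)
    lo, med, hi = np.percentile(ystar, [2.5, 50, 97.5], axis=0)
    yobs = data.Y[ii, jj, kk]
    inside = (yobs >= lo) & (yobs <= hi)
    table = pd.DataFrame({
        "area": np.asarray(data.area_ids)[ii],
        "period": np.asarray(data.periods)[jj],
        "outcome": np.asarray(data.outcomes)[kk],
        "n": n_cell, "observed": yobs,
        "pred_median": med, "pred_lo": lo, "pred_hi": hi,
        "covered": inside,
    })
    coverage = float(inside.mean())
    mae_rate = float(np.mean(np.abs(yobs - med) / n_cell))
    return HoldoutReport(keep, table, coverage, mae_rate)
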