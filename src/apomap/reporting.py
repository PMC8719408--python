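"""Descriptive and posterior summaries: yearly totals, percent changes,
rates per 100 or 1,000 live births, per-area absolute differences, and the
shared-component surface for mapping.

Rounding convention: percents and rates are presented to one decimal using
numpy's round-half-even.  Crude rates (counts over reported live births)
are always labelled crude to distinguish them from model-based
posterior-median rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PanelData
from .mcmc import PosteriorSamples

TOTAL = "Total"
ALL_OUTCOMES = "All outcomes"


def totals_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add row (per-outcome) and column (per-period) totals to an
    outcome x period count table."""
    t = counts.copy()
    t[TOTAL] = t.sum(axis=1)
    t.loc[ALL_OUTCOMES] = t.sum(axis=0)
    return t


def yearly_totals(data: PanelData) -> pd.DataFrame:
    """Observed event totals by outcome and period, with margins.

    Unobserved cells contribute 0; see ``completeness`` for the share of
    observed cells behind each total.
    """
    y = np.where(data.observed_mask, data.Y, 0).sum(axis=0)   # (J, K)
    counts = pd.DataFrame(y.T, index=list(data.outcomes),
                          columns=list(data.periods))
    return totals_table(counts)


def completeness(data: PanelData) -> pd.DataFrame:
    """Fraction of cells observed, by outcome and period."""
    frac = data.observed_mask.mean(axis=0)
    return pd.DataFrame(frac.T, index=list(data.outcomes),
                        columns=list(data.periods))


def percent_change(first, last, ndigits: int | None = 1):
    """Signed percent change 100*(last-first)/first.

    Accepts scalars or arrays (e.g. per posterior draw, from which an
    uncertainty interval of the change follows).  ``ndigits=None`` skips
    rounding.
    """
    first = np.asarray(first, dtype=float)
    if np.any(first == 0):
        raise ValueError("percent change undefined for a zero baseline")
    out = 100.0 * (np.asarray(last, dtype=float) - first) / first
    if ndigits is not None:
        out = np.round(out, ndigits)
    return float(out) if out.ndim == 0 else out


def rate_per(count, denominator, scale: float = 1000.0,
             ndigits: int | None = 1):
    """Rate per ``scale`` (100 or 1,000) live births.

    Applied to posterior draws of pi times n it yields model-based rates
    with uncertainty intervals; applied to raw totals it is a crude rate.
    """
    denominator = np.asarray(denominator, dtype=float)
    if np.any(denominator <= 0):
        raise ValueError("denominator must be positive")
    out = scale * np.asarray(count, dtype=float) / denominator
    if ndigits is not None:
        out = np.round(out, ndigits)
    return float(out) if out.ndim == 0 else out


@dataclass
class AreaChangeSummary:
    table: pd.DataFrame          # area, first, last, difference, rank
    n_decline: int
    n_increase: int
    n_zero: int
    top_decline: str             # area id with the largest decline
    top_increase: str


def area_absolute_difference(rates: np.ndarray, area_ids,
                             first_period: int = 0,
                             last_period: int = -1) -> AreaChangeSummary:
    """Per-area signed change in rate between two periods, with ranking.

    ``rates`` is (n_areas, n_periods) — typically posterior-median
    model-based rates for one outcome.  Areas are partitioned into
    decline / increase / no-change sets; ranks order |difference|
    descending.
    """
    rates = np.asarray(rates, dtype=float)
    diff = rates[:, last_period] - rates[:, first_period]
    order = np.argsort(-np.abs(diff), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(diff) + 1)
    table = pd.DataFrame({
        "area": list(area_ids),
        "first": rates[:, first_period],
        "last": rates[:, last_period],
        "difference": diff,
        "abs_rank": rank,
    })
    dec, inc = diff < 0, diff > 0
    return AreaChangeSummary(
        table=table,
        n_decline=int(dec.sum()), n_increase=int(inc.sum()),
        n_zero=int((diff == 0).sum()),
        top_decline=str(np.asarray(area_ids)[np.argmin(diff)])
        if dec.any() else "",
        top_increase=str(np.asarray(area_ids)[np.argmax(diff)])
        if inc.any() else "")


def shared_component_surface(samples: PosteriorSamples,
                             exp_transform: bool = False) -> pd.DataFrame:
    """Posterior median and 95% interval of the shared spatial field,
    keyed by area id (joinable to a GeoJSON on that property)."""
    u = samples.stacked("u_s")                      # (draws, N)
    if exp_transform:
        u = np.exp(u)
    lo, med, hi = np.percentile(u, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame({"area": list(samples.area_ids),
                         "median": med, "lo": lo, "hi": hi})


def shared_temporal_trend(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior summary of the shared temporal random walk per period."""
    u = samples.stacked("u_t")
    lo, med, hi = np.percentile(u, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame({"period": list(samples.periods),
                         "median": med, "lo": lo, "hi": hi})


def rate_summary(samples: PosteriorSamples, data: PanelData,
                 scales=None) -> pd.DataFrame:
    """Model-based posterior rate table per (area, period, outcome).

    Columns: posterior median, 2.5% and 97.5% of pi scaled per ``scale``
    live births, plus the crude rate.  Default scales: per 100 for the
    first two outcomes, per 1,000 otherwise (the convention of the four
    adverse-pregnancy-outcome rates).
    """
    K = data.n_outcomes
    if scales is None:
        scales = [100.0 if k < 2 else 1000.0 for k in range(K)]
    pi = samples.pi_draws(data)
    pi = pi.reshape(-1, *pi.shape[2:])              # (draws, N, J, K)
    lo, med, hi = np.percentile(pi, [2.5, 50, 97.5], axis=0)
    crude = data.crude_rates()
    N, J, _ = data.shape
    rows = []
    for k in range(K):
        s = scales[k]
        for i in range(N):
            for j in range(J):
                rows.append({
                    "area": data.area_ids[i], "period": data.periods[j],
                    "outcome": data.outcomes[k], "scale": s,
                    "rate_median": s * med[i, j, k],
                    "rate_lo": s * lo[i, j, k], "rate_hi": s * hi[i, j, k],
                    "crude_rate": s * crude[i, j, k],
                })
    return pd.DataFrame(rows)
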