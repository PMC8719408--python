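"""Two-step covariate screening for the joint model.

Step 1: for every (covariate, outcome) pair, a non-spatial Poisson
regression of event counts on the single covariate with a log live-birth
offset — log E[Y] = log n + b0 + b1 x — fitted by IRLS; the two-sided Wald
p-value of b1 and the residual deviance measure associative strength.

Step 2: covariates significant at p < 0.05 (for at least one outcome) are
kept; among pairs with absolute correlation above a collinearity threshold
the weaker (larger-p) member is dropped.  The threshold |r| > 0.7 is a
common epidemiological convention and is configurable.

A frequentist Wald interval accompanies each estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .data import PanelData


@dataclass
class ScreeningResult:
    covariate: str
    outcome: str
    coefficient: float            # log rate ratio per unit of x
    standard_error: float
    wald_p: float
    deviance: float
    conf_low: float
    conf_high: float
    converged: bool = True
    selected: bool = False


def fit_bivariate_poisson(y, offset_log, x, covariate: str = "x",
                          outcome: str = "y") -> ScreeningResult:
    """Bivariate Poisson rate regression with offset, via IRLS.

    Raises on a zero-variance covariate; a non-converged fit is returned
    flagged, never silently.
    """
    y = np.asarray(y, dtype=float)
    offset_log = np.asarray(offset_log, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative counts")
    if not np.all(np.isfinite(offset_log)):
        raise ValueError("non-finite offsets")
    if np.std(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset_log)
    res = model.fit()
    b1 = float(res.params[1])
    se = float(res.bse[1])
    z = b1 / se
    p = float(2 * stats.norm.sf(abs(z)))
    ci = res.conf_int()
    return ScreeningResult(
        covariate=covariate, outcome=outcome, coefficient=b1,
        standard_error=se, wald_p=p, deviance=float(res.deviance),
        conf_low=float(ci[1][0]), conf_high=float(ci[1][1]),
        converged=bool(res.converged))


def select_covariates(results: list[ScreeningResult],
                      covariate_table: pd.DataFrame | None = None,
                      p_threshold: float = 0.05,
                      collinearity_r: float = 0.7) -> list[str]:
    """Apply the significance threshold, then the collinearity filter.

    A covariate is carried forward if significant for any outcome (the
    joint model shares one covariate block).  Among pairs whose |pairwise
    correlation| exceeds ``collinearity_r`` the one with the larger
    best p-value is dropped (ties: larger deviance, then name).
    """
    if not results:
        raise ValueError("empty candidate list")
    best: dict[str, ScreeningResult] = {}
    for r in results:
        cur = best.get(r.covariate)
        if cur is None or (r.wald_p, r.deviance, r.outcome) < \
                (cur.wald_p, cur.deviance, cur.outcome):
            best[r.covariate] = r
    sig = {c: r for c, r in best.items()
           if r.converged and r.wald_p < p_threshold}
    # stable priority: smaller p, then smaller deviance, then name
    order = sorted(sig, key=lambda c: (sig[c].wald_p, sig[c].deviance, c))
    kept: list[str] = []
    for c in order:
        collinear = False
        if covariate_table is not None:
            for kc in kept:
                r = covariate_table[c].corr(covariate_table[kc])
                if np.isfinite(r) and abs(r) > collinearity_r:
                    collinear = True
                    break
        if not collinear:
            kept.append(c)
    for r in results:
        r.selected = r.covariate in kept
    return sorted(kept)


def _long_records(data: PanelData) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(area, period, outcome) records of counts, offsets, covariates."""
    N, J, K = data.shape
    w = data.observed_mask & (data.n[:, :, None] > 0)
    ii, jj, kk = np.nonzero(w)
    rec = pd.DataFrame({
        "outcome": np.asarray(data.outcomes)[kk],
        "y": data.Y[ii, jj, kk],
        "log_n": np.log(data.n[ii, jj]),
    })
    cov = {}
    for p, nm in enumerate(data.covariate_names_s):
        cov[nm] = data.X_s[ii, p]
    for q, nm in enumerate(data.covariate_names_st):
        cov[nm] = data.X_st[ii, jj, q]
    return rec, pd.DataFrame(cov)


class PoissonScreener(BaseEstimator):
    """Sklearn-style selector wrapping the two-step screen over a panel.

    Parameters
    ----------
    p_threshold:
        Wald significance level for step 1 (default 0.05).
    collinearity_r:
        Absolute-correlation cut for step 2 (default 0.7).

    Attributes
    ----------
    results_ : list of ScreeningResult, one per (covariate, outcome).
    selected_ : sorted list of covariate names surviving both steps.
    candidate_names_ : all screened covariate names.
    """

    def __init__(self, p_threshold: float = 0.05, collinearity_r: float = 0.7):
        self.p_threshold = p_threshold
        self.collinearity_r = collinearity_r

    def fit(self, data: PanelData, y=None):
        rec, cov = self._records(data)
        if cov.shape[1] == 0:
            raise ValueError("panel has no covariates to screen")
        results = []
        for name in cov.columns:
            for outcome, idx in rec.groupby("outcome").groups.items():
                sub = rec.loc[idx]
                results.append(fit_bivariate_poisson(
                    sub["y"], sub["log_n"], cov.loc[idx, name],
                    covariate=name, outcome=str(outcome)))
        self.results_ = results
        self.candidate_names_ = list(cov.columns)
        self.selected_ = select_covariates(
            results, cov, self.p_threshold, self.collinearity_r)
        return self

    def _records(self, data: PanelData):
        return _long_records(data)

    def get_support(self) -> np.ndarray:
        return np.array([c in self.selected_ for c in self.candidate_names_])

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results_])

    def transform(self, data: PanelData) -> PanelData:
        """Return a panel keeping only the selected covariates."""
        import dataclasses as _dc
        keep_s = [i for i, nm in enumerate(data.covariate_names_s)
                  if nm in self.selected_]
        keep_st = [i for i, nm in enumerate(data.covariate_names_st)
                   if nm in self.selected_]
        return _dc.replace(
            data,
            X_s=data.X_s[:, keep_s] if data.X_s is not None and keep_s else None,
            X_st=data.X_st[:, :, keep_st]
            if data.X_st is not None and keep_st else None,
            covariate_names_s=tuple(data.covariate_names_s[i] for i in keep_s),
            covariate_names_st=tuple(data.covariate_names_st[i] for i in keep_st))
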