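"""The space-time cube container shared by every pipeline stage.

``PanelData`` holds event counts ``Y[i, j, k]`` (area, period, outcome),
the live-birth denominators ``n[i, j]`` shared across outcomes, optional
time-invariant covariates ``X_s[i, p]`` and space-time covariates
``X_st[i, j, q]``, and an ``observed_mask`` marking which cells enter the
likelihood.  Long-format CSV round-tripping is provided for the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["area", "period", "outcome", "events", "live_births"]


@dataclass
class PanelData:
    Y: np.ndarray                 # (N, J, K) int
    n: np.ndarray                 # (N, J) int
    observed_mask: np.ndarray     # (N, J, K) bool
    area_ids: tuple[str, ...]
    periods: tuple
    outcomes: tuple[str, ...]
    X_s: np.ndarray | None = None     # (N, P)
    X_st: np.ndarray | None = None    # (N, J, Q)
    covariate_names_s: tuple[str, ...] = field(default=())
    covariate_names_st: tuple[str, ...] = field(default=())

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        self.n = np.asarray(self.n)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        N, J, K = self.Y.shape
        if self.n.shape != (N, J):
            raise ValueError("denominator array must be (n_areas, n_periods)")
        if self.observed_mask.shape != (N, J, K):
            raise ValueError("observed_mask must match Y's shape")
        if len(self.area_ids) != N or len(self.periods) != J \
                or len(self.outcomes) != K:
            raise ValueError("label lengths inconsistent with array shapes")
        if np.any(self.n < 0):
            raise ValueError("negative denominators")
        obs = self.observed_mask
        if np.any((self.Y < 0) & obs):
            raise ValueError("negative event counts in observed cells")
        if np.any((self.n[:, :, None] == 0) & (self.Y != 0) & obs):
            raise ValueError("cells with zero denominator must have zero events")
        if np.any((self.Y > self.n[:, :, None]) & obs):
            raise ValueError("observed cells with events > live births")
        for X, nm in ((self.X_s, "X_s"), (self.X_st, "X_st")):
            if X is not None and not np.all(np.isfinite(X)):
                raise ValueError(f"non-finite values in {nm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.Y.shape

    @property
    def n_areas(self) -> int:
        return self.Y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.Y.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.Y.shape[2]

    def crude_rates(self) -> np.ndarray:
        """Y / n per cell, NaN where the denominator is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.Y / self.n[:, :, None]
        return np.where(self.n[:, :, None] > 0, r, np.nan)

    def pooled_logit(self) -> np.ndarray:
        """Per-outcome empirical logit of the pooled rate (sampler init)."""
        obs = self.observed_mask
        num = np.where(obs, self.Y, 0).sum(axis=(0, 1)).astype(float)
        den = np.where(obs, self.n[:, :, None], 0).sum(axis=(0, 1)).astype(float)
        p = np.clip((num + 0.5) / (den + 1.0), 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    def mask_cells(self, cells) -> "PanelData":
        """Return a copy with the given (i, j, k) cells marked unobserved."""
        mask = self.observed_mask.copy()
        for i, j, k in cells:
            mask[i, j, k] = False
        return replace(self, observed_mask=mask)

    # ---- long-format CSV round trip -------------------------------------

    def to_counts_frame(self) -> pd.DataFrame:
        N, J, K = self.shape
        ii, jj, kk = np.meshgrid(range(N), range(J), range(K), indexing="ij")
        df = pd.DataFrame({
            "area": np.asarray(self.area_ids)[ii.ravel()],
            "period": np.asarray(self.periods)[jj.ravel()],
            "outcome": np.asarray(self.outcomes)[kk.ravel()],
            "events": self.Y.ravel(),
            "live_births": self.n[ii.ravel(), jj.ravel()],
            "observed": self.observed_mask.ravel(),
        })
        return df

    def to_covariates_frame(self) -> pd.DataFrame | None:
        if self.X_s is None and self.X_st is None:
            return None
        N, J = self.n_areas, self.n_periods
        rows = {"area": np.repeat(np.asarray(self.area_ids), J),
                "period": np.tile(np.asarray(self.periods), N)}
        if self.X_s is not None:
            for p, nm in enumerate(self.covariate_names_s):
                rows[nm] = np.repeat(self.X_s[:, p], J)
        if self.X_st is not None:
            for q, nm in enumerate(self.covariate_names_st):
                rows[nm] = self.X_st[:, :, q].ravel()
        return pd.DataFrame(rows)

    def write_csv(self, counts_path, covariates_path=None) -> None:
        self.to_counts_frame().to_csv(counts_path, index=False)
        cov = self.to_covariates_frame()
        if covariates_path is not None and cov is not None:
            cov.to_csv(covariates_path, index=False)


def read_counts_csv(path, covariates_path=None,
                    static_covariates=(), spacetime_covariates=()) -> PanelData:
    """Read the long-format counts table (and optional covariate table).

    The counts table needs columns area/period/outcome/events/live_births;
    an optional boolean ``observed`` column marks missing cells (absent rows
    are also treated as unobserved).  Covariates not named in
    ``static_covariates`` default to space-time varying.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    areas = tuple(str(a) for a in pd.unique(df["area"]))
    periods = tuple(sorted(pd.unique(df["period"])))
    outcomes = tuple(str(o) for o in pd.unique(df["outcome"]))
    ai = {a: i for i, a in enumerate(areas)}
    pj = {p: j for j, p in enumerate(periods)}
    ok = {o: k for k, o in enumerate(outcomes)}
    N, J, K = len(areas), len(periods), len(outcomes)
    Y = np.zeros((N, J, K), dtype=int)
    n = np.zeros((N, J), dtype=int)
    mask = np.zeros((N, J, K), dtype=bool)
    obs_col = df["observed"] if "observed" in df.columns else pd.Series(
        True, index=df.index)
    for row, obs in zip(df.itertuples(index=False), obs_col):
        i, j, k = ai[str(row.area)], pj[row.period], ok[str(row.outcome)]
        Y[i, j, k] = row.events
        n[i, j] = row.live_births
        mask[i, j, k] = bool(obs)

    X_s = X_st = None
    names_s: tuple[str, ...] = ()
    names_st: tuple[str, ...] = ()
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        value_cols = [c for c in cov.columns if c not in ("area", "period")]
        names_s = tuple(c for c in value_cols if c in set(static_covariates))
        if spacetime_covariates:
            names_st = tuple(c for c in value_cols
                             if c in set(spacetime_covariates))
        else:
            names_st = tuple(c for c in value_cols if c not in names_s)
        has_period = "period" in cov.columns
        if names_s:
            X_s = np.zeros((N, len(names_s)))
        if names_st:
            X_st = np.zeros((N, J, len(names_st)))
        for row in cov.itertuples(index=False):
            i = ai[str(row.area)]
            for p, nm in enumerate(names_s):
                X_s[i, p] = getattr(row, nm)
            if names_st:
                js = [pj[row.period]] if has_period else list(range(J))
                for j in js:
                    for q, nm in enumerate(names_st):
                        X_st[i, j, q] = getattr(row, nm)
    return PanelData(Y=Y, n=n, observed_mask=mask, area_ids=areas,
                     periods=periods, outcomes=outcomes,
                     X_s=X_s, X_st=X_st,
                     covariate_names_s=names_s, covariate_names_st=names_st)
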