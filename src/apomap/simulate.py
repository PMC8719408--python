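"""Synthetic space-time-cube generator with the model's own generative structure.

Emulates the assembled surveillance panel the joint model targets: ~290
areal units (a rook-contiguity lattice stands in for the sub-county map),
4 annual periods, 4 outcomes sharing one live-birth denominator per
area-period, binomial counts whose logit decomposes into shared/specific
CAR fields, shared/specific RW1 trends, scaling weights, covariate effects
and an unstructured interaction.  The true parameters are returned so every
downstream stage (screening, fitting, validation, reporting) can be tested
for recovery without any external data.

Default true baselines correspond to the national-scale rates of the four
outcomes (about 4.5 and 2.3 per 100 live births for low birth weight and
pre-term birth, 18.7 and 6.9 per 1,000 for stillbirth and neonatal death).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import PanelData
from .graph import SpatialGraph
from .model import ModelParams, linear_predictor_all

LOGIT_CLAMP = 30.0


def generate_lattice(n_rows: int, n_cols: int) -> SpatialGraph:
    """Rook-contiguity grid graph with n_rows * n_cols areas."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be positive")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            a = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((a, a + 1))
            if r + 1 < n_rows:
                edges.append((a, a + n_cols))
    ids = tuple(f"A{r:02d}{c:02d}" for r in range(n_rows) for c in range(n_cols))
    return SpatialGraph(n_rows * n_cols, tuple(sorted(edges)), ids)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def sample_icar_field(graph: SpatialGraph, precision: float, seed) -> np.ndarray:
    """Draw from the intrinsic CAR distribution on the sum-to-zero subspace.

    Per connected component, samples in the span of the nonzero-eigenvalue
    Laplacian eigenvectors with variances 1/(precision * eigenvalue); each
    component's field sums to zero by construction (singletons are 0).
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    rng = _rng(seed)
    L = graph.laplacian()
    out = np.zeros(graph.n_areas)
    for comp in sorted(graph.components, key=min):
        idx = sorted(comp)
        if len(idx) == 1:
            continue
        w, V = np.linalg.eigh(L[np.ix_(idx, idx)])
        pos = w > 1e-9
        z = rng.standard_normal(pos.sum())
        out[idx] = V[:, pos] @ (z / np.sqrt(precision * w[pos]))
        out[idx] -= out[idx].mean()     # mop up eigen-roundoff
    return out


def sample_rw1(n_periods: int, precision: float, seed) -> np.ndarray:
    """Centred random walk: cumulative Normal(0, 1/precision) increments."""
    if n_periods < 2:
        raise ValueError("need at least 2 periods")
    if precision <= 0:
        raise ValueError("precision must be positive")
    rng = _rng(seed)
    incr = rng.normal(0.0, 1.0 / np.sqrt(precision), n_periods - 1)
    series = np.concatenate([[0.0], np.cumsum(incr)])
    return series - series.mean()


@dataclass
class GeneratorConfig:
    """Study-condition settings for the simulated panel.

    The default scale mirrors the motivating application: a 29x10 lattice
    (290 areas), 4 annual periods labelled 2016-2019, 4 outcomes, and
    500-5,000 live births per area-period.
    """

    n_rows: int = 29
    n_cols: int = 10
    n_periods: int = 4
    n_outcomes: int = 4
    first_period: int = 2016
    denom_range: tuple[int, int] = (500, 5000)
    # logit-scale baselines ~ national rates of the four outcomes
    alpha: tuple = (-3.05, -3.75, -3.96, -4.97)
    gamma_s: tuple = None     # defaults to exp(centred logs) below
    gamma_t: tuple = None
    beta_s: tuple = (0.2, 0.0)      # smooth-signal and noise covariate
    beta_st: tuple = (-0.15, 0.0)
    tau_us: float = 4.0
    tau_usk: float = 10.0
    tau_ut: float = 25.0
    tau_utk: float = 50.0
    tau_nu: float = 100.0
    interaction: str = "iid"
    missing_fraction: float = 0.0
    outcome_names: tuple = ("low_birth_weight", "preterm_birth",
                            "stillbirth", "neonatal_death")

    def __post_init__(self):
        K = self.n_outcomes
        if self.gamma_s is None:
            lg = np.linspace(0.4, -0.4, K)
            self.gamma_s = tuple(np.exp(lg - lg.mean()))
        if self.gamma_t is None:
            lg = np.linspace(-0.3, 0.3, K)
            self.gamma_t = tuple(np.exp(lg - lg.mean()))
        if len(self.alpha) < K:
            raise ValueError("alpha must have one entry per outcome")
        self.alpha = tuple(self.alpha[:K])
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class TruthRecord:
    """The simulating parameters plus the realized risk surface."""

    params: ModelParams
    pi: np.ndarray                    # (N, J, K)
    n_clamped: int = 0
    config: GeneratorConfig = field(default=None, repr=False)


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0
                     ) -> tuple[PanelData, SpatialGraph, TruthRecord]:
    """Simulate a full panel from the shared-component generative model."""
    config = config or GeneratorConfig()
    rng = _rng(seed)
    graph = generate_lattice(config.n_rows, config.n_cols)
    N = graph.n_areas
    J, K = config.n_periods, config.n_outcomes

    u_s = sample_icar_field(graph, config.tau_us, rng)
    u_sk = np.column_stack([sample_icar_field(graph, config.tau_usk, rng)
                            for _ in range(K)])
    u_t = sample_rw1(J, config.tau_ut, rng)
    u_tk = np.column_stack([sample_rw1(J, config.tau_utk, rng)
                            for _ in range(K)])
    if config.interaction == "iid":
        nu = rng.normal(0.0, 1.0 / np.sqrt(config.tau_nu), (N, J))
        nu -= nu.mean()
    else:
        nu = np.stack([sample_rw1(J, config.tau_nu, rng) for _ in range(N)])

    # covariates: one spatially smooth and one white-noise variable per
    # block, standardized — lets screening separate signal from noise
    def _standardize(x):
        return (x - x.mean()) / x.std()

    X_s = np.column_stack([
        _standardize(sample_icar_field(graph, 1.0, rng)),
        rng.standard_normal(N)])
    smooth_st = _standardize(sample_icar_field(graph, 1.0, rng))
    X_st = np.stack([
        _standardize(smooth_st[:, None] + 0.5 * rng.standard_normal((N, J))),
        rng.standard_normal((N, J))], axis=2)
    P, Q = len(config.beta_s), len(config.beta_st)

    params = ModelParams(
        alpha=np.array(config.alpha, dtype=float),
        gamma_s=np.array(config.gamma_s, dtype=float),
        gamma_t=np.array(config.gamma_t, dtype=float),
        u_s=u_s, u_sk=u_sk, u_t=u_t, u_tk=u_tk, nu=nu,
        tau_us=config.tau_us, tau_usk=np.full(K, config.tau_usk),
        tau_ut=config.tau_ut, tau_utk=np.full(K, config.tau_utk),
        tau_nu=config.tau_nu,
        beta_s=np.array(config.beta_s[:P], dtype=float),
        beta_st=np.array(config.beta_st[:Q], dtype=float))

    n = rng.integers(config.denom_range[0], config.denom_range[1] + 1, (N, J))
    periods = tuple(config.first_period + j for j in range(J))
    outcomes = tuple(config.outcome_names[:K]) if len(config.outcome_names) >= K \
        else tuple(f"outcome_{k}" for k in range(K))
    shell = PanelData(Y=np.zeros((N, J, K), dtype=int), n=n,
                      observed_mask=np.ones((N, J, K), dtype=bool),
                      area_ids=graph.area_ids, periods=periods,
                      outcomes=outcomes, X_s=X_s, X_st=X_st,
                      covariate_names_s=("cov_s_smooth", "cov_s_noise")[:P],
                      covariate_names_st=("cov_st_smooth", "cov_st_noise")[:Q])
    eta = linear_predictor_all(params, shell)
    n_clamped = int(np.sum(np.abs(eta) > LOGIT_CLAMP))
    if n_clamped:
        warnings.warn(f"{n_clamped} cells had |logit| > {LOGIT_CLAMP}; clamped")
        eta = np.clip(eta, -LOGIT_CLAMP, LOGIT_CLAMP)
    pi = expit(eta)
    Y = rng.binomial(n[:, :, None], pi)
    mask = np.ones((N, J, K), dtype=bool)
    if config.missing_fraction > 0:
        n_cells = N * J * K
        n_miss = int(round(config.missing_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_miss, replace=False)
        mask.ravel()[flat] = False

    data = PanelData(Y=Y, n=n, observed_mask=mask, area_ids=graph.area_ids,
                     periods=periods, outcomes=outcomes, X_s=X_s, X_st=X_st,
                     covariate_names_s=shell.covariate_names_s,
                     covariate_names_st=shell.covariate_names_st)
    truth = TruthRecord(params=params, pi=pi, n_clamped=n_clamped,
                        config=config)
    return data, graph, truth
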