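"""Joint shared-component spatio-temporal model: likelihood, priors, constraints.

For areas i, periods j and outcomes k (low birth weight, pre-term birth,
stillbirth, neonatal death in the motivating application), event counts are

    Y_ijk ~ Binomial(n_ij, pi_ijk)
    logit(pi_ijk) = alpha_k + X_i beta_s + X_ij beta_st + mu_ijk
    mu_ijk = gamma_s[k] u_s[i] + u_sk[i,k] + gamma_t[k] u_t[j] + u_tk[j,k]
             + nu[i,j]

with one live-birth denominator n_ij shared by all outcomes.  ``u_s`` is a
spatial field common to all outcomes (intrinsic CAR prior), scaled per
outcome by a positive weight ``gamma_s[k]``; ``u_sk`` are outcome-specific
CAR fields.  ``u_t``/``u_tk`` are the analogous shared/specific temporal
random walks (RW1), and ``nu`` is a space-time interaction (exchangeable
normal by default, or an independent RW1 per area).

Identifiability: every random-effect field is centred (per graph component
for spatial fields) and the scaling weights satisfy the product-one
constraint ``sum_k log gamma = 0`` for both the spatial and temporal
weights.  An alternative "literal" mode imposes an additive sum-to-zero on
the spatial weights instead (allowing negative weights); see
``ModelConfig.literal_spatial_constraint``.

Intrinsic (rank-deficient) priors use the convention that the normalizing
constant carries ``rank/2`` powers of the precision, where rank is
``n_areas - n_components`` for CAR blocks (isolated areas add one rank unit
each through their exchangeable-normal prior), ``n_periods - 1`` for RW1
blocks, and ``size - #constraints`` for the interaction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import PanelData
from .graph import SpatialGraph, icar_quadform, rw1_quadform


@dataclass
class HyperPriors:
    """Hyperprior settings (all configurable; values must be positive).

    Defaults follow common WinBUGS-era practice: vague normals on the fixed
    effects, Gamma(0.5, 0.0005) on every precision, and a lognormal on the
    scaling weights whose sd 0.68 keeps weights mostly within [0.2, 5].
    """

    alpha_sd: float = 10.0
    beta_sd: float = 10.0
    precision_shape: float = 0.5
    precision_rate: float = 0.0005
    log_gamma_sd: float = 0.68

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class ModelConfig:
    """Structural switches of the joint model."""

    literal_spatial_constraint: bool = False  # additive sum-zero on gamma_s
    interaction: str = "iid"                  # "iid" (Type I) or "rw1" (Type II)
    share_coefficients: bool = True           # pooled beta across outcomes

    def __post_init__(self):
        if self.interaction not in ("iid", "rw1"):
            raise ValueError("interaction must be 'iid' or 'rw1'")


@dataclass
class ModelParams:
    """One complete parameter state.

    Shapes: alpha (K,); beta_s (P,) or (P, K); beta_st (Q,) or (Q, K);
    gamma_s, gamma_t (K,); u_s (N,); u_sk (N, K); u_t (J,); u_tk (J, K);
    nu (N, J); precisions tau_us, tau_ut, tau_nu scalars and tau_usk,
    tau_utk (K,).
    """

    alpha: np.ndarray
    gamma_s: np.ndarray
    gamma_t: np.ndarray
    u_s: np.ndarray
    u_sk: np.ndarray
    u_t: np.ndarray
    u_tk: np.ndarray
    nu: np.ndarray
    tau_us: float = 1.0
    tau_usk: np.ndarray = None
    tau_ut: float = 1.0
    tau_utk: np.ndarray = None
    tau_nu: float = 1.0
    beta_s: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_st: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        K = len(self.alpha)
        for name in ("alpha", "gamma_s", "gamma_t", "u_s", "u_sk", "u_t",
                     "u_tk", "nu", "beta_s", "beta_st"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.tau_usk is None:
            self.tau_usk = np.ones(K)
        if self.tau_utk is None:
            self.tau_utk = np.ones(K)
        self.tau_usk = np.asarray(self.tau_usk, dtype=float)
        self.tau_utk = np.asarray(self.tau_utk, dtype=float)

    @property
    def n_outcomes(self) -> int:
        return len(self.alpha)

    def copy(self) -> "ModelParams":
        return ModelParams(**{f.name: np.copy(getattr(self, f.name))
                              if isinstance(getattr(self, f.name), np.ndarray)
                              else getattr(self, f.name)
                              for f in dataclasses.fields(self)})

    def all_precisions(self) -> dict[str, float]:
        out = {"tau_us": self.tau_us, "tau_ut": self.tau_ut,
               "tau_nu": self.tau_nu}
        for k in range(self.n_outcomes):
            out[f"tau_usk[{k}]"] = self.tau_usk[k]
            out[f"tau_utk[{k}]"] = self.tau_utk[k]
        return out

    def validate_constraints(self, graph: SpatialGraph,
                             config: ModelConfig | None = None,
                             tol: float = 1e-8) -> None:
        """Raise if the identifiability constraints are violated."""
        config = config or ModelConfig()
        labels = graph.component_labels()
        for name, f in (("u_s", self.u_s), ("u_sk", self.u_sk)):
            for c in range(labels.max() + 1):
                s = f[labels == c].sum(axis=0)
                if np.any(np.abs(s) > tol):
                    raise ValueError(f"{name} not centred on component {c}")
        for name, f in (("u_t", self.u_t), ("u_tk", self.u_tk)):
            if np.any(np.abs(f.sum(axis=0)) > tol):
                raise ValueError(f"{name} not centred")
        if abs(self.nu.sum()) > tol * max(1, self.nu.size):
            raise ValueError("nu not centred")
        if config.literal_spatial_constraint:
            if abs(self.gamma_s.sum()) > tol:
                raise ValueError("gamma_s does not sum to zero (literal mode)")
        else:
            if np.any(self.gamma_s <= 0) or \
                    abs(np.log(self.gamma_s).sum()) > tol:
                raise ValueError("gamma_s violates the product-one constraint")
        if np.any(self.gamma_t <= 0) or abs(np.log(self.gamma_t).sum()) > tol:
            raise ValueError("gamma_t violates the product-one constraint")
        if min(self.tau_us, self.tau_ut, self.tau_nu,
               self.tau_usk.min(), self.tau_utk.min()) <= 0:
            raise ValueError("non-positive precision")


def initial_params(data: PanelData, n_cov_s: int = None, n_cov_st: int = None,
                   config: ModelConfig | None = None) -> ModelParams:
    """Sampler initial state: empirical-logit alpha, zero fields, unit
    weights and precisions."""
    config = config or ModelConfig()
    N, J, K = data.shape
    P = data.X_s.shape[1] if (n_cov_s is None and data.X_s is not None) \
        else (n_cov_s or 0)
    Q = data.X_st.shape[2] if (n_cov_st is None and data.X_st is not None) \
        else (n_cov_st or 0)
    bshape = (P,) if config.share_coefficients else (P, K)
    bstshape = (Q,) if config.share_coefficients else (Q, K)
    gamma_s = np.zeros(K) if config.literal_spatial_constraint else np.ones(K)
    return ModelParams(
        alpha=data.pooled_logit(), gamma_s=gamma_s, gamma_t=np.ones(K),
        u_s=np.zeros(N), u_sk=np.zeros((N, K)), u_t=np.zeros(J),
        u_tk=np.zeros((J, K)), nu=np.zeros((N, J)),
        beta_s=np.zeros(bshape), beta_st=np.zeros(bstshape))


# ---------------------------------------------------------------------------
# linear predictor and likelihood
# ---------------------------------------------------------------------------

def linear_predictor_all(params: ModelParams, data: PanelData) -> np.ndarray:
    """Full (N, J, K) array of logits."""
    N, J, K = data.shape
    eta = np.broadcast_to(params.alpha, (N, J, K)).copy()
    if params.beta_s.size:
        xb = data.X_s @ params.beta_s          # (N,) or (N, K)
        eta += xb[:, None, None] if xb.ndim == 1 else xb[:, None, :]
    if params.beta_st.size:
        xb = np.einsum("ijq,q...->ij...", data.X_st, params.beta_st)
        eta += xb[:, :, None] if xb.ndim == 2 else xb
    eta += params.gamma_s[None, None, :] * params.u_s[:, None, None]
    eta += params.u_sk[:, None, :]
    eta += params.gamma_t[None, None, :] * params.u_t[None, :, None]
    eta += params.u_tk[None, :, :]
    eta += params.nu[:, :, None]
    return eta


def linear_predictor(params: ModelParams, data: PanelData,
                     i: int, j: int, k: int) -> float:
    """Logit of pi for a single cell."""
    N, J, K = data.shape
    if not (0 <= i < N and 0 <= j < J and 0 <= k < K):
        raise IndexError(f"cell ({i},{j},{k}) out of range for shape {(N, J, K)}")
    eta = params.alpha[k]
    if params.beta_s.size:
        b = params.beta_s if params.beta_s.ndim == 1 else params.beta_s[:, k]
        eta += data.X_s[i] @ b
    if params.beta_st.size:
        b = params.beta_st if params.beta_st.ndim == 1 else params.beta_st[:, k]
        eta += data.X_st[i, j] @ b
    eta += params.gamma_s[k] * params.u_s[i] + params.u_sk[i, k]
    eta += params.gamma_t[k] * params.u_t[j] + params.u_tk[j, k]
    eta += params.nu[i, j]
    return float(eta)


def log_likelihood(params: ModelParams, data: PanelData) -> float:
    """Binomial log-likelihood over observed cells (n = 0 cells contribute 0)."""
    eta = linear_predictor_all(params, data)
    return float(binomial_loglik(eta, data, include_constant=True))


def binomial_loglik(eta: np.ndarray, data: PanelData,
                    include_constant: bool = False) -> float:
    """Sum of Y*eta - n*log(1+e^eta) over contributing cells.

    ``include_constant`` adds log C(n, Y); the MH sampler omits it.
    """
    n3 = data.n[:, :, None]
    w = data.observed_mask & (n3 > 0)
    y, n = data.Y[w].astype(float), np.broadcast_to(n3, data.Y.shape)[w]
    e = eta[w]
    ll = np.sum(y * e - n * np.logaddexp(0.0, e))
    if include_constant:
        ll += np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))
    return float(ll)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _spatial_block_logprior(u: np.ndarray, tau, graph: SpatialGraph):
    """Intrinsic CAR log-density (per trailing column if u is 2-D).

    Multi-area components contribute the pairwise-difference form at rank
    size-1; isolated areas contribute an exchangeable N(0, 1/tau) term.
    """
    quad = icar_quadform(u, graph)
    singles = [next(iter(c)) for c in graph.components if len(c) == 1]
    if singles:
        quad = quad + np.sum(u[singles] ** 2, axis=0)
    rank = graph.rank + len(singles)
    return 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * quad


def _rw1_block_logprior(u: np.ndarray, tau):
    J = u.shape[0]
    quad = rw1_quadform(u)
    return 0.5 * (J - 1) * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * quad


def _normal_logpdf(x, sd):
    x = np.asarray(x, dtype=float)
    return np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd)
                  - 0.5 * (x / sd) ** 2)


def _gamma_logpdf(x, shape, rate):
    x = np.asarray(x, dtype=float)
    return np.sum(shape * np.log(rate) - gammaln(shape)
                  + (shape - 1) * np.log(x) - rate * x)


def interaction_rank(N: int, J: int, config: ModelConfig) -> int:
    """Degrees of freedom of the interaction block under its constraints."""
    return N * J - 1 if config.interaction == "iid" else N * (J - 1)


def log_prior(params: ModelParams, graph: SpatialGraph, hyper: HyperPriors,
              config: ModelConfig | None = None) -> float:
    """Joint log-prior at a constraint-satisfying state.

    CAR blocks use the pairwise-difference intrinsic form, RW1 blocks the
    first-difference form, the interaction an exchangeable normal (Type I)
    or per-area RW1 (Type II); fixed effects get vague normals, scaling
    weights a lognormal (normal on the log), precisions Gamma densities.
    """
    config = config or ModelConfig()
    N, J = params.nu.shape
    lp = float(np.sum(_spatial_block_logprior(params.u_s, params.tau_us, graph)))
    lp += float(np.sum(_spatial_block_logprior(params.u_sk, params.tau_usk, graph)))
    lp += float(np.sum(_rw1_block_logprior(params.u_t, params.tau_ut)))
    lp += float(np.sum(_rw1_block_logprior(params.u_tk, params.tau_utk)))
    rank_nu = interaction_rank(N, J, config)
    if config.interaction == "iid":
        quad_nu = float(np.sum(params.nu ** 2))
    else:
        quad_nu = float(np.sum(rw1_quadform(params.nu.T)))
    lp += 0.5 * rank_nu * (np.log(params.tau_nu) - np.log(2 * np.pi)) \
        - 0.5 * params.tau_nu * quad_nu
    lp += _normal_logpdf(params.alpha, hyper.alpha_sd)
    lp += _normal_logpdf(params.beta_s, hyper.beta_sd)
    lp += _normal_logpdf(params.beta_st, hyper.beta_sd)
    if config.literal_spatial_constraint:
        lp += _normal_logpdf(params.gamma_s, 1.0)
    else:
        lp += _normal_logpdf(np.log(params.gamma_s), hyper.log_gamma_sd)
    lp += _normal_logpdf(np.log(params.gamma_t), hyper.log_gamma_sd)
    taus = np.concatenate([[params.tau_us, params.tau_ut, params.tau_nu],
                           params.tau_usk, params.tau_utk])
    lp += _gamma_logpdf(taus, hyper.precision_shape, hyper.precision_rate)
    return float(lp)


def log_posterior(params: ModelParams, data: PanelData, graph: SpatialGraph,
                  hyper: HyperPriors, config: ModelConfig | None = None) -> float:
    ll = log_likelihood(params, data)
    lp = log_prior(params, graph, hyper, config)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log-prior")
    return ll + lp


# ---------------------------------------------------------------------------
# identifiability constraints
# ---------------------------------------------------------------------------

def apply_constraints(params: ModelParams, graph: SpatialGraph,
                      config: ModelConfig | None = None,
                      labels: np.ndarray | None = None) -> ModelParams:
    """Project a state onto the constrained parameterization.

    Centres every random-effect field (per graph component for spatial
    blocks), rescales the weight vectors to product one (or recentres the
    spatial weights additively in literal mode), and pushes the removed
    means/scales into alpha and the remaining fields so that on a connected
    graph the likelihood is numerically unchanged.  Idempotent.
    """
    config = config or ModelConfig()
    p = params.copy()
    if labels is None:
        labels = graph.component_labels()
    n_comp = labels.max() + 1

    csize = np.bincount(labels, minlength=n_comp).astype(float)
    # shared spatial: component means move into the specific fields (scaled)
    cmeans = np.bincount(labels, weights=p.u_s, minlength=n_comp) / csize
    shift = cmeans[labels]                                    # (N,)
    p.u_s -= shift
    p.u_sk += shift[:, None] * p.gamma_s[None, :]
    # specific spatial: component means move into alpha (exact when the
    # graph is connected; otherwise the global mean is absorbed and the
    # between-component residual is the constraint itself)
    K = p.u_sk.shape[1]
    m = np.stack([np.bincount(labels, weights=p.u_sk[:, k],
                              minlength=n_comp) / csize
                  for k in range(K)], axis=1)                 # (n_comp, K)
    p.u_sk -= m[labels]
    p.alpha += m.mean(axis=0) if n_comp > 1 else m[0]
    # shared temporal
    m = p.u_t.mean()
    p.u_t -= m
    p.u_tk += m * p.gamma_t[None, :]
    m = p.u_tk.mean(axis=0)
    p.u_tk -= m[None, :]
    p.alpha += m
    # interaction
    if config.interaction == "rw1":
        # per-area RW1 level: constant over (j, k) within an area, so it is
        # an unscaled common spatial shift — fold into every specific
        # spatial field, then re-centre those into alpha
        row = p.nu.mean(axis=1)                  # (N,)
        p.nu -= row[:, None]
        p.u_sk += row[:, None]
        mm = np.stack([np.bincount(labels, weights=p.u_sk[:, k],
                                   minlength=n_comp) / csize
                       for k in range(K)], axis=1)
        p.u_sk -= mm[labels]
        p.alpha += mm.mean(axis=0) if n_comp > 1 else mm[0]
    m = p.nu.mean()
    p.nu -= m
    p.alpha += m
    # scaling weights
    if config.literal_spatial_constraint:
        g = p.gamma_s.mean()
        p.gamma_s = p.gamma_s - g
        p.u_sk += g * p.u_s[:, None]
    else:
        g = np.exp(np.mean(np.log(p.gamma_s)))
        p.gamma_s = p.gamma_s / g
        p.u_s *= g
    g = np.exp(np.mean(np.log(p.gamma_t)))
    p.gamma_t = p.gamma_t / g
    p.u_t *= g
    return p
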