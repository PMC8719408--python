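"""Adaptive Metropolis-within-Gibbs sampler for the joint model.

Block scheme per sweep:

* precisions — conjugate Gamma draws from their full conditionals, with
  shape offsets given by the intrinsic ranks of the corresponding blocks;
* alpha, scaling weights — random-walk Metropolis, vectorized across
  outcomes (outcome slices of the likelihood are disjoint, so parallel
  acceptance is exact);
* covariate coefficients — sequential scalar random-walk Metropolis;
* random-effect fields — chromatic single-site random-walk Metropolis:
  a proper colouring of the adjacency (or period path) graph is computed
  once, and all same-colour sites are proposed and accepted in parallel,
  which is valid because they are conditionally independent given the rest;
* identifiability — the state is re-projected onto the constrained
  parameterization after every sweep (likelihood-invariant on a connected
  graph).

Proposal scales adapt toward a target acceptance rate during burn-in only
(Robbins-Monro on the log scale), so the post-burn-in chain is a valid
fixed-kernel Markov chain.  Everything is reproducible given the per-chain
seeds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data import PanelData
from .graph import SpatialGraph, icar_quadform, rw1_quadform, path_graph
from .model import (HyperPriors, ModelConfig, ModelParams, apply_constraints,
                    initial_params, interaction_rank, linear_predictor_all,
                    log_prior)

logger = logging.getLogger(__name__)

FIELD_BLOCKS = ("u_s", "u_sk", "u_t", "u_tk", "nu")
ALL_BLOCKS = ("alpha", "beta_s", "beta_st", "gamma_s", "gamma_t",
              "precisions") + FIELD_BLOCKS


@dataclass
class ChainConfig:
    """Chain protocol; defaults follow the two-chain 80,000-iteration,
    4,000 burn-in scheme of the motivating analysis (thinning is ours)."""

    n_chains: int = 2
    n_iterations: int = 80_000
    burn_in: int = 4_000
    thin: int = 10
    seeds: tuple[int, ...] | None = None   # one per chain; derived if None
    base_seed: int = 0
    target_accept: float = 0.44            # scalar / single-site target
    adapt: bool = True
    fixed_blocks: tuple[str, ...] = ()     # blocks to hold at their initial value
    refresh_every: int = 1000              # recompute cached state (drift control)

    def __post_init__(self):
        if not 0 < self.burn_in < self.n_iterations:
            raise ValueError("need 0 < burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.n_chains:
            raise ValueError("need one seed per chain")
        unknown = set(self.fixed_blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")

    def chain_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [(self.base_seed + 7919 * c) % (2 ** 31) for c in
                range(self.n_chains)]

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws (chains x draws x ...) plus run metadata."""

    draws: dict[str, np.ndarray]
    acceptance: dict[str, float]
    seeds: list[int]
    config: ChainConfig
    model_config: ModelConfig
    outcomes: tuple[str, ...] = ()
    area_ids: tuple[str, ...] = ()
    periods: tuple = ()

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def stacked(self, name: str) -> np.ndarray:
        """Chains concatenated along the draw axis."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_names(self) -> list[str]:
        """Flattened names of every scalar parameter (for traces/diagnostics)."""
        out = []
        for name, a in self.draws.items():
            if name in ("u_sk", "u_tk", "nu", "u_s", "u_t", "log_posterior"):
                continue
            if a.ndim == 2:
                out.append(name)
            else:
                for idx in np.ndindex(a.shape[2:]):
                    out.append(f"{name}[{','.join(map(str, idx))}]")
        return out

    def scalar_series(self, name: str) -> np.ndarray:
        """(chains, draws) series for a flattened scalar-parameter name."""
        if "[" in name:
            base, idx = name[:-1].split("[")
            ix = tuple(int(t) for t in idx.split(","))
            return self.draws[base][(slice(None), slice(None)) + ix]
        a = self.draws[name]
        if a.ndim != 2:
            raise KeyError(f"{name} is not scalar; index it, e.g. {name}[0]")
        return a

    def params_at(self, chain: int, draw: int) -> ModelParams:
        d = self.draws
        return ModelParams(
            alpha=d["alpha"][chain, draw],
            beta_s=d["beta_s"][chain, draw], beta_st=d["beta_st"][chain, draw],
            gamma_s=d["gamma_s"][chain, draw], gamma_t=d["gamma_t"][chain, draw],
            u_s=d["u_s"][chain, draw], u_sk=d["u_sk"][chain, draw],
            u_t=d["u_t"][chain, draw], u_tk=d["u_tk"][chain, draw],
            nu=d["nu"][chain, draw],
            tau_us=d["tau_us"][chain, draw], tau_usk=d["tau_usk"][chain, draw],
            tau_ut=d["tau_ut"][chain, draw], tau_utk=d["tau_utk"][chain, draw],
            tau_nu=d["tau_nu"][chain, draw])

    def eta_draws(self, data: PanelData) -> np.ndarray:
        """Reconstruct the (chains, draws, N, J, K) logit surface."""
        d = self.draws
        C, D = self.n_chains, self.n_draws
        N, J, K = data.shape
        eta = np.broadcast_to(d["alpha"][:, :, None, None, :],
                              (C, D, N, J, K)).copy()
        if d["beta_s"].shape[-1] and data.X_s is not None:
            if d["beta_s"].ndim == 3:        # pooled (C, D, P)
                xb = np.einsum("ip,cdp->cdi", data.X_s, d["beta_s"])
                eta += xb[:, :, :, None, None]
            else:                            # outcome-specific (C, D, P, K)
                xb = np.einsum("ip,cdpk->cdik", data.X_s, d["beta_s"])
                eta += xb[:, :, :, None, :]
        if d["beta_st"].shape[-1] and data.X_st is not None:
            if d["beta_st"].ndim == 3:
                xb = np.einsum("ijq,cdq->cdij", data.X_st, d["beta_st"])
                eta += xb[:, :, :, :, None]
            else:
                xb = np.einsum("ijq,cdqk->cdijk", data.X_st, d["beta_st"])
                eta += xb
        eta += d["gamma_s"][:, :, None, None, :] * d["u_s"][:, :, :, None, None]
        eta += d["u_sk"][:, :, :, None, :]
        eta += d["gamma_t"][:, :, None, None, :] * d["u_t"][:, :, None, :, None]
        eta += d["u_tk"][:, :, None, :, :]
        eta += d["nu"][:, :, :, :, None]
        return eta

    def pi_draws(self, data: PanelData) -> np.ndarray:
        from scipy.special import expit
        return expit(self.eta_draws(data))


# ---------------------------------------------------------------------------
# one chain
# ---------------------------------------------------------------------------

class _ChainState:
    """Mutable per-chain state with cached logit and likelihood surfaces."""

    def __init__(self, data: PanelData, graph: SpatialGraph,
                 hyper: HyperPriors, mconf: ModelConfig, cconf: ChainConfig,
                 seed: int):
        self.data, self.graph = data, graph
        self.hyper, self.mconf, self.cconf = hyper, mconf, cconf
        self.rng = np.random.default_rng(seed)
        self.params = initial_params(data, config=mconf)
        N, J, K = data.shape
        self.N, self.J, self.K = N, J, K

        self.W = (data.observed_mask & (data.n[:, :, None] > 0)).astype(float)
        self.Yf = data.Y.astype(float) * self.W
        self.nf = np.broadcast_to(data.n[:, :, None], (N, J, K)).astype(float) \
            * self.W

        self.labels = graph.component_labels()
        self.adj = -graph.laplacian()
        np.fill_diagonal(self.adj, 0.0)
        self.deg = graph.n_neighbors.astype(float)
        self.single = np.array([len(c) == 1 for c in
                                sorted(graph.components, key=min)])
        self.is_single = np.zeros(N)
        for c in sorted(graph.components, key=min):
            if len(c) == 1:
                self.is_single[next(iter(c))] = 1.0
        self.rank_s = graph.rank + int(self.is_single.sum())
        col = graph.greedy_coloring()
        self.colors = [np.nonzero(col == c)[0] for c in range(col.max() + 1)]
        tcol = path_graph(J).greedy_coloring()
        self.tcolors = [np.nonzero(tcol == c)[0] for c in range(tcol.max() + 1)]
        # per-colour period neighbour structure (clipped indices + weights)
        self.tneigh = []
        for jdx in self.tcolors:
            jm, jp = np.clip(jdx - 1, 0, J - 1), np.clip(jdx + 1, 0, J - 1)
            wl = (jdx - 1 >= 0).astype(float)
            wr = (jdx + 1 <= J - 1).astype(float)
            self.tneigh.append((jm, jp, wl, wr, wl + wr))
        self.rank_nu = interaction_rank(N, J, mconf)

        # adaptive log step sizes and acceptance bookkeeping
        self.lstep = {b: np.log(0.1) for b in ALL_BLOCKS if b != "precisions"}
        self.acc_n = {b: 0 for b in self.lstep}
        self.acc_a = {b: 0 for b in self.lstep}
        self.refresh()
        if not np.isfinite(self.llc).all():
            raise FloatingPointError(
                "non-finite initial log-likelihood (block: likelihood)")

    # -- cached surfaces ---------------------------------------------------

    def cell_ll(self, eta):
        """Per-cell log-likelihood kernel (binomial, constant dropped)."""
        return self.Yf * eta - self.nf * np.logaddexp(0.0, eta)

    def refresh(self):
        self.eta = linear_predictor_all(self.params, self.data)
        self.llc = self.cell_ll(self.eta)

    def loglik(self) -> float:
        return float(self.llc.sum())

    # -- adaptation --------------------------------------------------------

    def _adapt(self, block, accepted, proposed, sweep):
        self.acc_n[block] += proposed
        self.acc_a[block] += accepted
        if self.cconf.adapt and sweep <= self.cconf.burn_in and proposed:
            rate = accepted / proposed
            step = min(0.25, 5.0 * (sweep + 10) ** -0.7)
            self.lstep[block] += step * (rate - self.cconf.target_accept)
            self.lstep[block] = float(np.clip(self.lstep[block], -12, 6))

    def _step(self, block) -> float:
        return float(np.exp(self.lstep[block]))

    # -- block updates -----------------------------------------------------

    def update_precisions(self):
        p, h = self.params, self.hyper
        a, b = h.precision_shape, h.precision_rate

        def draw(rank, quad):
            return self.rng.gamma(a + 0.5 * rank, 1.0 / (b + 0.5 * quad))

        qs = float(icar_quadform(p.u_s, self.graph)
                   + np.sum(self.is_single * p.u_s ** 2))
        p.tau_us = draw(self.rank_s, qs)
        qsk = icar_quadform(p.u_sk, self.graph) \
            + self.is_single @ (p.u_sk ** 2)
        p.tau_usk = draw(self.rank_s, qsk)
        p.tau_ut = draw(self.J - 1, float(rw1_quadform(p.u_t)))
        p.tau_utk = draw(self.J - 1, rw1_quadform(p.u_tk))
        if self.mconf.interaction == "iid":
            qnu = float(np.sum(p.nu ** 2))
        else:
            qnu = float(np.sum(rw1_quadform(p.nu.T)))
        p.tau_nu = draw(self.rank_nu, qnu)

    def update_alpha(self, sweep):
        p = self.params
        d = self._step("alpha") * self.rng.standard_normal(self.K)
        etaP = self.eta + d[None, None, :]
        llP = self.cell_ll(etaP)
        dll = llP.sum(axis=(0, 1)) - self.llc.sum(axis=(0, 1))
        a_new, a_old = p.alpha + d, p.alpha
        dlp = -0.5 * (a_new ** 2 - a_old ** 2) / self.hyper.alpha_sd ** 2
        acc = np.log(self.rng.random(self.K)) < dll + dlp
        if acc.any():
            p.alpha[acc] += d[acc]
            self.eta[:, :, acc] = etaP[:, :, acc]
            self.llc[:, :, acc] = llP[:, :, acc]
        self._adapt("alpha", int(acc.sum()), self.K, sweep)

    def _update_beta_block(self, name, X, sweep):
        """Sequential scalar MH over coefficients (pooled across outcomes)."""
        p = self.params
        beta = getattr(p, name)
        if beta.size == 0:
            return
        shared = beta.ndim == 1
        P = beta.shape[0]
        n_acc = n_prop = 0
        for pp in range(P):
            if shared:
                d = self._step(name) * self.rng.standard_normal()
                if X.ndim == 2:      # X_s (N, P)
                    etaP = self.eta + d * X[:, pp][:, None, None]
                else:                # X_st (N, J, Q)
                    etaP = self.eta + d * X[:, :, pp][:, :, None]
                llP = self.cell_ll(etaP)
                dll = llP.sum() - self.llc.sum()
                dlp = -0.5 * ((beta[pp] + d) ** 2 - beta[pp] ** 2) \
                    / self.hyper.beta_sd ** 2
                n_prop += 1
                if np.log(self.rng.random()) < dll + dlp:
                    beta[pp] += d
                    self.eta, self.llc = etaP, llP
                    n_acc += 1
            else:                    # outcome-specific: parallel across k
                d = self._step(name) * self.rng.standard_normal(self.K)
                if X.ndim == 2:
                    etaP = self.eta + d[None, None, :] * X[:, pp][:, None, None]
                else:
                    etaP = self.eta + d[None, None, :] * X[:, :, pp][:, :, None]
                llP = self.cell_ll(etaP)
                dll = llP.sum(axis=(0, 1)) - self.llc.sum(axis=(0, 1))
                dlp = -0.5 * ((beta[pp] + d) ** 2 - beta[pp] ** 2) \
                    / self.hyper.beta_sd ** 2
                acc = np.log(self.rng.random(self.K)) < dll + dlp
                beta[pp, acc] += d[acc]
                self.eta[:, :, acc] = etaP[:, :, acc]
                self.llc[:, :, acc] = llP[:, :, acc]
                n_prop += self.K
                n_acc += int(acc.sum())
        self._adapt(name, n_acc, n_prop, sweep)

    def update_betas(self, sweep):
        if "beta_s" not in self.cconf.fixed_blocks and self.data.X_s is not None:
            self._update_beta_block("beta_s", self.data.X_s, sweep)
        if "beta_st" not in self.cconf.fixed_blocks \
                and self.data.X_st is not None:
            self._update_beta_block("beta_st", self.data.X_st, sweep)

    def _update_gamma(self, name, u, axis_field, sweep):
        """Parallel-across-outcomes MH on the scaling weights."""
        p = self.params
        gamma = getattr(p, name)
        literal = name == "gamma_s" and self.mconf.literal_spatial_constraint
        step = self._step(name)
        if literal:
            d = step * self.rng.standard_normal(self.K)
            g_new = gamma + d
            dlp = -0.5 * (g_new ** 2 - gamma ** 2)        # N(0,1) prior
        else:
            d = step * self.rng.standard_normal(self.K)
            g_new = gamma * np.exp(d)
            lg, lg_new = np.log(gamma), np.log(g_new)
            dlp = -0.5 * (lg_new ** 2 - lg ** 2) / self.hyper.log_gamma_sd ** 2
        dg = g_new - gamma
        if axis_field == "space":
            etaP = self.eta + dg[None, None, :] * u[:, None, None]
        else:
            etaP = self.eta + dg[None, None, :] * u[None, :, None]
        llP = self.cell_ll(etaP)
        dll = llP.sum(axis=(0, 1)) - self.llc.sum(axis=(0, 1))
        acc = np.log(self.rng.random(self.K)) < dll + dlp
        if acc.any():
            gamma[acc] = g_new[acc]
            self.eta[:, :, acc] = etaP[:, :, acc]
            self.llc[:, :, acc] = llP[:, :, acc]
        self._adapt(name, int(acc.sum()), self.K, sweep)

    def update_gammas(self, sweep):
        if "gamma_s" not in self.cconf.fixed_blocks:
            self._update_gamma("gamma_s", self.params.u_s, "space", sweep)
        if "gamma_t" not in self.cconf.fixed_blocks:
            self._update_gamma("gamma_t", self.params.u_t, "time", sweep)

    def update_u_s(self, sweep):
        p = self.params
        step = self._step("u_s")
        n_acc = n_prop = 0
        for idx in self.colors:
            s = (self.adj @ p.u_s)[idx]
            u_old = p.u_s[idx]
            du = step * self.rng.standard_normal(len(idx))
            u_new = u_old + du
            dquad = (self.deg[idx] + self.is_single[idx]) \
                * (u_new ** 2 - u_old ** 2) - 2.0 * s * du
            dlp = -0.5 * p.tau_us * dquad
            etaP = self.eta[idx] + du[:, None, None] * p.gamma_s[None, None, :]
            llP = self.Yf[idx] * etaP - self.nf[idx] * np.logaddexp(0.0, etaP)
            dll = llP.sum(axis=(1, 2)) - self.llc[idx].sum(axis=(1, 2))
            acc = np.log(self.rng.random(len(idx))) < dll + dlp
            rows = idx[acc]
            p.u_s[rows] += du[acc]
            self.eta[rows] = etaP[acc]
            self.llc[rows] = llP[acc]
            n_prop += len(idx)
            n_acc += int(acc.sum())
        self._adapt("u_s", n_acc, n_prop, sweep)

    def update_u_sk(self, sweep):
        p = self.params
        step = self._step("u_sk")
        n_acc = n_prop = 0
        for idx in self.colors:
            s = (self.adj @ p.u_sk)[idx]                     # (n_c, K)
            u_old = p.u_sk[idx]
            du = step * self.rng.standard_normal(u_old.shape)
            u_new = u_old + du
            dquad = (self.deg[idx] + self.is_single[idx])[:, None] \
                * (u_new ** 2 - u_old ** 2) - 2.0 * s * du
            dlp = -0.5 * p.tau_usk[None, :] * dquad
            etaP = self.eta[idx] + du[:, None, :]
            llP = self.Yf[idx] * etaP - self.nf[idx] * np.logaddexp(0.0, etaP)
            dll = llP.sum(axis=1) - self.llc[idx].sum(axis=1)  # (n_c, K)
            acc = np.log(self.rng.random(u_old.shape)) < dll + dlp
            if acc.any():
                p.u_sk[idx] = np.where(acc, u_new, u_old)
                am = acc[:, None, :]
                self.eta[idx] = np.where(am, etaP, self.eta[idx])
                self.llc[idx] = np.where(am, llP, self.llc[idx])
            n_prop += acc.size
            n_acc += int(acc.sum())
        self._adapt("u_sk", n_acc, n_prop, sweep)

    def _temporal_prior_terms(self, series, color):
        """Path-graph neighbour sums and degrees for a period colour class."""
        jm, jp, wl, wr, deg = self.tneigh[color]
        if series.ndim == 1:
            s = wl * series[jm] + wr * series[jp]
        else:
            s = wl[:, None] * series[jm] + wr[:, None] * series[jp]
        return s, deg

    def update_u_t(self, sweep):
        p = self.params
        step = self._step("u_t")
        n_acc = n_prop = 0
        for color, jdx in enumerate(self.tcolors):
            s, deg = self._temporal_prior_terms(p.u_t, color)
            u_old = p.u_t[jdx]
            du = step * self.rng.standard_normal(len(jdx))
            u_new = u_old + du
            dlp = -0.5 * p.tau_ut * (deg * (u_new ** 2 - u_old ** 2)
                                     - 2.0 * s * du)
            etaP = self.eta[:, jdx, :] + p.gamma_t[None, None, :] \
                * du[None, :, None]
            llP = self.Yf[:, jdx, :] * etaP \
                - self.nf[:, jdx, :] * np.logaddexp(0.0, etaP)
            dll = llP.sum(axis=(0, 2)) - self.llc[:, jdx, :].sum(axis=(0, 2))
            acc = np.log(self.rng.random(len(jdx))) < dll + dlp
            cols = jdx[acc]
            p.u_t[cols] += du[acc]
            self.eta[:, cols, :] = etaP[:, acc, :]
            self.llc[:, cols, :] = llP[:, acc, :]
            n_prop += len(jdx)
            n_acc += int(acc.sum())
        self._adapt("u_t", n_acc, n_prop, sweep)

    def update_u_tk(self, sweep):
        p = self.params
        step = self._step("u_tk")
        n_acc = n_prop = 0
        for color, jdx in enumerate(self.tcolors):
            s, deg = self._temporal_prior_terms(p.u_tk, color)   # (n_c, K)
            u_old = p.u_tk[jdx]
            du = step * self.rng.standard_normal(u_old.shape)
            u_new = u_old + du
            dlp = -0.5 * p.tau_utk[None, :] * (
                deg[:, None] * (u_new ** 2 - u_old ** 2) - 2.0 * s * du)
            etaP = self.eta[:, jdx, :] + du[None, :, :]
            llP = self.Yf[:, jdx, :] * etaP \
                - self.nf[:, jdx, :] * np.logaddexp(0.0, etaP)
            dll = llP.sum(axis=0) - self.llc[:, jdx, :].sum(axis=0)
            acc = np.log(self.rng.random(u_old.shape)) < dll + dlp
            if acc.any():
                p.u_tk[jdx] = np.where(acc, u_new, u_old)
                am = acc[None, :, :]
                self.eta[:, jdx, :] = np.where(am, etaP, self.eta[:, jdx, :])
                self.llc[:, jdx, :] = np.where(am, llP, self.llc[:, jdx, :])
            n_prop += acc.size
            n_acc += int(acc.sum())
        self._adapt("u_tk", n_acc, n_prop, sweep)

    def update_nu(self, sweep):
        p = self.params
        step = self._step("nu")
        if self.mconf.interaction == "iid":
            du = step * self.rng.standard_normal((self.N, self.J))
            nu_new = p.nu + du
            dlp = -0.5 * p.tau_nu * (nu_new ** 2 - p.nu ** 2)
            etaP = self.eta + du[:, :, None]
            llP = self.cell_ll(etaP)
            dll = llP.sum(axis=2) - self.llc.sum(axis=2)
            acc = np.log(self.rng.random((self.N, self.J))) < dll + dlp
            if acc.any():
                p.nu = np.where(acc, nu_new, p.nu)
                am = acc[:, :, None]
                self.eta = np.where(am, etaP, self.eta)
                self.llc = np.where(am, llP, self.llc)
            self._adapt("nu", int(acc.sum()), acc.size, sweep)
            return
        # Type II: independent RW1 per area; colour the period path
        n_acc = n_prop = 0
        for color, jdx in enumerate(self.tcolors):
            jm, jp, wl, wr, deg = self.tneigh[color]
            s = wl[None, :] * p.nu[:, jm] + wr[None, :] * p.nu[:, jp]
            old = p.nu[:, jdx]
            du = step * self.rng.standard_normal(old.shape)
            new = old + du
            dlp = -0.5 * p.tau_nu * (deg[None, :] * (new ** 2 - old ** 2)
                                     - 2.0 * s * du)
            etaP = self.eta[:, jdx, :] + du[:, :, None]
            llP = self.Yf[:, jdx, :] * etaP \
                - self.nf[:, jdx, :] * np.logaddexp(0.0, etaP)
            dll = llP.sum(axis=2) - self.llc[:, jdx, :].sum(axis=2)
            acc = np.log(self.rng.random(old.shape)) < dll + dlp
            if acc.any():
                p.nu[:, jdx] = np.where(acc, new, old)
                am = acc[:, :, None]
                self.eta[:, jdx, :] = np.where(am, etaP, self.eta[:, jdx, :])
                self.llc[:, jdx, :] = np.where(am, llP, self.llc[:, jdx, :])
            n_prop += acc.size
            n_acc += int(acc.sum())
        self._adapt("nu", n_acc, n_prop, sweep)

    # -- sweep -------------------------------------------------------------

    def sweep(self, t: int):
        fixed = self.cconf.fixed_blocks
        if "precisions" not in fixed:
            self.update_precisions()
        if "alpha" not in fixed:
            self.update_alpha(t)
        self.update_betas(t)
        self.update_gammas(t)
        if "u_s" not in fixed:
            self.update_u_s(t)
        if "u_sk" not in fixed:
            self.update_u_sk(t)
        if "u_t" not in fixed:
            self.update_u_t(t)
        if "u_tk" not in fixed:
            self.update_u_tk(t)
        if "nu" not in fixed:
            self.update_nu(t)
        self.params = apply_constraints(self.params, self.graph, self.mconf,
                                        labels=self.labels)
        if t % self.cconf.refresh_every == 0:
            self.refresh()

    def acceptance_rates(self) -> dict[str, float]:
        return {b: (self.acc_a[b] / self.acc_n[b]) if self.acc_n[b] else np.nan
                for b in self.lstep}


def run_chains(data: PanelData, graph: SpatialGraph,
               hyper: HyperPriors | None = None,
               config: ChainConfig | None = None,
               model_config: ModelConfig | None = None,
               progress: bool = False) -> PosteriorSamples:
    """Run the full multi-chain protocol and collect retained draws."""
    hyper = hyper or HyperPriors()
    config = config or ChainConfig()
    mconf = model_config or ModelConfig()
    seeds = config.chain_seeds()
    record_names = ["alpha", "beta_s", "beta_st", "gamma_s", "gamma_t",
                    "u_s", "u_sk", "u_t", "u_tk", "nu",
                    "tau_us", "tau_usk", "tau_ut", "tau_utk", "tau_nu"]
    chains: dict[str, list] = {n: [] for n in record_names + ["log_posterior"]}
    acc_all: dict[str, float] = {}
    for c, seed in enumerate(seeds):
        state = _ChainState(data, graph, hyper, mconf, config, seed)
        per_draw: dict[str, list] = {n: [] for n in chains}
        for t in range(1, config.n_iterations + 1):
            state.sweep(t)
            if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
                p = state.params
                for n in record_names:
                    v = getattr(p, n)
                    per_draw[n].append(np.copy(v) if isinstance(v, np.ndarray)
                                       else float(v))
                per_draw["log_posterior"].append(
                    state.loglik() + log_prior(p, graph, hyper, mconf))
            if progress and t % 5000 == 0:
                logger.info("chain %d sweep %d loglik %.1f", c, t,
                            state.loglik())
        for n in chains:
            chains[n].append(np.asarray(per_draw[n]))
        rates = state.acceptance_rates()
        for b, r in rates.items():
            acc_all[f"chain{c}:{b}"] = r
            if np.isfinite(r) and not 0.05 <= r <= 0.95:
                warnings.warn(
                    f"acceptance rate {r:.3f} for block {b} (chain {c}) "
                    "outside [0.05, 0.95] after adaptation")
    draws = {n: np.stack(chains[n]) for n in chains}
    return PosteriorSamples(
        draws=draws, acceptance=acc_all, seeds=seeds, config=config,
        model_config=mconf, outcomes=tuple(data.outcomes),
        area_ids=tuple(data.area_ids), periods=tuple(data.periods))


# ---------------------------------------------------------------------------
# sklearn-style front end
# ---------------------------------------------------------------------------

class SharedComponentModel(BaseEstimator):
    """Sklearn-style estimator for the joint shared-component model.

    Parameters mirror the chain protocol and model switches; ``fit`` runs
    the sampler and exposes the posterior in ``samples_``.

    Examples
    --------
    >>> from apomap.simulate import GeneratorConfig, generate_dataset
    >>> data, graph, truth = generate_dataset(
    ...     GeneratorConfig(n_rows=4, n_cols=4), seed=1)
    >>> m = SharedComponentModel(n_iterations=2000, burn_in=500, thin=5,
    ...                          random_state=1).fit(data, graph)
    >>> m.samples_.n_draws
    300
    """

    def __init__(self, n_chains: int = 2, n_iterations: int = 80_000,
                 burn_in: int = 4_000, thin: int = 10, random_state: int = 0,
                 target_accept: float = 0.44, interaction: str = "iid",
                 share_coefficients: bool = True,
                 literal_spatial_constraint: bool = False,
                 hyper: HyperPriors | None = None,
                 fixed_blocks: tuple = (), progress: bool = False):
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.target_accept = target_accept
        self.interaction = interaction
        self.share_coefficients = share_coefficients
        self.literal_spatial_constraint = literal_spatial_constraint
        self.hyper = hyper
        self.fixed_blocks = fixed_blocks
        self.progress = progress

    def _configs(self) -> tuple[ChainConfig, ModelConfig]:
        return (ChainConfig(n_chains=self.n_chains,
                            n_iterations=self.n_iterations,
                            burn_in=self.burn_in, thin=self.thin,
                            base_seed=self.random_state,
                            target_accept=self.target_accept,
                            fixed_blocks=tuple(self.fixed_blocks)),
                ModelConfig(
                    literal_spatial_constraint=self.literal_spatial_constraint,
                    interaction=self.interaction,
                    share_coefficients=self.share_coefficients))

    def fit(self, data: PanelData, graph: SpatialGraph):
        cconf, mconf = self._configs()
        self.samples_ = run_chains(data, graph, self.hyper or HyperPriors(),
                                   cconf, mconf, progress=self.progress)
        self.acceptance_ = self.samples_.acceptance
        self.data_ = data
        self.graph_ = graph
        return self

    def predict_pi(self, data: PanelData | None = None) -> np.ndarray:
        """Posterior-median risk surface (N, J, K)."""
        self._check_fitted()
        pi = self.samples_.pi_draws(data or self.data_)
        return np.median(pi.reshape(-1, *pi.shape[2:]), axis=0)

    def predict_rate(self, scale: float = 100.0,
                     data: PanelData | None = None) -> np.ndarray:
        """Posterior-median model-based rate per ``scale`` live births."""
        return scale * self.predict_pi(data)

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise AttributeError("estimator is not fitted; call fit first")
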