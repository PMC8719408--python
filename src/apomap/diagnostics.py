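"""Convergence and stability diagnostics for the posterior chains.

Implements the classic (non-split, non-rank-normalized) Gelman-Rubin
potential scale reduction factor

    R-hat = sqrt( ((n-1)/n * W + B/n) / W )

with W the mean within-chain variance and B/n the sample variance of the
chain means, and the batch-means Monte-Carlo standard error with the
"MC error / SD < 5%" chain-precision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _series(samples, parameter):
    if parameter is not None:
        return np.asarray(samples.scalar_series(parameter), dtype=float)
    return np.atleast_2d(np.asarray(samples, dtype=float))


def gelman_rubin(samples, parameter: str | None = None) -> float:
    """Potential scale reduction factor over >= 2 chains.

    ``samples`` may be a PosteriorSamples (with ``parameter`` naming a
    scalar, e.g. ``"alpha[0]"``) or a (chains, draws) array.
    """
    x = _series(samples, parameter)
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 2:
        raise ValueError("need at least 2 retained draws per chain")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    var_means = float(np.var(np.mean(x, axis=1), ddof=1))   # = B/n
    if W == 0.0:
        return 1.0 if var_means == 0.0 else np.inf
    v_hat = (n - 1) / n * W + var_means
    return float(np.sqrt(v_hat / W))


@dataclass
class MCErrorResult:
    mc_error: float
    sd: float
    ratio: float
    passed: bool
    degenerate: bool = False


def mc_error_check(samples, parameter: str | None = None,
                   threshold: float = 0.05) -> MCErrorResult:
    """Batch-means MC standard error vs posterior SD.

    Chains are concatenated; the draw sequence is cut into floor(sqrt(n))
    batches and the MC error is sd(batch means)/sqrt(#batches).  A constant
    chain is flagged degenerate and fails.
    """
    x = _series(samples, parameter).ravel()
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 retained draws")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return MCErrorResult(0.0, 0.0, np.inf, False, degenerate=True)
    nb = int(np.floor(np.sqrt(n)))
    bs = n // nb
    means = x[:nb * bs].reshape(nb, bs).mean(axis=1)
    mce = float(np.std(means, ddof=1) / np.sqrt(nb))
    ratio = mce / sd
    return MCErrorResult(mce, sd, ratio, bool(ratio < threshold))


def convergence_report(samples, rhat_threshold: float = 1.1):
    """Per-scalar-parameter R-hat and MC-error table.

    The R-hat < 1.1 convergence flag is this package's choice of cut-off.
    """
    import pandas as pd
    rows = []
    for name in samples.scalar_names():
        x = samples.scalar_series(name)
        r = gelman_rubin(x) if x.shape[0] >= 2 else np.nan
        mc = mc_error_check(x)
        rows.append({"parameter": name, "rhat": r,
                     "converged": bool(r < rhat_threshold),
                     "mc_error": mc.mc_error, "sd": mc.sd,
                     "mc_ratio": mc.ratio, "mc_pass": mc.passed})
    return pd.DataFrame(rows)


def export_traces(samples, out_dir, parameters=None, max_per_page: int = 16):
    """Write trace plots (one panel per scalar parameter) as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(parameters or samples.scalar_names())
    written = []
    for start in range(0, len(names), max_per_page):
        chunk = names[start:start + max_per_page]
        ncol = 4
        nrow = int(np.ceil(len(chunk) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow),
                                 squeeze=False)
        for ax, name in zip(axes.ravel(), chunk):
            for ch in samples.scalar_series(name):
                ax.plot(ch, lw=0.5)
            ax.set_title(name, fontsize=8)
        for ax in axes.ravel()[len(chunk):]:
            ax.axis("off")
        fig.tight_layout()
        path = out_dir / f"traces_{start // max_per_page:02d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
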