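"""MCMC convergence and mixing diagnostics.

Implements the modern (rank-normalized, split-chain) variants of R-hat and
bulk/tail effective sample size, plus lag autocorrelations with Geyer's
initial-monotone-positive-sequence truncation, and a threshold-based
convergence report (R-hat <= 1.01, both ESS >= 1,000 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .inference import ChainSet

__all__ = [
    "DiagnosticsSummary",
    "split_chains",
    "rank_normalize",
    "split_rhat",
    "ess_bulk",
    "ess_tail",
    "autocorr",
    "convergence_report",
]


def _as_array(chains: Union[ChainSet, np.ndarray]) -> np.ndarray:
    if isinstance(chains, ChainSet):
        arr = chains.draws
    else:
        arr = np.asarray(chains, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("draws must be a (chains, iterations) array")
    return arr


def split_chains(draws: np.ndarray) -> np.ndarray:
    """Split each chain in half, yielding 2m half-chains of length n//2."""
    m, n = draws.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain to split")
    return np.vstack([draws[:, :half], draws[:, n - half :]])


def rank_normalize(draws: np.ndarray) -> np.ndarray:
    """Map pooled draws to normal scores via fractional ranks.

    Ranks (average ties) over all chains jointly are transformed with the
    inverse normal CDF of (r - 3/8) / (S + 1/4).
    """
    shape = draws.shape
    flat = draws.reshape(-1)
    ranks = stats.rankdata(flat, method="average")
    z = ndtri((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(shape)


def _rhat_basic(chains2d: np.ndarray) -> float:
    """Classic R-hat on already-split (and possibly transformed) chains."""
    m, n = chains2d.shape
    within = chains2d.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0 or not np.isfinite(w):
        return float("nan")
    if m < 2:
        return float("nan")
    b = n * chains2d.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(chains: Union[ChainSet, np.ndarray]) -> float:
    """Rank-normalized split R-hat.

    Returns NaN (an "undefined" flag, treated as non-convergence) when the
    draws are constant or only one half-chain pair exists.
    """
    draws = _as_array(chains)
    if np.ptp(draws) == 0:
        return float("nan")
    return _rhat_basic(rank_normalize(split_chains(draws)))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased (1/N) autocovariance of each row via FFT."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), size, axis=1)[:, :n].real
    return acov / n


def _ess_from_chains(chains2d: np.ndarray) -> float:
    """Effective sample size of split (possibly transformed) chains.

    Multi-chain autocorrelations are combined through the within/between
    variance decomposition and summed under Geyer's initial monotone
    positive sequence; the result is capped at the total draw count.
    """
    m, n = chains2d.shape
    if np.ptp(chains2d) == 0:
        return float("nan")
    acov = _autocov(chains2d)
    chain_var = acov[:, 0] * n / (n - 1)
    w = chain_var.mean()
    var_plus = w * (n - 1) / n
    if m > 1:
        var_plus += chains2d.mean(axis=1).var(ddof=1)
    if var_plus == 0:
        return float("nan")

    rho = np.zeros(n)
    rho[0] = 1.0
    mean_acov = acov.mean(axis=0)
    # Geyer pairs: accumulate while the paired sums stay positive
    rho_even = 1.0
    rho_odd = 1.0 - (w - mean_acov[1]) / var_plus
    rho[1] = rho_odd
    t = 1
    while t < n - 3 and (rho_even + rho_odd) > 0:
        rho_even = 1.0 - (w - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (w - mean_acov[t + 2]) / var_plus
        if rho_even + rho_odd >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho[max_t + 1] = rho_even
    # enforce monotone non-increasing pair sums
    t = 1
    while t <= max_t - 2:
        if rho[t + 1] + rho[t + 2] > rho[t - 1] + rho[t]:
            rho[t + 1] = (rho[t - 1] + rho[t]) / 2.0
            rho[t + 2] = rho[t + 1]
        t += 2
    tau = -1.0 + 2.0 * rho[: max_t + 1].sum() + rho[max_t + 1]
    tau = max(tau, 1.0 / np.log10(m * n))
    return float(min(m * n / tau, m * n))


def ess_bulk(chains: Union[ChainSet, np.ndarray]) -> float:
    """Bulk ESS: ESS of the rank-normalized split chains."""
    draws = _as_array(chains)
    return _ess_from_chains(rank_normalize(split_chains(draws)))


def ess_tail(chains: Union[ChainSet, np.ndarray]) -> float:
    """Tail ESS: the smaller of the 5% and 95% quantile-indicator ESSs."""
    draws = _as_array(chains)
    out = []
    for prob in (0.05, 0.95):
        q = np.quantile(draws, prob)
        indicator = (draws <= q).astype(float)
        out.append(_ess_from_chains(rank_normalize(split_chains(indicator))))
    return float(min(out))


def autocorr(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation of one chain at lags 0..max_lag (biased normalization)."""
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1:
        raise ValueError("autocorr expects a single chain")
    n = chain.size
    if max_lag >= n:
        raise ValueError(f"max_lag must be < chain length ({n})")
    acov = _autocov(chain[None, :])[0]
    if acov[0] == 0:  # constant chain: correlation undefined beyond lag 0
        out = np.full(max_lag + 1, np.nan)
        out[0] = 1.0
        return out
    return acov[: max_lag + 1] / acov[0]


@dataclass
class DiagnosticsSummary:
    """Convergence report for one ChainSet."""

    rhat: float
    ess_bulk: float
    ess_tail: float
    acf: np.ndarray
    converged: bool
    reasons: list = field(default_factory=list)
    trace_summary: Optional[np.ndarray] = None  # per-chain windowed means
    density_grid: Optional[tuple] = None  # (grid, density)

    def to_dict(self) -> dict:
        return {
            "rhat": None if np.isnan(self.rhat) else round(self.rhat, 4),
            "ess_bulk": None if np.isnan(self.ess_bulk) else round(self.ess_bulk, 1),
            "ess_tail": None if np.isnan(self.ess_tail) else round(self.ess_tail, 1),
            "converged": self.converged,
            "reasons": list(self.reasons),
        }


def _trace_summary(draws: np.ndarray, n_windows: int = 50) -> np.ndarray:
    m, n = draws.shape
    n_windows = min(n_windows, n)
    edges = np.linspace(0, n, n_windows + 1, dtype=int)
    return np.column_stack(
        [draws[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])]
    )


def convergence_report(
    chains: Union[ChainSet, np.ndarray],
    rhat_threshold: float = 1.01,
    ess_floor: float = 1000.0,
    max_lag: int = 50,
) -> DiagnosticsSummary:
    """Threshold-based pass/fail convergence report.

    converged = (R-hat <= threshold) and (bulk ESS >= floor) and
    (tail ESS >= floor); an undefined (NaN) R-hat counts as failure.
    Also emits per-chain windowed trace means and a kernel-density grid of
    the pooled draws for render-free plotting.
    """
    draws = _as_array(chains)
    rhat = split_rhat(draws)
    bulk = ess_bulk(draws) if draws.shape[1] >= 4 else float("nan")
    tail = ess_tail(draws) if draws.shape[1] >= 4 else float("nan")
    acf = autocorr(draws[0], min(max_lag, draws.shape[1] - 1))

    reasons = []
    if not np.isfinite(rhat):
        reasons.append("R-hat undefined (constant or degenerate chains)")
    elif rhat > rhat_threshold:
        reasons.append(f"R-hat {rhat:.3f} > {rhat_threshold}")
    if not np.isfinite(bulk) or bulk < ess_floor:
        reasons.append(f"bulk ESS {bulk:.0f} < {ess_floor:.0f}")
    if not np.isfinite(tail) or tail < ess_floor:
        reasons.append(f"tail ESS {tail:.0f} < {ess_floor:.0f}")

    pooled = draws.reshape(-1)
    if np.ptp(pooled) > 0:
        kde = stats.gaussian_kde(pooled)
        grid = np.linspace(pooled.min(), pooled.max(), 200)
        density = (grid, kde(grid))
    else:
        density = None

    return DiagnosticsSummary(
        rhat=rhat,
        ess_bulk=bulk,
        ess_tail=tail,
        acf=acf,
        converged=len(reasons) == 0,
        reasons=reasons,
        trace_summary=_trace_summary(draws),
        density_grid=density,
    )
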