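"""Posterior prevalence three ways: exact conjugate, MCMC, and frequentist.

The model is an intercept-only Bernoulli likelihood on the prevalence theta
with identity parameterization and a beta prior, so the posterior is the
closed-form Beta(alpha + k, beta + n - k). The MCMC route samples the same
posterior with an adaptive random-walk Metropolis chain on the logit scale;
its only job is to be checkably equivalent in distribution to the closed
form while exposing realistic convergence behaviour. The frequentist route
is the identity-link binomial GLM solution: the sample proportion with a
Wald interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import betaln, expit, logit

from .ascertainment import CountData
from .priors import BetaParams, beta_stats

__all__ = [
    "McmcSettings",
    "ChainSet",
    "PrevalenceResult",
    "Z_975",
    "conjugate_posterior",
    "log_evidence",
    "posterior_summary",
    "mcmc_sample",
    "mcmc_summary",
    "frequentist_prevalence",
    "format_percent_whole",
    "format_percent_decimal",
]

#: 97.5% standard-normal quantile, fixed for bit-stable Wald intervals.
Z_975 = 1.959964

#: Optimal acceptance rate for scalar random-walk Metropolis.
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings. ``iterations`` is the total per chain including
    warm-up; retained draws per chain = floor((iterations - warmup) / thin)."""

    chains: int = 4
    iterations: int = 20_000
    warmup: int = 500
    thin: int = 5
    master_seed: int = 123
    proposal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (self.iterations > self.warmup >= 0):
            raise ValueError("need iterations > warmup >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")
        if self.retained_per_chain < 1:
            raise ValueError("settings retain fewer than one draw per chain")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin


@dataclass
class ChainSet:
    """Retained posterior draws, one row per chain, plus sampler metadata."""

    draws: np.ndarray  # shape (chains, retained), values in (0, 1)
    settings: McmcSettings
    acceptance_rate: np.ndarray  # per chain, post-warm-up

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1)


@dataclass
class PrevalenceResult:
    """One analysis row: point estimate, interval, SE and diagnostics."""

    method: str  # frequentist | conjugate | mcmc
    estimate: float
    interval: tuple[float, float]
    interval_type: str  # CI | CrI
    se: float
    diagnostics: Optional[object] = None
    formatted: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo <= self.estimate <= hi:
            raise ValueError("estimate must lie inside its interval")
        if (self.interval_type == "CI") != (self.method == "frequentist"):
            raise ValueError("CI is reserved for the frequentist method")


def format_percent_whole(x: float) -> str:
    """Bayesian reporting convention: percent to the nearest whole, printed
    with one decimal (0.58561 -> '59.0%')."""
    return f"{round(100 * x):.1f}%"


def format_percent_decimal(x: float) -> str:
    """Frequentist reporting convention: percent with one decimal."""
    return f"{100 * x:.1f}%"


def _bayes_formatted(mean: float, lo: float, hi: float) -> dict:
    return {
        "estimate": format_percent_whole(mean),
        "interval": f"({round(100 * lo):.1f}, {format_percent_whole(hi)})",
    }


def conjugate_posterior(prior: BetaParams, data: CountData) -> BetaParams:
    """Exact conjugate update: Beta(alpha + k, beta + n - k)."""
    return BetaParams(
        alpha=prior.alpha + data.k,
        beta=prior.beta + data.n - data.k,
        label=f"posterior[{prior.label or 'prior'} + {data.source_label or 'data'}]",
    )


def log_evidence(prior: BetaParams, data: CountData) -> float:
    """Log marginal likelihood of the ordered Bernoulli sequence.

    log P(D) = log B(alpha + k, beta + n - k) - log B(alpha, beta), computed
    in log space so no overflow is possible at any sample size.
    """
    a, b = prior.alpha, prior.beta
    return float(betaln(a + data.k, b + data.n - data.k) - betaln(a, b))


def posterior_summary(post: BetaParams, level: float = 0.95) -> PrevalenceResult:
    """Summarize an exact beta posterior: mean, equal-tailed CrI, sd."""
    s = beta_stats(post, level=level)
    return PrevalenceResult(
        method="conjugate",
        estimate=s["mean"],
        interval=(s["lo"], s["hi"]),
        interval_type="CrI",
        se=s["sd"],
        formatted=_bayes_formatted(s["mean"], s["lo"], s["hi"]),
    )


def _chain_rng(master_seed: int, chain: int) -> np.random.Generator:
    # stable per-chain seeding: independent streams from (master_seed, chain)
    return np.random.default_rng(np.random.SeedSequence([master_seed, chain]))


def mcmc_sample(
    prior: BetaParams, data: CountData, settings: McmcSettings
) -> ChainSet:
    """Adaptive random-walk Metropolis on eta = logit(theta).

    The target is the conjugate posterior density with the |dtheta/deta|
    Jacobian, so the unnormalized log density in eta is
    a*eta - (a + b)*log(1 + e^eta) with a = alpha + k, b = beta + n - k.
    The Gaussian proposal scale adapts during warm-up toward 0.44 acceptance
    (the scalar RWM optimum) via Robbins-Monro on the log scale, then is
    frozen so the retained chain is Markovian. Every ``thin``-th post-warm-up
    draw is kept, mapped back to theta.
    """
    a = prior.alpha + data.k
    b = prior.beta + data.n - data.k

    def logp(eta: float) -> float:
        return a * eta - (a + b) * np.logaddexp(0.0, eta)

    n_keep = settings.retained_per_chain
    all_draws = np.empty((settings.chains, n_keep))
    acc_rates = np.empty(settings.chains)

    for c in range(settings.chains):
        rng = _chain_rng(settings.master_seed, c)
        # overdispersed start: uniform on a wide prevalence range
        eta = float(logit(rng.uniform(0.05, 0.95)))
        lp = logp(eta)
        log_scale = math.log(settings.proposal_scale)

        normals = rng.standard_normal(settings.iterations)
        log_us = np.log(rng.random(settings.iterations))

        kept = 0
        accepted_post = 0
        for t in range(settings.iterations):
            prop = eta + math.exp(log_scale) * normals[t]
            lp_prop = logp(prop)
            log_alpha = min(0.0, lp_prop - lp)
            if log_us[t] < log_alpha:
                eta, lp = prop, lp_prop
            if t < settings.warmup:
                # Robbins-Monro step toward the target acceptance rate
                log_scale += (math.exp(log_alpha) - _TARGET_ACCEPT) / (t + 1) ** 0.6
            else:
                s = t - settings.warmup
                if s % settings.thin == 0 and kept < n_keep:
                    all_draws[c, kept] = expit(eta)
                    kept += 1
                accepted_post += log_us[t] < log_alpha
        post_iters = settings.iterations - settings.warmup
        acc_rates[c] = accepted_post / post_iters if post_iters else float("nan")
        if acc_rates[c] == 0.0:
            raise RuntimeError(
                f"chain {c} rejected every post-warm-up proposal; sampler failed"
            )

    return ChainSet(draws=all_draws, settings=settings, acceptance_rate=acc_rates)


def mcmc_summary(
    chains: ChainSet, level: float = 0.95, diagnostics: Optional[object] = None
) -> PrevalenceResult:
    """Summarize pooled MCMC draws: mean, equal-tailed percentile CrI, sd."""
    pooled = chains.pooled()
    tail = (1 - level) / 2
    lo, hi = np.quantile(pooled, [tail, 1 - tail])
    mean = float(pooled.mean())
    return PrevalenceResult(
        method="mcmc",
        estimate=mean,
        interval=(float(lo), float(hi)),
        interval_type="CrI",
        se=float(pooled.std(ddof=1)),
        diagnostics=diagnostics,
        formatted=_bayes_formatted(mean, lo, hi),
    )


def frequentist_prevalence(data: CountData, level: float = 0.95) -> PrevalenceResult:
    """Intercept-only identity-link binomial GLM, in closed form.

    The MLE is the sample proportion k/n with Wald interval
    p +/- z * sqrt(p(1-p)/n), truncated to [0, 1]. At k = 0 or k = n the
    Wald interval is degenerate (se = 0); the estimate is still returned,
    with the degeneracy flagged rather than raised.
    """
    p = data.k / data.n
    se = math.sqrt(p * (1 - p) / data.n)
    if level == 0.95:
        z = Z_975
    else:
        from scipy import stats

        z = float(stats.norm.ppf(1 - (1 - level) / 2))
    lo = max(0.0, p - z * se)
    hi = min(1.0, p + z * se)
    flags = []
    if data.k in (0, data.n):
        flags.append("degenerate Wald interval: k on the boundary, se = 0")
    return PrevalenceResult(
        method="frequentist",
        estimate=p,
        interval=(lo, hi),
        interval_type="CI",
        se=se,
        formatted={
            "estimate": format_percent_decimal(p),
            "interval": f"({format_percent_decimal(lo)[:-1]}, {format_percent_decimal(hi)})",
        },
        flags=flags,
    )
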