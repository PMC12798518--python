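"""Beta prior elicitation from administrative case counts.

An administrative source that ascertained k cases among n persons is turned
into a Beta(k + 1, n - k + 1) prior on prevalence: the counts act as
pseudo-observations on top of the uniform Beta(1, 1), which is also exposed
directly as the non-informative default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .ascertainment import CountData

__all__ = ["BetaParams", "elicit_informative", "noninformative", "beta_stats"]


@dataclass(frozen=True)
class BetaParams:
    """Parameters (alpha, beta) of a beta distribution on (0, 1).

    Serves both as prior and as exact conjugate posterior; ``label`` records
    which data source the parameters were elicited from.
    """

    alpha: float
    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"alpha and beta must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def to_dict(self) -> dict:
        return {"label": self.label, "alpha": self.alpha, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaParams":
        return cls(alpha=d["alpha"], beta=d["beta"], label=d.get("label", ""))


def elicit_informative(counts: CountData) -> BetaParams:
    """Informative prior from administrative counts: alpha=k+1, beta=n-k+1."""
    return BetaParams(
        alpha=counts.k + 1,
        beta=counts.n - counts.k + 1,
        label=counts.source_label or f"counts(n={counts.n}, k={counts.k})",
    )


def noninformative() -> BetaParams:
    """Uniform Beta(1, 1): equal density everywhere on (0, 1)."""
    return BetaParams(alpha=1.0, beta=1.0, label="non-informative")


def beta_stats(p: BetaParams, level: float = 0.95) -> dict:
    """Exact mean, sd and equal-tailed quantiles of a beta distribution.

    The interval cuts (1 - level)/2 probability from each tail using the
    exact inverse CDF. Raises if the quantile solver fails to return finite
    probabilities.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1 - level) / 2
    lo, hi = stats.beta.ppf([tail, 1 - tail], p.alpha, p.beta)
    if not (math.isfinite(lo) and math.isfinite(hi) and 0 <= lo <= hi <= 1):
        raise ArithmeticError(
            f"beta quantile solver failed for alpha={p.alpha}, beta={p.beta}"
        )
    return {"mean": p.mean, "sd": p.sd, "lo": float(lo), "hi": float(hi)}
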