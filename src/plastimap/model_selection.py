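"""Information-criterion model comparison.

Machinery shared by every analysis arm: the small-sample Akaike information
criterion (AICc), the pairwise Akaike probability that the lower-AICc model
is the correct one of the two, and the conventional ``delta AICc > 2``
decision rule used to call a time course decisively nonlinear.

For two models whose AICc values differ by ``D`` (worse minus better), the
probability that the better model is correct is

    p = e^(D/2) / (1 + e^(D/2))

so ``D = 0`` gives even odds (0.5) and ``D = 2`` gives ~0.731.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.special import expit

__all__ = [
    "TRAJECTORY_SHAPES",
    "DECISIVE_DELTA_AICC",
    "ModelFit",
    "ModelComparison",
    "IncomparableFitsError",
    "aic",
    "aicc",
    "akaike_probability",
    "compare_trajectories",
    "comparison_table",
]

#: Candidate time-course families, from fewest to most curvature.
TRAJECTORY_SHAPES = ("linear", "asymptotic", "quadratic")

#: AICc margin beyond which the better model is considered decisively preferred.
DECISIVE_DELTA_AICC = 2.0


class IncomparableFitsError(ValueError):
    """Fits were obtained on different data and cannot share an AICc ranking."""


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, ``-2*logLik + 2k``."""
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    return -2.0 * float(log_likelihood) + 2.0 * k


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC.

    Parameters
    ----------
    log_likelihood : float
        Maximized log-likelihood of the fitted model.
    k : int
        Number of estimated parameters, counting every fitted mean parameter
        plus every variance/covariance component.
    n : int
        Number of observations the likelihood was evaluated on.

    Returns
    -------
    float
        ``AIC + 2k(k+1)/(n-k-1)``. The correction vanishes as ``n`` grows,
        so AICc converges to AIC from above.

    Raises
    ------
    ValueError
        If ``n <= k + 1``, where the correction is undefined (degenerate
        sample size for the requested model complexity).
    """
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n} observations with k={k} parameters "
            f"(requires n > k + 1)"
        )
    return aic(log_likelihood, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate model, carrying what AICc ranking needs.

    ``name`` is typically one of :data:`TRAJECTORY_SHAPES` but any label is
    accepted (the machinery is agnostic to what was fit).
    """

    name: str
    log_likelihood: float
    k: int
    n: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("model name must be nonempty")
        if self.k < 1:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.n < 1:
            raise ValueError(f"n must be positive, got {self.n}")
        if not math.isfinite(self.log_likelihood):
            raise ValueError(f"non-finite log-likelihood: {self.log_likelihood}")

    @property
    def aic(self) -> float:
        return aic(self.log_likelihood, self.k)

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of ranking candidate fits by AICc.

    ``delta_aicc`` is runner-up AICc minus preferred AICc (>= 0), and
    ``probability`` is the Akaike probability of the preferred model
    against the runner-up (in [0.5, 1]).
    """

    preferred: str
    runner_up: str
    delta_aicc: float
    probability: float

    @property
    def decisive(self) -> bool:
        """True when the preferred model wins by more than ΔAICc = 2."""
        return self.delta_aicc > DECISIVE_DELTA_AICC

    @property
    def probability_pct(self) -> float:
        """Preferred-model probability as a percentage, two decimals."""
        return round(100.0 * self.probability, 2)


def akaike_probability(aicc_reference: float, aicc_candidate: float) -> float:
    """Probability that the candidate model is correct, against a reference.

    ``D = AICc_reference - AICc_candidate``; positive ``D`` favors the
    candidate.  Returns ``e^(D/2) / (1 + e^(D/2))``; the two models'
    probabilities sum to one.
    """
    if not (math.isfinite(aicc_reference) and math.isfinite(aicc_candidate)):
        raise ValueError(
            f"AICc values must be finite, got ({aicc_reference}, {aicc_candidate})"
        )
    d = aicc_reference - aicc_candidate
    return float(expit(0.5 * d))


def compare_trajectories(fits: Iterable[ModelFit]) -> ModelComparison:
    """Rank candidate fits of the same data; lowest AICc wins.

    Ties in AICc are broken toward the simpler model (fewer parameters).
    The comparison is decisive when the runner-up trails by more than
    ΔAICc = 2.

    Raises
    ------
    IncomparableFitsError
        If fewer than two fits are given or the fits disagree on ``n``
        (they were not evaluated on identical data).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise IncomparableFitsError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise IncomparableFitsError(
            f"fits have mismatched numbers of observations: {sorted(ns)}"
        )
    ranked = sorted(fits, key=lambda f: (f.aicc, f.k, f.name))
    best, second = ranked[0], ranked[1]
    delta = second.aicc - best.aicc
    return ModelComparison(
        preferred=best.name,
        runner_up=second.name,
        delta_aicc=delta,
        probability=akaike_probability(second.aicc, best.aicc),
    )


def comparison_table(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Tabulate fits for reporting (one row per model, TSV-ready).

    Columns: model, k, n, logLik, AIC, AICc, deltaAICc (vs the best model),
    probability_pct (pairwise Akaike probability against the best model,
    percent to two decimals; the best model's row reads 50.00 against
    itself only when tied -- it is reported against the runner-up).
    """
    if len(fits) < 2:
        raise IncomparableFitsError("need at least two fits to tabulate")
    comp = compare_trajectories(fits)
    best_aicc = min(f.aicc for f in fits)
    rows = []
    for f in sorted(fits, key=lambda f: f.aicc):
        delta = f.aicc - best_aicc
        if f.name == comp.preferred:
            prob = comp.probability
        else:
            prob = 1.0 - akaike_probability(f.aicc, best_aicc)
        rows.append(
            {
                "model": f.name,
                "k": f.k,
                "n": f.n,
                "logLik": f.log_likelihood,
                "AIC": f.aic,
                "AICc": f.aicc,
                "deltaAICc": delta,
                "probability_pct": round(100.0 * prob, 2),
            }
        )
    return pd.DataFrame(rows)
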