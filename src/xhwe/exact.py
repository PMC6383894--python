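"""Exact finite-sample rejection probability by full enumeration.

The female genotype counts follow a trinomial(n1; pi1, pi2, pi3)
distribution and the male allele count an independent binomial(n2; pY).
The exact rejection probability of the equivalence test is the sum of the
outcome probabilities over the critical region:

    sum over (x1, x2, y) of  trinom(x1, x2) * binom(y) * 1{bound < epsilon}.

Outcomes with a zero cell among {x1, x2, x3, y, n2-y} leave the plug-in
estimate undefined; the engine's policy is that such outcomes never
reject (a conservative convention, validated against published exact
operating characteristics for rare-allele configurations).

Probability masses are computed in log space via log-gamma, so sample
sizes in the thousands are handled without overflow.  Enumeration is
vectorized over chunks of (x1, x2) pairs crossed with the full range of
y.  Optional pruning skips (x1, x2) pairs whose trinomial mass falls
below a threshold; the skipped mass bounds the induced error and is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._kernel import ucb_bound
from .equivtest import TestSettings
from .errors import DomainError
from .measures import FemaleGenotypeFreqs

__all__ = ["ExactResult", "exact_rejection_prob", "outcome_mass_total"]


@dataclass(frozen=True)
class ExactResult:
    """Exact rejection probability with enumeration diagnostics."""

    probability: float
    n_outcomes: int
    mass_enumerated: float
    pruned_mass_bound: float

    def __float__(self) -> float:
        return self.probability


def _valid_pairs(n1: int) -> tuple[np.ndarray, np.ndarray]:
    """All (x1, x2) with x1, x2, x3 = n1-x1-x2 all >= 1."""
    if n1 < 3:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    x1_vals = np.arange(1, n1 - 1)
    reps = n1 - 1 - x1_vals
    x1 = np.repeat(x1_vals, reps)
    x2 = np.concatenate([np.arange(1, n1 - v) for v in x1_vals])
    return x1, x2


def _trinomial_logpmf(
    x1: np.ndarray, x2: np.ndarray, n1: int, freqs: FemaleGenotypeFreqs
) -> np.ndarray:
    x3 = n1 - x1 - x2
    return (
        gammaln(n1 + 1)
        - gammaln(x1 + 1)
        - gammaln(x2 + 1)
        - gammaln(x3 + 1)
        + x1 * math.log(freqs.pi1)
        + x2 * math.log(freqs.pi2)
        + x3 * math.log(freqs.pi3)
    )


def _binomial_logpmf(y: np.ndarray, n2: int, pY: float) -> np.ndarray:
    return (
        gammaln(n2 + 1)
        - gammaln(y + 1)
        - gammaln(n2 - y + 1)
        + y * math.log(pY)
        + (n2 - y) * math.log1p(-pY)
    )


def exact_rejection_prob(
    freqs: FemaleGenotypeFreqs,
    pY: float,
    n1: int,
    n2: int,
    settings: TestSettings | None = None,
    *,
    prune: float = 0.0,
    chunk_size: int = 8192,
) -> ExactResult:
    """Exact probability that the equivalence test rejects (declares
    approximate HWE compatibility) under the given true configuration.

    Parameters
    ----------
    freqs, pY
        True female genotype frequencies and male allele frequency.
    n1, n2
        Numbers of genotyped females and males.
    settings
        Test settings (level, margin); defaults reproduce the standard
        alpha = 0.05, epsilon = sqrt(2) log 1.4 specification.
    prune
        Skip (x1, x2) pairs whose trinomial mass is below this
        threshold.  The total skipped mass bounds the error from below
        zero (pruned outcomes could only add rejections) and is
        reported.  Default 0: no pruning.
    chunk_size
        Number of (x1, x2) pairs processed per vectorized block.
    """
    settings = settings or TestSettings()
    if not 0.0 < pY < 1.0:
        raise DomainError(f"pY must lie in (0, 1); got {pY!r}")
    if n1 < 1 or n2 < 1:
        raise DomainError("n1 and n2 must be positive")

    x1, x2 = _valid_pairs(n1)
    if x1.size == 0 or n2 < 2:
        # every outcome has a zero cell: nothing can reject
        return ExactResult(0.0, 0, 0.0, 0.0)

    pair_mass = np.exp(_trinomial_logpmf(x1, x2, n1, freqs))
    pruned = 0.0
    if prune > 0.0:
        keep = pair_mass >= prune
        pruned = float(pair_mass[~keep].sum())
        x1, x2, pair_mass = x1[keep], x2[keep], pair_mass[keep]

    y = np.arange(1, n2)
    y_mass = np.exp(_binomial_logpmf(y, n2, pY))
    py = (y / n2)[None, :]

    eps = settings.epsilon
    prob = 0.0
    for start in range(0, x1.size, chunk_size):
        sl = slice(start, start + chunk_size)
        c1 = (x1[sl] / n1)[:, None]
        c2 = (x2[sl] / n1)[:, None]
        c3 = 1.0 - c1 - c2
        bound = ucb_bound(c1, c2, c3, py, n1, n2, settings.alpha)
        prob += float(pair_mass[sl] @ ((bound < eps) @ y_mass))

    n_outcomes = int(x1.size) * int(n2 - 1)
    mass = float(pair_mass.sum()) * float(y_mass.sum())
    return ExactResult(prob, n_outcomes, mass, pruned)


def outcome_mass_total(
    freqs: FemaleGenotypeFreqs, pY: float, n1: int, n2: int
) -> float:
    """Total probability mass of the full enumerated outcome space
    (including degenerate outcomes) — a normalization sanity channel
    that must return 1 to within roundoff."""
    x1 = np.repeat(np.arange(0, n1 + 1), np.arange(n1 + 1, 0, -1))
    x2 = np.concatenate([np.arange(0, n1 - v + 1) for v in range(n1 + 1)])
    tri = np.exp(_trinomial_logpmf(x1, x2, n1, freqs)).sum()
    y = np.arange(0, n2 + 1)
    bino = np.exp(_binomial_logpmf(y, n2, pY)).sum()
    return float(tri * bino)
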