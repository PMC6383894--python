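"""Inverted chi-square comparator and Monte-Carlo harness.

A widespread malpractice is to "establish" HWE by running a lack-of-fit
test and declaring compatibility when its p-value exceeds alpha.  For an
X-chromosomal marker the natural lack-of-fit statistic combines a Pearson
HWE chi-square among females (1 df) with a 2x2 allele-table chi-square
comparing female and male allele frequencies (1 df), referred to a
chi-square distribution with 2 df.  The Monte-Carlo harness here runs the
equivalence test and this inverted rule side by side on synthetic counts
drawn from a specified truth, exposing the inverted rule's lack of level
control (anti-conservative in small samples, over-conservative and
power-capped in large ones).

Also home of the synthetic count sampler used throughout the test suite:
counts are drawn from the model itself — multinomial female genotypes and
an independent binomial male allele count — so sampler output exercises
exactly the distributional assumptions of the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._kernel import ucb_bound
from .equivtest import TestSettings
from .errors import DegenerateCountsError, DomainError
from .measures import PopulationConfig, SnpCounts

__all__ = [
    "McResult",
    "sample_counts",
    "combined_chisq_pvalue",
    "inverted_decision",
    "monte_carlo_compare",
]


@dataclass(frozen=True)
class McResult:
    """Rejection rates of both procedures over a Monte-Carlo experiment."""

    reps: int
    gof_rate: float
    inverted_rate: float
    concordance: float
    seed: int


def sample_counts(
    config: PopulationConfig, n1: int, n2: int, seed: int | np.random.Generator
) -> SnpCounts:
    """Draw one synthetic SNP record: (x1,x2,x3) ~ multinomial(n1; pi),
    y ~ binomial(n2; pY)."""
    if n1 < 1 or n2 < 1:
        raise DomainError("n1 and n2 must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = config.female_freqs
    x = rng.multinomial(n1, [f.pi1, f.pi2, f.pi3])
    y = rng.binomial(n2, config.pY)
    return SnpCounts("sim", int(x[0]), int(x[1]), int(x[2]), n2, int(y))


def _female_allele_counts(x1, x2, x3):
    return 2 * x1 + x2, x2 + 2 * x3


def combined_chisq_pvalue(counts: SnpCounts) -> float:
    """Combined lack-of-fit statistic: Pearson HWE chi-square in females
    plus the 2x2 allele-table chi-square (females vs males), on 2 df."""
    stat = _combined_chisq_stat(
        np.array([counts.x1]),
        np.array([counts.x2]),
        np.array([counts.x3]),
        np.array([counts.y]),
        counts.n1,
        counts.n2,
    )[0]
    if not np.isfinite(stat):
        raise DegenerateCountsError(
            f"{counts.snp_id}: zero expected cell in the chi-square statistic"
        )
    return float(chi2.sf(stat, df=2))


def _combined_chisq_stat(x1, x2, x3, y, n1, n2):
    """Vectorized combined statistic; returns nan where an expected cell
    vanishes."""
    fA, fB = _female_allele_counts(x1, x2, x3)
    pX = fA / (2.0 * n1)
    qX = 1.0 - pX
    exp1 = n1 * pX * pX
    exp2 = n1 * 2.0 * pX * qX
    exp3 = n1 * qX * qX
    with np.errstate(divide="ignore", invalid="ignore"):
        hwe = (
            (x1 - exp1) ** 2 / exp1
            + (x2 - exp2) ** 2 / exp2
            + (x3 - exp3) ** 2 / exp3
        )
        a, b, c, d = fA.astype(float), fB.astype(float), y.astype(float), (n2 - y).astype(float)
        n_all = a + b + c + d
        alleles = (
            n_all
            * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        stat = hwe + alleles
    return np.where(np.isfinite(stat), stat, np.nan)


def inverted_decision(p: float, alpha: float = 0.05) -> bool:
    """The inverted lack-of-fit rule: declare HWE iff p > alpha
    (strict inequality)."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must lie in [0, 1]; got {p!r}")
    return p > alpha


def _sparse_correct_arrays(x1, x2, x3, y, n2):
    """Vectorized sparse-table correction (zeros -> 1, compensated from
    the largest same-stratum cell)."""
    x = np.stack([x1, x2, x3], axis=1).astype(np.int64)
    zeros = x == 0
    n_zero = zeros.sum(axis=1)
    largest = np.argmax(x, axis=1)
    x[zeros] = 1
    x[np.arange(x.shape[0]), largest] -= n_zero
    yc = np.clip(y, 1, n2 - 1)
    return x[:, 0], x[:, 1], x[:, 2], yc


def monte_carlo_compare(
    config: PopulationConfig,
    n1: int,
    n2: int,
    reps: int,
    settings: TestSettings | None = None,
    seed: int = 0,
) -> McResult:
    """Run the equivalence test and the inverted chi-square rule on
    ``reps`` synthetic datasets drawn from ``config``.

    Degenerate replicates follow each procedure's own policy: the
    equivalence test never rejects on them, while the chi-square
    statistic is computed from sparse-corrected counts.
    """
    if reps < 1:
        raise DomainError("reps must be >= 1")
    settings = settings or TestSettings()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    f = config.female_freqs
    x = rng.multinomial(n1, [f.pi1, f.pi2, f.pi3], size=reps)
    y = rng.binomial(n2, config.pY, size=reps)
    x1, x2, x3 = x[:, 0], x[:, 1], x[:, 2]

    ok = (x1 > 0) & (x2 > 0) & (x3 > 0) & (y > 0) & (y < n2)
    gof_reject = np.zeros(reps, dtype=bool)
    if ok.any():
        bound = ucb_bound(
            x1[ok] / n1,
            x2[ok] / n1,
            x3[ok] / n1,
            y[ok] / n2,
            n1,
            n2,
            settings.alpha,
        )
        gof_reject[ok] = bound < settings.epsilon

    cx1, cx2, cx3, cy = _sparse_correct_arrays(x1, x2, x3, y, n2)
    stat = _combined_chisq_stat(cx1, cx2, cx3, cy, n1, n2)
    pvals = chi2.sf(stat, df=2)
    inverted = pvals > settings.alpha

    concord = np.mean(gof_reject == inverted)
    return McResult(
        reps=reps,
        gof_rate=float(np.mean(gof_reject)),
        inverted_rate=float(np.mean(inverted)),
        concordance=float(concord),
        seed=seed,
    )
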