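"""Asymptotic variances of the disequilibrium estimators.

With N = n1 + n2 and n1/N -> lam, the centered and sqrt(N)-scaled plug-in
estimators of the two signed components are asymptotically independent
normals with variances

    sigma_f^2 = (1/lam) * ( (1/4) (1 - pi2) / (pi1 pi3) + 1/pi2 )
    sigma_m^2 = 1 / ((1-lam) pY qY) + (pi1 + pi2/4 - pX^2) / (lam pX^2 qX^2)

where pX = pi1 + pi2/2 and qX = 1 - pX.  sigma_m^2 is the delta-method
variance of the empirical logit difference: the first term is the male
binomial part, the second the variance of logit(pX-hat) under multinomial
sampling of the female genotypes (Var(pX-hat) = (pi1 + pi2/4 - pX^2)/n1).

Away from the origin the combined estimator sqrt(N)(Delta-hat - Delta) is
asymptotically normal with variance tau^2, a weighted mean of the two
component variances with weights Delta_f^2/Delta^2 and Delta_m^2/Delta^2.
At Delta = 0 the weighting is undefined; this module adopts the symmetric
limit convention (equal weights).
"""

from __future__ import annotations

from .errors import DomainError
from .measures import (
    DisequilibriumPoint,
    FemaleGenotypeFreqs,
    PopulationConfig,
    SnpCounts,
    estimate_point,
)

__all__ = [
    "sigma_f_sq",
    "sigma_m_sq",
    "sigma_ratio",
    "tau_sq",
    "tau_hat_sq",
]


def sigma_f_sq(freqs: FemaleGenotypeFreqs, lam: float) -> float:
    """Asymptotic variance of sqrt(N) times the female component estimator."""
    if not 0.0 < lam < 1.0:
        raise DomainError(f"lam must lie in (0, 1); got {lam!r}")
    return (1.0 / lam) * (
        0.25 * (1.0 - freqs.pi2) / (freqs.pi1 * freqs.pi3) + 1.0 / freqs.pi2
    )


def sigma_m_sq(config: PopulationConfig) -> float:
    """Asymptotic variance of sqrt(N) times the male component estimator."""
    f = config.female_freqs
    pX = f.pX
    qX = 1.0 - pX
    qY = 1.0 - config.pY
    male = 1.0 / ((1.0 - config.lam) * config.pY * qY)
    female = (f.pi1 + f.pi2 / 4.0 - pX * pX) / (config.lam * pX * pX * qX * qX)
    return male + female


def sigma_ratio(config: PopulationConfig) -> float:
    """Standard-deviation ratio sigma_m / sigma_f — the scale parameter c
    of the extended chi limit under null alternatives."""
    return (sigma_m_sq(config) / sigma_f_sq(config.female_freqs, config.lam)) ** 0.5


def tau_sq(point: DisequilibriumPoint, sf_sq: float, sm_sq: float) -> float:
    """Combined asymptotic variance of sqrt(N) * Delta-hat.

    Weighted mean of the component variances with weights
    delta_f^2/delta^2, delta_m^2/delta^2; at delta = 0 the symmetric
    equal-weight limit is used.
    """
    d2 = point.delta * point.delta
    if d2 == 0.0:
        return 0.5 * (sf_sq + sm_sq)
    wf = point.delta_f * point.delta_f / d2
    wm = point.delta_m * point.delta_m / d2
    return wf * sf_sq + wm * sm_sq


def tau_hat_sq(counts: SnpCounts) -> float:
    """Consistent plug-in estimate of tau^2 from observed counts.

    Empirical genotype/allele frequencies replace the population values
    and the female fraction lam is replaced by n1/(n1+n2).  Degenerate
    counts (any zero cell) raise, as in :func:`xhwe.measures.estimate_point`.
    """
    point = estimate_point(counts)
    n1 = counts.n1
    lam_hat = n1 / counts.n_total
    freqs = FemaleGenotypeFreqs(counts.x1 / n1, counts.x2 / n1, counts.x3 / n1)
    config = PopulationConfig(freqs, counts.y / counts.n2, lam_hat)
    return tau_sq(point, sigma_f_sq(freqs, lam_hat), sigma_m_sq(config))
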