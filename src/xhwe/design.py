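"""Study planning: approximate power and sample-size formulas.

Two regimes are covered.

*Non-null alternatives* (0 < Delta* < epsilon): the combined estimate is
asymptotically normal, and the power of the test is approximately

    Phi[ (tau~ z_alpha - sqrt(N) (Delta* - epsilon)) / tau ],

with tau evaluated at the alternative and tau~ at a *conjugate boundary
point* — the point on the circle Delta = epsilon sharing pi1 with the
alternative and having both signed components equal to +epsilon/sqrt(2).
Solving for N gives the closed sample-size formula

    N = (tau~ z_{1-alpha} + tau z_{1-beta})^2 / (Delta* - epsilon)^2.

The boundary scale tau~ admits two conventions: the published sample-size
tables are reproduced by tau~ = sigma_f~ (the female component's standard
deviation at the conjugate point, convention ``"sigma-f"``, the default),
whereas the literal weighted-mean variance formula at the conjugate point
gives the average of sigma_f~^2 and sigma_m~^2 (convention ``"weighted-mean"``).
Both are available; see docs/methods.md for the discrepancy analysis.

*Null alternatives* (perfect HWE, Delta = 0): the limit of
sqrt(N) Delta-hat is sigma_f times an extended-chi variable with
c = sigma_m/sigma_f, giving

    power ~= Q_c( [sqrt(N) epsilon - z_{1-alpha} max(sigma_f~, sigma_m~)] / sigma_f )

and the sample-size formula

    N = (z_{1-alpha} max(sigma_f~, sigma_m~) + sigma_f Q_c^{-1}(1-beta))^2 / epsilon^2.

Rounding convention: n1 = ceil(lam N), n2 = round(n1 (1-lam)/lam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import norm

from .errors import DomainError, InfeasibleDesignError
from .extchi import qc_cdf, qc_quantile
from .measures import (
    DEFAULT_MARGIN,
    FemaleGenotypeFreqs,
    PopulationConfig,
    combined_delta,
    config_point,
    solve_pY_for_delta_m,
    solve_pi2_for_delta_f,
)
from .variances import sigma_f_sq, sigma_m_sq, tau_sq

__all__ = [
    "ConjugatePoint",
    "DesignResult",
    "conjugate_point",
    "approx_power_nonnull",
    "sample_size_nonnull",
    "approx_power_null",
    "sample_size_null",
]

_NULL_TOL = 1e-8


@dataclass(frozen=True)
class ConjugatePoint:
    """Boundary configuration conjugate to an alternative: same pi1,
    both signed components at +epsilon/sqrt(2), with the variances
    evaluated there."""

    pi_tilde: FemaleGenotypeFreqs
    pY_tilde: float
    sigma_f_tilde_sq: float
    sigma_m_tilde_sq: float
    tau_tilde_sq: float


@dataclass(frozen=True)
class DesignResult:
    """Sample sizes from a closed-form design calculation.

    ``N_total`` is the raw formula output; ``n1``/``n2`` apply the
    rounding convention; ``approx_power_at_n`` re-evaluates the power
    approximation at the rounded total.  ``convention`` records the
    boundary-scale rule used (``"sigma-f"``, ``"weighted-mean"``, or ``"max"``
    for null-alternative designs).
    """

    N_total: float
    n1: int
    n2: int
    approx_power_at_n: float
    convention: str


def conjugate_point(
    pi1_star: float, lam: float, epsilon: float = DEFAULT_MARGIN
) -> ConjugatePoint:
    """Construct the conjugate boundary point for an alternative with
    AA-frequency ``pi1_star``."""
    component = epsilon / math.sqrt(2.0)
    pi2 = solve_pi2_for_delta_f(pi1_star, component)
    freqs = FemaleGenotypeFreqs(pi1_star, pi2, 1.0 - pi1_star - pi2)
    pY = solve_pY_for_delta_m(freqs.pX, component)
    sf2 = sigma_f_sq(freqs, lam)
    sm2 = sigma_m_sq(PopulationConfig(freqs, pY, lam))
    t2 = tau_sq(combined_delta(component, component), sf2, sm2)
    return ConjugatePoint(freqs, pY, sf2, sm2, t2)


def _tau_tilde(conj: ConjugatePoint, convention: str) -> float:
    if convention == "sigma-f":
        return math.sqrt(conj.sigma_f_tilde_sq)
    if convention == "weighted-mean":
        return math.sqrt(conj.tau_tilde_sq)
    raise DomainError(f"unknown tau-tilde convention {convention!r}")


def _round_sizes(N: float, lam: float) -> tuple[int, int]:
    # Round N up to the next total for which both lam*N and (1-lam)*N are
    # integers (lam is a design fraction a/b with small denominator), so
    # the per-sex sizes realize lam exactly.  Falls back to
    # n1 = ceil(lam N), n2 = round(n1 (1-lam)/lam) for non-simple lam.
    frac = Fraction(lam).limit_denominator(100)
    if abs(float(frac) - lam) < 1e-9:
        a, b = frac.numerator, frac.denominator
        m = math.ceil(N / b - 1e-9)
        return a * m, (b - a) * m
    n1 = math.ceil(lam * N - 1e-9)
    n2 = int(round(n1 * (1.0 - lam) / lam))
    return n1, n2


def approx_power_nonnull(
    alt: PopulationConfig,
    N: float,
    alpha: float = 0.05,
    epsilon: float = DEFAULT_MARGIN,
    convention: str = "sigma-f",
) -> float:
    """Normal approximation to the power against a non-null alternative
    (Delta* > 0) at total sample size N."""
    point = config_point(alt)
    if point.delta <= 0.0:
        raise DomainError(
            "alternative has Delta = 0; use approx_power_null for "
            "perfect-HWE alternatives"
        )
    sf2 = sigma_f_sq(alt.female_freqs, alt.lam)
    sm2 = sigma_m_sq(alt)
    tau = math.sqrt(tau_sq(point, sf2, sm2))
    conj = conjugate_point(alt.female_freqs.pi1, alt.lam, epsilon)
    tau_t = _tau_tilde(conj, convention)
    z_alpha = float(norm.ppf(alpha))
    arg = (tau_t * z_alpha - math.sqrt(N) * (point.delta - epsilon)) / tau
    return float(norm.cdf(arg))


def sample_size_nonnull(
    alt: PopulationConfig,
    alpha: float = 0.05,
    power_target: float = 0.80,
    epsilon: float = DEFAULT_MARGIN,
    convention: str = "sigma-f",
) -> DesignResult:
    """Closed-form sample size for a non-null alternative."""
    point = config_point(alt)
    if point.delta >= epsilon:
        raise InfeasibleDesignError(
            f"alternative distance Delta* = {point.delta:.5f} is not below "
            f"the margin epsilon = {epsilon:.5f}; the test cannot establish "
            "equivalence there"
        )
    if point.delta <= 0.0:
        raise DomainError("Delta* = 0; use sample_size_null")
    sf2 = sigma_f_sq(alt.female_freqs, alt.lam)
    sm2 = sigma_m_sq(alt)
    tau = math.sqrt(tau_sq(point, sf2, sm2))
    conj = conjugate_point(alt.female_freqs.pi1, alt.lam, epsilon)
    tau_t = _tau_tilde(conj, convention)
    z_a = float(norm.ppf(1.0 - alpha))
    z_b = float(norm.ppf(power_target))
    N = (tau_t * z_a + tau * z_b) ** 2 / (point.delta - epsilon) ** 2
    n1, n2 = _round_sizes(N, alt.lam)
    attained = approx_power_nonnull(alt, n1 + n2, alpha, epsilon, convention)
    return DesignResult(N, n1, n2, attained, convention)


def _check_null(alt: PopulationConfig) -> None:
    point = config_point(alt)
    if point.delta > _NULL_TOL:
        raise DomainError(
            f"configuration is not a null alternative (Delta = {point.delta:.3g}); "
            "require perfect HWE with equal allele frequencies"
        )


def approx_power_null(
    null_alt: PopulationConfig,
    N: float,
    alpha: float = 0.05,
    epsilon: float = DEFAULT_MARGIN,
) -> float:
    """Extended-chi approximation to the power against a perfect-HWE
    alternative at total sample size N."""
    _check_null(null_alt)
    sf = math.sqrt(sigma_f_sq(null_alt.female_freqs, null_alt.lam))
    sm = math.sqrt(sigma_m_sq(null_alt))
    conj = conjugate_point(null_alt.female_freqs.pi1, null_alt.lam, epsilon)
    s_max = math.sqrt(max(conj.sigma_f_tilde_sq, conj.sigma_m_tilde_sq))
    z = float(norm.ppf(1.0 - alpha))
    arg = (math.sqrt(N) * epsilon - z * s_max) / sf
    if arg <= 0.0:
        return 0.0
    return qc_cdf(arg, sm / sf)


def sample_size_null(
    null_alt: PopulationConfig,
    alpha: float = 0.05,
    power_target: float = 0.80,
    epsilon: float = DEFAULT_MARGIN,
) -> DesignResult:
    """Closed-form sample size against a perfect-HWE alternative, using
    the extended-chi quantile."""
    _check_null(null_alt)
    sf = math.sqrt(sigma_f_sq(null_alt.female_freqs, null_alt.lam))
    sm = math.sqrt(sigma_m_sq(null_alt))
    conj = conjugate_point(null_alt.female_freqs.pi1, null_alt.lam, epsilon)
    s_max = math.sqrt(max(conj.sigma_f_tilde_sq, conj.sigma_m_tilde_sq))
    z = float(norm.ppf(1.0 - alpha))
    q = qc_quantile(power_target, sm / sf)
    N = (z * s_max + sf * q) ** 2 / epsilon**2
    n1, n2 = _round_sizes(N, null_alt.lam)
    attained = approx_power_null(null_alt, n1 + n2, alpha, epsilon)
    return DesignResult(N, n1, n2, attained, "max")
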