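"""Disequilibrium measures for X-chromosomal diallelic markers.

For a marker on the X chromosome, females carry genotype triples
(AA, AB, BB) with population frequencies (pi1, pi2, pi3), while hemizygous
males carry a single allele with A-frequency pY.  Hardy-Weinberg
equilibrium holds iff the female genotype distribution lies on the HWE
curve (pi2^2 = 4 pi1 pi3) *and* the allele frequencies agree between the
sexes (pX = pi1 + pi2/2 = pY).

Departure from the model is measured by two signed components on the log
scale:

* the female component, the log relative excess heterozygosity (REH),
  ``log(pi2) - (log(pi1) + log(pi3))/2 - log 2`` — zero exactly on the
  HWE curve;
* the male component, the log odds ratio between the female and male
  allele frequencies, ``logit(pX) - logit(pY)`` — zero when the
  frequencies coincide.

The combined distance is the Euclidean norm of the pair, and the default
equivalence margin is the radius of the smallest circle containing the
square with half-edge log 1.4, i.e. ``sqrt(2) * log 1.4``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import DegenerateCountsError, DomainError

__all__ = [
    "DEFAULT_MARGIN",
    "FemaleGenotypeFreqs",
    "PopulationConfig",
    "SnpCounts",
    "DisequilibriumPoint",
    "delta_f_signed",
    "delta_m_signed",
    "combined_delta",
    "estimate_point",
    "solve_pi2_for_delta_f",
    "solve_pY_for_delta_m",
]

_LOG2 = math.log(2.0)

#: Default equivalence margin: sqrt(2) * log 1.4, the radius of the circle
#: through the points with both signed components equal to +/- log 1.4.
DEFAULT_MARGIN: float = math.sqrt(2.0) * math.log(1.4)


def _check_open_unit(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise DomainError(f"{name} must lie strictly in (0, 1); got {value!r}")


@dataclass(frozen=True)
class FemaleGenotypeFreqs:
    """Population genotype frequencies (AA, AB, BB) among females."""

    pi1: float
    pi2: float
    pi3: float

    def __post_init__(self) -> None:
        for name, value in (("pi1", self.pi1), ("pi2", self.pi2), ("pi3", self.pi3)):
            _check_open_unit(name, value)
        if abs(self.pi1 + self.pi2 + self.pi3 - 1.0) > 1e-9:
            raise DomainError(
                f"genotype frequencies must sum to 1; got {self.pi1 + self.pi2 + self.pi3!r}"
            )

    @property
    def pX(self) -> float:
        """Allele-A frequency among females, pi1 + pi2/2."""
        return self.pi1 + self.pi2 / 2.0


@dataclass(frozen=True)
class PopulationConfig:
    """True parameter configuration for exact and design computations.

    Parameters
    ----------
    female_freqs
        Female genotype frequencies (pi1, pi2, pi3).
    pY
        Male A-allele frequency, in (0, 1).
    lam
        Limiting fraction of females among all subjects, n1/(n1+n2),
        in (0, 1).
    """

    female_freqs: FemaleGenotypeFreqs
    pY: float
    lam: float

    def __post_init__(self) -> None:
        _check_open_unit("pY", self.pY)
        _check_open_unit("lam", self.lam)


@dataclass(frozen=True)
class SnpCounts:
    """Observed counts for one SNP: female genotype counts and male
    allele counts.

    ``x1, x2, x3`` are the numbers of AA, AB and BB females
    (``n1 = x1 + x2 + x3``); ``y`` is the number of A-alleles among the
    ``n2`` hemizygous males.
    """

    snp_id: str
    x1: int
    x2: int
    x3: int
    n2: int
    y: int

    def __post_init__(self) -> None:
        for name, value in (
            ("x1", self.x1),
            ("x2", self.x2),
            ("x3", self.x3),
            ("y", self.y),
        ):
            if value < 0:
                raise DomainError(f"{name} must be nonnegative; got {value!r}")
        if self.n1 < 1:
            raise DomainError("at least one female genotype is required (n1 >= 1)")
        if self.n2 < 1:
            raise DomainError("at least one male is required (n2 >= 1)")
        if self.y > self.n2:
            raise DomainError(f"y ({self.y}) cannot exceed n2 ({self.n2})")

    @property
    def n1(self) -> int:
        return self.x1 + self.x2 + self.x3

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2

    def zero_cells(self) -> tuple[str, ...]:
        """Names of the degenerate (zero) cells among x1, x2, x3, y, n2-y."""
        zeros = []
        for name, value in (
            ("x1", self.x1),
            ("x2", self.x2),
            ("x3", self.x3),
            ("y", self.y),
            ("n2-y", self.n2 - self.y),
        ):
            if value == 0:
                zeros.append(name)
        return tuple(zeros)


@dataclass(frozen=True)
class DisequilibriumPoint:
    """Signed disequilibrium components and their Euclidean combination."""

    delta_f: float
    delta_m: float
    delta: float

    def __post_init__(self) -> None:
        if abs(self.delta - math.hypot(self.delta_f, self.delta_m)) > 1e-12:
            raise ValueError("delta must equal hypot(delta_f, delta_m)")


def delta_f_signed(freqs: FemaleGenotypeFreqs) -> float:
    """Signed female component: the log relative excess heterozygosity.

    Returns ``log(pi2) - (log(pi1) + log(pi3))/2 - log 2``, which is zero
    iff the female genotype distribution is on the HWE curve
    (pi2^2 = 4 pi1 pi3), positive under heterozygote excess.
    """
    return (
        math.log(freqs.pi2)
        - (math.log(freqs.pi1) + math.log(freqs.pi3)) / 2.0
        - _LOG2
    )


def delta_m_signed(pX: float, pY: float) -> float:
    """Signed male component: log odds ratio of the female vs male
    allele-A frequencies, ``logit(pX) - logit(pY)``."""
    _check_open_unit("pX", pX)
    _check_open_unit("pY", pY)
    return float(logit(pX) - logit(pY))


def combined_delta(delta_f: float, delta_m: float) -> DisequilibriumPoint:
    """Combine signed components into the Euclidean distance from the
    origin of the (delta_f, delta_m) plane."""
    if not (math.isfinite(delta_f) and math.isfinite(delta_m)):
        raise DomainError("components must be finite")
    return DisequilibriumPoint(delta_f, delta_m, math.hypot(delta_f, delta_m))


def config_point(config: PopulationConfig) -> DisequilibriumPoint:
    """Disequilibrium point of a population configuration."""
    df = delta_f_signed(config.female_freqs)
    dm = delta_m_signed(config.female_freqs.pX, config.pY)
    return combined_delta(df, dm)


def estimate_point(counts: SnpCounts) -> DisequilibriumPoint:
    """Plug-in estimate of the disequilibrium point from observed counts.

    Replaces the population frequencies by the empirical proportions
    xj/n1 and y/n2.  Requires all five cells x1, x2, x3, y, n2-y to be
    strictly positive; otherwise the logs are undefined and a
    :class:`~xhwe.errors.DegenerateCountsError` is raised (see
    :func:`xhwe.equivtest.sparse_correct` for the remedial rule).
    """
    zeros = counts.zero_cells()
    if zeros:
        raise DegenerateCountsError(
            f"{counts.snp_id}: zero cell(s) {', '.join(zeros)}; "
            "the plug-in estimator is undefined (consider sparse correction)"
        )
    n1 = counts.n1
    p1, p2, p3 = counts.x1 / n1, counts.x2 / n1, counts.x3 / n1
    df = math.log(p2) - (math.log(p1) + math.log(p3)) / 2.0 - _LOG2
    dm = delta_m_signed(p1 + p2 / 2.0, counts.y / counts.n2)
    return combined_delta(df, dm)


def solve_pi2_for_delta_f(pi1: float, target: float) -> float:
    """Find the unique pi2 with ``delta_f_signed(pi1, pi2, 1-pi1-pi2)``
    equal to ``target``.

    The component is strictly increasing in pi2 at fixed pi1 and spans
    the whole real line as pi2 ranges over (0, 1-pi1), so a bracketing
    search always succeeds.
    """
    _check_open_unit("pi1", pi1)
    if not math.isfinite(target):
        raise DomainError("target must be finite")
    tol = 1e-12
    upper = 1.0 - pi1

    def f(pi2: float) -> float:
        return delta_f_signed(FemaleGenotypeFreqs(pi1, pi2, upper - pi2)) - target

    return float(brentq(f, tol, upper - tol, xtol=1e-14, rtol=8.9e-16))


def solve_pY_for_delta_m(pX: float, target: float) -> float:
    """Male allele frequency pY with ``delta_m_signed(pX, pY) == target``
    (closed form: inverse logit of ``logit(pX) - target``)."""
    _check_open_unit("pX", pX)
    return float(expit(logit(pX) - target))
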