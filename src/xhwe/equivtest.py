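"""Per-SNP equivalence test for goodness of fit to HWE.

The hypotheses are H0: Delta >= epsilon versus H1: Delta < epsilon, where
Delta is the combined disequilibrium distance and epsilon the equivalence
margin.  The test rejects H0 — i.e. declares the SNP approximately
HWE-compatible — iff the one-sided upper confidence bound

    Delta-hat + z_{1-alpha} * tau-hat / sqrt(n1 + n2)

falls below epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import norm

from .errors import DegenerateCountsError, DomainError, UnrecoverableSparsityError
from .measures import DEFAULT_MARGIN, SnpCounts, estimate_point
from .variances import tau_hat_sq

__all__ = ["TestSettings", "TestResult", "sparse_correct", "upper_confidence_bound", "decide"]


@dataclass(frozen=True)
class TestSettings:
    """Settings of the equivalence test.

    Parameters
    ----------
    alpha
        Nominal one-sided level, in (0, 0.5).  Default 0.05.
    epsilon
        Equivalence margin on the combined log-scale distance.
        Default ``sqrt(2) * log 1.4``.
    sparse_policy
        ``"reject-input"`` (default): counts with zero cells raise
        :class:`~xhwe.errors.DegenerateCountsError`.
        ``"auto-correct"``: apply :func:`sparse_correct` first and flag
        the result.  The correction alters the data, so it is opt-in.
    """

    alpha: float = 0.05
    epsilon: float = DEFAULT_MARGIN
    sparse_policy: str = "reject-input"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise DomainError(f"alpha must lie in (0, 0.5); got {self.alpha!r}")
        if self.epsilon <= 0.0:
            raise DomainError(f"epsilon must be positive; got {self.epsilon!r}")
        if self.sparse_policy not in ("reject-input", "auto-correct"):
            raise DomainError(f"unknown sparse_policy {self.sparse_policy!r}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of the per-SNP test.

    ``reject_null`` is True when the null hypothesis of relevant
    disequilibrium is rejected, i.e. approximate HWE compatibility is
    established (the "+" decision).
    """

    snp_id: str
    delta_hat: float
    tau_hat_sq: float
    upper_bound: float
    reject_null: bool
    corrected: bool


def sparse_correct(counts: SnpCounts) -> SnpCounts:
    """Sparse-contingency-table correction for counts with zero cells.

    Each zero cell among the female genotype counts is set to 1 and the
    total added is subtracted from the largest female cell, preserving
    n1; a zero among the male cells {y, n2-y} is set to 1 with
    compensation from the other male cell, preserving n2.  Zero-free
    counts are returned unchanged.
    """
    x = [counts.x1, counts.x2, counts.x3]
    female_zeros = [i for i, v in enumerate(x) if v == 0]
    if female_zeros:
        largest = max(range(3), key=lambda i: x[i])
        x[largest] -= len(female_zeros)
        for i in female_zeros:
            x[i] = 1
        if x[largest] < 1:
            raise UnrecoverableSparsityError(
                f"{counts.snp_id}: female counts too small to correct"
            )
    y = counts.y
    if counts.n2 < 2:
        if y == 0 or y == counts.n2:
            raise UnrecoverableSparsityError(
                f"{counts.snp_id}: male counts too small to correct"
            )
    elif y == 0:
        y = 1
    elif counts.n2 - y == 0:
        y = counts.n2 - 1
    return replace(counts, x1=x[0], x2=x[1], x3=x[2], y=y)


def _prepared(counts: SnpCounts, settings: TestSettings) -> tuple[SnpCounts, bool]:
    if not counts.zero_cells():
        return counts, False
    if settings.sparse_policy == "auto-correct":
        return sparse_correct(counts), True
    raise DegenerateCountsError(
        f"{counts.snp_id}: zero cell(s) {', '.join(counts.zero_cells())}; "
        "set sparse_policy='auto-correct' to apply the sparse-table rule"
    )


def upper_confidence_bound(counts: SnpCounts, settings: TestSettings | None = None) -> float:
    """One-sided upper confidence bound for Delta at asymptotic level
    1 - alpha: ``Delta-hat + z_{1-alpha} tau-hat / sqrt(n1+n2)``."""
    settings = settings or TestSettings()
    counts, _ = _prepared(counts, settings)
    z = float(norm.ppf(1.0 - settings.alpha))
    point = estimate_point(counts)
    t2 = tau_hat_sq(counts)
    return point.delta + z * math.sqrt(t2) / math.sqrt(counts.n_total)


def decide(counts: SnpCounts, settings: TestSettings | None = None) -> TestResult:
    """Run the equivalence test on one SNP's counts."""
    settings = settings or TestSettings()
    used, corrected = _prepared(counts, settings)
    point = estimate_point(used)
    t2 = tau_hat_sq(used)
    z = float(norm.ppf(1.0 - settings.alpha))
    bound = point.delta + z * math.sqrt(t2) / math.sqrt(used.n_total)
    return TestResult(
        snp_id=counts.snp_id,
        delta_hat=point.delta,
        tau_hat_sq=t2,
        upper_bound=bound,
        reject_null=bool(bound < settings.epsilon),
        corrected=corrected,
    )
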