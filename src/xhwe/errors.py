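"""Exception hierarchy for xhwe."""


class XhweError(Exception):
    """Base class for all xhwe-specific errors."""


class DomainError(XhweError, ValueError):
    """A parameter lies outside the open parameter space (e.g. a frequency
    of 0 or 1 where a logarithm or logit is required)."""


class DegenerateCountsError(XhweError, ValueError):
    """Observed counts contain a zero cell, so the plug-in disequilibrium
    estimate is undefined.  Distinct from :class:`DomainError`: the inputs
    are valid data, but the statistic cannot be formed without a
    sparse-count correction."""


class UnrecoverableSparsityError(XhweError, ValueError):
    """Counts are too small for the sparse-count correction to be applied
    (no cell is large enough to compensate the filled-in zeros)."""


class InfeasibleDesignError(XhweError, ValueError):
    """A sample-size calculation was requested for an alternative that the
    test cannot establish (combined distance at or beyond the margin)."""
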