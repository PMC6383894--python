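"""Vectorized evaluation of the upper confidence bound.

Shared numeric core of the exact enumeration engine and the Monte-Carlo
harness: given broadcastable arrays of empirical frequencies it returns
the one-sided upper confidence bound for the combined disequilibrium
distance at each outcome.  All inputs must correspond to nondegenerate
outcomes (strictly positive cell frequencies); degenerate outcomes are
handled by the callers' policies.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

_LOG2 = math.log(2.0)


def ucb_bound(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    py: np.ndarray,
    n1: int,
    n2: int,
    alpha: float,
) -> np.ndarray:
    """Upper confidence bound Delta-hat + z_{1-alpha} tau-hat / sqrt(N)
    for broadcastable arrays of empirical frequencies.

    The plug-in tau-hat uses lam-hat = n1/(n1+n2); outcomes with
    Delta-hat = 0 use the equal-weight variance convention.
    """
    n_total = n1 + n2
    lam = n1 / n_total
    z = float(norm.ppf(1.0 - alpha))

    log_p1, log_p2, log_p3 = np.log(p1), np.log(p2), np.log(p3)
    df = log_p2 - 0.5 * (log_p1 + log_p3) - _LOG2

    pX = p1 + 0.5 * p2
    qX = 1.0 - pX
    dm = (np.log(pX) - np.log(qX)) - (np.log(py) - np.log1p(-py))

    df2 = df * df
    dm2 = dm * dm
    d2 = df2 + dm2

    sf2 = (1.0 / lam) * (0.25 * (1.0 - p2) / (p1 * p3) + 1.0 / p2)
    sm2 = 1.0 / ((1.0 - lam) * py * (1.0 - py)) + (p1 + 0.25 * p2 - pX * pX) / (
        lam * pX * pX * qX * qX
    )

    num = df2 * sf2 + dm2 * sm2
    zero = d2 == 0.0
    tau2 = np.where(zero, 0.5 * (sf2 + sm2), num / np.where(zero, 1.0, d2))
    return np.sqrt(d2) + z * np.sqrt(tau2 / n_total)
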