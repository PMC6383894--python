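import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xhwe import (
    DEFAULT_MARGIN,
    DegenerateCountsError,
    DomainError,
    FemaleGenotypeFreqs,
    SnpCounts,
    combined_delta,
    delta_f_signed,
    delta_m_signed,
    estimate_point,
    solve_pY_for_delta_m,
    solve_pi2_for_delta_f,
)

# tolerance for values quoted to 5 decimals from rounded parameter inputs
PRINTED = 5e-5


@pytest.mark.parametrize(
    "freqs, expected",
    [
        ((0.25, 0.5, 0.25), 0.0),
        ((0.25, 0.57897, 0.17103), 0.33647),
        ((0.25, 0.41402, 0.33598), -0.33647),
    ],
)
def test_delta_f_signed_examples(freqs, expected):
    assert delta_f_signed(FemaleGenotypeFreqs(*freqs)) == pytest.approx(
        expected, abs=PRINTED
    )


@pytest.mark.parametrize(
    "pX, pY, expected",
    [
        (0.3, 0.3, 0.0),
        (0.53949, 0.45557, 0.33647),
        # pX and pY both rounded to 5 decimals: rounding propagates ~2e-4
        (0.52048, 0.47846, 0.16824),
    ],
)
def test_delta_m_signed_examples(pX, pY, expected):
    assert delta_m_signed(pX, pY) == pytest.approx(expected, abs=2e-4)


@pytest.mark.parametrize(
    "df, dm, expected",
    [(0.0, 0.0, 0.0), (0.16824, 0.16824, 0.23792), (0.13459, 0.13459, 0.19034)],
)
def test_combined_delta_examples(df, dm, expected):
    assert combined_delta(df, dm).delta == pytest.approx(expected, abs=1e-5)


def test_default_margin_is_circle_radius():
    # circle through the corner point with both components log 1.4
    corner = combined_delta(math.log(1.4), math.log(1.4))
    assert corner.delta == pytest.approx(DEFAULT_MARGIN, abs=1e-12)


@pytest.mark.parametrize(
    "x, n2, y, expected",
    [
        ((230, 314, 107), 604, 399, 0.2835),
        ((275, 296, 80), 604, 392, 0.0040),
        ((25, 50, 25), 100, 50, 0.0),
    ],
)
def test_estimate_point_examples(x, n2, y, expected):
    counts = SnpCounts("snp", *x, n2, y)
    assert estimate_point(counts).delta == pytest.approx(expected, abs=5e-5)


def test_estimate_point_degenerate_distinct_from_domain_error():
    with pytest.raises(DegenerateCountsError):
        estimate_point(SnpCounts("s", 651, 0, 0, 605, 603))
    with pytest.raises(DomainError):
        delta_m_signed(0.0, 0.5)
    with pytest.raises(DomainError):
        FemaleGenotypeFreqs(0.0, 0.5, 0.5)


@pytest.mark.parametrize(
    "pi1, target, expected",
    [
        (0.25, 0.0, 0.5),
        (0.25, math.log(1.4), 0.57897),
        (0.09, math.log(1.4), 0.52274),
    ],
)
def test_solve_pi2_examples(pi1, target, expected):
    pi2 = solve_pi2_for_delta_f(pi1, target)
    assert pi2 == pytest.approx(expected, abs=1e-5)
    residual = delta_f_signed(FemaleGenotypeFreqs(pi1, pi2, 1 - pi1 - pi2)) - target
    assert abs(residual) < 1e-10


@pytest.mark.parametrize(
    "pX, target, expected",
    [
        (0.53949, math.log(1.4), 0.45557),
        (0.3, 0.0, 0.3),
        (0.35137, -math.log(1.4), 0.43130),
    ],
)
def test_solve_pY_examples(pX, target, expected):
    pY = solve_pY_for_delta_m(pX, target)
    assert pY == pytest.approx(expected, abs=1e-5)
    assert delta_m_signed(pX, pY) == pytest.approx(target, abs=1e-12)


@st.composite
def genotype_freqs(draw):
    pi1 = draw(st.floats(0.01, 0.9))
    pi2 = draw(st.floats(0.01, 0.98 - pi1))
    return FemaleGenotypeFreqs(pi1, pi2, 1.0 - pi1 - pi2)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(genotype_freqs(), st.floats(0.01, 0.99))
def test_allele_relabeling_symmetry(freqs, pY):
    """Swapping the roles of alleles A and B (pi1<->pi3, pY<->1-pY)
    leaves the female component invariant (log REH is symmetric in the
    homozygote frequencies), negates the male log odds ratio, and
    preserves the combined distance."""
    swapped = FemaleGenotypeFreqs(freqs.pi3, freqs.pi2, freqs.pi1)
    df, dfs = delta_f_signed(freqs), delta_f_signed(swapped)
    dm = delta_m_signed(freqs.pX, pY)
    dms = delta_m_signed(swapped.pX, 1.0 - pY)
    assert dfs == pytest.approx(df, abs=1e-12)
    assert dms == pytest.approx(-dm, abs=1e-9)
    assert combined_delta(df, dm).delta == pytest.approx(
        combined_delta(dfs, dms).delta, abs=1e-9
    )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(0.02, 0.9), st.floats(-5.0, 5.0))
def test_pi2_solver_roundtrip(pi1, target):
    pi2 = solve_pi2_for_delta_f(pi1, target)
    assert 0.0 < pi2 < 1.0 - pi1
    value = delta_f_signed(FemaleGenotypeFreqs(pi1, pi2, 1 - pi1 - pi2))
    assert abs(value - target) < 1e-10


def test_delta_f_strictly_increasing_in_pi2():
    pi1 = 0.2
    values = [
        delta_f_signed(FemaleGenotypeFreqs(pi1, pi2, 1 - pi1 - pi2))
        for pi2 in (0.05, 0.2, 0.4, 0.6, 0.79)
    ]
    assert all(a < b for a, b in zip(values, values[1:]))


def test_equivalence_circle_configs_have_delta_epsilon():
    """Configurations built with both components +/- log 1.4 lie on the
    circle of radius sqrt(2) log 1.4."""
    for sf in (1, -1):
        for sm in (1, -1):
            pi2 = solve_pi2_for_delta_f(0.25, sf * math.log(1.4))
            freqs = FemaleGenotypeFreqs(0.25, pi2, 0.75 - pi2)
            pY = solve_pY_for_delta_m(freqs.pX, sm * math.log(1.4))
            point = combined_delta(
                delta_f_signed(freqs), delta_m_signed(freqs.pX, pY)
            )
            assert point.delta == pytest.approx(DEFAULT_MARGIN, abs=1e-10)
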