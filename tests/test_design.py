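import math

import pytest

from xhwe import (
    DEFAULT_MARGIN,
    DomainError,
    InfeasibleDesignError,
    approx_power_nonnull,
    approx_power_null,
    conjugate_point,
    config_point,
    delta_f_signed,
    delta_m_signed,
    sample_size_nonnull,
    sample_size_null,
)

from .conftest import hwe_null, make_config

ALT_HALF_MARGIN = lambda lam: make_config(0.25, 0.54097, 0.47846, lam)
ALT_RARE_HALF_MARGIN = lambda lam: make_config(0.04, 0.35573, 0.19580, lam)


class TestConjugatePoint:
    def test_matches_published_boundary_point(self):
        conj = conjugate_point(0.25, 0.5)
        assert conj.pi_tilde.pi2 == pytest.approx(0.57897, abs=1e-5)
        assert conj.pY_tilde == pytest.approx(0.45557, abs=1e-5)
        conj2 = conjugate_point(0.09, 0.5)
        assert conj2.pi_tilde.pi2 == pytest.approx(0.52274, abs=1e-5)

    def test_components_and_circle_membership(self):
        conj = conjugate_point(0.33, 0.4)
        df = delta_f_signed(conj.pi_tilde)
        dm = delta_m_signed(conj.pi_tilde.pX, conj.pY_tilde)
        target = DEFAULT_MARGIN / math.sqrt(2.0)
        assert df == pytest.approx(target, abs=1e-10)
        assert dm == pytest.approx(target, abs=1e-10)
        assert math.hypot(df, dm) == pytest.approx(DEFAULT_MARGIN, abs=1e-10)

    def test_tau_tilde_is_mean_at_diagonal(self):
        conj = conjugate_point(0.2, 0.5)
        assert conj.tau_tilde_sq == pytest.approx(
            0.5 * (conj.sigma_f_tilde_sq + conj.sigma_m_tilde_sq)
        )


@pytest.mark.parametrize(
    "alt, lam, expected",
    [
        (ALT_HALF_MARGIN, 1 / 2, (485, 485)),
        (ALT_HALF_MARGIN, 1 / 3, (449, 898)),
        (ALT_HALF_MARGIN, 2 / 3, (552, 276)),
        (ALT_HALF_MARGIN, 1 / 4, (436, 1308)),
        (ALT_HALF_MARGIN, 3 / 4, (612, 204)),
        (ALT_RARE_HALF_MARGIN, 1 / 2, (697, 697)),
    ],
)
def test_nonnull_sample_sizes_reproduce_published_table(alt, lam, expected):
    result = sample_size_nonnull(alt(lam))
    assert (result.n1, result.n2) == expected
    assert result.convention == "sigma-f"


def test_nonnull_formula_self_consistent():
    """Plugging the formula's N back into the power approximation must
    return (at least) the target power, by construction."""
    for lam in (0.3, 0.5, 0.7):
        alt = ALT_HALF_MARGIN(lam)
        result = sample_size_nonnull(alt, power_target=0.80)
        assert result.approx_power_at_n >= 0.80 - 1e-9
        assert approx_power_nonnull(alt, result.N_total) == pytest.approx(0.80, abs=1e-9)


def test_nonnull_power_limits():
    alt = ALT_HALF_MARGIN(0.5)
    assert approx_power_nonnull(alt, 10_000_000) > 0.9999
    # at Delta* = epsilon the approximation returns roughly alpha
    boundary = make_config(0.25, 0.57897, 0.45557)
    assert approx_power_nonnull(boundary, 1000) == pytest.approx(0.05, abs=0.02)


def test_nonnull_errors():
    with pytest.raises(InfeasibleDesignError):
        sample_size_nonnull(make_config(0.25, 0.7, 0.2))  # far outside margin
    with pytest.raises(DomainError):
        approx_power_nonnull(hwe_null(0.5), 500)


@pytest.mark.parametrize(
    "p, lam, power, expected",
    [
        (0.5, 1 / 2, 0.60, (213, 213)),
        (0.5, 1 / 2, 0.80, (279, 279)),
        (0.5, 1 / 2, 0.90, (338, 338)),
        (0.5, 1 / 3, 0.80, (214, 428)),
        (0.3, 1 / 2, 0.80, (346, 346)),
        (0.3, 1 / 4, 0.90, (321, 963)),
        (0.1, 1 / 2, 0.80, (1375, 1375)),
    ],
)
def test_null_sample_sizes_reproduce_published_table(p, lam, power, expected):
    result = sample_size_null(hwe_null(p, lam), power_target=power)
    assert (result.n1, result.n2) == expected


def test_null_power_behavior():
    cfg = hwe_null(0.5)
    # inversion of the published n1 = 279 row: N = 558 attains ~80%
    assert approx_power_null(cfg, 558) == pytest.approx(0.80, abs=0.01)
    assert approx_power_null(cfg, 10) == 0.0
    assert approx_power_null(cfg, 5_000_000) > 0.9999


def test_null_sample_size_monotonicity():
    cfg = hwe_null(0.3)
    n_by_power = [
        sample_size_null(cfg, power_target=p).N_total for p in (0.6, 0.8, 0.9)
    ]
    assert n_by_power[0] < n_by_power[1] < n_by_power[2]
    n_by_eps = [
        sample_size_null(cfg, epsilon=e).N_total for e in (0.3, 0.45, 0.6)
    ]
    assert n_by_eps[0] > n_by_eps[1] > n_by_eps[2]


def test_null_functions_reject_nonnull_configs():
    with pytest.raises(DomainError):
        approx_power_null(make_config(0.25, 0.57897, 0.45557), 500)
    with pytest.raises(DomainError):
        sample_size_null(make_config(0.25, 0.57897, 0.45557))


def test_weighted_mean_convention_available_and_differs():
    alt = ALT_HALF_MARGIN(0.5)
    default = sample_size_nonnull(alt, convention="sigma-f")
    literal = sample_size_nonnull(alt, convention="weighted-mean")
    assert literal.convention == "weighted-mean"
    assert literal.n1 != default.n1  # the two boundary-scale rules disagree


def test_config_point_on_alternative():
    # published alternative parameters are rounded to 5 decimals
    point = config_point(ALT_HALF_MARGIN(0.5))
    assert point.delta == pytest.approx(0.23792, abs=2e-4)
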