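"""First-order rate fitting and thermal-resistance parameter derivation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermokin.datasets import (
    ANTHOCYANIN_REPORTED,
    ANTIOXIDANT_REPORTED,
    purple_maize_anthocyanin_kinetics,
    purple_maize_antioxidant_kinetics,
)
from thermokin.errors import (
    InsufficientDataError,
    NoDegradationError,
    TransformError,
)
from thermokin.kinetics import (
    GAS_CONSTANT,
    DecaySeries,
    compare_reaction_orders,
    decimal_reduction_time,
    fit_arrhenius,
    fit_first_order_rate,
    fit_z_value,
    half_life,
    predicted_retention,
    summarize_kinetics,
)
from thermokin.synthetic import GeneratorConfig, simulate_decay

PAPER_GRID = (0.0, 2.0, 5.0, 7.0, 10.0, 20.0, 30.0, 40.0)


def _series(k, c0=1.0, times=PAPER_GRID, temperature=120.0):
    values = tuple(c0 * math.exp(-k * t) for t in times)
    return DecaySeries(temperature=temperature, times=times, values=values)


def grid_search_k(series, k_max=1.0, step=1e-5):
    """Brute-force SSE minimiser over k with the intercept profiled out.

    Independent oracle for the ln-linear fit: for each candidate k the best
    intercept is the mean of (y + k·t), and the SSE is evaluated directly.
    """
    t = np.asarray(series.times)
    y = np.log(np.asarray(series.values) / series.values[0])
    ks = np.arange(0.0, k_max + step, step)
    # residuals y - (b - k t) with b profiled: center both y and -k t
    yc = y - y.mean()
    tc = t - t.mean()
    sse = ((yc[None, :] + ks[:, None] * tc[None, :]) ** 2).sum(axis=1)
    return float(ks[np.argmin(sse)])


class TestFitFirstOrderRate:
    def test_noiseless_exponential_on_study_grid(self):
        fit = fit_first_order_rate(_series(0.05))
        assert fit.k == pytest.approx(0.05, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.significant_degradation
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_is_not_degradation(self):
        fit = fit_first_order_rate(
            DecaySeries(100.0, PAPER_GRID, (5.0,) * len(PAPER_GRID))
        )
        assert fit.k == 0.0
        assert not fit.significant_degradation

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        clean = np.exp(-0.05 * np.asarray(PAPER_GRID))
        noisy = clean * np.exp(rng.normal(scale=0.02, size=len(PAPER_GRID)))
        series = DecaySeries(120.0, PAPER_GRID, tuple(noisy))
        fit = fit_first_order_rate(series)
        assert abs(fit.k - grid_search_k(series)) <= 1e-4

    @given(
        k=st.floats(min_value=0.0, max_value=0.5),
        noise=st.lists(
            st.floats(min_value=-0.2, max_value=0.2), min_size=8, max_size=8
        ),
    )
    def test_oracle_agreement_on_random_instances(self, k, noise):
        values = tuple(
            math.exp(-k * t + e) for t, e in zip(PAPER_GRID, noise)
        )
        series = DecaySeries(120.0, PAPER_GRID, values)
        fit = fit_first_order_rate(series)
        assert abs(fit.k - grid_search_k(series, k_max=0.8)) <= 1e-4

    def test_nonpositive_value_names_the_time_point(self):
        values = (1.0, 0.8, 0.0, 0.5, 0.4, 0.2, 0.1, 0.05)
        with pytest.raises(TransformError, match="t=5"):
            fit_first_order_rate(DecaySeries(120.0, PAPER_GRID, values))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_first_order_rate(DecaySeries(120.0, (0.0, 5.0), (1.0, 0.5)))


@pytest.mark.parametrize(
    "k, expected_d",
    [
        (2.28e-2, 101.0),  # published 120 °C anthocyanin rate
        (math.log(10.0), 1.0),
        (0.2268, 10.15),  # published 180 °C anthocyanin rate
    ],
)
def test_decimal_reduction_time(k, expected_d):
    assert decimal_reduction_time(k) == pytest.approx(expected_d, rel=1e-2)


@pytest.mark.parametrize(
    "k, expected_t12",
    [
        (2.28e-2, 30.40),
        (math.log(2.0), 1.0),
        (0.0485, 14.29),  # published 180 °C antioxidant rate (printed 14.26)
    ],
)
def test_half_life(k, expected_t12):
    assert half_life(k) == pytest.approx(expected_t12, rel=1e-2)


def test_resistance_parameters_require_positive_rate():
    for bad in (0.0, -0.1):
        with pytest.raises(NoDegradationError):
            decimal_reduction_time(bad)
        with pytest.raises(NoDegradationError):
            half_life(bad)


class TestZValue:
    def test_published_anthocyanin_d_column(self):
        df = purple_maize_anthocyanin_kinetics()
        fit = fit_z_value(list(zip(df.temperature_c, df.d_value_min)))
        assert fit.physical
        assert fit.z_value == pytest.approx(ANTHOCYANIN_REPORTED["z_c"][0], rel=0.02)

    def test_published_antioxidant_d_column(self):
        df = purple_maize_antioxidant_kinetics()
        fit = fit_z_value(list(zip(df.temperature_c, df.d_value_min)))
        assert fit.z_value == pytest.approx(ANTIOXIDANT_REPORTED["z_c"][0], rel=0.02)

    def test_exact_log_linear_input(self):
        z = 50.0
        pairs = [(t, 100.0 * 10 ** (-(t - 100.0) / z)) for t in (100, 120, 140, 160)]
        fit = fit_z_value(pairs)
        assert fit.z_value == pytest.approx(50.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.z_se == pytest.approx(0.0, abs=1e-6)

    def test_increasing_d_is_nonphysical_not_an_error(self):
        fit = fit_z_value([(100.0, 10.0), (120.0, 20.0), (140.0, 40.0)])
        assert not fit.physical
        assert math.isnan(fit.z_value)

    def test_too_few_temperatures(self):
        with pytest.raises(InsufficientDataError):
            fit_z_value([(100.0, 10.0), (120.0, 5.0)])


class TestArrhenius:
    def test_published_anthocyanin_k_column(self):
        df = purple_maize_anthocyanin_kinetics()
        fit = fit_arrhenius(list(zip(df.temperature_c, df.k_per_min)))
        assert fit.ea == pytest.approx(ANTHOCYANIN_REPORTED["ea_kj_mol"][0], rel=0.02)
        assert fit.n_temps == 7

    def test_published_antioxidant_k_column(self):
        df = purple_maize_antioxidant_kinetics()
        fit = fit_arrhenius(list(zip(df.temperature_c, df.k_per_min)))
        assert fit.ea == pytest.approx(ANTIOXIDANT_REPORTED["ea_kj_mol"][0], rel=0.03)
        assert fit.n_temps == 11

    def test_exact_arrhenius_input(self):
        ea, ln_a = 50.0, math.log(1e6)
        pairs = [
            (t, math.exp(ln_a - ea * 1000.0 / (GAS_CONSTANT * (t + 273.15))))
            for t in (100.0, 120.0, 140.0, 160.0, 180.0)
        ]
        fit = fit_arrhenius(pairs)
        assert fit.ea == pytest.approx(50.0, rel=1e-10)
        assert fit.ln_pre_exponential == pytest.approx(ln_a, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicate_temperatures_collapse_to_geometric_mean(self):
        base = [(100.0, 0.01), (120.0, 0.03), (140.0, 0.08)]
        dup = base + [(120.0, 0.12)]  # geometric mean with 0.03 is 0.06
        collapsed = [(100.0, 0.01), (120.0, 0.06), (140.0, 0.08)]
        assert fit_arrhenius(dup).ea == pytest.approx(
            fit_arrhenius(collapsed).ea, rel=1e-12
        )


@pytest.mark.parametrize(
    "k, minutes, expected",
    [
        (0.0485, 7.0, 71.2),  # ~30% antioxidant reduction at 180 °C for 7 min
        (0.1, 0.0, 100.0),
        (0.0, 500.0, 100.0),
    ],
)
def test_predicted_retention(k, minutes, expected):
    assert predicted_retention(k, minutes) == pytest.approx(expected, abs=0.1)


class TestSummarizeKinetics:
    def test_recovers_generator_and_classifies_thermostable_range(self):
        cfg = GeneratorConfig(ea_true=55.0, noise_cv=0.0, stable_below=120.0)
        series, truth = simulate_decay(cfg)
        summary = summarize_kinetics(series)
        assert summary.thermostable == (80.0, 90.0, 100.0, 110.0)
        assert [r.temperature for r in summary.rows] == [
            120.0, 130.0, 140.0, 150.0, 160.0, 170.0, 180.0
        ]
        assert summary.arrhenius.ea == pytest.approx(55.0, rel=1e-6)
        for row in summary.rows:
            assert row.k == pytest.approx(truth["k_true"][row.temperature], rel=1e-9)

    def test_all_flat_input_has_no_rows_and_no_cross_fits(self):
        series = [
            DecaySeries(t, PAPER_GRID, (3.0,) * len(PAPER_GRID))
            for t in (80.0, 90.0, 100.0)
        ]
        summary = summarize_kinetics(series)
        assert summary.rows == ()
        assert summary.thermostable == (80.0, 90.0, 100.0)
        assert summary.arrhenius is None and summary.z_fit is None

    def test_single_temperature_leaves_cross_fits_unavailable(self):
        summary = summarize_kinetics([_series(0.05)])
        assert len(summary.rows) == 1
        assert summary.arrhenius is None and summary.z_fit is None

    def test_replicates_are_averaged_before_fitting(self):
        reps = [
            DecaySeries(120.0, PAPER_GRID,
                        tuple(c0 * math.exp(-0.05 * t) for t in PAPER_GRID),
                        replicate_id=r)
            for c0, r in ((0.9, "r1"), (1.1, "r2"))
        ]
        summary = summarize_kinetics(reps)
        assert len(summary.rows) == 1
        assert summary.rows[0].k == pytest.approx(0.05, rel=1e-9)

    def test_row_identities(self):
        cfg = GeneratorConfig(noise_cv=0.0, temperatures=(120.0, 150.0, 180.0),
                              stable_below=None)
        series, _ = simulate_decay(cfg)
        summary = summarize_kinetics(series)
        for row in summary.rows:
            assert row.d_value * row.k == pytest.approx(math.log(10.0), rel=1e-12)
            assert row.half_life * row.k == pytest.approx(math.log(2.0), rel=1e-12)
            assert row.half_life / row.d_value == pytest.approx(
                math.log10(2.0), rel=1e-12
            )


def test_rate_increases_with_temperature_at_zero_noise():
    cfg = GeneratorConfig(noise_cv=0.0, stable_below=None)
    series, _ = simulate_decay(cfg)
    summary = summarize_kinetics(series)
    ks = [r.k for r in summary.rows]
    assert all(b > a for a, b in zip(ks, ks[1:]))


def test_z_and_ea_are_linked_by_the_midrange_approximation():
    """z ≈ ln(10)·R·T_mid²/Ea (T_mid in kelvin) — an approximate identity the
    published anthocyanin parameters satisfy within 5%."""
    ea = ANTHOCYANIN_REPORTED["ea_kj_mol"][0] * 1000.0
    z = ANTHOCYANIN_REPORTED["z_c"][0]
    t_mid = 423.0
    assert math.log(10.0) * GAS_CONSTANT * t_mid**2 / ea == pytest.approx(z, rel=0.05)


def test_first_order_beats_zero_order_on_exponential_data():
    series = _series(0.1, c0=10.0)
    r2 = compare_reaction_orders(series)
    assert r2["first_order_r2"] == pytest.approx(1.0)
    assert r2["first_order_r2"] > r2["zero_order_r2"]
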