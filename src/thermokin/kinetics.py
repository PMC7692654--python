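"""First-order thermal degradation kinetics and thermal-resistance parameters.

The model: at a constant holding temperature the concentration (or antioxidant
activity) decays as C(t) = C₀·e^(−kt). The rate constant k is estimated by
ordinary least squares of ln(C_t/C₀) on time, with a free intercept (robust to
measurement error in C₀; the intercept is reported so the forced-origin
variant is recoverable). From k follow the classical thermal-resistance
parameters:

* decimal reduction time D = ln(10)/k (time for a 10-fold reduction),
* half-life t½ = ln(2)/k,
* z-value: the temperature increase producing a 10-fold drop in D, fitted as
  −1/slope of log₁₀(D) versus temperature,
* activation energy Ea from the Arrhenius law ln k = ln A − Ea/(R·T_K),
  fitted as −slope·R of ln k versus 1/T_K.

"No significant degradation" is operationalised as a one-sided t-test on the
ln-linear slope (H₁: slope < 0) at a configurable α; temperatures that fail
the test are classified thermostable and excluded from the Ea/z regressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    NoDegradationError,
    ParameterError,
    TransformError,
    ValidationError,
)

__all__ = [
    "GAS_CONSTANT",
    "ABSOLUTE_ZERO_C",
    "DecaySeries",
    "RateFit",
    "ZValueFit",
    "ArrheniusFit",
    "SummaryRow",
    "ThermalSummary",
    "fit_first_order_rate",
    "decimal_reduction_time",
    "half_life",
    "fit_z_value",
    "fit_arrhenius",
    "predicted_retention",
    "summarize_kinetics",
    "compare_reaction_orders",
    "celsius_to_kelvin",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
ABSOLUTE_ZERO_C = -273.15


def celsius_to_kelvin(temperature_c: float) -> float:
    if temperature_c <= ABSOLUTE_ZERO_C:
        raise ParameterError(f"temperature {temperature_c} °C is at/below absolute zero")
    return temperature_c + 273.15


@dataclass(frozen=True)
class DecaySeries:
    """One temperature's concentration/activity-versus-time record.

    Times are minutes, strictly increasing and starting at 0; values share one
    unit throughout and must be positive at t = 0.
    """

    temperature: float  # °C
    times: tuple[float, ...]  # min
    values: tuple[float, ...]
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if len(times) != len(values):
            raise ValidationError(
                f"times ({len(times)}) and values ({len(values)}) differ in length"
            )
        if len(times) == 0:
            raise ValidationError("empty decay series")
        if not all(math.isfinite(t) for t in times) or not all(
            math.isfinite(v) for v in values
        ):
            raise ValidationError("decay series contains non-finite entries")
        if times[0] != 0:
            raise ValidationError(f"first time point must be 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"times not strictly increasing: {times}")
        if values[0] <= 0:
            raise ValidationError(f"value at t=0 must be > 0, got {values[0]}")


@dataclass(frozen=True)
class RateFit:
    """A fitted first-order rate constant with its inference."""

    k: float  # min^-1, >= 0
    k_se: float  # min^-1
    intercept: float  # ln-ratio units
    r_squared: float
    n_points: int
    significant_degradation: bool
    alpha: float
    p_value: float


@dataclass(frozen=True)
class ZValueFit:
    z_value: float  # °C
    z_se: float  # °C
    r_squared: float
    n_temps: int
    physical: bool  # False when D did not decrease with temperature


@dataclass(frozen=True)
class ArrheniusFit:
    ea: float  # kJ mol^-1
    ea_se: float  # kJ mol^-1
    ln_pre_exponential: float  # ln(min^-1)
    slope_se: float  # K
    r_squared: float
    n_temps: int


@dataclass(frozen=True)
class SummaryRow:
    temperature: float  # °C
    k: float  # min^-1
    k_se: float
    d_value: float  # min
    half_life: float  # min
    r_squared: float


@dataclass(frozen=True)
class ThermalSummary:
    """Per-temperature rate parameters plus the cross-temperature Ea and z fits.

    ``rows`` holds only temperatures with statistically significant
    degradation; ``thermostable`` lists those that showed none. ``arrhenius``
    and ``z_fit`` are None when fewer than 3 significant temperatures exist.
    """

    rows: tuple[SummaryRow, ...]
    thermostable: tuple[float, ...]
    arrhenius: Optional[ArrheniusFit]
    z_fit: Optional[ZValueFit]
    alpha: float
    gas_constant: float = field(default=GAS_CONSTANT)


def _ols(x: np.ndarray, y: np.ndarray):
    """linregress wrapper that tolerates a constant response (r := 0)."""
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return res, min(r2, 1.0)


def fit_first_order_rate(series: DecaySeries, alpha: float = 0.05) -> RateFit:
    """Estimate k by OLS of ln(C_t/C₀) on t.

    k = −slope, clipped at 0 (growth is reported as k = 0, never significant).
    ``significant_degradation`` is a one-sided t-test of slope < 0 at ``alpha``;
    an exact fit (zero residual variance) is significant iff the slope is
    negative.

    Raises
    ------
    TransformError
        Any non-positive value (the ln transform is undefined), naming the
        offending time point.
    InsufficientDataError
        Fewer than 3 time points.
    """
    if not 0 < alpha < 0.5:
        raise ParameterError(f"alpha must be in (0, 0.5), got {alpha}")
    if len(series.times) < 3:
        raise InsufficientDataError(
            f"need >= 3 time points to fit, got {len(series.times)}"
        )
    for t, v in zip(series.times, series.values):
        if v <= 0:
            raise TransformError(
                f"non-positive value {v} at t={t} min "
                f"({series.temperature} °C): ln transform undefined"
            )
    t = np.asarray(series.times)
    y = np.log(np.asarray(series.values) / series.values[0])
    res, r2 = _ols(t, y)
    df = len(t) - 2
    if res.stderr > 0:
        t_stat = res.slope / res.stderr
        p = float(stats.t.cdf(t_stat, df))  # one-sided: H1 slope < 0
        significant = p < alpha
    else:
        # exact fit: degradation is certain iff the slope is strictly negative
        p = 0.0 if res.slope < 0 else 1.0
        significant = res.slope < 0
    return RateFit(
        k=max(0.0, -float(res.slope)),
        k_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(t),
        significant_degradation=bool(significant),
        alpha=alpha,
        p_value=p,
    )


def decimal_reduction_time(k: float) -> float:
    """D-value: time for a 10-fold reduction, ln(10)/k. Requires k > 0."""
    if not (math.isfinite(k) and k > 0):
        raise NoDegradationError(f"D-value undefined for k={k!r} (needs k > 0)")
    return math.log(10.0) / k


def half_life(k: float) -> float:
    """t½: time for a 2-fold reduction, ln(2)/k. Requires k > 0."""
    if not (math.isfinite(k) and k > 0):
        raise NoDegradationError(f"half-life undefined for k={k!r} (needs k > 0)")
    return math.log(2.0) / k


def fit_z_value(d_by_temp: Sequence[tuple[float, float]]) -> ZValueFit:
    """z-value from OLS of log₁₀(D) on temperature; z = −1/slope.

    The standard error of z follows by the delta method:
    SE(z) = SE(slope)/slope². A non-negative slope (D not decreasing with
    temperature) is returned as a non-physical result rather than an error.
    """
    if len(d_by_temp) < 3:
        raise InsufficientDataError(
            f"need >= 3 temperatures for a z-value, got {len(d_by_temp)}"
        )
    temps = np.asarray([p[0] for p in d_by_temp], dtype=float)
    d = np.asarray([p[1] for p in d_by_temp], dtype=float)
    if np.any(d <= 0):
        raise TransformError("all D values must be > 0 for the log10 transform")
    if len(np.unique(temps)) < 3:
        raise InsufficientDataError("need >= 3 distinct temperatures")
    res, r2 = _ols(temps, np.log10(d))
    if res.slope >= 0:
        logger.warning(
            "non-physical z-value fit: D does not decrease with temperature"
        )
        return ZValueFit(
            z_value=math.nan, z_se=math.nan, r_squared=r2,
            n_temps=len(temps), physical=False,
        )
    z = -1.0 / float(res.slope)
    z_se = float(res.stderr) / float(res.slope) ** 2
    return ZValueFit(z_value=z, z_se=z_se, r_squared=r2,
                     n_temps=len(temps), physical=True)


def fit_arrhenius(k_by_temp: Sequence[tuple[float, float]]) -> ArrheniusFit:
    """Activation energy from OLS of ln k on 1/T_K; Ea = −slope·R, in kJ/mol.

    Temperatures are °C and converted with T_K = T + 273.15. Duplicate
    temperatures are collapsed by the geometric mean of their k values (with a
    logged note), since the ln-space regression averages them anyway.
    """
    if len(k_by_temp) < 3:
        raise InsufficientDataError(
            f"need >= 3 temperatures for an Arrhenius fit, got {len(k_by_temp)}"
        )
    temps = np.asarray([p[0] for p in k_by_temp], dtype=float)
    k = np.asarray([p[1] for p in k_by_temp], dtype=float)
    if np.any(k <= 0):
        raise TransformError("all rate constants must be > 0 for the ln transform")
    uniq = np.unique(temps)
    if len(uniq) != len(temps):
        logger.info("duplicate temperatures collapsed by geometric-mean k")
        k = np.asarray(
            [math.exp(np.mean(np.log(k[temps == u]))) for u in uniq]
        )
        temps = uniq
    if len(temps) < 3:
        raise InsufficientDataError("need >= 3 distinct temperatures")
    inv_tk = 1.0 / np.asarray([celsius_to_kelvin(t) for t in temps])
    res, r2 = _ols(inv_tk, np.log(k))
    ea_j = -float(res.slope) * GAS_CONSTANT  # J/mol
    return ArrheniusFit(
        ea=ea_j / 1000.0,
        ea_se=float(res.stderr) * GAS_CONSTANT / 1000.0,
        ln_pre_exponential=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=r2,
        n_temps=len(temps),
    )


def predicted_retention(k: float, minutes: float) -> float:
    """Percent remaining after holding for ``minutes``: 100·e^(−k·t)."""
    if minutes < 0:
        raise ParameterError(f"duration must be >= 0, got {minutes}")
    if k < 0:
        raise ParameterError(f"rate constant must be >= 0, got {k}")
    return 100.0 * math.exp(-k * minutes)


def _merge_replicates(group: Sequence[DecaySeries]) -> DecaySeries:
    """Average replicate series at one temperature, point-wise over the
    union time grid (unweighted; per-point spread is not propagated into the
    default unweighted fit)."""
    if len(group) == 1:
        return group[0]
    by_time: dict[float, list[float]] = {}
    for s in group:
        for t, v in zip(s.times, s.values):
            by_time.setdefault(t, []).append(v)
    times = tuple(sorted(by_time))
    values = tuple(float(np.mean(by_time[t])) for t in times)
    return DecaySeries(
        temperature=group[0].temperature, times=times, values=values,
        replicate_id="mean",
    )


def summarize_kinetics(
    series_set: Sequence[DecaySeries], alpha: float = 0.05
) -> ThermalSummary:
    """Full thermal-resistance summary across temperatures.

    Replicates at the same temperature are averaged before fitting. Each
    temperature is classified significant/thermostable by
    :func:`fit_first_order_rate`; the significant rows carry k, D = ln(10)/k
    and t½ = ln(2)/k, and — when at least 3 exist — feed the Arrhenius (Ea)
    and z-value regressions. D values for the z fit are derived from the
    fitted k, not re-entered independently.
    """
    if not series_set:
        raise InsufficientDataError("no decay series supplied")
    groups: dict[float, list[DecaySeries]] = {}
    for s in series_set:
        groups.setdefault(s.temperature, []).append(s)

    rows: list[SummaryRow] = []
    thermostable: list[float] = []
    for temp in sorted(groups):
        fit = fit_first_order_rate(_merge_replicates(groups[temp]), alpha=alpha)
        if fit.significant_degradation and fit.k > 0:
            rows.append(
                SummaryRow(
                    temperature=temp,
                    k=fit.k,
                    k_se=fit.k_se,
                    d_value=decimal_reduction_time(fit.k),
                    half_life=half_life(fit.k),
                    r_squared=fit.r_squared,
                )
            )
        else:
            thermostable.append(temp)

    arrhenius = z_fit = None
    if len(rows) >= 3:
        arrhenius = fit_arrhenius([(r.temperature, r.k) for r in rows])
        z_fit = fit_z_value([(r.temperature, r.d_value) for r in rows])
    return ThermalSummary(
        rows=tuple(rows),
        thermostable=tuple(thermostable),
        arrhenius=arrhenius,
        z_fit=z_fit,
        alpha=alpha,
    )


def compare_reaction_orders(series: DecaySeries) -> dict[str, float]:
    """Model-selection helper: r² of zero-order (C on t) versus first-order
    (ln C on t) linear fits. First-order is the package default and the only
    model used downstream; this comparison just documents the choice per
    dataset."""
    if len(series.times) < 3:
        raise InsufficientDataError("need >= 3 points to compare models")
    t = np.asarray(series.times)
    c = np.asarray(series.values)
    _, r2_zero = _ols(t, c)
    if np.any(c <= 0):
        raise TransformError("first-order comparison needs positive values")
    _, r2_first = _ols(t, np.log(c / c[0]))
    return {"zero_order_r2": r2_zero, "first_order_r2": r2_first}
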