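"""Spectrophotometric quantification of anthocyanins and antioxidant activity.

Two assays are covered:

* the **pH-differential method** for total monomeric anthocyanin content (TAC),
  which exploits the reversible flavylium/hemiketal equilibrium between pH 1.0
  and pH 4.5 — the net absorbance difference isolates the monomeric pigment —
  and converts it to cyanidin-3-O-glucoside (C3G) equivalents per gram dry
  weight via Beer–Lambert with the C3G molar absorptivity;
* the **DPPH radical-scavenging assay**, calibrated against a Trolox standard
  series and expressed as Trolox equivalents per gram dry weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidReadingError,
    ParameterError,
)

__all__ = [
    "AbsorbanceQuadruple",
    "PhDifferentialParams",
    "CalibrationCurve",
    "TacResult",
    "net_absorbance",
    "tac_ph_differential",
    "fit_trolox_calibration",
    "trolox_equivalents",
    "MG_PER_G_SCALE",
]

#: Unit-resolution constant of the pH-differential formula.
#:
#: (Abs / (epsilon * L)) is mol/L; * MW (g/mol) gives g/L == mg/mL; * final
#: volume (mL) gives mg of pigment; dividing by the dry mass in mg gives
#: mg pigment per mg sample, and expressing that per *gram* of sample
#: multiplies by 1000. One constant, unit-tested, so the bookkeeping cannot
#: silently drift.
MG_PER_G_SCALE = 1000.0

#: Readings above this magnitude are outside any spectrophotometer's linear
#: range and are rejected as implausible.
DEFAULT_ABSORBANCE_CAP = 4.0


@dataclass(frozen=True)
class AbsorbanceQuadruple:
    """The four readings of one pH-differential measurement.

    A520/A700 at pH 1.0 and pH 4.5. A700 is the haze/turbidity reference.
    Small negative values are tolerated (instrument noise around zero).
    """

    a520_ph1: float
    a700_ph1: float
    a520_ph45: float
    a700_ph45: float
    cap: float = DEFAULT_ABSORBANCE_CAP

    def __post_init__(self) -> None:
        for name in ("a520_ph1", "a700_ph1", "a520_ph45", "a700_ph45"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidReadingError(f"{name} is not finite: {v!r}")
            if abs(v) > self.cap:
                raise InvalidReadingError(
                    f"{name}={v} exceeds the absorbance cap {self.cap}"
                )


@dataclass(frozen=True)
class PhDifferentialParams:
    """Constants and sample bookkeeping for the pH-differential formula.

    Defaults are the standard cyanidin-3-O-glucoside values: molar
    absorptivity 26 900 L mol⁻¹ cm⁻¹, 1 cm path, molecular weight 449.2 Da.
    """

    epsilon: float = 26900.0  # L mol^-1 cm^-1
    path_length: float = 1.0  # cm
    mol_weight: float = 449.2  # g/mol
    dilution_factor: float = 1.0  # dimensionless, >= 1
    final_volume: float = 1.0  # mL
    dry_mass: float = 1.0  # mg

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_length", "mol_weight", "final_volume", "dry_mass"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (math.isfinite(self.dilution_factor) and self.dilution_factor >= 1):
            raise ParameterError(
                f"dilution_factor must be >= 1, got {self.dilution_factor!r}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear calibration: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    concentration_unit: str = "mmol Trolox"
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DegenerateDesignError("calibration slope must be nonzero")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ParameterError(f"r_squared outside [0, 1]: {self.r_squared!r}")
        if self.n_points < 2:
            raise InsufficientDataError("calibration needs at least 2 points")


@dataclass(frozen=True)
class TacResult:
    """TAC in mg C3G equivalents per g dry weight, with a below-detection flag."""

    tac_mg_per_g: float
    net_abs: float
    below_detection: bool


def net_absorbance(q: AbsorbanceQuadruple) -> float:
    """Net pH-differential absorbance.

    Abs = (A520 − A700) at pH 1.0 minus (A520 − A700) at pH 4.5. May be ≤ 0,
    which signals that no monomeric anthocyanin is detectable.
    """
    return (q.a520_ph1 - q.a700_ph1) - (q.a520_ph45 - q.a700_ph45)


def tac_ph_differential(q: AbsorbanceQuadruple, p: PhDifferentialParams) -> TacResult:
    """Total monomeric anthocyanin content by the pH-differential method.

    TAC [mg C3G / g DW] = (Abs / (ε·L)) · MW · DF · V / M · 1000, where Abs is
    :func:`net_absorbance`, ε the molar absorptivity, L the path length, MW the
    C3G molecular weight, DF the dilution factor, V the final volume in mL and
    M the dry mass in mg (see :data:`MG_PER_G_SCALE` for the unit resolution).

    A non-positive net absorbance yields a flagged zero rather than an error so
    that time-series pipelines can continue past fully degraded samples.
    """
    abs_net = net_absorbance(q)
    if abs_net <= 0:
        return TacResult(tac_mg_per_g=0.0, net_abs=abs_net, below_detection=True)
    tac = (
        (abs_net / (p.epsilon * p.path_length))
        * p.mol_weight
        * p.dilution_factor
        * p.final_volume
        / p.dry_mass
        * MG_PER_G_SCALE
    )
    return TacResult(tac_mg_per_g=tac, net_abs=abs_net, below_detection=False)


def fit_trolox_calibration(
    standards: Sequence[tuple[float, float]],
    concentration_unit: str = "mmol Trolox",
) -> CalibrationCurve:
    """Ordinary least-squares line through a (concentration, response) series.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 standards.
    DegenerateDesignError
        All standard concentrations identical (zero design variance).
    """
    if len(standards) < 3:
        raise InsufficientDataError(
            f"need >= 3 calibration standards, got {len(standards)}"
        )
    conc = np.asarray([s[0] for s in standards], dtype=float)
    resp = np.asarray([s[1] for s in standards], dtype=float)
    if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(resp))):
        raise InvalidReadingError("calibration standards contain non-finite values")
    if np.ptp(conc) == 0:
        raise DegenerateDesignError("all calibration concentrations are identical")
    res = stats.linregress(conc, resp)
    # a perfectly constant response has r undefined; report r^2 = 0
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        concentration_unit=concentration_unit,
        n_points=len(standards),
    )


def trolox_equivalents(
    response: float,
    curve: CalibrationCurve,
    dry_mass_basis: float = 1.0,
) -> tuple[float, bool]:
    """Invert a calibration curve: response → Trolox equivalents per g DW.

    Returns ``(activity, below_range)`` where ``activity`` is
    (response − intercept) / slope scaled per gram dry weight and
    ``below_range`` flags a negative (sub-calibration) result.
    """
    if not (math.isfinite(dry_mass_basis) and dry_mass_basis > 0):
        raise ParameterError(f"dry_mass_basis must be > 0, got {dry_mass_basis!r}")
    value = (response - curve.intercept) / curve.slope / dry_mass_basis
    return value, value < 0
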