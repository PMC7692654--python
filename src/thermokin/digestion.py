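"""Sequential gastric → intestinal in vitro digestion analysis.

An extract (optionally heat-pretreated) is incubated in simulated gastric
juice (pepsin, pH 2) for 2 h, then an aliquot is diluted into simulated
intestinal juice (pancreatin/bicarbonate, pH 7) for another 2 h, with TAC and
DPPH activity sampled every 30 min in each phase. This module computes
phase-relative retention (each phase rebased to its own t = 0), handles the
dilution bookkeeping at the phase transition, and correlates anthocyanin loss
with antioxidant-activity loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "DigestionCourse",
    "phase_retention",
    "apply_intestinal_dilution",
    "loss_correlation",
    "DEFAULT_DIGESTA_VOLUME_ML",
    "DEFAULT_INTESTINAL_JUICE_ML",
]

DEFAULT_DIGESTA_VOLUME_ML = 5.0
DEFAULT_INTESTINAL_JUICE_ML = 10.0

Phase = Literal["gastric", "intestinal"]


@dataclass(frozen=True)
class DigestionCourse:
    """One pretreatment × phase time course of TAC and DPPH activity.

    ``times`` are minutes within the phase (0, 30, …, 120); both assays are
    sampled on the same grid. ``dilution_applied`` records whether the
    intestinal-phase values were already rescaled for the juice addition.
    """

    pretreatment: str
    phase: Phase
    times: tuple[float, ...]
    tac_values: tuple[float, ...]
    dpph_values: tuple[float, ...]
    dilution_applied: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "tac_values", tuple(float(v) for v in self.tac_values))
        object.__setattr__(self, "dpph_values", tuple(float(v) for v in self.dpph_values))
        if self.phase not in ("gastric", "intestinal"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        n = len(self.times)
        if n == 0:
            raise ValidationError("empty digestion course")
        if len(self.tac_values) != n or len(self.dpph_values) != n:
            raise ValidationError("assay grids differ in length from the time grid")
        if self.times[0] != 0:
            raise ValidationError("phase time grid must start at 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError(f"times not strictly increasing: {self.times}")
        for name in ("tac_values", "dpph_values"):
            vals = getattr(self, name)
            if any(not math.isfinite(v) or v < 0 for v in vals):
                raise ValidationError(f"{name} must be finite and nonnegative")


def phase_retention(course: DigestionCourse) -> pd.DataFrame:
    """Percent of the phase-initial value retained at each sampling time.

    Returns a tidy frame with columns ``time_min``, ``assay`` (tac | dpph),
    ``retention_pct`` and ``decrease_pct`` (= 100 − retention). Retention is
    relative to the course's own t = 0, so it is invariant to any constant
    rescaling of the whole course (including the intestinal dilution, as long
    as it is applied to the entire phase).
    """
    records = []
    for assay, values in (("tac", course.tac_values), ("dpph", course.dpph_values)):
        if values[0] <= 0:
            raise ValidationError(
                f"{assay} value at phase start is {values[0]}: retention undefined"
            )
        for t, v in zip(course.times, values):
            retention = 100.0 * v / values[0]
            records.append(
                {
                    "pretreatment": course.pretreatment,
                    "phase": course.phase,
                    "assay": assay,
                    "time_min": t,
                    "retention_pct": retention,
                    "decrease_pct": 100.0 - retention,
                }
            )
    return pd.DataFrame.from_records(records)


def apply_intestinal_dilution(
    gastric_end_value: float,
    digesta_volume: float = DEFAULT_DIGESTA_VOLUME_ML,
    added_juice_volume: float = DEFAULT_INTESTINAL_JUICE_ML,
) -> float:
    """Concentration after mixing digesta with intestinal juice.

    With the default 5 mL digesta + 10 mL juice the factor is 1/3. The inverse
    (multiplying by (V_d + V_j)/V_d) restores the gastric-end concentration,
    so both raw and dilution-corrected series can be carried downstream.
    """
    if digesta_volume <= 0 or added_juice_volume <= 0:
        raise ParameterError("volumes must be > 0")
    return gastric_end_value * digesta_volume / (digesta_volume + added_juice_volume)


def loss_correlation(
    courses: Sequence[DigestionCourse],
    times: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Pearson correlation between TAC loss and DPPH-activity loss.

    Percent losses (100 − retention) are paired per (course, time) and pooled
    across phases and pretreatments; t = 0 points (identically zero loss) are
    excluded. Returns ``(r, p_value)``.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 pooled pairs.
    ValidationError
        Zero variance in either loss series (correlation undefined).
    """
    tac_loss: list[float] = []
    dpph_loss: list[float] = []
    for course in courses:
        ret = phase_retention(course)
        if times is not None:
            ret = ret[ret["time_min"].isin(times)]
        ret = ret[ret["time_min"] > 0]
        wide = ret.pivot_table(
            index="time_min", columns="assay", values="decrease_pct", sort=True
        )
        tac_loss.extend(wide["tac"].tolist())
        dpph_loss.extend(wide["dpph"].tolist())
    if len(tac_loss) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired loss points, got {len(tac_loss)}"
        )
    x = np.asarray(tac_loss)
    y = np.asarray(dpph_loss)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in a loss series: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
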