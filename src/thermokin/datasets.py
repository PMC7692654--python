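"""Published reference kinetics for purple maize flour extract.

Two small tables of published thermal-degradation parameters for anthocyanins
(total monomeric content, 120–180 °C) and DPPH antioxidant activity
(80–180 °C) in purple maize flour extract: per-temperature first-order rate
constants k (min⁻¹) with their reported decimal-reduction times D (min) and
half-lives t½ (min). They serve as worked inputs for the cross-temperature
regressions (Arrhenius activation energy, z-value) and as ground truth for
consistency tests; the reported Ea/z summary values are carried alongside for
reference, never fed back into any fit.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "purple_maize_anthocyanin_kinetics",
    "purple_maize_antioxidant_kinetics",
    "ANTHOCYANIN_REPORTED",
    "ANTIOXIDANT_REPORTED",
]

# temperature_c, k_per_min, d_value_min, half_life_min
_ANTHOCYANIN_ROWS = [
    (120.0, 2.28e-2, 101.01, 30.40),
    (130.0, 4.99e-2, 46.08, 13.86),
    (140.0, 7.39e-2, 31.15, 9.37),
    (150.0, 14.37e-2, 16.02, 4.82),
    (160.0, 16.95e-2, 13.58, 4.08),
    (170.0, 19.29e-2, 11.93, 3.59),
    (180.0, 22.68e-2, 10.15, 3.05),
]

_ANTIOXIDANT_ROWS = [
    (80.0, 0.16e-2, 1428.57, 429.96),
    (90.0, 0.34e-2, 666.66, 200.65),
    (100.0, 0.57e-2, 400.00, 120.39),
    (110.0, 0.64e-2, 357.14, 107.49),
    (120.0, 1.42e-2, 161.29, 48.54),
    (130.0, 1.70e-2, 135.13, 40.67),
    (140.0, 1.93e-2, 119.04, 35.83),
    (150.0, 2.18e-2, 105.26, 31.68),
    (160.0, 2.23e-2, 103.09, 31.02),
    (170.0, 3.91e-2, 58.82, 17.70),
    (180.0, 4.85e-2, 47.39, 14.26),
]

_COLUMNS = ["temperature_c", "k_per_min", "d_value_min", "half_life_min"]

#: Reported cross-temperature summaries (value, standard error, r²) — kept for
#: comparison in tests and examples only.
ANTHOCYANIN_REPORTED = {
    "ea_kj_mol": (55.75, 6.83, 0.93),
    "z_c": (61.72, 2.28, 0.90),
}
ANTIOXIDANT_REPORTED = {
    "ea_kj_mol": (41.12, 3.00, 0.95),
    "z_c": (75.75, 2.87, 0.93),
}


def purple_maize_anthocyanin_kinetics() -> pd.DataFrame:
    """Published per-temperature kinetics of total monomeric anthocyanin
    degradation (120–180 °C; below 120 °C the pigment was thermostable)."""
    return pd.DataFrame(_ANTHOCYANIN_ROWS, columns=_COLUMNS)


def purple_maize_antioxidant_kinetics() -> pd.DataFrame:
    """Published per-temperature kinetics of DPPH antioxidant-activity
    degradation (80–180 °C)."""
    return pd.DataFrame(_ANTIOXIDANT_ROWS, columns=_COLUMNS)
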