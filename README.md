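# thermokin

Thermal degradation kinetics of anthocyanins and antioxidant activity in
food extracts — from raw spectrophotometric readings to the full
thermal-resistance parameter set, plus in vitro digestion release analysis.

The package is aimed at food chemists and process engineers who hold
time–temperature assay tables (anthocyanin content by the pH-differential
method, DPPH antioxidant activity against a Trolox calibration) and need the
kinetic parameters that predict quality loss during thermal processing.

## The model

At a constant holding temperature, first-order degradation:

    C(t) = C0 · exp(−k t)

`k` (min⁻¹) is estimated by ordinary least squares of ln(C_t/C₀) on time,
with a one-sided t-test on the slope deciding whether a temperature degrades
at all (thermostable otherwise). From `k` follow the classical
thermal-resistance parameters:

- decimal reduction time **D = ln(10)/k** (min, 10-fold reduction),
- half-life **t½ = ln(2)/k** (min),
- **z-value** = −1/slope of log₁₀(D) vs temperature (°C for a 10-fold drop in D),
- activation energy **Ea = −slope·R** from the Arrhenius regression
  ln k vs 1/T_K (kJ/mol, R = 8.314 J mol⁻¹ K⁻¹).

Quantification uses the pH-differential method,
TAC = Abs/(ε·L) · MW · DF · V/M · 1000 (mg cyanidin-3-O-glucoside
equivalents per g dry weight, ε = 26 900 L mol⁻¹ cm⁻¹, MW = 449.2 Da), and a
linear Trolox calibration for DPPH activity. The digestion module computes
phase-relative retention over sequential gastric → intestinal incubation
(with the 5 mL digesta + 10 mL juice dilution handled at the phase switch)
and the Pearson correlation between anthocyanin loss and antioxidant-activity
loss. A synthetic-data module generates every input with known ground truth
for parameter-recovery testing.

## Worked example

Refit the published purple-maize kinetic tables
(`examples/refit_published_tables.py`):

```
anthocyanins (120-180 °C)
  Ea refit  55.80 ± 6.84 kJ/mol (r^2 0.93)   reported 55.75 ± 6.83
  z  refit  61.84 ± 8.75 °C    (r^2 0.91)   reported 61.72 ± 2.28
antioxidant activity (80-180 °C)
  Ea refit  41.30 ± 3.00 kJ/mol (r^2 0.95)   reported 41.12 ± 3.0
  z  refit  75.48 ± 6.80 °C    (r^2 0.93)   reported 75.75 ± 2.87
```

The Arrhenius and z regressions over the printed per-temperature k and D
columns reproduce the reported cross-temperature summaries to a fraction of a
percent: an anthocyanin activation energy near 56 kJ/mol means a 10 °C step
roughly doubles the degradation rate in this range, and a z-value of ~62 °C
says color loss is far less temperature-sensitive than microbial
inactivation (z ≈ 5–12 °C).

A full synthetic run (`examples/thermal_kinetics.py`) simulates triplicate
decay series on the 80–180 °C / 0–40 min study grid, classifies 80–110 °C as
thermostable, and recovers the generating parameters:

```
Ea fitted / true      : 55.99 / 55.75 kJ/mol
z fitted              : 60.99 ± 1.24 °C
```

The other examples cover assay quantification
(`examples/quantify_extract.py`) and digestion release
(`examples/digestion_release.py`). The same stages are scriptable through a
thin CLI (`thermokin simulate|quantify|fit|summary|arrhenius|zvalue|digest|report`).

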