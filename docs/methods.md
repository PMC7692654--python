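# Methods

## Degradation model and rate estimation

Each holding temperature is modelled as first-order decay,
C(t) = C₀·e^(−kt). The fit is ordinary least squares of y = ln(C_t/C₀) on t
with a **free intercept**: forcing the line through the origin would make the
fit hostage to measurement error in the single t = 0 reading, while the free
intercept costs one degree of freedom and is reported so the forced-origin
variant is recoverable. `k = −slope`, clipped at zero (apparent growth is
reported as no degradation, never a negative rate); `k_se` is the OLS slope
standard error.

Whether a temperature degrades at all is decided by a one-sided t-test of
slope < 0 at α = 0.05 (configurable). Temperatures failing the test are
classified *thermostable* and excluded from the cross-temperature
regressions. An exact fit (zero residual variance) counts as significant iff
the slope is strictly negative, so noiseless synthetic data classify
deterministically. Replicates at the same temperature are averaged per time
point before fitting (unweighted; the per-point spread is not propagated —
a weighted variant was considered and deferred as out of proportion to the
3-replicate designs this targets).

Model choice between zero- and first-order is exposed as an r² comparison
(`compare_reaction_orders`); first-order is the default and the only model
used downstream.

## Thermal-resistance parameters

- D = ln(10)/k, t½ = ln(2)/k — exact identities, enforced per summary row.
- z-value: OLS of log₁₀(D) on temperature (°C); z = −1/slope, with
  SE(z) = SE(slope)/slope² by the delta method. A non-negative slope (D not
  decreasing with temperature) yields a flagged non-physical result, not an
  exception. In the pipeline the D values feeding this regression are derived
  from the fitted k, not re-entered by hand.
- Arrhenius: OLS of ln k on 1/T_K with T_K = T_°C + 273.15 and
  R = 8.314 J mol⁻¹ K⁻¹; Ea = −slope·R reported in kJ/mol, slope SE
  propagated linearly. Duplicate temperatures are collapsed by geometric-mean
  k (the ln-space mean) with a logged note.
- Both cross-fits require ≥ 3 significant temperatures; otherwise the summary
  carries its rows but flags Ea/z unavailable (rendered as explicit nulls).
- Useful consistency check (tested, approximate): z ≈ ln(10)·R·T_mid²/Ea,
  within 5% at T_mid = 423 K for the published anthocyanin parameters.

## Quantification

pH-differential: Abs = (A520 − A700)_pH1.0 − (A520 − A700)_pH4.5, and
TAC = Abs/(ε·L)·MW·DF·V/M·1000 in mg C3G equivalents per g dry weight
(ε = 26 900 L mol⁻¹ cm⁻¹, L = 1 cm, MW = 449.2 Da; V in mL, M in mg). The
single ×1000 constant resolves mg/mL-per-mg to mg/g and is pinned by a unit
test. Non-positive net absorbance returns a flagged zero ("below detection")
rather than raising, so time series can run past fully degraded samples.
Readings above 4.0 absorbance units are rejected as outside any instrument's
range. DPPH activity is a linear Trolox calibration (OLS, ≥ 3 distinct
standards) inverted per response; negative inversions are flagged
below-range. Standard concentrations are treated as mmol/L throughout.

## Digestion release

Phase-relative retention: each phase (gastric, intestinal) is rebased to its
own t = 0, making retention invariant to any whole-phase rescaling —
including the intestinal dilution (5 mL digesta into 10 mL juice, factor
1/3), which is therefore bookkeeping for concentrations, not for
percentages. Both raw and dilution-corrected series can be emitted; whether
published digestion decreases were dilution-corrected is not stated in the
source, so no default correction is silently applied to values. Loss
correlation is Pearson's r on pooled (TAC-loss%, DPPH-loss%) pairs across
times, phases and pretreatments, excluding the identically-zero t = 0 points.

## Synthetic data

Every generator is the exact forward model of one fitting operation and
returns its ground truth alongside the data (sidecar `truth.json` in file
output), so zero-noise round trips recover parameters to machine precision
and noisy runs quantify recovery. Defaults mirror the purple-maize study
design: 80–180 °C in 10 °C steps, sampling times 0, 2, 5, 7, 10, 20, 30,
40 min, triplicates, Ea = 55.75 kJ/mol anchored at k(120 °C) = 0.0228 min⁻¹,
thermostable below 120 °C, C₀ = 520.42 mg/g. The default noise model is
mean-preserving multiplicative lognormal (σ² = ln(1 + cv²)) because
spectrophotometric error scales with signal; cv defaults to 2%, a typical
repeatability for triplicate absorbance work (the source reports none). An
additive-Gaussian option resamples non-positive draws with bounded retries.
Digestion defaults invert the reported loss narrative
(k_gastric = −ln(0.79)/120 for a 21% loss over 120 min). The assay generator
back-solves the pH-differential formula and, when the implied net absorbance
exceeds the 1.0 linear-range limit, raises the dilution factor to the
minimal integer restoring feasibility.

What the generators deliberately do **not** emulate: Maillard browning and
copigmentation chemistry, pH-dependent flavylium speciation, enzyme kinetics
of the digestion juices, autocorrelated instrument drift, or heteroscedastic
replicate structure beyond the single cv. Passing recovery tests therefore
show the estimators are correct for the stated first-order/Arrhenius world
with multiplicative noise — not that real extracts obey that world.

## Numerical and testing choices

- All regressions run through one OLS backend; the test suite checks the rate
  fit against an independent brute-force grid-search SSE minimiser
  (k ∈ [0, 1], step 10⁻⁵, intercept profiled out) rather than a second call
  into the same library.
- Stochastic recovery is assessed over 200 seeded datasets at 5% noise on the
  120–180 °C degrading range (the regime where k recovery is defined):
  median relative k error ≤ 5%, and the fitted Ea inside the published
  ±6.83 kJ/mol band around the true 55.75 in ≥ 80% of runs. The band is the
  published uncertainty, not each fit's own standard error — ±1 own-SE
  coverage under t(5 df) is ~64% by construction and would test the t
  distribution, not the estimator.
- The thermostability classification test runs at zero noise, where the
  gate is deterministic; a companion Monte-Carlo test pins the noisy
  false-positive rate near the nominal α (any significance gate flags flat
  series at rate α — that is the test's size, not a defect).
- Comparisons against published values use 1–3% relative tolerances,
  reflecting that the printed k/D columns are rounded to 2–4 significant
  digits.
- Reports round to the precision the reference tables print (times and Ea/z
  to 2 decimals, k to 6); the CSV report carries its Ea/z footer as one
  `#`-prefixed JSON line so a single reader round-trips it byte-identically.
- Problem sizes throughout (11 temperatures × 8 time points × 3 replicates;
  200 recovery datasets; 400 gate simulations) match the study design while
  keeping the whole suite in seconds.

## Known limitations

- Single-phase first-order only: no biphasic, Weibull or
  fractional-conversion kinetics, and no non-isothermal (dynamic temperature)
  fitting.
- The z-value SE uses the delta method, which understates uncertainty for
  poorly determined slopes (r² far below the ~0.9 of the reference data).
- Published low-temperature antioxidant rows are internally inconsistent at
  printed precision (e.g. 80 °C: t½ printed 429.96 min vs ln 2/0.0016 =
  433.2 min); value-level tests pin the 180 °C row where rounding agrees,
  while the regression-level checks use the columns as printed.
- The digestion module analyses release; it does not model bioavailability,
  enzyme kinetics or pH-dependent speciation.
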