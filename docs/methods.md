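# Methods

`mitotherm` implements the inference chain used in fluorimeter-based
organelle thermometry: converting fluorescence time series from
mitochondrion-targeted temperature probes into calibrated temperature
shifts and absolute mitochondrial temperatures. Because raw instrument
traces are rarely distributed in machine-readable form, the package pairs
every analysis stage with a seeded forward simulator, so each estimator is
validated by parameter recovery: simulate a known thermal scenario, render
it through a probe model, analyse the rendered trace, and compare the
recovered quantity with the configured truth.

## Measurement model

**Thermal state.** The cuvette temperature `T_cuv(t)` follows the Peltier
setpoint schedule through a first-order lag,
`dT_cuv/dt = (S(t) − T_cuv)/τ`, integrated exactly per sample
(`T[i+1] = S + (T[i] − S)·e^(−dt/τ)`). The default lag τ = 40 s puts
practical equilibration (residual of a 3 °C step below 0.05 °C) at about
2–3 minutes, matching the reported cuvette behaviour. Respiring
mitochondria sit at an elevation `E(t) ≥ 0` above the cuvette, so the probe
senses `T_mito(t) = T_cuv(t) + E(t)`.

**MTY (single channel).** Mito Thermo Yellow fluorescence falls
approximately linearly with sensed temperature:

    F(t) = q·g·[1 − s·(T_mito − T_ref) − c·(T_mito − T_ref)²]·e^(−λt) + A + ε(t)

with gain `g` (AU), relative slope `s` (default 0.01 /°C), quench factor
`q` (drug-induced quenching, default 1), autofluorescence `A`, bleach rate
`λ` (default 0), optional mild curvature `c` (default 0 — the response is
treated as linear, with any high-temperature deviation acknowledged as an
uncorrected ±2 °C-scale uncertainty), and i.i.d. Gaussian noise
`ε ~ N(0, (noise_sd·g)²)`. A `leakage` flag adds an unbounded slow
post-drug rise (default 1% of gain per minute), reproducing the
uncalibratable drug/cell-line combinations in which dye redistribution
never lets the signal settle.

**mito-gTEMP (two channels).** mT-Sapphire is temperature-insensitive
(`F_sap = e·k + A_sap`), and the Sirius channel is modelled
reciprocal-linearly,

    F_sir(t) = e / (1 + s_sir·(T_mito − T_ref)) + A_sir,

so that Sirius is strictly decreasing in temperature while the
Sapphire/Sirius ratio is *exactly* affine in temperature with zero
backgrounds: `R(T) = k·(1 + s_sir·(T − T_ref))`. This form was chosen so
that the linear calibration the ratio pipeline fits is the exact inverse of
the rendering model — zero-noise round trips then recover truth to machine
precision, which is what makes the recovery tests sharp. A linear-in-`T`
Sirius channel would make the ratio hyperbolic in `T` and leave a ~2 °C
model-mismatch artifact at 56 °C that would be an artifact of the
simulator, not of the analysis. The default `s_sir` = 0.02 /°C gives a
ratio slope of 0.02 per °C at `k` = 1, so 1% channel noise maps to roughly
0.7–1 °C of per-sample temperature noise before windowed averaging.

## Ground-truth scenarios

The generator ships the study conditions as named scenarios (all times in
seconds, temperatures in °C, sampling 1 Hz):

- **inhibitor** — constant elevation (default 18) abolished to a residual
  (default 0) after the drug event (default 600 s) by a single exponential
  (τ = 180 s, plateau inside ~10 min). The kinetic law is a modelling
  choice; only the plateau timescale is constrained by observation.
- **starvation** — elevation rises with a saturating exponential
  (τ = 150 s) to a peak (default 16.5, reached at 600 s), then declines
  linearly so that the value at the 35-min reference sits exactly 4 °C
  below the peak. Peak temperature ≈ 53 °C at 37 °C ambient.
- **substrate_rescue** — starvation rise, then partial exponential settling
  toward peak − 2 °C after the substrate event.
- **bka** — inhibitor-type decline (drop 5 °C, τ = 600 s) starting at
  11 min; for MTY use the probe's quench factor represents the dye
  quenching that motivates the drug-compatibility QC.
- **aox_inhibitor** — exponential drop (default 10 °C, τ = 180 s), then —
  after a delay (900 s) representing the observed fluorescence peak before
  recovery — exponential rewarming toward the pre-drug elevation.
  Presets: rotenone (τ = 1800 s, full recovery), antimycin / KCN (faster,
  partial). Substantial recovery spans 40–70 min post-drug.
- **anisomycin** — a transient ~4 °C warming bump
  (`amp·(1−e^(−x/τ_rise))·e^(−x/τ_decay)`, τ_rise = 300 s,
  τ_decay = 4000 s) reverting over 2–3 h; the long-run inhibitor-dependence
  shifts are configuration, not mechanism.

Each scenario records its configured elevation change as `truth_drop` for
recovery tests. MTY-style scenarios default to a terminal ±3 °C
calibration staircase (three 5-min steps); ratio-calibration records use a
30→42 °C staircase in 3 °C × 3-min steps kept under the 35-min photodamage
limit.

## Analysis pipelines

**Plateau criterion.** A sliding-window OLS slope (window 300 s) below
tolerance — default 0.1% of the pre-drug baseline per minute. The slope is
computed by correlating the signal with the centered-index kernel, the
closed form of per-window OLS on a uniform time base; tests verify
equivalence against a brute-force per-window `polyfit` scan. Stability
screening searches between the drug event and the first calibration step;
traces with no plateau are flagged and their estimates withheld.

**Internal step calibration (MTY).** Each staircase step is measured by
discarding the first 120 s (thermal equilibration) and averaging the final
60 s; the imposed temperature is read from the setpoint track. Steps closer
than 240 s are flagged but still measured. An OLS line through the step
points gives the slope in AU/°C; non-negative slopes or r² < 0.9 are
flagged as suspicious rather than silently dropped. The temperature shift
is `ΔT = (F̄_response − F̄_baseline)/slope`, with baseline defaulting to the
60 s before the drug and response to the 60 s before the first calibration
step; cooling is signed negative, and reported "decreases" are magnitudes.
Because the calibration is internal to each trace, the estimate is exactly
invariant to gain scaling and offset shifts.

**Ratio calibration and inversion (gTEMP).** Per-step ratio means (same
discard/average windows — for 3-min steps, "discard 2 min, average the
final minute" and "record during the third minute" coincide) are regressed
on imposed temperature; records spanning ≥ 35 min are rejected outright
(UV photodamage). Replicates are pooled by averaging per-replicate
coefficients (a pooled-points fit is available by flag). Inversion is
`T = (R − c0)/c1`; samples outside the calibrated 30–42 °C range are
reported with an extrapolation flag, never clipped. The Sirius denominator
is floored at 1% of its median: floored samples are masked, and more than
10% masked aborts as denominator collapse. Drug-background QC compares
cell-free blanks with and without drug and passes only when the mean ratio
shift is ≤ 2%, regardless of common-mode channel shifts.

**Peaks and rewarming.** Extreme values of noisy series (post-drug
fluorescence troughs, temperature peaks) are taken from a 60-s boxcar
smoothed series; a raw per-sample argmax is biased upward by 2–3 noise SD.
Rewarming is quantified as `(F_peak − F(t))/|slope|` after the post-drug
peak, zero before it.

**Statistics.** Means ± sample SD (n−1); one-way ANOVA with Tukey HSD
(studentized-range distribution, via `scipy.stats.tukey_hsd`) for ≥ 3
groups; two-sided unpaired equal-variance t test for 2 groups (Welch by
flag); stars at 0.05/0.01/0.001. Absolute temperature is reconstructed
additively: `T_mito = T_ambient + decrease magnitude`, a lower bound
whenever residual heat production remains after inhibition.

## Numerical behaviour and known biases

- **Zero-noise exactness.** With a zero-lag protocol and a fully decayed
  elevation, both pipelines recover `truth_drop` to better than 1e−6 °C;
  the ratio pipeline's calibration coefficients equal the generator's
  closed-form line to machine precision.
- **Thermal-lag bias.** At the realistic 40 s lag, un-equilibrated residual
  in the staircase measurement windows biases the fitted slope by ~0.2%
  (three 5-min steps, 120 s discard), i.e. ~0.03 °C on an 18 °C estimate.
  With 3-min calibration steps the first (large) staircase step retains
  ~0.18 °C residual; 4-min spacing with a 3-min discard brings every window
  under 0.05 °C, which is why widely spaced steps are the recommended
  practice.
- **Rewarming drift.** When elevation is still recovering during the
  terminal staircase (AOX scenarios), the drift aliases into the
  calibration slope (~2% at the default late-staircase placement),
  inflating peak-drop estimates by the same fraction; together with the
  residual smoothed-peak noise bias this leaves the recovered 10 °C
  rotenone drop reading ~0.2–0.4 °C high at 0.5% noise.
- **Degenerate inputs.** Identical calibration temperatures raise a
  singular-design error; zero calibration slope raises a
  non-identifiability error; negative autofluorescence-corrected
  fractionation signals raise rather than clip; all-identical statistical
  groups define F = 0, t = 0, p = 1.

## What the simulator does and does not emulate

The generator reproduces the *structure* of real records — plateaus,
drug-response kinetics, staircase calibrations, backgrounds,
photobleaching, leakage drift, expression variation — under i.i.d.
Gaussian noise relative to gain. It does not model autocorrelated
instrument drift, membrane-potential or ion-concentration confounds
(excluded experimentally for the dye), photon statistics, spectral
bleed-through, or cell-to-cell heterogeneity (single-cuvette ensemble
only). Passing recovery tests therefore demonstrates that the analysis
chain is a correct inverse of a faithful-in-structure forward model at
realistic noise, not that real traces are free of systematic confounds;
the QC stages (stability screening, drug-background checks, suspicious-fit
flags, photodamage limits) encode the known failure modes.

## Problem sizes

Default studies use 1 Hz sampling: 3600-sample inhibitor records,
2100-sample starvation records (35 min), 7200-sample rewarming records,
20 replicate traces for the oligomycin recovery study, 10 for the AOX
study, and 9 replicate staircases for the pooled ratio calibration —
matching the replication levels of the experiments they emulate while
keeping any study re-runnable in seconds.
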