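# mitotherm

Mitochondrial thermometry from fluorimeter time series.

Respiring mammalian mitochondria run substantially hotter than the medium
their cells sit in. Two fluorimetric probes make that measurable in a
cuvette: **Mito Thermo Yellow (MTY)**, a mitochondrion-accumulating dye
whose fluorescence falls roughly linearly with temperature, and
**mito-gTEMP**, a genetically encoded pair (temperature-insensitive
mT-Sapphire over temperature-sensitive Sirius) whose emission ratio rises
with temperature and is independent of expression level. Neither probe has
a usable universal calibration in cells — uptake, autofluorescence and
quenching vary per trial — so inference rests on *internal* calibration:
stepping the cuvette's Peltier jacket by a known ±3 °C at the end of each
experiment (MTY), or a 30→42 °C staircase fitted once per cell line and
extrapolated linearly (gTEMP).

`mitotherm` implements that inference chain for analysts working with such
traces, plus a seeded forward simulator so every estimator can be validated
by parameter recovery:

- **synthetic traces** — Peltier thermal lag, ground-truth elevation
  scenarios (OXPHOS-inhibitor cooling, substrate starvation and rescue,
  AOX-mediated rewarming, anisomycin transients), probe rendering with
  noise, bleaching, leakage and background artifacts;
- **MTY pipeline** — plateau detection, stability screening, internal step
  calibration, signed temperature-shift estimation, rewarming
  quantification;
- **gTEMP pipeline** — channel ratio with denominator QC, drug-background
  compatibility checks, in-vivo linear calibration (35-min photodamage
  limit), inversion with explicit extrapolation flags, interval summaries;
- **fractionation accounting** — autofluorescence-corrected label-recovery
  proportions across sub-mitochondrial fractions;
- **statistics** — means ± SD, one-way ANOVA + Tukey HSD, Student's t,
  and the additive absolute-temperature reconstruction
  `T_mito = T_ambient + decrease magnitude`.

## The core estimator

For an MTY trace with a drug event and a terminal staircase, the fitted
line through the per-step (imposed °C, mean AU) points gives a slope
`m` (AU/°C, negative for MTY), and

    ΔT = (F̄_response − F̄_baseline) / m

with baseline averaged over the 60 s before the drug and response over the
60 s before the first calibration step. Cooling is signed negative; the
gain and offset of the trace cancel exactly. For gTEMP, the calibration
`R(T) = c0 + c1·T` is inverted as `T(t) = (R(t) − c0)/c1`, flagging samples
outside the calibrated range as extrapolated.

## Worked example

```python
import mitotherm as mt
from mitotherm.mty import MtyThermometry
from mitotherm.statsrep import reconstruct_mito_temperature

# simulate an oligomycin experiment: an 18 °C mitochondrial elevation
# abolished by ATP-synthase inhibition, terminal ±3 °C calibration steps
scn = mt.build_scenario("inhibitor", dict(initial_elevation=18.0))
trace = mt.render_mty_trace(scn, mt.MtyProbeModel(), noise_sd=0.005, seed=1)

res = MtyThermometry(trace).fit()
print(res.summary())
print("T_mito =", reconstruct_mito_temperature(37.0, res.magnitude))
```

prints

```
MTY thermometry results
==============================================
temperature shift        -18.338 °C
decrease magnitude        18.338 °C
stable plateau         True
calibration slope         -9.837 AU/°C (r² = 0.9986, n = 3)
calibrated range       34.0–40.0 °C  [extrapolated]
T_mito = 55.33773275106694
```

The pipeline recovered the simulated 18 °C drop to within noise
(calibration-slope error at 0.5% noise dominates the ±0.3 °C scatter), the
post-drug plateau passed the stability screen, and — since the drop was
measured against a 37 °C ambient — the implied pre-inhibition
mitochondrial temperature is ~55 °C, flagged as an extrapolation far
beyond the ±3 °C calibrated span. Averaged over 20 seeds the recovered
mean is 18.0 °C.

The same objects drive the ratio pipeline
(`mitotherm.gtemp.GtempThermometry` with a `fit_ratio_calibration`
calibration) and there is a CLI for file-based work:

```bash
mitotherm simulate --config sim.yaml --out trace.tsv
mitotherm analyze-mty --trace trace.tsv --out report.json
mitotherm calibrate-gtemp --trace stair1.tsv --trace stair2.tsv --out cal.json
mitotherm analyze-gtemp --trace trace.tsv --calibration cal.json --out report.json
mitotherm fractions --table fractions.tsv --out report.json
mitotherm stats --table groups.csv --out report.json
```

Exit codes: 0 success, 2 validation error, 3 QC failure.

## Layout

```
src/mitotherm/
  traces.py     # FluorescenceTrace container
  synthgen.py   # protocols, scenarios, probe models, trace rendering
  mty.py        # MTY pipeline + MtyThermometry model/results
  gtemp.py      # ratio pipeline + GtempThermometry model/results
  fractions.py  # fractionation recovery accounting
  statsrep.py   # group statistics, temperature reconstruction
  studies.py    # canned simulation-and-recovery protocols
  io.py         # trace files, YAML config, JSON reports
  cli.py        # `mitotherm` command group
docs/methods.md # model, assumptions, defaults, known biases
```
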