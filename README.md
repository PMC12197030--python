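# edawave

Electrodermal activity (EDA) is usually measured exosomatically with a DC
voltage between two skin electrodes.  Charge accumulating at the
electrode–skin interface then builds a counter-electromotive force that
drags the apparent skin conductance downward over minutes — a drift that is
artefact, not physiology.  Driving the skin with a zero-mean, full-wave AC
signal inverts the polarity every half cycle, leaves the interface
uncharged, and additionally exposes the skin's capacitive response.

`edawave` is a toolkit for studying exactly this trade-off in silico and
for processing recordings from such a device.  It provides:

* **Skin circuit model** — series deep-tissue resistance feeding a
  stratum-corneum resistor in parallel with a sudomotor-controlled
  sweat-duct resistor, the block shunted by an epidermal capacitor.  Its
  admittance is

  `Y(f) = 1 / ( R_series + R_par / (1 + i·2πf·R_par·C) )`,  `G = Re Y`, `B = Im Y`,

  so both conductance G and susceptance B rise with frequency, as the
  device observes.
* **Electrode polarisation model** — a first-order charge accumulator whose
  EMF adds to the measured voltage, producing the characteristic downward
  drift under one-signed (DC or half-wave) excitation.
* **Excitation and acquisition chain** — 0–3.3 V PWM source, clamper stage
  (→ ±1.65 V full-wave), R0 = 100 kΩ current-limiting divider (≤ 16.5 µA
  worst case), 16-bit ADC with seeded Gaussian front-end noise.
* **Lock-in demodulation** — in-phase/quadrature mixing and cycle-average
  low-pass recover the amplitude and phase of the skin voltage at the
  carrier, invert the divider (`Z = V_skin·R0/(V_AC − V_skin)`), and split
  the admittance into `G = |Y|cos ϕ`, `B = |Y|sin ϕ`.
* **Layered-tissue field solver** — finite-volume solution of
  `∇·((σ + iωε₀εᵣ)∇V) = 0` on a 2-D four-layer skin cross-section with two
  surface electrodes, reporting conduction (`J = σE`), displacement
  (`J = iωε₀εᵣE`) and total current-density maps.
* **Tonic/phasic decomposition** — an asymmetric penalised-least-squares
  smoother extracts the skin conductance level (SCL); phasic responses
  (SCRs) are the positive residual.
* **Virtual-study runner** — seeded populations of synthetic subjects and
  the two study protocols (65 s DC vs half-wave at 20 Hz; 180 s DC vs
  full-wave at 5/20/70/100 Hz) with Pearson/RMSE/mean/std summaries.

## Worked example

```python
import numpy as np
import edawave as ew

model = ew.SkinRCModel()          # 10 kΩ + (250 kΩ ∥ 1 MΩ ∥ 30 nF)
spec = ew.ExcitationSpec(mode="full_ac", frequency=20.0)
fe = ew.FrontEndConfig()

rec, truth = ew.acquire(spec, model, None, fe, duration=10.0, seed=0,
                        polarization_on=False)
adm = ew.admittance_from_recording(rec, fe, spec)
y = ew.admittance_at(model, 20.0) * 1e6
print(f"demodulated: G = {np.mean(adm.g):.3f} µS, B = {np.mean(adm.b):.3f} µS, "
      f"phase = {np.mean(adm.phase):.2f}°")
print(f"closed form: G = {y.real:.3f} µS, B = {y.imag:.3f} µS")

pop = ew.make_population(10, seed=1)
drift = ew.run_drift_study(pop, duration=180.0)
print(f"median drift over 180 s  dc: {drift['drift_dc_uS'].median():.3f} µS, "
      f"half-wave: {drift['drift_half_ac_uS'].median():.3f} µS, "
      f"full-wave: {drift['drift_full_ac_uS'].median():.5f} µS")
```

prints

```
demodulated: G = 4.885 µS, B = 3.416 µS, phase = 34.97°
closed form: G = 4.885 µS, B = 3.415 µS
median drift over 180 s  dc: 1.278 µS, half-wave: 1.269 µS, full-wave: 0.00076 µS
```

The first two lines show the complete simulate → digitise → lock-in chain
recovering the circuit's closed-form conductance and susceptance at 20 Hz.
The drift lines show the core finding the toolkit reproduces: with
electrode polarisation active, the DC and half-wave conductance estimates
decline by over a microsiemens in three minutes beyond any true tonic
change, while the full-wave AC estimate moves by less than a nanosiemens —
three orders of magnitude less.

## Command line

```bash
edawave --seed 7 --out run1 simulate --duration 60     # subject → recording.csv + truth.csv
edawave --seed 7 --out run1 demodulate run1/recording.csv
edawave --seed 7 --out run2 decompose conductance.csv  # SCL/SCR split
edawave --seed 7 --out study stage1 -n 10              # DC vs half-wave protocol
edawave --seed 7 --out study stage2 -n 10              # DC vs full-wave sweep
edawave --out field field-solve                        # layered-skin field maps
```

Every command validates its YAML configuration (`--config`), seeds all
randomness (`--seed`), and writes a provenance JSON beside its outputs.

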