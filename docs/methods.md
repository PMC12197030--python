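# Methods

This note documents the models behind `edawave`, the defaults and why they
were chosen, the numerical schemes, and what the synthetic-data generator
does and does not emulate.

## Skin circuit model

The skin between two surface electrodes is lumped as

```
            ┌── R_corneum ──┐
 ── R_series┤── R_duct ─────┼──
            └── C_epidermal ┘
```

* `R_series` (default 10 kΩ): deep tissue and dermis in series with the
  measurement path.
* `R_corneum` (250 kΩ): fixed stratum-corneum resistance.
* `R_duct` (50 kΩ–5 MΩ): sweat-gland duct resistance, the physiologically
  modulated element.  Duct conductance is affine in a dimensionless
  sudomotor drive, `1/R_duct(t) = g_min + k·d(t)`, clamped to the bounds
  above (a clamp is logged).
* `C_epidermal` (30 nF): capacitance shunting the corneum/duct block.

The admittance `Y(f) = 1/(R_series + R_par/(1 + i·2πf·R_par·C))` is purely
real at DC and rises in both real and imaginary parts through the 5–100 Hz
band used here; with the defaults the DC conductance (4.76 µS) sits inside
the 0.2–100 µS range the front end is designed for.  The topology — series
resistance outside the capacitor — is what makes measured conductance grow
with frequency; a plain parallel G‖B cannot do that.

Assumptions: linearity (no electroporation or voltage dependence), a single
dispersion (no Cole–Cole spectrum), no temperature dependence.

## Sudomotor drive

The drive `d(t)` is a tonic trajectory (baseline 1, slow linear decline
plus a low-amplitude sine) with sparse phasic events added.  Each event is
an unnormalised bi-exponential `a·(e^(−t/τ_decay) − e^(−t/τ_rise))` with
τ_rise = 0.75 s, τ_decay = 2 s by default — standard EDA phenomenology;
both constants are configurable and jittered per subject.  The drive is
clipped at zero.

## Electrode polarisation

One-signed current through the electrode interface accumulates charge on a
capacitance `C_pol` with a parallel leak `R_leak`:

```
dV_emf/dt = I_skin/C_pol − V_emf/(R_leak·C_pol)
```

The EMF sits electrically between the measurement tap and ground (in series
with the skin), so the tapped voltage reads `V_emf + V_skin`: the apparent
impedance inflates and the conductance estimate drifts *down*, which is the
artefact under study.  Zero-mean excitation leaves `V_emf` at the ripple
level.

Defaults `C_pol = 500 µF`, `R_leak = 300 kΩ`.  These were chosen so the
drift has the observed character of real DC recordings: a double-layer
capacitance of hundreds of µF is the right scale for a 2 cm² hydrogel
electrode, and with a typical total loop resistance of ~300 kΩ the EMF
equilibrates at a substantial fraction of the drive with a time constant
`C_pol·(R_leak ∥ R_loop) ≈ 75 s` — a progressive 20–70 % decline over a
180 s record rather than an instant collapse.  A much smaller capacitance
with a much larger leak (e.g. 10 µF / 10 MΩ) makes the signal collapse to a
few percent within seconds, which matches no published EDA recording.  The
first-order accumulator itself is this package's modelling choice; the
underlying electrochemistry is not modelled.

## Excitation

* `dc`: constant level (default 1.65 V).
* `half_ac`: rectified sine `A·max(sin 2πft, 0)` (A = 3.3 V in the study
  protocol), mean `A/π` — alternating but never negative, hence no
  polarity inversion.  Read as a rectified sine because that is the minimal
  interpretation of "positive half-wave"; an offset square is also
  generatable via the PWM path.
* `full_ac`: a 0–3.3 V, 50 %-duty PWM square passed through an ideal
  level-shift/clamp (diode drop configurable, default 0 V) and capacitive
  coupling: ±1.65 V with exactly zero mean over whole periods.  Its
  fundamental at f carries amplitude `(4/π)·1.65 V`; demodulation targets
  the fundamental only and the lock-in rejects the odd harmonics, so no
  harmonic correction is applied (the residual harmonic bias of the full
  chain is measured in tests at well under 1 %).

## Acquisition chain

Per internal sample (50 samples per carrier cycle by default; 200 Hz for
DC): excitation → polarisation EMF → R0 divider with the skin circuit →
output clamper → Gaussian front-end noise (1 mV RMS default, seeded) →
quantisation to `2^bits − 1` levels over 3.3 V.

* `R0 = 100 kΩ`: smallest round value keeping the worst-case (shorted
  electrodes) current at `1.65/R0 = 16.5 µA`, under the 20 µA medical
  limit, while preserving divider sensitivity across 0.2–100 µS.
* The device's "20 Hz sampling" is interpreted as the *output* rate of
  conductance estimates: a 20 Hz carrier cannot be demodulated from 20 Hz
  samples, so the simulated ADC runs at the internal rate and the
  demodulated G/B series are decimated to 20 Hz (200 Hz when the carrier is
  70 or 100 Hz) by sample-and-hold, mirroring a simple firmware loop.
* The output clamper's `+1.65 V` shift is applied to the bipolar full-wave
  signal only; DC and half-wave skin voltages are already non-negative and
  would saturate the converter if shifted.
* ADC saturation beyond 1 % of samples is recorded as a warning in the
  recording metadata.

### Time stepping

The capacitor-block ODE is linear but stiff when the load is nearly
resistive (block time constant far below the sample interval).  The
trapezoidal rule's amplification factor approaches −1 there and rings at
every PWM edge, so the integrator instead solves the ODE exactly over each
step with the input interpolated quadratically through the last three
samples (exponential integrator): L-stable, exact in the DC limit, and
third-order accurate in the input.  At 50 samples per cycle the
steady-state current phasor matches the closed-form admittance to better
than 0.2 % at 5–100 Hz (the test contract is 1 %).

## Lock-in demodulation

`I = LPF(x·sin 2πft)`, `Q = LPF(x·cos 2πft)`, amplitude `2√(I²+Q²)`, phase
`atan2(Q, I)`.  The default low-pass is an average over 4 whole reference
cycles, which nulls the 2f mixing product exactly and makes the noiseless
sinusoid case exact; a zero-phase Butterworth is available as an
alternative.  Both the reconstructed skin voltage and a regenerated copy of
the excitation are demodulated with the same lock-in, so the divider
inversion `Z = V_skin·R0/(V_AC − V_skin)` operates on phasors with a common
time origin.  Outputs use degrees; positive phase means current leads
voltage (capacitive, B > 0).

Half-wave recordings admit two conductance readings: the lock-in at the
carrier, and a mean-rectified estimate (cycle means of skin voltage and
drive through the divider inversion).  A lock-in is blind to the quasi-DC
polarisation EMF in a linear circuit, so a lock-in-based half-wave estimate
would not drift; real half-wave devices read the voltage drop directly and
do drift.  The study protocols therefore use the mean-rectified estimator
for half-wave (and the DC estimator for DC); the lock-in remains the
default for full-wave admittance work.

## Moving-average filter

Centred mean over `round(span·fs)` samples (20 at 20 Hz, 200 at 200 Hz for
1 s), truncated at the edges, output length = input length.  The truncated
centred window preserves constant and linear series' means exactly; for
general series edge re-weighting perturbs the global mean slightly (the
window is 1 s against ≥ 65 s records, so the effect is per mille).

## Tonic/phasic decomposition

The SCL is extracted by asymmetric penalised least squares: minimise
`Σ wᵢ(gᵢ−tᵢ)² + λ Σ(Δ²t)ᵢ²` with `wᵢ = asym` where `gᵢ > tᵢ` and `1−asym`
otherwise, iterated 10 times (each iteration a banded Cholesky solve).
Defaults: `asym = 0.01`, `λ = 1e5` at 20 Hz, scaled by `(fs/20)³` so the
smoothing *time* scale is rate-invariant.  `scr = max(g − scl, 0)`;
`residual = g − scl − scr`, so the three components reconstruct the input
exactly and scr is non-negative by construction.

This smoother is a deliberate, fully specified surrogate for
deconvolution-based tonic/phasic methods: those are prior work this
package only consumes, and tonic tracking is the sole use here.  An
external implementation can be plugged in wherever an SCL series is
consumed, since the decomposition is a pure function of the conductance
series.  Known behaviour: the upward-excursion smoothing span (~2.8 s at
the defaults) is shorter than a bi-exponential SCR (~8 s), so roughly a
tenth of each event's amplitude leaks into the SCL; with realistic resting
tonic ranges this puts median tonic RMSE at ~4–5 % of the tonic range —
adequate for SCL-level comparisons, not for SCR scoring (which is out of
scope).  The asymmetric weighting also biases the tonic ≈ 2 noise standard
deviations below the noise mean, which the 1 s pre-filter keeps at the
few-nA level; the study pipeline always filters before decomposing.
Comparison statistics use population (ddof = 0) standard deviations.

## Field solver

Quasi-static frequency domain: `∇·(κ∇V) = 0`, `κ = σ + iωε₀εᵣ` per layer,
on a 2-D cross-section (valid because tissue dimensions are vastly below
the wavelength).  Cell-centred finite volumes on a uniform grid; harmonic
averaging of κ across faces makes the 1-D layered (plate-electrode) limit
exact, which is the solver's closed-form oracle.  Electrode Dirichlet
values enter via half-cell face conductances, so electrode currents come
out of the same flux algebra and complex charge balance holds to solver
accuracy (≤ 0.1 %, typically 1e-9).  A direct sparse LU solves the system;
the residual is checked against a 1e-8 relative tolerance.

Defaults: four layers (stratum corneum 20 µm, epidermis 80 µm, dermis
1.5 mm, subcutis 3 mm), two 8 mm surface electrodes with a 12 mm gap on a
64 mm-wide domain, ±1.65 V drive, `dx = 0.5 mm`, `dz = 10 µm`.  The grid
default was set so that halving both spacings moves the peak current
density by < 2 % (the peak sits under the electrode edge, where the
resistive stratum corneum regularises the edge singularity).  Maps report
E, conduction current `σE`, displacement `ε₀εᵣE`, displacement current
`iωε₀εᵣE` and the per-cell modulus of the complex total; a summary gives
the peak in mA/cm² (A/m² × 0.1), a laterally averaged depth profile, the
fraction of injected current crossing the epidermis–dermis interface, and
the electrode current balance.

The bundled σ/εᵣ tables at 1 Hz/100 Hz/1 kHz are *synthetic plausible
values* (log-frequency interpolated, clamped outside the table).  They
reproduce the qualitative behaviour — current reaches the dermis at 1 Hz
and above, and the peak current density grows with frequency — but
absolute peak values depend on measured dielectric data, which users must
supply through the layer configuration for quantitative reproduction.
Electrode size and spacing are likewise configurable because no standard
geometry exists for this measurement.

## Virtual studies

`make_population(n, seed)` draws per subject: baseline DC conductance
log-uniform in 1–20 µS (split 40 % duct / 60 % corneum conductance within
the parallel block), epidermal capacitance 20–40 nF, tonic slope −0.03 to
−0.25 per 180 s (resting decline), a slow sine (1–5 %, 60–120 s period),
Poisson SCR events at 3/min with log-normal amplitudes (median 0.15 drive
units ≈ 3 % of baseline conductance), and ±30 % log-normal jitter on the
polarisation parameters.  Everything is reproducible bit-for-bit from
`(n, seed, config)`.

* **Stage 1** (65 s): DC and half-wave 20 Hz acquisitions share one
  sudomotor drive per subject (both hands recorded at once); each gets its
  own fresh polarisation state.  Pipeline: estimator → 1 s moving average →
  tonic extraction → per-subject SCL mean/std and paired Pearson r / RMSE.
* **Stage 2** (180 s): DC plus full-wave at 5/20/70/100 Hz (200 Hz output
  rate at 70/100 Hz); per-condition SCL summaries, paired DC-vs-AC
  statistics at 20 Hz, and the median G/B frequency-sweep table.
* **Drift study**: excess drift = (early − late 15 s means) of the
  estimate minus the same for the ground truth at the estimator's own
  frequency, so shared physiology cancels and only the polarisation
  artefact remains.  Reported per subject for DC, half-wave and full-wave,
  with a two-sided sign test of half-wave vs DC and the fraction of
  subjects whose full-wave drift is below 5 % of their DC drift.

### What the generator does and does not emulate

It emulates the signal structure the processing chain must handle: baseline
heterogeneity across the device range, slow tonic decline, sparse phasic
events with realistic kinetics, polarisation drift with subject-dependent
magnitude, front-end noise and quantisation.  It does not emulate: motion
and contact artefacts, mains interference (a hook exists, off by default),
inter-hand physiological asymmetry (optional, off), electrode gel drying,
or the between-subject variance structure of real humans.  Passing tests
therefore demonstrate that the *method* behaves as described on signals
with the study's structure — not that human r/RMSE values would be
reproduced, which depend on real participants and are deliberately not
targeted.

## Numerical choices and degenerate inputs

* Lock-in cycle averaging requires an integer number of samples per cycle;
  the excitation spec enforces `internal_rate` as an exact multiple of the
  carrier.
* Divider inversion refuses `V_AC = V_skin` (open circuit); the DC and
  rectified estimators clip at one LSB from the rails and flag clipping.
* Amplitudes below 10 LSB in a lock-in block raise a low-signal warning.
* The smoother warns if the tonic estimate is still moving more than
  1e-6 µS after the configured iterations.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; population members derive child seeds from
  `(seed, index)` so populations of different sizes share their prefix.

## Known limitations

* The polarisation model is first-order and symmetric; real Ag/AgCl
  half-cell behaviour is nonlinear and history-dependent.
* Absolute field-solver current densities await measured dielectric
  tables; only directions and oracle configurations are quantitative.
* The tonic surrogate under-separates long SCR tails (see above); SCR
  amplitude/latency scoring is explicitly out of scope.
* 2-D field geometry: electrode strips are effectively infinite in the
  third dimension; absolute currents are per metre of depth.
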