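# Methods

This note records the models implemented in `bioz`, the assumptions behind
them, the defaults that matter, and what the synthetic validation studies
do and do not demonstrate.

## Tissue model and spectra

The 2R1C equivalent circuit (extracellular resistance R_e in parallel with
intracellular resistance R_i in series with a membrane capacitance C)
captures the β-dispersion of tissue between ~1 kHz and ~1 MHz. The
implementation is the exact complex expression; no multi-dispersion
(Cole–Cole α) generalisation is attempted. Two analytic facts are used as
self-checks throughout: the magnitude limits (R_e at DC,
R_∞ = R_e·R_i/(R_e+R_i) at high frequency) and the semicircular
(−Im, Re) locus centred at ((R_e+R_∞)/2, 0).

The capacitance field stores the *branch value as wired*. Physical test
fixtures are sometimes labelled with half-element values (two capacitors in
series each of 2C); only the branch value enters the impedance, so that is
what the model carries. The reference verification circuit is
R_e = 681 Ω, R_i = 909 Ω, C = 3.3 nF, swept over 4 kHz–1 MHz on a
50-point logarithmic grid (geometric spacing is the standard choice for
dispersion spectroscopy; grids default to 50 points).

The electrode–skin interface is a series 50 Ω + 100 nF group per electrode.
In a tetrapolar measurement it loads the current path, not the sensed
voltage ratio, so the operation exists to build two-electrode fixtures and
to reason about current-source headroom (0, 1 or 2 interfaces in series).

**Fitting.** `fit_cole` minimises the stacked real/imaginary residuals with
Levenberg–Marquardt in log-parameter space (positivity by construction;
optional 1/|Z| relative weighting). Initial values come from the spectrum
itself: R_e from the lowest-frequency magnitude, R_∞ from the
highest-frequency magnitude, and C from the −Im extremum via
f₀ = 1/(2πC(R_e+R_i)) (the model is exactly a single Debye relaxation with
τ = C(R_e+R_i)). A spectrum with no measurable reactance leaves C
unidentifiable; the fit reports an explicit failure rather than a silent
boundary value. Non-convergence within the iteration cap (2000 evaluations)
is likewise reported.

## Polar demodulator

The front-end model follows the magnitude-ratio / phase-difference
principle: both channels see the same excitation current, so the current
amplitude cancels and the impedance is encoded as
K = |Z_X|/R_S and θ = |arg Z_X|.

Key modelling choices:

- **Log-magnitude channel.** The successive-detection log amplifier is
  modelled as an ideal logarithm over a configurable dynamic range
  (default 60 dB per channel, hence the channel *ratio* is representable
  within ±60 dB); the stage-by-stage pseudo-log curve is out of scope. The
  two log outputs are low-pass filtered, digitised and subtracted in the
  digital domain. The slope default is 0.3 V/decade: with the reference
  level at mid-supply, ±3.3 decades of K must fit inside the 2 V ADC
  window, which the instrument's own magnitude range (1 Ω–1.2 kΩ against
  autotuned references of 500 Ω or 500‖56 ≈ 50.4 Ω, i.e. K up to ±34 dB)
  requires; a 0.5 V/decade slope would clip.
- **Phase channel.** XOR semantics: the duty cycle of the XOR of the two
  hard-limited channels is θ/π, so V_p = VDD·θ/π exactly, linear from 0 to
  VDD over 0–180°. (A hardware XNOR would give the complement
  VDD·(1−θ/π); the XOR convention is what the linear V_p(θ) relation
  implies, and is what this model implements.) The duty cycle measures |θ|
  only; tissue being capacitive, the sign is fixed internally and phases
  are reported positive (5–80° operating range).
- **Digitisation.** 12-bit quantisation over [0, VDD] plus zero-mean
  Gaussian noise sized so one conversion has 10-bit effective resolution
  (σ² = (LSB₁₀² − LSB₁₂²)/12). Because the demodulator outputs are DC
  levels and the converter runs at 200 ksample/s, a reading averages
  `n_adc_samples` conversions (default 16), as firmware reading a static
  level would. Noise is applied only when a seed is supplied and is
  reproducible under it.
- **Waveform mode.** `demodulate_waveform` synthesises the two sinusoids,
  adds any residual limiter offset, hard-limits, and integrates the XOR
  pulse train with sub-sample edge timing (limiter crossings located by
  linear interpolation — the software analogue of a timer-capture
  readout). Mean extraction is over an integer number of periods. A duty
  cycle counted on raw samples instead would quantise at
  1/samples_per_period and could not resolve sub-degree phase.
- **Limiter offset.** A *common* offset added to both channels before
  limiting shifts each channel's rising and falling edges by ±asin(o/A)
  symmetrically, and the two XOR pulse widths per period change by equal
  and opposite amounts: the full-period duty cycle is exactly
  offset-immune. A measurable bias appears only when the channel
  amplitudes differ (K ≠ 1) *and* θ is smaller than the differential edge
  shift, so that edges reorder (e.g. θ = 2°, K = 4, 5% offset → ≈ +0.15°);
  it vanishes when the offset-cancellation loop drives the offset to zero.
  This is weaker than the usual informal claim that any offset biases a
  phase extractor — that claim holds for single-edge (flip-flop)
  extractors, not for a full-period XOR average.
- **Autotune.** Chooses the reference (on-chip 500 Ω alone, or with the
  off-chip 56 Ω in parallel — the off-chip value is configuration, not a
  datasheet number) minimising |log K|, then the largest excitation
  amplitude in 5 µA–1 mA keeping both sensed peaks under the IA linear
  ceiling (default 1 V). Infeasible targets raise a range error.
- The IA band-pass corners have no hardware-backed default; they are
  configuration only.

## Synthetic thoracic recordings

A recording is Z0 + per-beat deflections + respiration sinusoid + white
Gaussian noise, sampled at 1 kHz (the demodulated-output rate is a free
choice; 1 kHz resolves all timing tolerances used here), excitation
frequency recorded as 100 kHz (single-frequency analysis).

**Beat template.** −dZ/dt is two raised-cosine lobes: a systolic ejection
lobe of width w_e = t_LVE − w_r/2 peaking at (dZ/dt)_max (the C point at
its centre), and a negative recovery lobe of width w_r = t_LVE/2 centred
exactly at t_LVE, which returns the impedance to baseline (areas match).
Everything is C¹, so the landmarks survive band-pass filtering: B (the
upward departure of −dZ/dt from zero) at t = 0, X (the −dZ/dt minimum) at
t = t_LVE, and the template scales linearly in (dZ/dt)_max. This is the
smallest parameterisation that exercises B/C/X detection; Y and O waves,
motion artifacts, arrhythmia and ECG are deliberately not synthesised. An
early C¹-discontinuous variant (exponential recovery) was rejected because
the 20 Hz zero-phase filter displaced its X corner by ~15 ms.

**Ground truth.** `truth_from_hemodynamics` inverts the stroke-volume
equation for (dZ/dt)_max = SV·Z0²/(ρL²·T_LVE) so the forward equation
returns the target SV exactly; a feasibility cap (dZ/dt)_max < 5 Ω/s
rejects non-physiological combinations (e.g. large Z0 with large SV —
random closure draws resample until feasible). Respiration defaults to
1 Ω at 0.25 Hz; noise is white Gaussian, seeded. Basal impedance is
validated to the 20–200 Ω thoracic range.

## Analysis pipeline

1. **Preprocess.** Linear detrend and 4th-order Butterworth band-pass
   0.5–20 Hz applied forward–backward (zero phase, so B/C/X timings are
   unbiased). The raw mean is kept untouched as Z0. An optional
   moving-average smoothing exists but is off by default (ensemble
   averaging is the mandatory averaging step; smoothing is redundant with
   it).
2. **Beat detection.** C candidates are peaks of −dZ/dt above
   0.4 × (rolling 10 s maximum), floored at 0.05 Ω/s absolute (a flat
   record must yield *no* beats), with a 0.3 s refractory period.
   Detection runs on an 80 ms moving-average copy of −dZ/dt:
   differentiation amplifies broadband noise, and the C lobe is wide
   enough (~0.2 s) that the smoothing does not move it.
3. **Ensemble averaging.** Beats align on C; beats whose RR deviates more
   than 20% from the median are excluded and flagged; window 0.3 s before
   to 0.5 s after C; all accepted beats in the record are used. A second
   pass re-aligns each beat by cross-correlation with the first-pass
   ensemble template (±60 ms): aligning on each beat's own noisy maximum
   selects positive noise at the alignment point — a bias that does *not*
   average out (observed up to +30% on (dZ/dt)_max at realistic noise);
   template correlation uses the whole beat shape and removes it.
4. **Characteristic points.** On the averaged beat, C is the −dZ/dt
   maximum and X the minimum within 0.6 s after C. B is located by
   tangent extrapolation: at the last ascent through 12% of the C peak,
   t_B = t − 2·d(t)/d′(t), exact for the quadratic leading behaviour any
   smooth upstroke has, and read where the trace stands well above the
   noise floor. The plain last-zero-crossing rule is computed as a
   cross-check (the annotation is flagged when they disagree by >25 ms)
   and the *later* candidate wins: both estimators fail only toward early
   B (noise plateaus stall the crossing; toe shoulders deflate the tangent
   slope). Fallbacks, each flagged: zero crossing alone, then the
   second-derivative maximum in the 150 ms before C. A plain zero-crossing
   B is unreliable at realistic noise — residual ensemble noise keeps the
   averaged trace above zero through late diastole and can drift the
   crossing ~100 ms early.
   In full-record analysis (`analyze`) an extra 15 Hz zero-phase low-pass
   precedes point reading (the beat's −dZ/dt content lies below ~10 Hz;
   the narrower band suppresses the upward bias of reading a maximum in
   noise). The low-level `find_characteristic_points` leaves it off by
   default so clean-template landmarks are recovered exactly.
5. **Hemodynamics.** Z0 = mean of the raw impedance; HR = 60/median RR of
   accepted C–C intervals (derived from the impedance channel — no ECG);
   SV from the averaged beat's annotation via the stroke-volume equation;
   CO = SV·HR/1000 in L/min. (Conventions sometimes state CO in mL/min;
   clinical values ~4–5 are litres per minute, and this package reports
   L/min throughout.) The CO–SV–HR identity holds exactly in every result
   object, enforced at construction.

## Passing–Bablok comparison

Slope = shifted median of the N pairwise slopes S_ij (pairs with equal x
skipped; S_ij = −1 excluded; shift K = #{S_ij < −1}); intercept =
median(y − b·x); 95% CIs from the rank-based normal approximation
(w = 1.96·√(n(n−1)(2n+5)/18)), intercept CI induced by the slope CI
endpoints. Equivalence = slope CI ∋ 1 and intercept CI ∋ 0. With fewer
than 10 pairs only point estimates are returned, flagged. R² is the
squared Pearson correlation of the paired values (the customary companion
statistic; other estimators exist, this is an explicit choice).
Bland–Altman analysis is intentionally out of scope. The plot drawn by the
CLI shades the band induced by the parameter CIs and labels it as such
(not a pointwise regression-line band).

## Validation studies and their scope

`bioz.studies` holds the seeded experiments the test suite and
`scripts/acceptance.py` share:

- **Demodulator round trip** — 1000 autotuned draws over the full
  instrument range with ENOB noise; contract: ≤1.2% magnitude, ≤1.5% of
  phase reading. With single conversions the phase contract is
  unreachable at 5° readings (one LSB₁₀ ≈ 0.09° ≈ 1.8% of reading); the
  16-sample DC averaging is what makes the contract attainable, and is
  stated above as a modelling choice, not a tuning.
- **Mode agreement** — waveform vs behavioural ≤0.5% / ≤0.5° at ideal
  settings; **XOR linearity** ≤0.5% of VDD over 5–170°.
- **End-to-end recovery** — 20 subjects drawn from resting ranges
  (Z0 25–42 Ω, SV 50–90 mL, HR 60–90 bpm, T_LVE 0.26–0.34 s, resampled
  to keep (dZ/dt)_max in the physiological 1.2–3.5 Ω/s), each a
  10-minute 1 kHz recording with respiration (1 Ω, 0.25 Hz) and noise
  (sd 0.05 Ω). Contract: SV within 5%, HR within 1 beat/min. The
  10-minute duration was sized from the ensemble-averaging noise floor
  (the B/X timing and peak-reading errors scale as 1/√n_beats); at 1–2
  minutes the same pipeline is typically within 2–3% but single-subject
  outliers can exceed 5%.
- **Cole recovery** — ≤0.1% noiseless, ≤5% under 0.5% multiplicative
  spectral noise; **Passing–Bablok** — exact on noiseless linear data,
  ≥90% CI coverage over 500 unbiased 33-pair simulations.

What passing these studies shows: the pipeline inverts its own generator
under the stated noise model. What it does not show: performance on real
thoracic signals, whose beat morphology varies within and between
subjects, whose noise is not white, and whose respiration is neither
sinusoidal nor stationary; nor anything about electrode placement,
motion, or arrhythmia. The generator's template has a fixed C position at
37.5% of T_LVE — detectors tuned only to it would not be validated for
morphology changes, which is why the B rule keeps the zero-crossing
cross-check and quality flags rather than assuming the template.

## Numerical choices and degenerate inputs

- Zero-phase filtering throughout timing-sensitive paths; filter family
  and order are configuration (4th-order Butterworth default).
- Recording CSVs are written with 17 significant digits and read with
  round-trip float parsing, so writer/reader pairs are exact inverses;
  the time grid is validated uniform to 1 ppm.
- Flat or empty recordings: detection returns an empty list plus a flag;
  `analyze` raises only when no beats exist at all. Ensemble averaging
  requires ≥3 usable beats; records must be ≥5 s (preprocess) / ≥10 s
  (analyze).
- Ties in the Passing–Bablok slope set use plain sorted-median semantics.
- All stochastic operations take explicit seeds; absence of a seed in the
  CLI is logged as a non-reproducible run.
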