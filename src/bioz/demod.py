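"""Polar (magnitude-ratio / phase-difference) demodulator model.

The measuring principle: a sinusoidal excitation current flows through both
the unknown impedance ``Z_X`` and a reference resistor ``R_S``, producing two
voltages whose *ratio* carries ``|Z_X|/R_S`` and whose *phase difference*
carries ``arg Z_X``.  Two matched limiting/logarithmic amplifiers yield

* a logarithmic envelope output per channel; the digital difference of the
  two (after low-pass extraction of the DC) encodes ``K = |Z_X|/R_S`` on a
  log scale, ``V_m = g * log10(K)``;
* a hard-limited square wave per channel; an XOR of the two gives a
  pulse train whose duty cycle is ``theta/pi``, hence after low-pass
  filtering ``V_p = VDD * theta / pi``.

so ``Z_X = R_S * K`` at angle ``theta``.  Because both channels see the same
current, the excitation amplitude drops out of the measurement.

Two simulation levels are provided: :func:`demodulate_behavioral` evaluates
the channel equations directly (ideal matched channels), while
:func:`demodulate_waveform` synthesises the actual waveforms, hard-limits
them, forms the XOR pulse train and extracts its DC — including the bias a
residual limiter offset introduces, which the chip's feedback offset
cancellation removes (``limiter_offset=0``).

Digitisation models the 12-bit SAR ADC with additive Gaussian noise sized so
the effective resolution matches the stated ENOB; the DC outputs are
oversampled and averaged as a microcontroller reading a static level would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cole import ImpedanceSample
from .errors import RangeError, ValidationError

__all__ = [
    "ExcitationConfig",
    "DemodulatorConfig",
    "PolarReading",
    "demodulate_behavioral",
    "demodulate_waveform",
    "autotune",
    "reconstruct",
]

AMPLITUDE_RANGE = (5e-6, 1e-3)  # A, excitation current programmability
FREQUENCY_RANGE = (1e3, 1e6)  # Hz


@dataclass(frozen=True)
class ExcitationConfig:
    """Sinusoidal excitation current: amplitude 5 uA - 1 mA, 1 kHz - 1 MHz."""

    amplitude: float = 120e-6
    frequency: float = 100e3

    def __post_init__(self) -> None:
        lo, hi = AMPLITUDE_RANGE
        if not (lo <= self.amplitude <= hi):
            raise ValidationError(
                f"amplitude {self.amplitude} A outside programmable range [{lo}, {hi}]"
            )
        lo, hi = FREQUENCY_RANGE
        if not (lo <= self.frequency <= hi):
            raise ValidationError(
                f"frequency {self.frequency} Hz outside programmable range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class DemodulatorConfig:
    """Front-end chain parameters.

    Parameters
    ----------
    r_s_onchip : float
        On-chip reference resistor, ohm.
    r_s_offchip : float or None
        Optional off-chip resistor that can be switched in parallel with the
        on-chip one to re-centre the measurement range.
    use_offchip : bool
        Whether the off-chip resistor is currently switched in.
    vdd : float
        Supply voltage, V; also the ADC full scale and the XOR logic high.
    adc_bits, enob_bits : int
        Nominal and effective ADC resolution.
    n_adc_samples : int
        Conversions averaged per DC reading (the outputs are static levels).
    log_slope : float
        Magnitude-channel slope, V per decade of K.  The default (0.3
        V/decade) keeps the log levels of the whole 1 ohm - 1.2 kohm
        magnitude range, after reference centring, inside the [0, VDD] ADC
        window.
    log_range_db : float
        Usable dynamic range of the logarithmic amplifiers, dB (20*log10 K).
    lpf_cutoff : float
        Output low-pass corner, Hz (informational at this modelling level).
    ia_band : (float, float)
        Instrumentation-amplifier band-pass corners, Hz.
    ia_ceiling : float
        Linear-range ceiling of the IA inputs, V peak; autotune keeps both
        sensed voltages below it.
    limiter_offset : float
        Residual input-referred limiter offset after cancellation, V.
    """

    r_s_onchip: float = 500.0
    r_s_offchip: float | None = 56.0
    use_offchip: bool = False
    vdd: float = 2.0
    adc_bits: int = 12
    enob_bits: int = 10
    n_adc_samples: int = 16
    log_slope: float = 0.3
    log_range_db: float = 60.0
    lpf_cutoff: float = 100.0
    ia_band: tuple[float, float] = (100.0, 2e6)
    ia_ceiling: float = 1.0
    limiter_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.r_s_onchip <= 0:
            raise ValidationError("r_s_onchip must be > 0")
        if self.r_s_offchip is not None and self.r_s_offchip <= 0:
            raise ValidationError("r_s_offchip must be > 0 when given")
        if self.use_offchip and self.r_s_offchip is None:
            raise ValidationError("use_offchip requires r_s_offchip")
        if self.vdd <= 0:
            raise ValidationError("vdd must be > 0")
        if self.adc_bits < self.enob_bits:
            raise ValidationError("adc_bits must be >= enob_bits")
        if self.n_adc_samples < 1:
            raise ValidationError("n_adc_samples must be >= 1")
        if self.log_slope <= 0 or self.log_range_db <= 0:
            raise ValidationError("log_slope and log_range_db must be > 0")

    @property
    def r_s_total(self) -> float:
        """Effective reference resistance, ohm (parallel combination if the
        off-chip resistor is switched in)."""
        if self.use_offchip:
            assert self.r_s_offchip is not None
            return self.r_s_onchip * self.r_s_offchip / (self.r_s_onchip + self.r_s_offchip)
        return self.r_s_onchip


@dataclass(frozen=True)
class PolarReading:
    """Demodulator output pair and the impedance reconstructed from it."""

    v_m: float  # magnitude-channel DC output (log-ratio domain), V
    v_p: float  # phase-channel DC output, V
    k: float  # magnitude ratio |Z|/R_S
    theta_deg: float  # phase difference, degrees (reported positive)
    magnitude: float  # reconstructed |Z|, ohm
    phase_deg: float  # reconstructed phase, degrees, positive convention
    r_s_total: float
    frequency: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("k must be > 0")
        if self.v_p < -1e-12:
            raise ValidationError("v_p must be >= 0")

    def to_dict(self) -> dict:
        return {
            "v_m_v": self.v_m,
            "v_p_v": self.v_p,
            "k": self.k,
            "theta_deg": self.theta_deg,
            "magnitude_ohm": self.magnitude,
            "phase_deg": self.phase_deg,
            "r_s_total_ohm": self.r_s_total,
            "frequency_hz": self.frequency,
        }


def _check_log_range(k: float, cfg: DemodulatorConfig) -> None:
    # each log amplifier conforms over log_range_db of input amplitude, so the
    # channel ratio is representable within +/- log_range_db
    if abs(20.0 * np.log10(k)) > cfg.log_range_db:
        raise RangeError(
            f"magnitude ratio K={k:.4g} outside the +/-{cfg.log_range_db:.0f} dB "
            "log-amplifier range; re-run autotune"
        )


def _adc_read(value: float, cfg: DemodulatorConfig, rng: np.random.Generator | None) -> float:
    """Digitise a DC level: clip to [0, VDD], quantise to adc_bits, and (when a
    noise generator is supplied) add Gaussian noise sized so a single
    conversion has ENOB-limited resolution; n_adc_samples conversions are
    averaged."""
    lsb = cfg.vdd / 2**cfg.adc_bits
    lsb_eff = cfg.vdd / 2**cfg.enob_bits
    if rng is None:
        v = np.clip(value, 0.0, cfg.vdd)
        return float(np.round(v / lsb) * lsb)
    # total error of one conversion ~ LSB_enob/sqrt(12); quantisation supplies
    # LSB_adc/sqrt(12) of that, Gaussian noise the rest
    sigma = np.sqrt(max(lsb_eff**2 - lsb**2, 0.0) / 12.0)
    samples = value + rng.normal(0.0, sigma, size=cfg.n_adc_samples)
    samples = np.clip(samples, 0.0, cfg.vdd)
    return float(np.mean(np.round(samples / lsb) * lsb))


def _reading_from_channels(
    v_z_log: float,
    v_s_log: float,
    v_p_analog: float,
    cfg: DemodulatorConfig,
    frequency: float,
    rng: np.random.Generator | None,
) -> PolarReading:
    """Digitise the three DC levels and invert the channel equations."""
    v_z_d = _adc_read(v_z_log, cfg, rng)
    v_s_d = _adc_read(v_s_log, cfg, rng)
    v_p_d = _adc_read(v_p_analog, cfg, rng)
    v_m = v_z_d - v_s_d  # subtraction done in the digital domain
    k = 10.0 ** (v_m / cfg.log_slope)
    theta = np.pi * v_p_d / cfg.vdd
    return PolarReading(
        v_m=v_m,
        v_p=v_p_d,
        k=k,
        theta_deg=float(np.degrees(theta)),
        magnitude=cfg.r_s_total * k,
        phase_deg=float(np.degrees(theta)),
        r_s_total=cfg.r_s_total,
        frequency=frequency,
    )


def demodulate_behavioral(
    z_x: ImpedanceSample,
    exc: ExcitationConfig,
    cfg: DemodulatorConfig,
    noise_seed: int | None = None,
) -> PolarReading:
    """Ideal-channel demodulation: evaluate K and theta directly.

    Assumes the two measurement channels are identical, so the excitation
    amplitude cancels exactly.  ADC quantisation is always applied; ENOB
    noise only when ``noise_seed`` is given.
    """
    k_true = z_x.magnitude / cfg.r_s_total
    _check_log_range(k_true, cfg)
    theta_true = np.radians(z_x.phase_deg)  # |arg Z|
    # log-channel DC levels, referenced to mid-supply so K<1 stays on scale
    v_s_log = cfg.vdd / 2.0
    v_z_log = v_s_log + cfg.log_slope * np.log10(k_true)
    v_p = cfg.vdd * theta_true / np.pi
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    return _reading_from_channels(v_z_log, v_s_log, v_p, cfg, exc.frequency, rng)


def _xor_duty(
    s1: np.ndarray, s2: np.ndarray, t: np.ndarray
) -> float:
    """Fraction of time sign(s1) != sign(s2), with limiter edges located by
    linear interpolation between samples (timer-capture-style resolution)."""
    d1 = np.signbit(s1)
    d2 = np.signbit(s2)
    total = t[-1] - t[0]

    def crossings(s: np.ndarray, d: np.ndarray) -> np.ndarray:
        idx = np.nonzero(d[:-1] != d[1:])[0]
        frac = s[idx] / (s[idx] - s[idx + 1])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    events = np.concatenate(([t[0]], np.sort(np.concatenate([crossings(s1, d1), crossings(s2, d2)])), [t[-1]]))
    mids = 0.5 * (events[:-1] + events[1:])
    st1 = np.interp(mids, t, s1) < 0
    st2 = np.interp(mids, t, s2) < 0
    return float(np.sum((events[1:] - events[:-1])[st1 != st2]) / total)


def demodulate_waveform(
    z_x: ImpedanceSample,
    exc: ExcitationConfig,
    cfg: DemodulatorConfig,
    samples_per_period: int = 200,
    n_periods: int = 50,
    noise_seed: int | None = None,
) -> PolarReading:
    """Waveform-level demodulation.

    Synthesises the two sensed sinusoids, runs the ideal-log magnitude path
    on their rectified envelopes, hard-limits both signals (after adding any
    residual ``cfg.limiter_offset``), forms the XOR pulse train and takes its
    mean over an integer number of periods as the low-pass-extracted DC.
    Agrees with :func:`demodulate_behavioral` when ``limiter_offset = 0``.
    """
    if samples_per_period < 20:
        raise ValidationError("samples_per_period must be >= 20")
    if n_periods < 10:
        raise ValidationError("n_periods must be >= 10")
    k_true = z_x.magnitude / cfg.r_s_total
    _check_log_range(k_true, cfg)

    f = exc.frequency
    n = samples_per_period * n_periods
    t = np.arange(n + 1) / (samples_per_period * f)
    w = 2.0 * np.pi * f
    # tissue is capacitive: the voltage across Z_X lags the reference by theta
    theta_true = np.radians(z_x.phase_deg)
    v_z = exc.amplitude * z_x.magnitude * np.sin(w * t - theta_true)
    v_s = exc.amplitude * cfg.r_s_total * np.sin(w * t)

    # magnitude path: amplitude envelope of each channel over whole periods
    # (sqrt(2) * rms of a sine), then the ideal-log map
    a_z = float(np.sqrt(2.0) * np.std(v_z[:-1]))
    a_s = float(np.sqrt(2.0) * np.std(v_s[:-1]))
    v_s_log = cfg.vdd / 2.0
    v_z_log = v_s_log + cfg.log_slope * np.log10(a_z / a_s)

    # phase path: offset, hard limit, XOR, DC extraction
    s1 = v_z + cfg.limiter_offset
    s2 = v_s + cfg.limiter_offset
    for s in (s1, s2):
        n_cross = int(np.sum(np.signbit(s[:-1]) != np.signbit(s[1:])))
        # an unclipped sine has 2 crossings/period (edge effects aside); an
        # offset at or beyond the amplitude removes them entirely
        if n_cross < 2 * n_periods - 2:
            raise ValidationError(
                "limiter offset exceeds the signal amplitude: fewer than 2 "
                "zero crossings per period (degenerate waveform)"
            )
    v_p = cfg.vdd * _xor_duty(s1, s2, t)

    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    return _reading_from_channels(v_z_log, v_s_log, v_p, cfg, f, rng)


def autotune(
    z_estimate: float,
    cfg: DemodulatorConfig,
    exc_frequency: float = 100e3,
) -> tuple[ExcitationConfig, DemodulatorConfig]:
    """Select the reference resistor and the excitation amplitude.

    Picks the reference option (on-chip alone, or with the off-chip resistor
    in parallel) minimising ``|log(Z/R_S)|`` — i.e. centring the operating
    point at K = 1 — then the largest amplitude within the programmable range
    keeping both sensed voltages below the IA linear ceiling.  Deterministic.
    """
    if z_estimate <= 0:
        raise ValidationError("z_estimate must be > 0")
    options = [replace(cfg, use_offchip=False)]
    if cfg.r_s_offchip is not None:
        options.append(replace(cfg, use_offchip=True))
    best = min(options, key=lambda c: abs(np.log(z_estimate / c.r_s_total)))

    v_peak_per_amp = max(z_estimate, best.r_s_total)
    a_max = best.ia_ceiling / v_peak_per_amp
    lo, hi = AMPLITUDE_RANGE
    amplitude = min(a_max, hi)
    if amplitude < lo:
        raise RangeError(
            f"no feasible excitation amplitude: even {lo * 1e6:.0f} uA drives "
            f"{lo * v_peak_per_amp:.3g} V > ceiling {best.ia_ceiling} V"
        )
    return ExcitationConfig(amplitude=amplitude, frequency=exc_frequency), best


def reconstruct(
    v_m: float,
    v_p: float,
    cfg: DemodulatorConfig,
    frequency: float = 100e3,
) -> ImpedanceSample:
    """Invert the channel equations: (V_m, V_p) -> complex impedance.

    ``theta = pi * V_p / VDD``; ``K = 10**(V_m / slope)``; magnitude is
    ``R_S_total * K``.  The phase is reported positive (capacitive
    convention); the complex sample carries Im <= 0.
    """
    if not (0.0 <= v_p <= cfg.vdd):
        raise ValidationError(f"v_p must lie in [0, VDD={cfg.vdd}], got {v_p}")
    theta = np.pi * v_p / cfg.vdd
    k = 10.0 ** (v_m / cfg.log_slope)
    mag = cfg.r_s_total * k
    return ImpedanceSample.from_complex(frequency, mag * np.exp(-1j * theta))
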