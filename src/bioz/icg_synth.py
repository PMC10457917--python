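"""Synthetic single-frequency thoracic-impedance recordings with known truth.

Impedance cardiography rides a small cardiac-synchronous deflection (a few
hundred milli-ohm) on a basal thoracic impedance Z0 of 20-200 ohm, together
with a much larger, slower respiration component and instrument noise.  This
module builds such recordings from explicit hemodynamic ground truth so the
analysis pipeline can be validated without clinical data.

The per-beat deflection is a minimal parametric stand-in for the real
waveform: a raised-cosine systolic ejection lobe in -dZ/dt spanning the left
ventricular ejection time, followed by an exponential recovery of the
impedance to baseline.  It is parameterised solely by ((dZ/dt)_max, T_LVE)
and reproduces the B (ejection onset, upward zero crossing of -dZ/dt),
C (peak -dZ/dt) and X (ejection end, -dZ/dt minimum) landmarks exactly by
construction.  Y and O waves are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError

__all__ = [
    "SubjectProfile",
    "IcgGroundTruth",
    "BioimpedanceRecording",
    "make_beat_template",
    "template_span",
    "synthesize_recording",
    "truth_from_hemodynamics",
    "kubicek_sv",
]

BLOOD_RESISTIVITY = 135.0  # ohm*cm, conventional constant
THORAX_FRACTION_OF_HEIGHT = 0.17
Z0_RANGE = (20.0, 200.0)  # ohm, basal thoracic impedance
TLVE_RANGE = (0.1, 0.6)  # s
RECOVERY_FRACTION = 0.5  # recovery-lobe width as a fraction of t_lve
DZDT_MAX_CAP = 5.0  # ohm/s sanity cap


def kubicek_sv(rho: float, length: float, z0: float, dzdt_max: float, t_lve: float) -> float:
    """Kubicek stroke volume, mL.

    SV = rho * (L/Z0)^2 * (dZ/dt)_max * T_LVE with rho in ohm*cm, L in cm,
    Z0 in ohm, (dZ/dt)_max in ohm/s and T_LVE in s.
    """
    for name, v in (("rho", rho), ("length", length), ("z0", z0)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
    if dzdt_max < 0 or t_lve < 0:
        raise ValidationError("dzdt_max and t_lve must be >= 0")
    return rho * (length / z0) ** 2 * dzdt_max * t_lve


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry entering the Kubicek equation.

    ``length`` is the inter-electrode thoracic length in cm, by default 17%
    of the subject's height; ``rho`` is the blood resistivity (135 ohm*cm by
    convention).
    """

    height: float
    rho: float = BLOOD_RESISTIVITY
    length: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.rho <= 0:
            raise ValidationError("height and rho must be > 0")
        if self.length is None:
            object.__setattr__(self, "length", THORAX_FRACTION_OF_HEIGHT * self.height)
        if self.length <= 0:
            raise ValidationError("length must be > 0")


@dataclass(frozen=True)
class IcgGroundTruth:
    """Hemodynamic ground truth carried alongside a synthetic recording.

    Self-consistency is enforced at construction: each stored per-beat SV
    must equal the Kubicek equation applied to the stored parameters, and
    CO = mean(SV) * HR / 1000 (L/min).
    """

    subject: SubjectProfile
    z0: float
    dzdt_max_per_beat: tuple[float, ...]
    t_lve_per_beat: tuple[float, ...]
    beat_times: tuple[float, ...]
    hr: float
    sv_per_beat: tuple[float, ...]
    co: float

    def __post_init__(self) -> None:
        if not (Z0_RANGE[0] <= self.z0 <= Z0_RANGE[1]):
            raise ValidationError(f"z0 must lie in {Z0_RANGE} ohm, got {self.z0}")
        n = len(self.beat_times)
        if not (len(self.dzdt_max_per_beat) == len(self.t_lve_per_beat) == len(self.sv_per_beat) == n):
            raise ValidationError("per-beat arrays must have equal length")
        for t_lve in self.t_lve_per_beat:
            if not (TLVE_RANGE[0] < t_lve < TLVE_RANGE[1]):
                raise ValidationError(f"t_lve must lie in {TLVE_RANGE} s, got {t_lve}")
        for d, t_lve, sv in zip(self.dzdt_max_per_beat, self.t_lve_per_beat, self.sv_per_beat):
            expected = kubicek_sv(self.subject.rho, self.subject.length, self.z0, d, t_lve)
            if abs(expected - sv) > 1e-9 * max(1.0, abs(sv)):
                raise ValidationError(
                    f"stored SV {sv} inconsistent with Kubicek value {expected}"
                )
        co = float(np.mean(self.sv_per_beat)) * self.hr / 1000.0
        if abs(co - self.co) > 1e-9 * max(1.0, abs(co)):
            raise ValidationError(f"stored CO {self.co} != mean SV * HR / 1000 = {co}")

    def to_dict(self) -> dict:
        return {
            "height_cm": self.subject.height,
            "rho_ohm_cm": self.subject.rho,
            "length_cm": self.subject.length,
            "z0_ohm": self.z0,
            "dzdt_max_ohm_s": list(self.dzdt_max_per_beat),
            "t_lve_s": list(self.t_lve_per_beat),
            "beat_times_s": list(self.beat_times),
            "hr_bpm": self.hr,
            "sv_ml": list(self.sv_per_beat),
            "co_l_min": self.co,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IcgGroundTruth":
        subject = SubjectProfile(height=d["height_cm"], rho=d["rho_ohm_cm"], length=d["length_cm"])
        return cls(
            subject=subject,
            z0=d["z0_ohm"],
            dzdt_max_per_beat=tuple(d["dzdt_max_ohm_s"]),
            t_lve_per_beat=tuple(d["t_lve_s"]),
            beat_times=tuple(d["beat_times_s"]),
            hr=d["hr_bpm"],
            sv_per_beat=tuple(d["sv_ml"]),
            co=d["co_l_min"],
        )


@dataclass
class BioimpedanceRecording:
    """Uniformly sampled |Z|(t) at a fixed excitation frequency."""

    t: np.ndarray
    z: np.ndarray
    fs: float
    excitation_frequency: float = 100e3
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.t.shape != self.z.shape:
            raise ValidationError("t and z must have equal length")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if np.any(~np.isfinite(self.z)) or np.any(self.z <= 0):
            raise ValidationError("z must be finite and > 0 throughout")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


def template_span(t_lve: float) -> float:
    """Total duration of one beat deflection (ejection lobe + recovery)."""
    return t_lve * (1.0 + RECOVERY_FRACTION / 2.0)


def _lobe_integral(t: np.ndarray, width: float) -> np.ndarray:
    """Integral from 0 to t of the unit-peak raised cosine
    g(t) = (1 - cos(2 pi t / width)) / 2 on [0, width]; clamps outside."""
    tc = np.clip(t, 0.0, width)
    return 0.5 * tc - (width / (4.0 * np.pi)) * np.sin(2.0 * np.pi * tc / width)


def make_beat_template(dzdt_max: float, t_lve: float, fs: float) -> np.ndarray:
    """Impedance deflection (ohm, <= 0) of a single beat, sampled at ``fs``.

    The template is defined through -dZ/dt as two raised-cosine lobes:
    a systolic ejection lobe of width ``w_e = t_lve - w_r/2`` peaking at
    ``dzdt_max`` (the C point at its centre), and a negative recovery lobe of
    width ``w_r = t_lve/2`` centred exactly at ``t_lve``, returning the
    impedance to baseline.  Everything is continuously differentiable, so the
    landmarks survive band-pass filtering: B (upward zero crossing of
    -dZ/dt) is at t=0 and X (the -dZ/dt minimum) at t=t_lve exactly.
    The template scales linearly with ``dzdt_max``.
    """
    if dzdt_max < 0:
        raise ValidationError("dzdt_max must be >= 0")
    if not (TLVE_RANGE[0] < t_lve < TLVE_RANGE[1]):
        raise ValidationError(f"t_lve must lie in {TLVE_RANGE} s, got {t_lve}")
    if fs * t_lve < 20:
        raise ValidationError(f"fs={fs} Hz resolves t_lve={t_lve} s with fewer than 20 samples")
    w_r = RECOVERY_FRACTION * t_lve
    w_e = t_lve - w_r / 2.0
    amp_drop = dzdt_max * w_e / 2.0  # total impedance drop over ejection
    recovery_peak = 2.0 * amp_drop / w_r  # area match: recovery refills the drop
    span = template_span(t_lve)
    t = np.arange(int(round(span * fs)) + 1) / fs
    d = -dzdt_max * _lobe_integral(t, w_e) + recovery_peak * _lobe_integral(t - w_e, w_r)
    return d


def truth_from_hemodynamics(
    subject: SubjectProfile,
    z0: float,
    sv_target: float,
    hr: float,
    t_lve: float = 0.3,
    n_beats: int = 60,
    start_time: float = 0.5,
) -> IcgGroundTruth:
    """Build ground truth from target hemodynamics by inverting the Kubicek
    equation for (dZ/dt)_max:

        (dZ/dt)_max = SV * Z0^2 / (rho * L^2 * T_LVE)

    Beats are evenly spaced at 60/HR s.  The forward Kubicek equation applied
    to the result returns ``sv_target`` exactly.
    """
    if sv_target < 0 or hr <= 0 or n_beats < 1:
        raise ValidationError("sv_target >= 0, hr > 0 and n_beats >= 1 required")
    dzdt_max = sv_target * z0**2 / (subject.rho * subject.length**2 * t_lve)
    if dzdt_max > DZDT_MAX_CAP:
        raise ValidationError(
            f"required (dZ/dt)_max = {dzdt_max:.3g} ohm/s exceeds the {DZDT_MAX_CAP} ohm/s cap"
        )
    beat_times = tuple(start_time + 60.0 / hr * k for k in range(n_beats))
    sv = kubicek_sv(subject.rho, subject.length, z0, dzdt_max, t_lve)
    return IcgGroundTruth(
        subject=subject,
        z0=z0,
        dzdt_max_per_beat=(dzdt_max,) * n_beats,
        t_lve_per_beat=(t_lve,) * n_beats,
        beat_times=beat_times,
        hr=hr,
        sv_per_beat=(sv,) * n_beats,
        co=sv * hr / 1000.0,
    )


def synthesize_recording(
    truth: IcgGroundTruth,
    fs: float = 1000.0,
    respiration: tuple[float, float] | None = (1.0, 0.25),
    noise_sd: float = 0.0,
    seed: int | None = None,
    excitation_frequency: float = 100e3,
    tail: float = 0.5,
) -> BioimpedanceRecording:
    """Render ground truth into a sampled |Z|(t) recording.

    z(t) = Z0 + respiration sinusoid + per-beat deflections + white Gaussian
    noise (seeded).  ``respiration`` is (amplitude_ohm, rate_hz) or None.
    Raises when consecutive beat deflections would overlap.
    """
    if fs < 250:
        raise ValidationError("fs must be >= 250 Hz")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    beat_times = np.asarray(truth.beat_times)
    spans = np.array([template_span(tl) for tl in truth.t_lve_per_beat])
    if len(beat_times) > 1 and np.any(np.diff(beat_times) < spans[:-1]):
        raise ValidationError("beat interval shorter than the beat template span (overlap)")

    duration = beat_times[-1] + spans[-1] + tail
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    z = np.full(n, truth.z0)

    for t0, dzdt_max, t_lve in zip(beat_times, truth.dzdt_max_per_beat, truth.t_lve_per_beat):
        tpl = make_beat_template(dzdt_max, t_lve, fs)
        i0 = int(round(t0 * fs))
        z[i0 : i0 + len(tpl)] += tpl[: max(0, n - i0)]

    if respiration is not None:
        amp, rate = respiration
        z += amp * np.sin(2.0 * np.pi * rate * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        z += rng.normal(0.0, noise_sd, size=n)

    meta = {
        "seed": seed,
        "noise_sd_ohm": noise_sd,
        "respiration": None if respiration is None else {"amplitude_ohm": respiration[0], "rate_hz": respiration[1]},
        "ground_truth": truth.to_dict(),
    }
    return BioimpedanceRecording(t=t, z=z, fs=fs, excitation_frequency=excitation_frequency, metadata=meta)
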