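"""Impedance-cardiography analysis: from |Z|(t) to stroke volume and cardiac
output.

Processing chain, mirroring standard thoracic-bioimpedance practice:

1. preprocess   — linear detrend + zero-phase band-pass (default 0.5-20 Hz)
                  isolating the cardiac deflection; the raw mean is kept
                  separately as the basal impedance Z0.
2. detect_beats — C points as peaks of -dZ/dt above an adaptive threshold
                  with a physiological refractory period.
3. ensemble_average — align accepted beats on C and average pointwise,
                  suppressing residual respiration and noise; beats with an
                  RR interval deviating >20% from the median are excluded.
4. find_characteristic_points — on the averaged beat: C = -dZ/dt maximum,
                  B = ejection onset via tangent extrapolation cross-checked
                  against the last upward zero crossing (fallbacks flagged),
                  X = -dZ/dt minimum within 0.6 s after C; T_LVE = t_X - t_B.
5. kubicek-based SV, HR from the median C-C interval, CO = SV*HR/1000 L/min.

The systolic event is an impedance *decrease*; all detection operates on
-dZ/dt so that (dZ/dt)_max is the positive peak of -dZ/dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError
from .icg_synth import BioimpedanceRecording, SubjectProfile, kubicek_sv

__all__ = [
    "PipelineConfig",
    "ANALYSIS_DEFAULTS",
    "cardiac_output",
    "PreprocessedRecording",
    "BeatAnnotation",
    "HemodynamicResult",
    "preprocess",
    "detect_beats",
    "ensemble_average",
    "find_characteristic_points",
    "analyze",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the analysis chain (defaults in docstrings of
    the stage functions)."""

    detrend: bool = True
    band: tuple[float, float] = (0.5, 20.0)
    filter_order: int = 4
    peak_threshold_frac: float = 0.4  # of the rolling -dZ/dt maximum
    threshold_window: float = 10.0  # s, rolling-max window
    refractory: float = 0.3  # s, minimum C-C separation
    min_peak_height: float = 0.05  # ohm/s, absolute floor of the detection threshold
    detection_smoothing: float = 0.08  # s, moving-average width on -dZ/dt for detection only
    ensemble_window: tuple[float, float] = (0.3, 0.5)  # s before/after C
    rr_exclusion_frac: float = 0.2  # beats deviating more from median RR are dropped
    realign: bool = True  # second-pass template cross-correlation alignment
    realign_window: float = 0.06  # s, +/- search range for realignment
    annotation_lowpass: float | None = None  # Hz, extra zero-phase LP before point reading
    x_search_window: float = 0.6  # s after C
    b_onset_fraction: float = 0.12  # of the C peak: level for the B tangent rule
    b_slope_halfwidth: float = 0.02  # s, half-width for the slope estimate at the level point
    b_fallback_window: float = 0.15  # s before C for the d2 fallback
    min_duration: float = 5.0  # s
    smoothing: float | None = None  # optional moving-average width, s


@dataclass
class PreprocessedRecording:
    """Band-passed cardiac component plus the raw mean kept for Z0."""

    t: np.ndarray
    z_filtered: np.ndarray
    fs: float
    z0_raw_mean: float
    source: BioimpedanceRecording


@dataclass(frozen=True)
class BeatAnnotation:
    """Characteristic points of one (possibly averaged) beat; times in s on
    the time axis of the signal the annotation was made on."""

    beat_index: int
    t_b: float
    t_c: float
    t_x: float
    dzdt_max: float
    rr_interval: float = float("nan")
    b_from_fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.t_b < self.t_c < self.t_x):
            raise ValidationError(f"need t_b < t_c < t_x, got {(self.t_b, self.t_c, self.t_x)}")
        if self.dzdt_max <= 0:
            raise ValidationError("dzdt_max must be > 0")

    @property
    def t_lve(self) -> float:
        return self.t_x - self.t_b


@dataclass(frozen=True)
class HemodynamicResult:
    """Aggregate hemodynamics: CO = SV * HR / 1000 holds exactly."""

    z0: float
    hr: float
    sv: float
    co: float
    beats: tuple[BeatAnnotation, ...]
    n_beats_used: int
    quality_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_beats_used > 0:
            if self.sv <= 0 or self.z0 <= 0:
                raise ValidationError("sv and z0 must be > 0 when beats were used")
            if abs(self.co - self.sv * self.hr / 1000.0) > 1e-12 * max(1.0, self.co):
                raise ValidationError("co must equal sv * hr / 1000")

    def to_dict(self) -> dict:
        return {
            "z0_ohm": self.z0,
            "hr_bpm": self.hr,
            "sv_ml": self.sv,
            "co_l_min": self.co,
            "n_beats_used": self.n_beats_used,
            "beats": [
                {
                    "beat_index": b.beat_index,
                    "t_b_s": b.t_b,
                    "t_c_s": b.t_c,
                    "t_x_s": b.t_x,
                    "t_lve_s": b.t_lve,
                    "dzdt_max_ohm_s": b.dzdt_max,
                    "rr_interval_s": b.rr_interval,
                }
                for b in self.beats
            ],
            "flags": list(self.quality_flags),
        }


def cardiac_output(sv_ml: float, hr_bpm: float) -> float:
    """Cardiac output in L/min from stroke volume (mL/beat) and heart rate
    (beat/min): CO = SV * HR / 1000."""
    if sv_ml < 0 or hr_bpm < 0:
        raise ValidationError("sv_ml and hr_bpm must be >= 0")
    return sv_ml * hr_bpm / 1000.0


def neg_dzdt(z: np.ndarray, fs: float) -> np.ndarray:
    """-dZ/dt by central differences, ohm/s."""
    return -np.gradient(np.asarray(z, dtype=float), 1.0 / fs)


def preprocess(rec: BioimpedanceRecording, cfg: PipelineConfig = PipelineConfig()) -> PreprocessedRecording:
    """Detrend and zero-phase band-pass the recording.

    The raw mean is stored untouched for Z0 estimation; the filtered trace
    keeps the sample count.  An optional moving-average smoothing
    (``cfg.smoothing`` seconds) can precede the band-pass.
    """
    if rec.duration < cfg.min_duration:
        raise ValidationError(
            f"recording of {rec.duration:.2f} s is shorter than the {cfg.min_duration} s minimum"
        )
    z = rec.z.astype(float)
    z0_raw = float(np.mean(z))
    if cfg.smoothing:
        width = max(1, int(round(cfg.smoothing * rec.fs)))
        z = ndimage.uniform_filter1d(z, size=width, mode="nearest")
    if cfg.detrend:
        z = signal.detrend(z, type="linear")
    lo, hi = cfg.band
    sos = signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    z = signal.sosfiltfilt(sos, z)
    return PreprocessedRecording(t=rec.t, z_filtered=z, fs=rec.fs, z0_raw_mean=z0_raw, source=rec)


def detect_beats(pre: PreprocessedRecording, cfg: PipelineConfig = PipelineConfig()) -> tuple[np.ndarray, list[str]]:
    """Locate C points (peaks of -dZ/dt).

    The threshold adapts as ``peak_threshold_frac`` times the rolling maximum
    of -dZ/dt over ``threshold_window`` seconds; peaks closer than the
    refractory period are merged (largest wins).  Detection runs on a
    moving-average-smoothed copy of -dZ/dt (``detection_smoothing`` s wide):
    differentiation amplifies broadband noise, and the smoothing leaves the
    broad, symmetric C lobe in place while suppressing spurious peaks.
    Returns (times, flags); an empty result is flagged, not raised.
    """
    d = neg_dzdt(pre.z_filtered, pre.fs)
    if cfg.detection_smoothing:
        width = max(1, int(round(cfg.detection_smoothing * pre.fs)))
        d = ndimage.uniform_filter1d(d, size=width, mode="nearest")
    win = max(1, int(round(cfg.threshold_window * pre.fs)))
    rolling_max = ndimage.maximum_filter1d(d, size=win, mode="nearest")
    threshold = np.maximum(cfg.peak_threshold_frac * rolling_max, cfg.min_peak_height)
    idx, _ = signal.find_peaks(d, height=threshold, distance=max(1, int(round(cfg.refractory * pre.fs))))
    idx = idx[d[idx] > 0]
    if len(idx) == 0:
        return np.array([]), ["no_beats_detected"]
    return pre.t[idx], []


def _rr_accept(c_times: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Accept beats whose adjacent RR intervals are within ``frac`` of the
    median RR; returns (mask, rr_per_beat with NaN at the first beat)."""
    rr = np.diff(c_times)
    rr_per_beat = np.concatenate([[np.nan], rr])
    if len(rr) == 0:
        return np.ones(len(c_times), bool), rr_per_beat
    med = float(np.median(rr))
    ok_prev = np.concatenate([[True], np.abs(rr - med) <= frac * med])
    ok_next = np.concatenate([np.abs(rr - med) <= frac * med, [True]])
    return ok_prev & ok_next, rr_per_beat


def ensemble_average(
    pre: PreprocessedRecording,
    c_times: np.ndarray,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Average beats aligned on their C points.

    Beats whose RR interval deviates more than ``rr_exclusion_frac`` from the
    median RR, or whose window exceeds the record, are excluded and flagged.

    When ``cfg.realign`` is set a second pass re-aligns every beat by
    maximising its cross-correlation with the first-pass ensemble template
    over ``+/- realign_window``.  Aligning directly on each beat's own noisy
    -dZ/dt peak selects positive noise at the alignment point, a bias that
    does not average out; template correlation uses the whole beat shape and
    removes it.

    Returns (window time axis relative to C, averaged z, averaged -dZ/dt,
    flags); requires >= 3 usable beats.
    """
    flags: list[str] = []
    c_times = np.asarray(c_times, dtype=float)
    keep, _ = _rr_accept(c_times, cfg.rr_exclusion_frac)
    if not np.all(keep):
        flags.append(f"rr_outliers_excluded:{int(np.sum(~keep))}")
    before, after = cfg.ensemble_window
    nb, na = int(round(before * pre.fs)), int(round(after * pre.fs))
    d = neg_dzdt(pre.z_filtered, pre.fs)
    z = pre.z_filtered

    def collect(centers: np.ndarray, note_edges: bool) -> tuple[list, list]:
        segs_z, segs_d = [], []
        for i in centers:
            if i - nb < 0 or i + na + 1 > len(z):
                if note_edges:
                    flags.append("edge_beat_excluded")
                continue
            segs_z.append(z[i - nb : i + na + 1])
            segs_d.append(d[i - nb : i + na + 1])
        return segs_z, segs_d

    centers = np.array(
        [int(round((tc - pre.t[0]) * pre.fs)) for tc, ok in zip(c_times, keep) if ok], dtype=int
    )
    segs_z, segs_d = collect(centers, note_edges=True)
    if len(segs_z) < 3:
        raise ValidationError(f"only {len(segs_z)} usable beats; ensemble averaging needs >= 3")

    if cfg.realign:
        template = np.mean(segs_z, axis=0)
        shift_max = int(round(cfg.realign_window * pre.fs))
        realigned = []
        for i in centers:
            if i - nb - shift_max < 0 or i + na + shift_max + 1 > len(z):
                realigned.append(i)
                continue
            window = z[i - nb - shift_max : i + na + shift_max + 1]
            xc = np.correlate(window, template, mode="valid")
            realigned.append(i + int(np.argmax(xc)) - shift_max)
        segs_z, segs_d = collect(np.asarray(realigned, dtype=int), note_edges=False)
        if len(segs_z) < 3:
            raise ValidationError("realignment left fewer than 3 usable beats")

    t_rel = (np.arange(nb + na + 1) - nb) / pre.fs
    return t_rel, np.mean(segs_z, axis=0), np.mean(segs_d, axis=0), flags


def find_characteristic_points(
    t_rel: np.ndarray,
    avg_beat: np.ndarray,
    avg_neg_dzdt: np.ndarray,
    fs: float,
    cfg: PipelineConfig = PipelineConfig(),
    beat_index: int = 0,
) -> tuple[BeatAnnotation, list[str]]:
    """Annotate B, C and X on an averaged beat.

    C is the global maximum of -dZ/dt and X the global minimum within
    ``x_search_window`` after C.  B (the onset of the ejection upstroke,
    i.e. the point where -dZ/dt leaves zero before C) is located by tangent
    extrapolation: at the last ascent of -dZ/dt through ``b_onset_fraction``
    of the C peak, the local tangent of a quadratic onset intersects zero at
    ``t - 2*d(t)/d'(t)``, which is exact for the generic quadratic leading
    behaviour of a smooth upstroke and, unlike the plain zero crossing,
    reads the trace where it stands well above residual ensemble noise.
    The plain zero crossing is still computed as a cross-check (flagged when
    it disagrees by more than 25 ms); if the tangent rule finds no usable
    level point the zero crossing is used, and failing that the maximum of
    the second derivative in the ``b_fallback_window`` before C (flagged).

    ``cfg.annotation_lowpass`` applies an extra zero-phase low-pass to the
    averaged -dZ/dt before reading the points: the beat's derivative content
    sits below ~10 Hz, so narrowing the band suppresses residual ensemble
    noise that would otherwise bias the peak reading upward.  It is off by
    default here (exact landmark recovery on clean templates) and enabled by
    :func:`analyze` for full-record analysis.
    """
    flags: list[str] = []
    d = np.asarray(avg_neg_dzdt, dtype=float)
    if cfg.annotation_lowpass is not None:
        sos = signal.butter(4, cfg.annotation_lowpass, btype="lowpass", fs=fs, output="sos")
        d = signal.sosfiltfilt(sos, d)
    ic = int(np.argmax(d))
    if d[ic] <= 0:
        raise ValidationError("averaged beat has no positive -dZ/dt peak")

    upward = np.nonzero((d[:ic] <= 0) & (d[1 : ic + 1] > 0))[0]
    t_cross = float(t_rel[int(upward[-1])]) if len(upward) else None

    t_b: float | None = None
    h = max(2, int(round(cfg.b_slope_halfwidth * fs)))
    below = np.nonzero(d[:ic] <= cfg.b_onset_fraction * d[ic])[0]
    if len(below):
        ie = int(below[-1])
        if h <= ie < len(d) - h:
            slope = (d[ie + h] - d[ie - h]) * fs / (2 * h)
            if slope > 0:
                t_b = float(t_rel[ie] - 2.0 * d[ie] / slope)
                if t_b < t_rel[0]:
                    t_b = None
    if t_b is not None and t_cross is not None:
        if abs(t_b - t_cross) > 0.025:
            flags.append("b_zero_crossing_disagrees")
        # both rules fail only toward early B (noise plateaus stall the
        # crossing, toe shoulders deflate the tangent slope): the later
        # candidate is the reliable one
        t_b = max(t_b, t_cross)
    elif t_b is None and t_cross is not None:
        t_b = t_cross
        flags.append("b_point_from_zero_crossing")
    if t_b is None:
        lo = max(0, ic - int(round(cfg.b_fallback_window * fs)))
        if ic - lo < 2:
            raise ValidationError("B-point detection failed: no onset, no crossing, no fallback window")
        d2 = np.gradient(d[lo:ic], 1.0 / fs)
        t_b = float(t_rel[lo + int(np.argmax(d2))])
        flags.append("b_point_from_second_derivative")

    hi = min(len(d), ic + int(round(cfg.x_search_window * fs)) + 1)
    ix = ic + int(np.argmin(d[ic:hi]))
    if ix <= ic:
        raise ValidationError("X-point detection failed: no minimum after C")

    ann = BeatAnnotation(
        beat_index=beat_index,
        t_b=t_b,
        t_c=float(t_rel[ic]),
        t_x=float(t_rel[ix]),
        dzdt_max=float(d[ic]),
        b_from_fallback="b_point_from_second_derivative" in flags,
    )
    return ann, flags


#: defaults for full-record analysis: identical to :class:`PipelineConfig`
#: except that the annotation low-pass noise-suppression stage is enabled.
ANALYSIS_DEFAULTS = PipelineConfig(annotation_lowpass=15.0)


def analyze(
    rec: BioimpedanceRecording,
    subject: SubjectProfile,
    cfg: PipelineConfig | None = None,
) -> HemodynamicResult:
    """Full chain: preprocess, detect, average, annotate, Kubicek SV/CO.

    Z0 is the mean of the raw (unfiltered) impedance; HR = 60 / median
    accepted RR; SV comes from the averaged beat's annotation; CO is
    reported in L/min as SV * HR / 1000.  Deterministic given the recording.
    The default configuration is :data:`ANALYSIS_DEFAULTS` (annotation
    low-pass on).
    """
    if cfg is None:
        cfg = ANALYSIS_DEFAULTS
    if rec.duration < 10.0:
        raise ValidationError(f"analysis requires >= 10 s of data, got {rec.duration:.2f} s")
    flags: list[str] = []
    pre = preprocess(rec, cfg)
    c_times, det_flags = detect_beats(pre, cfg)
    flags += det_flags
    if len(c_times) == 0:
        raise ValidationError("no beats detected in recording")

    keep, rr_per_beat = _rr_accept(c_times, cfg.rr_exclusion_frac)
    rr_used = np.diff(c_times[keep]) if np.sum(keep) > 1 else np.diff(c_times)
    hr = 60.0 / float(np.median(rr_used)) if len(rr_used) else float("nan")

    t_rel, avg_beat, avg_d, ens_flags = ensemble_average(pre, c_times, cfg)
    flags += ens_flags
    ann, point_flags = find_characteristic_points(t_rel, avg_beat, avg_d, pre.fs, cfg)
    flags += point_flags

    # per-beat annotations on the full record (for inspection; SV uses the average)
    beats: list[BeatAnnotation] = []
    for j, tc in enumerate(c_times):
        beats.append(
            BeatAnnotation(
                beat_index=j,
                t_b=float(tc + ann.t_b - ann.t_c),
                t_c=float(tc),
                t_x=float(tc + ann.t_x - ann.t_c),
                dzdt_max=ann.dzdt_max,
                rr_interval=float(rr_per_beat[j]),
                b_from_fallback=ann.b_from_fallback,
            )
        )

    z0 = pre.z0_raw_mean
    sv = kubicek_sv(subject.rho, subject.length, z0, ann.dzdt_max, ann.t_lve)
    co = sv * hr / 1000.0
    return HemodynamicResult(
        z0=z0,
        hr=hr,
        sv=sv,
        co=co,
        beats=tuple(beats),
        n_beats_used=int(np.sum(keep)),
        quality_flags=tuple(flags),
    )
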