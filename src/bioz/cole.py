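"""2R1C Cole tissue model: evaluation, spectra, electrode interface, fitting.

Biological tissue in the beta-dispersion band (roughly 1 kHz - 1 MHz) is well
described by an equivalent circuit of an extracellular-fluid resistance ``R_e``
in parallel with the series combination of an intracellular resistance ``R_i``
and a membrane capacitance ``C``:

    Z(w) = R_e * (R_i + 1/(jwC)) / (R_e + R_i + 1/(jwC))

The model interpolates between two purely resistive limits: ``|Z| -> R_e`` as
f -> 0 (current cannot cross the membranes) and ``|Z| -> R_e*R_i/(R_e+R_i)``
as f -> inf (membranes are shorted).  Its impedance locus (-Im{Z} vs Re{Z})
is a semicircle centred on the real axis.

Tissue is capacitive, so Im{Z} <= 0 everywhere; following the instrument
convention, the *reported* phase is the positive angle ``|arg Z|`` in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize

from .errors import FitError, ValidationError

__all__ = [
    "ColeTissueModel",
    "ElectrodeInterface",
    "ImpedanceSample",
    "ImpedanceSpectrum",
    "ColeFitResult",
    "cole_impedance",
    "sweep_spectrum",
    "with_electrode_interface",
    "fit_cole",
]


@dataclass(frozen=True)
class ColeTissueModel:
    """2R1C tissue equivalent circuit.

    Parameters
    ----------
    r_e : float
        Extracellular fluid resistance, ohm.
    r_i : float
        Intracellular matter resistance, ohm.
    c : float
        Effective membrane capacitance of the series branch as wired, farad.
        (Physical fixtures are sometimes labelled with half-element values
        such as "C_m/2"; this field always stores the branch value that
        actually enters the impedance.)
    """

    r_e: float
    r_i: float
    c: float

    def __post_init__(self) -> None:
        for name in ("r_e", "r_i", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def r_inf(self) -> float:
        """Infinite-frequency resistance limit R_e*R_i/(R_e+R_i), ohm."""
        return self.r_e * self.r_i / (self.r_e + self.r_i)

    def impedance(self, frequency) -> complex | np.ndarray:
        """Complex impedance at ``frequency`` (Hz, scalar or array)."""
        f = np.asarray(frequency, dtype=float)
        if np.any(f <= 0):
            raise ValidationError("frequency must be > 0")
        branch = self.r_i + 1.0 / (1j * 2.0 * np.pi * f * self.c)
        z = self.r_e * branch / (self.r_e + branch)
        return complex(z) if np.isscalar(frequency) else z


@dataclass(frozen=True)
class ElectrodeInterface:
    """Series R-C electrode-skin interface (defaults: 50 ohm + 100 nF)."""

    r_es: float = 50.0
    c_es: float = 100e-9

    def __post_init__(self) -> None:
        if self.r_es < 0 or not np.isfinite(self.r_es):
            raise ValidationError(f"r_es must be >= 0, got {self.r_es!r}")
        if self.c_es <= 0 or not np.isfinite(self.c_es):
            raise ValidationError(f"c_es must be > 0, got {self.c_es!r}")

    def impedance(self, frequency) -> complex | np.ndarray:
        f = np.asarray(frequency, dtype=float)
        if np.any(f <= 0):
            raise ValidationError("frequency must be > 0")
        z = self.r_es + 1.0 / (1j * 2.0 * np.pi * f * self.c_es)
        return complex(z) if np.isscalar(frequency) else z


@dataclass(frozen=True)
class ImpedanceSample:
    """One complex impedance reading at a single frequency.

    ``phase_deg`` is the reported (positive, capacitive-convention) angle
    ``|arg Z|``; the signed complex value is available as :attr:`z`.
    """

    frequency: float
    magnitude: float
    phase_deg: float
    real: float
    imag: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValidationError("frequency must be > 0")
        if self.magnitude < 0:
            raise ValidationError("magnitude must be >= 0")
        # reported phase is unsigned; reconstruct the signed value from re/im
        signed = np.angle(self.real + 1j * self.imag, deg=True)
        if abs(abs(signed) - self.phase_deg) > 1e-6 + 1e-9 * self.phase_deg:
            raise ValidationError("phase_deg inconsistent with real/imag parts")
        if abs(np.hypot(self.real, self.imag) - self.magnitude) > 1e-6 * max(1.0, self.magnitude):
            raise ValidationError("magnitude inconsistent with real/imag parts")

    @classmethod
    def from_complex(cls, frequency: float, z: complex) -> "ImpedanceSample":
        z = complex(z)
        return cls(
            frequency=float(frequency),
            magnitude=abs(z),
            phase_deg=abs(float(np.angle(z, deg=True))),
            real=z.real,
            imag=z.imag,
        )

    @property
    def z(self) -> complex:
        """Signed complex impedance (Im <= 0 for capacitive loads)."""
        return complex(self.real, self.imag)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Ordered impedance samples at strictly increasing frequencies."""

    samples: tuple[ImpedanceSample, ...]

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValidationError("spectrum must contain at least one sample")
        f = self.frequencies
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")

    @classmethod
    def from_arrays(cls, frequencies, z) -> "ImpedanceSpectrum":
        frequencies = np.asarray(frequencies, dtype=float)
        z = np.asarray(z, dtype=complex)
        return cls(tuple(ImpedanceSample.from_complex(f, zi) for f, zi in zip(frequencies, z)))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ImpedanceSample]:
        return iter(self.samples)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency for s in self.samples])

    @property
    def z(self) -> np.ndarray:
        return np.array([s.z for s in self.samples])

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([s.magnitude for s in self.samples])


def cole_impedance(model: ColeTissueModel, frequency: float) -> ImpedanceSample:
    """Evaluate the 2R1C model at one frequency (Hz)."""
    return ImpedanceSample.from_complex(frequency, model.impedance(float(frequency)))


def sweep_spectrum(
    model: ColeTissueModel,
    f_min: float,
    f_max: float,
    n_points: int = 50,
    grid: str = "log",
) -> ImpedanceSpectrum:
    """Sweep the model over [f_min, f_max].

    ``grid`` is ``"log"`` (geometric spacing, the usual choice for
    beta-dispersion spectroscopy) or ``"linear"``; both grids include the
    two endpoints exactly.
    """
    if not (0 < f_min < f_max):
        raise ValidationError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if grid == "log":
        f = np.geomspace(f_min, f_max, n_points)
    elif grid == "linear":
        f = np.linspace(f_min, f_max, n_points)
    else:
        raise ValidationError(f"grid must be 'log' or 'linear', got {grid!r}")
    return ImpedanceSpectrum.from_arrays(f, model.impedance(f))


def with_electrode_interface(
    obj: ImpedanceSample | ImpedanceSpectrum,
    interface: ElectrodeInterface,
    n_series: int = 2,
) -> ImpedanceSample | ImpedanceSpectrum:
    """Add ``n_series`` copies of the electrode-skin series RC to an impedance.

    In a tetrapolar measurement the interface sits in the current path, not
    the sensed voltage divider, so this matters for two-electrode fixtures
    and current-source headroom, not for the ratio-based readout itself.
    """
    if n_series not in (0, 1, 2):
        raise ValidationError(f"n_series must be 0, 1 or 2, got {n_series!r}")
    if n_series == 0:
        return obj
    if isinstance(obj, ImpedanceSample):
        return ImpedanceSample.from_complex(
            obj.frequency, obj.z + n_series * interface.impedance(obj.frequency)
        )
    f = obj.frequencies
    return ImpedanceSpectrum.from_arrays(f, obj.z + n_series * interface.impedance(f))


@dataclass(frozen=True)
class ColeFitResult:
    """Outcome of :func:`fit_cole`.

    ``success`` is False when the optimiser failed or the capacitance is
    unidentifiable (e.g. a purely resistive spectrum); in that case ``model``
    holds the best available point and ``message`` explains the failure.
    """

    model: ColeTissueModel
    residual_norm: float
    success: bool
    message: str = ""
    n_iterations: int = 0
    initial: ColeTissueModel | None = field(default=None, repr=False)


def _initial_guess(spectrum: ImpedanceSpectrum) -> ColeTissueModel:
    """Heuristic start: endpoints give R_e and R_inf, the -Im extremum gives C."""
    mags = spectrum.magnitudes
    r_e = float(mags[0])
    r_inf = float(min(mags[-1], 0.999 * r_e))
    r_inf = max(r_inf, 1e-3 * r_e)
    r_i = r_e * r_inf / (r_e - r_inf)
    # Z = R_inf + (R_e - R_inf)/(1 + jw*tau) with tau = C*(R_e + R_i), so the
    # -Im extremum sits at f0 = 1/(2*pi*C*(R_e + R_i))
    neg_im = -spectrum.z.imag
    f0 = float(spectrum.frequencies[int(np.argmax(neg_im))])
    c = 1.0 / (2.0 * np.pi * f0 * (r_e + r_i))
    return ColeTissueModel(r_e=r_e, r_i=r_i, c=c)


def fit_cole(
    spectrum: ImpedanceSpectrum,
    initial: ColeTissueModel | None = None,
    weighting: str = "unweighted",
    max_nfev: int = 2000,
) -> ColeFitResult:
    """Least-squares fit of a 2R1C model to a measured spectrum.

    The loss stacks real and imaginary residuals (``weighting="unweighted"``,
    the default) or scales each sample's residual pair by 1/|Z|
    (``weighting="relative"``).  Parameters are optimised in log space to
    enforce positivity.  Requires at least 3 distinct frequencies spanning
    one decade.

    Returns a :class:`ColeFitResult`; an unidentifiable or non-convergent fit
    is reported explicitly via ``success=False``, never silently.
    """
    f = spectrum.frequencies
    if len(f) < 3:
        raise ValidationError("fit requires at least 3 distinct frequencies")
    if f[-1] / f[0] < 10.0:
        raise ValidationError("fit requires a spectrum spanning at least one decade")
    if weighting not in ("unweighted", "relative"):
        raise ValidationError(f"unknown weighting {weighting!r}")

    z_obs = spectrum.z
    w = 1.0 / np.abs(z_obs) if weighting == "relative" else np.ones_like(f)

    # degenerate input: no measurable reactance -> C unidentifiable
    reactance_scale = float(np.max(-z_obs.imag) / np.max(np.abs(z_obs)))
    guess = initial if initial is not None else _initial_guess(spectrum)
    if reactance_scale < 1e-6:
        return ColeFitResult(
            model=guess,
            residual_norm=float("nan"),
            success=False,
            message="spectrum is purely resistive: capacitance unidentifiable",
            initial=guess,
        )

    def residuals(p: np.ndarray) -> np.ndarray:
        m = ColeTissueModel(*np.exp(p))
        dz = (m.impedance(f) - z_obs) * w
        return np.concatenate([dz.real, dz.imag])

    p0 = np.log([guess.r_e, guess.r_i, guess.c])
    sol = optimize.least_squares(residuals, p0, method="lm", max_nfev=max_nfev)
    fitted = ColeTissueModel(*np.exp(sol.x))
    ok = bool(sol.success) and sol.nfev < max_nfev
    return ColeFitResult(
        model=fitted,
        residual_norm=float(np.linalg.norm(sol.fun)),
        success=ok,
        message="" if ok else f"fit did not converge: {sol.message}",
        n_iterations=int(sol.nfev),
        initial=guess,
    )
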