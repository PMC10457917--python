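"""Passing-Bablok method comparison for paired measurements.

Passing-Bablok regression is the standard nonparametric procedure for
judging whether two measurement methods are interchangeable: the slope is a
shifted median of all pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i)
(excluding S_ij = -1 and pairs with x_i = x_j), with offset K equal to the
number of S_ij < -1; the intercept is median(y_i - b*x_i).  Confidence
intervals come from the rank-based normal approximation.  The two methods
are declared equivalent when the 95% slope CI contains 1 and the 95%
intercept CI contains 0.  The squared Pearson correlation (R^2) is reported
alongside, as method-comparison studies conventionally do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PairedMeasurements",
    "ComparisonResult",
    "passing_bablok",
    "simulate_equivalence_study",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired observations of a reference method (a) and a candidate (b)."""

    method_a: tuple[float, ...]
    method_b: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.method_a) != len(self.method_b):
            raise ValidationError("method_a and method_b must have equal length")
        if len(self.method_a) < 3:
            raise ValidationError("need at least 3 pairs")
        vals = np.concatenate([self.method_a, self.method_b])
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            raise ValidationError("all values must be finite and positive")
        if self.labels is not None and len(self.labels) != len(self.method_a):
            raise ValidationError("labels length mismatch")

    @classmethod
    def from_arrays(cls, a, b, labels=None) -> "PairedMeasurements":
        return cls(
            tuple(float(v) for v in a),
            tuple(float(v) for v in b),
            None if labels is None else tuple(str(x) for x in labels),
        )

    def __len__(self) -> int:
        return len(self.method_a)


@dataclass(frozen=True)
class ComparisonResult:
    """Passing-Bablok estimates; CIs are None below 10 pairs (flagged)."""

    slope: float
    intercept: float
    slope_ci_95: tuple[float, float] | None
    intercept_ci_95: tuple[float, float] | None
    r_squared: float
    n_pairs: int
    equivalent: bool | None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci_95": list(self.slope_ci_95) if self.slope_ci_95 else None,
            "intercept_ci_95": list(self.intercept_ci_95) if self.intercept_ci_95 else None,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
            "equivalent": self.equivalent,
            "flags": list(self.flags),
        }


def _shifted_median(s: np.ndarray, offset: int) -> float:
    """Median of sorted array shifted right by ``offset`` ranks."""
    n = len(s)
    if n % 2 == 1:
        return float(s[(n + 1) // 2 + offset - 1])
    return 0.5 * float(s[n // 2 + offset - 1] + s[n // 2 + offset])


def passing_bablok(pairs: PairedMeasurements, conf: float = 0.95) -> ComparisonResult:
    """Passing-Bablok regression of method_b on method_a.

    Deterministic and invariant to the ordering of the pairs.  With fewer
    than 10 pairs only point estimates are returned, flagged ``no_ci``.
    """
    x = np.asarray(pairs.method_a)
    y = np.asarray(pairs.method_b)
    n = len(x)
    flags: list[str] = []

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    valid = dx != 0
    if not np.any(valid):
        raise ValidationError("all x values identical: slope undefined")
    if np.any(~valid):
        flags.append(f"tied_x_pairs_skipped:{int(np.sum(~valid))}")
    s = dy[valid] / dx[valid]
    s = np.sort(s[s != -1.0])
    if len(s) == 0:
        raise ValidationError("no usable pairwise slopes")
    big_n = len(s)
    offset = int(np.sum(s < -1.0))
    slope = _shifted_median(s, offset)
    intercept = float(np.median(y - slope * x))
    r = float(stats.pearsonr(x, y).statistic)
    r_squared = r * r

    if n < 10:
        flags.append("no_ci")
        return ComparisonResult(slope, intercept, None, None, r_squared, n, None, tuple(flags))

    z = stats.norm.ppf(0.5 + conf / 2.0)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_idx = max(m1 + offset, 1)
    hi_idx = min(m2 + offset, big_n)
    slope_ci = (float(s[lo_idx - 1]), float(s[hi_idx - 1]))
    intercept_ci = (float(np.median(y - slope_ci[1] * x)), float(np.median(y - slope_ci[0] * x)))
    equivalent = bool(slope_ci[0] <= 1.0 <= slope_ci[1] and intercept_ci[0] <= 0.0 <= intercept_ci[1])
    return ComparisonResult(
        slope, intercept, slope_ci, intercept_ci, r_squared, n, equivalent, tuple(flags)
    )


def simulate_equivalence_study(
    n_subjects: int = 33,
    sv_range: tuple[float, float] = (30.0, 90.0),
    method_noise: tuple[float, float] = (3.0, 3.0),
    bias_slope: float = 1.0,
    bias_intercept: float = 0.0,
    seed: int | None = None,
) -> PairedMeasurements:
    """Synthetic paired SV cohort: truth uniform in ``sv_range``; method A
    = truth + noise_a, method B = bias_slope*truth + bias_intercept + noise_b."""
    if n_subjects < 3:
        raise ValidationError("n_subjects must be >= 3")
    rng = np.random.default_rng(seed)
    truth = rng.uniform(*sv_range, size=n_subjects)
    a = truth + rng.normal(0.0, method_noise[0], size=n_subjects)
    b = bias_slope * truth + bias_intercept + rng.normal(0.0, method_noise[1], size=n_subjects)
    return PairedMeasurements.from_arrays(a, b, labels=[f"S{k + 1:03d}" for k in range(n_subjects)])
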