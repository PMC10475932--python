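"""Scatter correction and derivative mathematics for NIR spectra.

The preprocessing chain mirrors classical chemometrics practice for
diffuse-reflectance spectra of dried, ground samples:

1. **SNV** (standard normal variate): each spectrum is centred and scaled
   to unit standard deviation, removing multiplicative and additive
   scatter effects.
2. **Detrend**: a low-order polynomial in wavelength is fitted per
   spectrum and subtracted, removing curvilinear baseline drift.
3. **Gap-segment derivative**: running-mean smoothing followed by
   repeated centred gap differences, encoded by the four-number
   "d,g,s,s2" math-treatment code (derivative order, gap in nm,
   smoothing points, second smoothing points; s2 = 1 means none).

All stages are linear or affine per spectrum and strictly deterministic.
Edges are trimmed, never padded: the output grid shrinks by the window
arithmetic documented on each function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraSet

__all__ = [
    "MathTreatment",
    "PreprocessingSettings",
    "parse_math_treatment",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_pipeline",
]


@dataclass(frozen=True)
class MathTreatment:
    """Derivative math treatment "d,g,s,s2".

    derivative_order : 0, 1 or 2 — number of gap-difference passes.
    gap_nm : gap width g in nm; the centred difference is
        f(lambda + g/2) - f(lambda - g/2). Must convert to a positive even
        number of grid points when a derivative is taken.
    smooth_points : running-mean window before the derivative (1 = none).
    second_smooth_points : running-mean window after (1 = none).
    """

    derivative_order: int = 2
    gap_nm: float = 8.0
    smooth_points: int = 6
    second_smooth_points: int = 1

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > 0 and self.gap_nm <= 0:
            raise ValueError("gap_nm must be positive when a derivative is taken")
        if self.smooth_points < 1 or self.second_smooth_points < 1:
            raise ValueError("smoothing windows must be >= 1 point")

    def code(self) -> str:
        g = self.gap_nm
        g_txt = f"{int(g)}" if float(g).is_integer() else f"{g}"
        return f"{self.derivative_order},{g_txt},{self.smooth_points},{self.second_smooth_points}"

    def gap_points(self, grid_step: float) -> int:
        """Gap expressed in grid points; must be even so the half-gap is integral."""
        if self.derivative_order == 0:
            return 0
        pts = self.gap_nm / grid_step
        if abs(pts - round(pts)) > 1e-9:
            raise ValueError(
                f"gap of {self.gap_nm} nm is not a whole number of {grid_step} nm steps"
            )
        pts = int(round(pts))
        if pts <= 0 or pts % 2 != 0:
            raise ValueError(
                f"gap of {self.gap_nm} nm maps to {pts} grid points; need a positive even count"
            )
        return pts


IDENTITY_TREATMENT = MathTreatment(0, 0.0, 1, 1)


@dataclass(frozen=True)
class PreprocessingSettings:
    """Full preprocessing recipe: scatter correction then derivative.

    scatter_mode is one of "none", "snv", "snv+detrend"; detrend always
    follows SNV (detrending a raw-scale spectrum mixes scatter back in).
    """

    scatter_mode: str = "snv+detrend"
    detrend_degree: int = 2
    treatment: MathTreatment = field(default_factory=MathTreatment)

    def __post_init__(self) -> None:
        if self.scatter_mode not in ("none", "snv", "snv+detrend"):
            raise ValueError(f"unknown scatter_mode {self.scatter_mode!r}")
        if self.detrend_degree < 1:
            raise ValueError("detrend_degree must be >= 1")

    def to_dict(self) -> dict:
        return {
            "scatter_mode": self.scatter_mode,
            "detrend_degree": self.detrend_degree,
            "math_treatment": self.treatment.code(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessingSettings":
        return cls(
            scatter_mode=d.get("scatter_mode", "snv+detrend"),
            detrend_degree=int(d.get("detrend_degree", 2)),
            treatment=parse_math_treatment(d.get("math_treatment", "2,8,6,1")),
        )


def parse_math_treatment(code: str) -> MathTreatment:
    """Parse a "d,g,s,s2" code, e.g. ``"2,8,6,1"``.

    Four comma-separated numbers: derivative order, gap in nm, smoothing
    points, second smoothing points (1 = no second smooth).
    """
    parts = [p.strip() for p in str(code).split(",")]
    if len(parts) != 4:
        raise ValueError(
            f"math treatment code must have four comma-separated fields, got {code!r}"
        )
    try:
        order = int(parts[0])
        gap = float(parts[1])
        smooth = int(parts[2])
        smooth2 = int(parts[3])
    except ValueError as exc:
        raise ValueError(f"malformed math treatment code {code!r}: {exc}") from None
    return MathTreatment(order, gap, smooth, smooth2)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centre and scale to unit SD.

    Uses the n-1 denominator. Output rows have mean 0 and SD 1, so the
    transform is invariant to any per-spectrum affine map a*x + b, a > 0.
    """
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = [spectra.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"constant spectrum (zero SD) for sample(s) {ids}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return SpectraSet(list(spectra.sample_ids), spectra.wavelengths.copy(), out)


def detrend(spectra: SpectraSet, degree: int = 2) -> SpectraSet:
    """Subtract a per-spectrum least-squares polynomial in wavelength.

    The residual is orthogonal to the polynomial basis, so a spectrum that
    IS a polynomial of the given degree maps to zero.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if spectra.n_wavelengths <= degree:
        raise ValueError(
            f"degree {degree} needs more than {degree} grid points, "
            f"have {spectra.n_wavelengths}"
        )
    # centred/scaled wavelength axis keeps the Vandermonde well conditioned
    wl = spectra.wavelengths
    span = np.ptp(wl)
    u = (wl - wl.mean()) / (span / 2 if span > 0 else 1.0)
    basis = np.polynomial.polynomial.polyvander(u, degree)  # (p, degree+1)
    coef, *_ = np.linalg.lstsq(basis, spectra.absorbance.T, rcond=None)
    out = spectra.absorbance - (basis @ coef).T
    return SpectraSet(list(spectra.sample_ids), wl.copy(), out)


def _running_mean(X: np.ndarray, wl: np.ndarray, points: int) -> tuple[np.ndarray, np.ndarray]:
    """Running mean over `points` grid points, valid region only.

    Odd windows are centred; even windows are left-biased half-open,
    [i - s/2, i + s/2 - 1], so the conventional even segment lengths stay
    usable. Returns (smoothed matrix, trimmed grid).
    """
    if points == 1:
        return X, wl
    n = X.shape[1]
    if points > n:
        raise ValueError(f"smoothing window of {points} exceeds grid length {n}")
    kernel = np.full(points, 1.0 / points)
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, X)
    left = points // 2
    right = points - 1 - left  # even window: right trim = s/2 - 1
    new_wl = wl[left : n - right]
    return out, new_wl


def _gap_difference(X: np.ndarray, wl: np.ndarray, half_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred gap difference f(i + h) - f(i - h); trims h points per side."""
    n = X.shape[1]
    if 2 * half_gap >= n:
        raise ValueError(f"gap of {2 * half_gap} points exceeds grid length {n}")
    out = X[:, 2 * half_gap :] - X[:, : n - 2 * half_gap]
    return out, wl[half_gap : n - half_gap]


def gap_segment_derivative(spectra: SpectraSet, treatment: MathTreatment) -> SpectraSet:
    """Apply the "d,g,s,s2" smoothing + gap-derivative treatment.

    Order of stages: first running-mean smooth over ``smooth_points``,
    then ``derivative_order`` passes of the centred gap difference with
    gap ``gap_nm``, then the optional second running-mean.  Differences
    are NOT divided by the gap width; the scale constant is absorbed by
    the downstream regression coefficients.
    """
    X = spectra.absorbance
    wl = spectra.wavelengths
    X, wl = _running_mean(X, wl, treatment.smooth_points)
    if treatment.derivative_order > 0:
        half = treatment.gap_points(spectra.grid_step) // 2
        for _ in range(treatment.derivative_order):
            X, wl = _gap_difference(X, wl, half)
    X, wl = _running_mean(X, wl, treatment.second_smooth_points)
    return SpectraSet(list(spectra.sample_ids), wl, X)


def apply_pipeline(spectra: SpectraSet, settings: PreprocessingSettings) -> SpectraSet:
    """SNV -> detrend -> gap-segment derivative, per the settings.

    The composition order is fixed; the output carries the (possibly
    trimmed) wavelength grid, so callers can compare grids across runs.
    """
    out = spectra
    if settings.scatter_mode in ("snv", "snv+detrend"):
        out = snv(out)
    if settings.scatter_mode == "snv+detrend":
        out = detrend(out, settings.detrend_degree)
    if settings.treatment != IDENTITY_TREATMENT:
        out = gap_segment_derivative(out, settings.treatment)
    return out


def trim_per_side(settings: PreprocessingSettings, grid_step: float) -> tuple[int, int]:
    """(left, right) points removed from the grid by the full pipeline."""
    t = settings.treatment
    left = right = 0
    for pts in (t.smooth_points, t.second_smooth_points):
        if pts > 1:
            left += pts // 2
            right += pts - 1 - pts // 2
    if t.derivative_order > 0:
        half = t.gap_points(grid_step) // 2
        left += half * t.derivative_order
        right += half * t.derivative_order
    return left, right
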