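"""Calibration and validation statistics for spectroscopic prediction.

Conventions (fixed so the usual printed report columns are reproducible):

* ``bias``   = mean(predicted - reference)
* ``SEP``    = sqrt(sum(e^2) / N)                 (N denominator)
* ``SEP(C)`` = sqrt(N/(N-1) * (SEP^2 - bias^2))   = SD of residuals about
  their mean with the N-1 denominator (algebraic identity)
* ``SEC``    = sqrt(sum(e_cal^2) / (N - n_terms - 1))
* ``SECV``   = sqrt(sum(e_cv^2) / N)
* ``RPD``    = SD / error (reported to one decimal)
* validation slope / R^2 come from the OLS of predicted (response) on
  measured (predictor); R^2 is the squared Pearson correlation.

The identity SEP^2 = bias^2 + (N-1)/N * SEP(C)^2 holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CalibrationReport",
    "ValidationReport",
    "compute_sep_bias_sepc",
    "compute_rpd",
    "regression_slope_r2",
    "compute_sec_secv",
    "build_validation_report",
    "flag_validation_outliers",
]


@dataclass
class CalibrationReport:
    constituent: str
    n: int
    mean: float
    sd: float
    r2_cal: float
    sec: float
    secv: float
    sd_over_secv: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ValidationReport:
    constituent: str
    n: int
    mean: float
    sd: float
    sep: float
    bias: float
    sep_c: float
    slope: float
    r2_val: float
    sd_over_sep: float
    flagged_outliers: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compute_sep_bias_sepc(predicted: np.ndarray, reference: np.ndarray) -> tuple[float, float, float]:
    """Return (SEP, bias, SEP(C)) for a validation set."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference must have equal length")
    n = predicted.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    e = predicted - reference
    bias = float(e.mean())
    sep = float(np.sqrt(np.mean(e**2)))
    sep_c = float(np.sqrt(max(n / (n - 1) * (sep**2 - bias**2), 0.0)))
    return sep, bias, sep_c


def sepc_from_printed(sep: float, bias: float, n: int) -> float:
    """Bias-corrected SEP recomputed from reported SEP, bias and N."""
    if n < 2:
        raise ValueError("need N >= 2")
    return float(np.sqrt(max(n / (n - 1) * (sep**2 - bias**2), 0.0)))


def compute_rpd(sd: float, error: float) -> float:
    """Ratio of SD to a standard error (RPD), reported to one decimal."""
    if error <= 0:
        raise ValueError("error must be positive")
    return round(sd / error, 1)


def regression_slope_r2(predicted: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """OLS slope of predicted on measured, plus squared Pearson R.

    Accuracy is read off the slope (1 = unbiased proportionality),
    precision off R^2.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.size != reference.size:
        raise ValueError("length mismatch")
    if predicted.size < 3:
        raise ValueError("need at least 3 samples")
    var_x = reference.var(ddof=1)
    if var_x == 0:
        raise ValueError("reference values have zero variance")
    cov = np.cov(reference, predicted, ddof=1)
    slope = float(cov[0, 1] / cov[0, 0])
    var_y = predicted.var(ddof=1)
    r2 = 0.0 if var_y == 0 else float(cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1]))
    return slope, r2


def compute_sec_secv(cal_residuals: np.ndarray, n_terms: int,
                     cv_residuals: np.ndarray | None = None) -> tuple[float, float | None]:
    """(SEC, SECV): calibration error with n_terms+1 df lost; CV error with N."""
    e = np.asarray(cal_residuals, dtype=float)
    n = e.size
    df = n - n_terms - 1
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (N={n}, terms={n_terms})")
    sec = float(np.sqrt(np.sum(e**2) / df))
    secv = None
    if cv_residuals is not None:
        ecv = np.asarray(cv_residuals, dtype=float)
        secv = float(np.sqrt(np.mean(ecv**2)))
    return sec, secv


def build_validation_report(constituent: str, predicted: np.ndarray,
                            reference: np.ndarray,
                            flagged: list[str] | None = None) -> ValidationReport:
    """Assemble the full validation row for one constituent."""
    reference = np.asarray(reference, dtype=float)
    sep, bias, sep_c = compute_sep_bias_sepc(predicted, reference)
    slope, r2 = regression_slope_r2(predicted, reference)
    sd = float(reference.std(ddof=1))
    return ValidationReport(
        constituent=constituent,
        n=int(reference.size),
        mean=float(reference.mean()),
        sd=sd,
        sep=sep,
        bias=bias,
        sep_c=sep_c,
        slope=slope,
        r2_val=r2,
        sd_over_sep=compute_rpd(sd, sep) if sep > 0 else float("inf"),
        flagged_outliers=list(flagged or []),
    )


def flag_validation_outliers(predicted: np.ndarray, reference: np.ndarray,
                             sample_ids: list[str], constituent: str = "",
                             k: float = 2.5) -> tuple[ValidationReport, ValidationReport]:
    """One round of validation-outlier screening.

    Residuals more than ``k`` bias-corrected standard errors from the mean
    residual are flagged and excluded; the statistics are then recomputed
    once on the remainder (no second removal round).  Returns the
    (pre-removal, post-removal) reports; with nothing flagged the two are
    identical.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(sample_ids) != predicted.size:
        raise ValueError("sample_ids length mismatch")
    sep, bias, sep_c = compute_sep_bias_sepc(predicted, reference)
    e = predicted - reference
    if sep_c > 0:
        mask = np.abs(e - bias) > k * sep_c
    else:
        mask = np.zeros(e.shape, dtype=bool)
    flagged = [sample_ids[i] for i in np.flatnonzero(mask)]
    pre = build_validation_report(constituent, predicted, reference, flagged)
    if not flagged:
        return pre, pre
    keep = ~mask
    if not keep.any() or keep.sum() < 3:
        raise ValueError("outlier screening would remove (almost) all samples")
    post = build_validation_report(constituent, predicted[keep], reference[keep], [])
    return pre, post
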