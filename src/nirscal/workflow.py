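"""Per-constituent calibration / validation orchestration.

One NIRS model is fitted per constituent (constituent-wise pairwise
complete data: samples with a missing reference value are dropped for
that constituent only, never imputed), tying together preprocessing,
MPLS with CV term selection, the two-round global-H outlier protocol
and the report statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ReferenceTable, SpectraSet
from .mpls import (
    CVSettings,
    MPLSModel,
    OutlierPolicy,
    calibrate_with_outlier_protocol,
    predict,
)
from .preprocessing import PreprocessingSettings, apply_pipeline
from .validation import (
    CalibrationReport,
    ValidationReport,
    build_validation_report,
    compute_rpd,
    compute_sec_secv,
    flag_validation_outliers,
    regression_slope_r2,
)

__all__ = ["ConstituentCalibration", "calibrate_constituent",
           "calibrate_all", "validate_constituent"]


@dataclass
class ConstituentCalibration:
    constituent: str
    model: MPLSModel
    report: CalibrationReport
    outlier_report: dict


def _aligned_ids(spectra: SpectraSet, reference: ReferenceTable,
                 constituent: str) -> list[str]:
    series = reference.data[constituent].dropna()
    ids = [s for s in spectra.sample_ids if s in series.index]
    if not ids:
        raise ValueError(
            f"no overlapping samples between spectra and reference for {constituent!r}"
        )
    return ids


def calibrate_constituent(spectra: SpectraSet, reference: ReferenceTable,
                          constituent: str,
                          settings: PreprocessingSettings | None = None,
                          cv: CVSettings | None = None,
                          policy: OutlierPolicy | None = None,
                          residual_scaling: bool = True) -> ConstituentCalibration:
    """Full calibration of one constituent from raw spectra.

    Preprocess -> CV term selection -> GH outlier protocol -> final model
    and a calibration report (N, mean, SD, R^2, SEC, SECV, SD/SECV) on
    the retained samples.
    """
    settings = settings or PreprocessingSettings()
    cv = cv or CVSettings()
    if constituent not in reference.constituents:
        raise KeyError(f"reference table has no column {constituent!r}")
    ids = _aligned_ids(spectra, reference, constituent)
    sub = spectra.select(ids)
    pre = apply_pipeline(sub, settings)
    X = pre.absorbance
    y = reference.data[constituent].loc[ids].to_numpy(dtype=float)
    if X.shape[0] <= cv.max_terms + 1:
        raise ValueError(
            f"max_terms={cv.max_terms} needs more than {cv.max_terms + 1} samples, "
            f"have {X.shape[0]} for {constituent!r}"
        )

    model, outlier_report = calibrate_with_outlier_protocol(
        X, y, cv, policy, sample_ids=ids, residual_scaling=residual_scaling
    )
    model.settings = settings
    model.training_grid = pre.wavelengths

    kept = [i for i, s in enumerate(ids) if s not in model.removed_samples]
    Xk, yk = X[kept], y[kept]
    fitted = model.predict_matrix(Xk)
    sec, _ = compute_sec_secv(fitted - yk, model.selected_terms)
    secv = model.secv_by_terms.get(model.selected_terms, float("nan"))
    _, r2 = regression_slope_r2(fitted, yk)
    sd = float(yk.std(ddof=1))
    report = CalibrationReport(
        constituent=constituent, n=len(kept), mean=float(yk.mean()), sd=sd,
        r2_cal=r2, sec=sec, secv=secv,
        sd_over_secv=compute_rpd(sd, secv) if secv > 0 else float("inf"),
    )
    return ConstituentCalibration(constituent, model, report, outlier_report)


def calibrate_all(spectra: SpectraSet, reference: ReferenceTable,
                  constituents: list[str] | None = None,
                  **kwargs) -> dict[str, ConstituentCalibration]:
    """Calibrate every requested constituent independently."""
    constituents = constituents or reference.constituents
    return {c: calibrate_constituent(spectra, reference, c, **kwargs)
            for c in constituents}


def validate_constituent(model: MPLSModel, spectra: SpectraSet,
                         reference: ReferenceTable, constituent: str,
                         outlier_k: float | None = None
                         ) -> tuple[ValidationReport, ValidationReport]:
    """Validate a fitted model on an independent set.

    Returns (pre-removal, post-removal) reports.  With
    ``outlier_k=None`` no screening is attempted and the two reports are
    identical (the leaf-style protocol); with a threshold k the
    one-round residual screening is applied (the media-style protocol).
    """
    ids = _aligned_ids(spectra, reference, constituent)
    sub = spectra.select(ids)
    predicted = predict(model, sub)
    y = reference.data[constituent].loc[ids].to_numpy(dtype=float)
    if outlier_k is None:
        rep = build_validation_report(constituent, predicted, y)
        return rep, rep
    return flag_validation_outliers(predicted, y, ids, constituent, k=outlier_k)
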