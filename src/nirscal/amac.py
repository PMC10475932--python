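"""Single-extraction (ammonium acetate) screening calibration.

An AmAc extraction at buffered pH gives an extractable nutrient
concentration per litre of substrate; totals measured on a dry-matter
basis are converted to the same volume basis via the dry bulk density.
Because both quantities are right-skewed across substrate types, the
calibration is an ordinary least-squares line on the square-root scale:

    sqrt(total) = slope * sqrt(amac) + intercept

Prediction back-transforms by squaring (no retransformation-bias
correction), clamping negative sqrt-scale predictions at zero — relevant
for elements with a negative intercept (Ca, Mg) at low extractable
levels.  Validation regresses the back-transformed predictions on the
measured totals: the slope carries the accuracy, R^2 the precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .validation import regression_slope_r2

__all__ = [
    "AMAC_EQUATIONS",
    "AmAcCalibrationModel",
    "convert_dm_to_volume",
    "fit_amac",
    "predict_total",
    "validate_amac",
]


def _load_equations() -> dict[str, tuple[float, float]]:
    with resources.files("nirscal.data").joinpath("amac_equations.json").open() as fh:
        raw = json.load(fh)
    return {el: (eq["slope"], eq["intercept"]) for el, eq in raw["equations"].items()}


#: element -> (sqrt-scale slope, sqrt-scale intercept), g/L substrate basis
AMAC_EQUATIONS: dict[str, tuple[float, float]] = _load_equations()


@dataclass
class AmAcCalibrationModel:
    """Sqrt-scale linear calibration for one element."""

    element: str
    slope_sqrt: float
    intercept_sqrt: float
    r2_cal: float
    n_cal: int

    def __post_init__(self) -> None:
        if self.element not in ("P", "K", "Ca", "Mg"):
            raise ValueError(f"unsupported element {self.element!r}")
        if not np.isfinite(self.slope_sqrt):
            raise ValueError("slope must be finite")

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "slope_sqrt": self.slope_sqrt,
            "intercept_sqrt": self.intercept_sqrt,
            "r2_cal": self.r2_cal,
            "n_cal": self.n_cal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmAcCalibrationModel":
        return cls(d["element"], float(d["slope_sqrt"]), float(d["intercept_sqrt"]),
                   float(d["r2_cal"]), int(d["n_cal"]))


def convert_dm_to_volume(content_dm: float | np.ndarray,
                         dry_bulk_density: float) -> float | np.ndarray:
    """g/kg DM -> g/L substrate.

    (g / kg DM) * (kg DM / L substrate) = g / L substrate; the density is
    the laboratory compacted dry bulk density.
    """
    if dry_bulk_density <= 0:
        raise ValueError("dry bulk density must be positive")
    return np.asarray(content_dm, dtype=float) * dry_bulk_density if np.ndim(content_dm) \
        else float(content_dm) * dry_bulk_density


def fit_amac(amac: np.ndarray, total: np.ndarray, element: str = "K") -> AmAcCalibrationModel:
    """OLS of sqrt(total) on sqrt(amac); inputs in g/L substrate."""
    amac = np.asarray(amac, dtype=float)
    total = np.asarray(total, dtype=float)
    if amac.size != total.size:
        raise ValueError("amac and total lengths differ")
    if amac.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.any(amac < 0) or np.any(total < 0):
        raise ValueError("concentrations must be non-negative")
    x = np.sqrt(amac)
    y = np.sqrt(total)
    if x.std() == 0:
        raise ValueError("zero variance in sqrt(amac)")
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return AmAcCalibrationModel(element, float(slope), float(intercept),
                                float(r**2), int(amac.size))


def predict_total(model: AmAcCalibrationModel,
                  amac: float | np.ndarray) -> float | np.ndarray:
    """Predicted total (g/L) from extractable concentration (g/L)."""
    arr = np.asarray(amac, dtype=float)
    if np.any(arr < 0):
        raise ValueError("amac concentrations must be non-negative")
    s = model.slope_sqrt * np.sqrt(arr) + model.intercept_sqrt
    out = np.clip(s, 0.0, None) ** 2
    return out if np.ndim(amac) else float(out)


def validate_amac(model: AmAcCalibrationModel, amac: np.ndarray,
                  total: np.ndarray) -> tuple[float, float]:
    """(slope, R^2) of back-transformed predictions vs measured totals."""
    amac = np.asarray(amac, dtype=float)
    total = np.asarray(total, dtype=float)
    if amac.size != total.size:
        raise ValueError("length mismatch")
    if amac.size < 3:
        raise ValueError("need at least 3 validation pairs")
    predicted = predict_total(model, amac)
    return regression_slope_r2(predicted, total)
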