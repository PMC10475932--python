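"""CSV / JSON file formats for spectra, reference chemistry, extraction
pairs, models and reports.

Spectra CSV: first column ``sample_id``, one column per wavelength with
the wavelength in nm (one decimal) as header.  Reference CSV:
``sample_id`` plus one column per constituent; units live in a sidecar
``<name>.units.json``.  Models serialize to a single JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .amac import AmAcCalibrationModel
from .containers import ReferenceTable, SpectraSet
from .mpls import MPLSModel

__all__ = [
    "read_spectra_csv", "write_spectra_csv",
    "read_reference_csv", "write_reference_csv",
    "read_amac_csv", "write_amac_csv",
    "read_model_json", "write_model_json",
    "read_amac_model_json", "write_amac_model_json",
]


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraSet:
    return SpectraSet.from_frame(pd.read_csv(path))


def _units_sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".units.json") if p.suffix != ".csv" \
        else p.with_name(p.stem + ".units.json")


def write_reference_csv(reference: ReferenceTable, path: str | Path) -> None:
    reference.data.to_csv(path)
    if reference.units:
        _units_sidecar(path).write_text(json.dumps(reference.units, indent=1))


def read_reference_csv(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    sidecar = _units_sidecar(path)
    units = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ReferenceTable(df, units)


def write_amac_csv(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, index=False)


def read_amac_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"element", "amac_g_per_L", "total_g_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"AmAc table missing column(s) {sorted(missing)}")
    return df


def write_model_json(model: MPLSModel, path: str | Path,
                     constituent: str | None = None) -> None:
    doc = model.to_dict()
    if constituent is not None:
        doc["constituent"] = constituent
    Path(path).write_text(json.dumps(doc))


def read_model_json(path: str | Path) -> MPLSModel:
    return MPLSModel.from_dict(json.loads(Path(path).read_text()))


def write_amac_model_json(model: AmAcCalibrationModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_amac_model_json(path: str | Path) -> AmAcCalibrationModel:
    return AmAcCalibrationModel.from_dict(json.loads(Path(path).read_text()))
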