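"""File formats: wide spectra CSV, chemistry CSV, JSON model files, YAML
configs.  All text, all lossless for float64 (shortest round-trip repr)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import ChemTable, DataValidationError, SpectraBlock
from .plsmodel import PLSModel


def write_spectra_csv(block: SpectraBlock, path: str | Path) -> Path:
    path = Path(path)
    block.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectra_csv(
    path: str | Path, instrument_name: str, axis_unit: str
) -> SpectraBlock:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"{path} is empty") from exc
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"{path}: malformed rows ({exc})") from exc
    if df.shape[0] == 0:
        raise DataValidationError(f"{path} contains no spectra rows")
    return SpectraBlock.from_frame(df, instrument_name=instrument_name, axis_unit=axis_unit)


def write_chem_csv(chem: ChemTable, path: str | Path) -> Path:
    path = Path(path)
    chem.data.to_csv(path, index=False, float_format="%.17g")
    return path


def read_chem_csv(path: str | Path) -> ChemTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError(f"{path} is empty") from exc
    if df.shape[0] == 0:
        raise DataValidationError(f"{path} contains no chemistry rows")
    return ChemTable(data=df)


def save_model(model: PLSModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(model.to_dict()))
    return path


def load_model(path: str | Path) -> PLSModel:
    return PLSModel.from_dict(json.loads(Path(path).read_text()))


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
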