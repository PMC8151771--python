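"""Core data containers shared across the pipeline.

A :class:`SpectraBlock` holds one instrument's absorbance matrix together
with its wavelength/wavenumber axis and (unit, replicate) row labels; a
:class:`ChemTable` holds the reference chemistry (five responses, with
replicate measurements); a :class:`MergedDataset` is the row-aligned
chemistry + spectra matrix used for PCA and Kennard-Stone partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical response column names, in reporting order.
RESPONSES = ["moisture_pct", "oil_pct", "ssc_brix", "tpc_ga_kg", "dpph_inhib_mg"]


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


class DataValidationError(ValueError):
    """Input data violate a structural contract (labels, shapes, ranges)."""


@dataclass
class SpectraBlock:
    """Absorbance spectra from one acquisition system.

    Parameters
    ----------
    instrument_name:
        Label of the acquisition system (e.g. ``"sphere"``, ``"probe"``,
        ``"portable"``).
    axis:
        Strictly monotone numeric axis (wavenumbers in cm^-1 or
        wavelengths in nm), one value per spectral variable.
    axis_unit:
        ``"cm-1"`` or ``"nm"``.
    unit_ids:
        Sample-unit label per row.
    replicates:
        Replicate index per row (1-based). After replicate averaging all
        entries are 0.
    A:
        Absorbance matrix, shape ``(n_rows, axis.size)``.
    """

    instrument_name: str
    axis: np.ndarray
    axis_unit: str
    unit_ids: np.ndarray
    replicates: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        self.replicates = np.asarray(self.replicates, dtype=int)
        self.A = np.asarray(self.A, dtype=float)
        self.validate()

    def validate(self) -> None:
        d = np.diff(self.axis)
        if self.axis.ndim != 1 or self.axis.size < 2:
            raise DataValidationError("axis must be a 1-D vector with >= 2 points")
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataValidationError("axis must be strictly monotone")
        if self.A.shape != (self.unit_ids.size, self.axis.size):
            raise DataValidationError(
                f"A has shape {self.A.shape}, expected "
                f"({self.unit_ids.size}, {self.axis.size})"
            )
        if self.replicates.size != self.unit_ids.size:
            raise DataValidationError("unit_ids and replicates length mismatch")
        if not np.all(np.isfinite(self.A)):
            raise DataValidationError("absorbance matrix contains non-finite values")
        keys = list(zip(self.unit_ids.tolist(), self.replicates.tolist()))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DataValidationError(f"duplicate (unit, replicate) rows: {dupes[:5]}")

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def copy_with(self, **kwargs) -> "SpectraBlock":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: unit_id, replicate, then one column per axis value."""
        df = pd.DataFrame(self.A, columns=[repr(float(v)) for v in self.axis])
        df.insert(0, "replicate", self.replicates)
        df.insert(0, "unit_id", self.unit_ids)
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, instrument_name: str, axis_unit: str
    ) -> "SpectraBlock":
        if list(df.columns[:2]) != ["unit_id", "replicate"]:
            raise DataValidationError(
                "spectra table must start with columns unit_id, replicate"
            )
        try:
            axis = np.array([float(c) for c in df.columns[2:]])
        except ValueError as exc:
            raise DataValidationError(f"non-numeric axis header: {exc}") from exc
        return cls(
            instrument_name=instrument_name,
            axis=axis,
            axis_unit=axis_unit,
            unit_ids=df["unit_id"].to_numpy(),
            replicates=df["replicate"].to_numpy(),
            A=df.iloc[:, 2:].to_numpy(dtype=float),
        )


@dataclass
class ChemTable:
    """Reference chemistry: one row per (unit, replicate) measurement."""

    data: pd.DataFrame
    responses: list[str] = field(default_factory=lambda: list(RESPONSES))

    def __post_init__(self) -> None:
        required = ["unit_id", "replicate"] + list(self.responses)
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise DataValidationError(f"chemistry table missing columns: {missing}")
        keys = self.data[["unit_id", "replicate"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise DataValidationError(
                f"duplicate (unit, replicate) keys: "
                f"{sorted(keys[keys.duplicated()].unique())[:5]}"
            )

    @property
    def unit_ids(self) -> np.ndarray:
        return self.data["unit_id"].unique()

    def unit_means(self) -> pd.DataFrame:
        """One row per unit: replicate-averaged responses, indexed by unit_id."""
        cols = [c for c in self.data.columns if c not in ("unit_id", "replicate")]
        out = self.data.groupby("unit_id", sort=False)[cols].mean()
        return out

    def duplicate_pairs(self, response: str) -> np.ndarray:
        """(m, 2) array of the first two replicate values per unit."""
        wide = self.data.pivot(index="unit_id", columns="replicate", values=response)
        wide = wide.reindex(self.unit_ids)
        if wide.shape[1] < 2 or wide.iloc[:, :2].isna().any().any():
            raise DataValidationError(
                f"response {response!r} lacks complete duplicate pairs"
            )
        return wide.iloc[:, :2].to_numpy(dtype=float)


@dataclass
class MergedDataset:
    """Row-aligned chemistry + spectral blocks used for PCA / Kennard-Stone.

    ``merged`` concatenates the five unit-mean chemical variables with each
    averaged spectral block; ``column_block`` records per-column provenance.
    """

    unit_ids: np.ndarray
    chem: pd.DataFrame
    blocks: dict[str, np.ndarray]
    merged: np.ndarray
    column_block: np.ndarray
    column_label: np.ndarray

    @property
    def n_units(self) -> int:
        return self.unit_ids.size

    @property
    def n_columns(self) -> int:
        return self.merged.shape[1]
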