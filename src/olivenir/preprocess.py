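"""Spectral pretreatments and response transforms.

Implements the pretreatment vocabulary of the calibration workflow:
replicate averaging, trimming of non-informative spectral regions,
standard normal variate (SNV), the Savitzky-Golay first derivative
(order-2 polynomial, 11-point window), their combination, and the
response transforms used to symmetrize skewed constituents
(reciprocal TPC, log10 DPPH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import ChemTable, ConfigurationError, DataValidationError, SpectraBlock

#: Default kept interval for FT-NIR blocks: drops the noisy 3,600-4,000 and
#: 10,500-12,500 cm^-1 extremes.  Vis/NIR blocks are used over the full range.
FTNIR_KEEP = [(4000.0, 10500.0)]


@dataclass(frozen=True)
class PretreatRecipe:
    """Ordered pretreatment chain applied to a spectra block.

    ``steps`` is an ordered subset of {"snv", "d1"}; the derivative uses a
    Savitzky-Golay local polynomial of ``polyorder`` over ``window`` points.
    """

    steps: tuple[str, ...] = ()
    window: int = 11
    polyorder: int = 2

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in ("snv", "d1"):
                raise ConfigurationError(f"unknown pretreatment step {s!r}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ConfigurationError(
                "window must be odd and larger than the polynomial order"
            )

    @property
    def label(self) -> str:
        return "+".join(self.steps) if self.steps else "none"

    @classmethod
    def from_label(cls, label: str, window: int = 11, polyorder: int = 2):
        label = label.strip().lower()
        if label in ("none", ""):
            return cls((), window, polyorder)
        steps = tuple(s.strip() for s in label.split("+"))
        return cls(steps, window, polyorder)


def average_replicates(block: SpectraBlock) -> SpectraBlock:
    """Average replicate scans so each sample unit keeps one spectrum.

    Unit order follows first appearance; the replicate label of averaged
    rows is 0.
    """
    units, first = np.unique(block.unit_ids, return_index=True)
    units = units[np.argsort(first)]  # preserve original unit order
    A_out = np.empty((units.size, block.n_points))
    for i, u in enumerate(units):
        A_out[i] = block.A[block.unit_ids == u].mean(axis=0)
    return block.copy_with(
        unit_ids=units, replicates=np.zeros(units.size, dtype=int), A=A_out
    )


def trim_range(
    block: SpectraBlock, keep: list[tuple[float, float]]
) -> SpectraBlock:
    """Keep only axis points inside the given closed intervals.

    Boundary membership is evaluated with a small relative tolerance so
    grids whose endpoints are floating-point reconstructions of the
    interval bounds are kept.
    """
    axis = block.axis
    tol = 1e-9 * max(1.0, np.abs(axis).max())
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in keep:
        if not lo <= hi:
            raise ConfigurationError(f"interval ({lo}, {hi}) has lo > hi")
        mask |= (axis >= lo - tol) & (axis <= hi + tol)
    if not mask.any():
        raise DataValidationError(
            f"trim of {block.instrument_name!r} to {keep} leaves no axis points"
        )
    return block.copy_with(axis=axis[mask], A=block.A[:, mask])


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard normal variate: center and scale each spectrum individually.

    Removes per-scan additive offsets and multiplicative scatter. Uses the
    n-1 (sample) standard deviation.
    """
    mean = block.A.mean(axis=1, keepdims=True)
    sd = block.A.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        labels = [
            f"({block.unit_ids[i]}, rep {block.replicates[i]})" for i in bad[:5]
        ]
        raise DataValidationError(f"constant spectra cannot be SNV-scaled: {labels}")
    return block.copy_with(A=(block.A - mean) / sd)


def _uniform_spacing(axis: np.ndarray, rtol: float = 1e-6) -> float:
    d = np.diff(axis)
    step = d.mean()
    if np.abs(d - step).max() > rtol * abs(step):
        raise DataValidationError("Savitzky-Golay derivative requires a uniform axis")
    return step


def savgol_d1(block: SpectraBlock, recipe: PretreatRecipe | None = None) -> SpectraBlock:
    """Savitzky-Golay first derivative (per axis unit).

    Interior points use the centered `window`-point order-`polyorder`
    least-squares fit; near the edges the window is truncated to the
    available points (one-sided fits), so the output keeps the input
    length.
    """
    recipe = recipe or PretreatRecipe(("d1",))
    w, order = recipe.window, recipe.polyorder
    if block.n_points < w:
        raise DataValidationError(
            f"need >= {w} axis points for the derivative, have {block.n_points}"
        )
    step = _uniform_spacing(block.axis)
    half = w // 2
    out = savgol_filter(
        block.A, window_length=w, polyorder=order, deriv=1, delta=step, axis=1
    )
    # replace the edge columns with truncated-window one-sided fits
    n = block.n_points
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = (block.axis[lo:hi] - block.axis[i])
        V = np.vander(x, order + 1, increasing=True)  # [1, x, x^2, ...]
        coef, *_ = np.linalg.lstsq(V, block.A[:, lo:hi].T, rcond=None)
        out[:, i] = coef[1]  # derivative at x = 0
    return block.copy_with(A=out)


def apply_recipe(block: SpectraBlock, recipe: PretreatRecipe) -> SpectraBlock:
    """Apply the recipe's steps in their listed order."""
    for step in recipe.steps:
        block = snv(block) if step == "snv" else savgol_d1(block, recipe)
    return block


# --- response transforms -------------------------------------------------

#: Model-scale definitions: response -> (column name, forward, inverse).
#: TPC is modelled as its reciprocal and DPPH on log10, which evens out
#: their strongly right-skewed distributions; the other responses are
#: modelled natively.
MODEL_SCALE = {
    "moisture_pct": ("moisture_pct", lambda x: x, lambda y: y),
    "oil_pct": ("oil_pct", lambda x: x, lambda y: y),
    "ssc_brix": ("ssc_brix", lambda x: x, lambda y: y),
    "tpc_ga_kg": ("tpc_inv_kg_ga", lambda x: 1.0 / x, lambda y: 1.0 / y),
    "dpph_inhib_mg": ("dpph_log10", np.log10, lambda y: np.power(10.0, y)),
}


def model_scale_name(response: str) -> str:
    return MODEL_SCALE[response][0]


def forward_transform(response: str, values: np.ndarray) -> np.ndarray:
    return MODEL_SCALE[response][1](np.asarray(values, dtype=float))


def back_transform(response: str, values: np.ndarray) -> np.ndarray:
    return MODEL_SCALE[response][2](np.asarray(values, dtype=float))


def transform_responses(chem: ChemTable) -> ChemTable:
    """Add the model-scale columns (1/TPC in kg/g_GA, log10 DPPH).

    Original columns are retained. Raises if any TPC or DPPH value is
    non-positive, listing the offending units.
    """
    data = chem.data.copy()
    for response in ("tpc_ga_kg", "dpph_inhib_mg"):
        bad = data.loc[data[response] <= 0, "unit_id"].unique()
        if bad.size:
            raise DataValidationError(
                f"non-positive {response} values for units {bad[:5].tolist()}"
            )
    data["tpc_inv_kg_ga"] = 1.0 / data["tpc_ga_kg"]
    data["dpph_log10"] = np.log10(data["dpph_inhib_mg"])
    out = ChemTable(data=data, responses=list(chem.responses))
    if hasattr(chem, "truth"):
        truth = chem.truth.copy()
        truth["tpc_inv_kg_ga"] = 1.0 / truth["tpc_ga_kg"]
        truth["dpph_log10"] = np.log10(truth["dpph_inhib_mg"])
        out.truth = truth
    return out
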