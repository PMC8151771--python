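"""Dataset assembly and calibration/prediction partitioning.

The chemistry and all averaged spectral blocks are merged into one wide
matrix, autoscaled, and projected by PCA; the Kennard-Stone max-min
algorithm then picks a representative 70% calibration subset in score
space, and venetian-blind (interleaved) segments drive the internal
cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    RESPONSES,
    ChemTable,
    ConfigurationError,
    DataValidationError,
    MergedDataset,
    SpectraBlock,
)


@dataclass
class SplitIndices:
    """Disjoint calibration/prediction unit-id partition."""

    calibration: np.ndarray
    prediction: np.ndarray
    fraction: float = 0.70

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration.tolist()), set(self.prediction.tolist())
        if cal & pred:
            raise DataValidationError("calibration and prediction sets overlap")


@dataclass
class CVSegments:
    """Interleaved cross-validation segment assignment for calibration units."""

    n_segments: int
    assignment: dict = field(default_factory=dict)

    def fold_masks(self, unit_ids: np.ndarray) -> list[np.ndarray]:
        seg = np.array([self.assignment[u] for u in unit_ids])
        return [seg == k for k in range(self.n_segments)]


def merge_dataset(
    chem: ChemTable, blocks: list[SpectraBlock], include_chem: bool = True
) -> MergedDataset:
    """Column-concatenate [chem | block_1 | ... | block_B], row-aligned on unit id.

    Blocks must be replicate-averaged (one row per unit) and cover exactly
    the chemistry's unit set; rows are aligned regardless of block row order.
    """
    means = chem.unit_means()[RESPONSES]
    unit_ids = means.index.to_numpy()
    unit_set = set(unit_ids.tolist())

    mats, col_block, col_label = [], [], []
    if include_chem:
        mats.append(means.to_numpy())
        col_block += ["chem"] * len(RESPONSES)
        col_label += list(RESPONSES)
    aligned_blocks: dict[str, np.ndarray] = {}
    for block in blocks:
        if np.unique(block.unit_ids).size != block.n_rows:
            raise DataValidationError(
                f"block {block.instrument_name!r} is not replicate-averaged"
            )
        block_set = set(block.unit_ids.tolist())
        if block_set != unit_set:
            missing = sorted(unit_set ^ block_set)
            raise DataValidationError(
                f"unit mismatch for block {block.instrument_name!r}: {missing[:5]}"
            )
        lookup = {u: i for i, u in enumerate(block.unit_ids)}
        rows = np.array([lookup[u] for u in unit_ids])
        aligned = block.A[rows]
        aligned_blocks[block.instrument_name] = aligned
        mats.append(aligned)
        col_block += [block.instrument_name] * block.n_points
        col_label += [repr(float(v)) for v in block.axis]

    return MergedDataset(
        unit_ids=unit_ids,
        chem=means,
        blocks=aligned_blocks,
        merged=np.hstack(mats),
        column_block=np.array(col_block),
        column_label=np.array(col_label),
    )


def autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and unit-variance scaling (n-1 sd).

    Returns (scaled, centers, scales) so the same transform can be reused
    on new rows.
    """
    M = np.asarray(M, dtype=float)
    centers = M.mean(axis=0)
    scales = M.std(axis=0, ddof=1)
    constant = np.flatnonzero(scales == 0)
    if constant.size:
        raise DataValidationError(
            f"constant columns cannot be autoscaled: indices {constant[:10].tolist()}"
        )
    return (M - centers) / scales, centers, scales


def pca_scores(
    M: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of an already-autoscaled matrix via SVD.

    Returns (scores, loadings, explained_variance_ratio). Loadings are
    orthonormal columns; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ConfigurationError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s[n_components - 1] <= max(n, p) * np.finfo(float).eps * s[0]:
        raise DataValidationError(
            f"matrix rank is below the requested {n_components} components"
        )
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s
    total_var = np.sum(M**2) / (n - 1)
    evr = (s**2 / (n - 1)) / total_var
    return scores, Vt.T, evr


def kennard_stone(
    points: np.ndarray, fraction: float, ids: np.ndarray | None = None
) -> SplitIndices:
    """Classic Kennard-Stone max-min selection.

    Seeds with the two mutually farthest points (Euclidean), then
    repeatedly adds the candidate whose minimum distance to the selected
    set is largest, until round-half-up(fraction * n) points are selected.
    Ties break toward the lowest id (rows are processed in sorted-id order,
    so the split does not depend on row permutation).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise DataValidationError("Kennard-Stone needs at least 2 points")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    ids = np.arange(n) if ids is None else np.asarray(ids)

    order = np.argsort(ids, kind="stable")
    pts, ids_sorted = points[order], ids[order]

    n_cal = int(math.floor(fraction * n + 0.5))  # round half up
    n_cal = min(max(n_cal, 2), n)

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    # farthest pair; ties -> lowest (i, j) in id order
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_dist = np.minimum(dist[:, selected[0]], dist[:, selected[1]])

    while len(selected) < n_cal:
        cand = remaining[int(np.argmax(min_dist[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, dist[:, cand])

    cal_mask = np.zeros(n, dtype=bool)
    cal_mask[selected] = True
    # calibration ids are kept in selection order (seed pair first) so the
    # venetian-blind segments can follow the max-min ordering
    return SplitIndices(
        calibration=ids_sorted[selected],
        prediction=ids_sorted[~cal_mask],
        fraction=fraction,
    )


def venetian_blinds(units: np.ndarray | list, n_segments: int = 10) -> CVSegments:
    """Interleaved segments: the unit at position i joins segment i mod k."""
    units = np.asarray(units)
    if n_segments < 2:
        raise ConfigurationError("need at least 2 cross-validation segments")
    if n_segments > units.size:
        raise ConfigurationError(
            f"{n_segments} segments for only {units.size} units"
        )
    assignment = {u: int(i % n_segments) for i, u in enumerate(units.tolist())}
    return CVSegments(n_segments=n_segments, assignment=assignment)


def ks_split_on_pca(
    merged: MergedDataset,
    fraction: float = 0.70,
    variance_target: float | None = 0.95,
) -> SplitIndices:
    """Autoscale the merged matrix, project by PCA, and split with
    Kennard-Stone in score space.

    ``variance_target`` keeps the leading components reaching that
    cumulative explained-variance fraction (None keeps all components).
    """
    Z, _, _ = autoscale(merged.merged)
    s = np.linalg.svd(Z, compute_uv=False)
    rank = int(np.sum(s > max(Z.shape) * np.finfo(float).eps * s[0]))
    max_comp = min(merged.n_units - 1, merged.n_columns, rank)
    scores, _, evr = pca_scores(Z, max_comp)
    if variance_target is not None:
        k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
        k = min(k, scores.shape[1])
        scores = scores[:, :k]
    return kennard_stone(scores, fraction, ids=merged.unit_ids)
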