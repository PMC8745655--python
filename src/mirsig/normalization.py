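"""Quantile normalization and median-polish summarization (RMA core).

The two numerical stages of RMA that operate on log2 intensity matrices:
across-sample quantile normalization and per-feature additive median
polish. Background correction is offered only as a simplified, optional
floor shift (off by default); input matrices are assumed to be log2 scale
already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "ProbeMatrix",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "floor_shift_background",
]


@dataclass
class ProbeMatrix:
    """Probe-level log2 intensities plus the probe -> feature assignment."""

    values: pd.DataFrame  # probes x samples
    probe_to_feature: pd.Series  # probe id -> feature id

    def __post_init__(self) -> None:
        self.probe_to_feature = pd.Series(self.probe_to_feature)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe identifiers")
        missing = self.values.index.difference(self.probe_to_feature.index)
        if len(missing):
            raise ValueError(f"probes without a feature assignment: {list(missing)[:5]}")
        self.probe_to_feature = self.probe_to_feature.loc[self.values.index]

    @property
    def features(self) -> list[str]:
        seen: list[str] = []
        for f in self.probe_to_feature:
            if f not in seen:
                seen.append(f)
        return seen


def _quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``x`` to the mean order-statistic curve.

    Ties within a column receive the mean of the order-statistic means for
    the ranks they occupy.
    """
    n, _ = x.shape
    mean_os = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(mean_os)))
    for j in range(x.shape[1]):
        uniq, inv, counts = np.unique(x[:, j], return_inverse=True, return_counts=True)
        ends = np.cumsum(counts)
        starts = ends - counts
        tie_means = (cum[ends] - cum[starts]) / counts
        out[:, j] = tie_means[inv]
    return out


def quantile_normalize(matrix):
    """Make every sample column share the mean order-statistic distribution.

    Accepts and returns a DataFrame, :class:`ExpressionMatrix` or
    :class:`ProbeMatrix` (matching the input type). Rank order within each
    column is preserved; the multiset of values in each column becomes the
    across-sample mean of the order statistics.
    """
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(
            quantile_normalize(matrix.values), matrix.sample_groups, matrix.group_order
        )
    if isinstance(matrix, ProbeMatrix):
        return ProbeMatrix(quantile_normalize(matrix.values), matrix.probe_to_feature)
    values: pd.DataFrame = matrix
    if values.isna().any().any():
        raise ValueError("missing values are not supported")
    if values.shape[1] < 2:
        warnings.warn("single sample column: quantile normalization is a no-op")
        return values.copy()
    out = _quantile_normalize_values(values.to_numpy(dtype=float))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Fit overall + row + column effects by iterated median sweeps.

    Returns ``(overall, row_effects, col_effects, residuals)``. Iteration
    stops when the largest absolute change in the residual matrix between
    successive sweep cycles falls below ``tol`` or after ``max_iter``
    cycles.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in probe matrix")
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        prev = resid.copy()
        rdelta = np.median(resid, axis=1)
        resid -= rdelta[:, None]
        row += rdelta
        cshift = np.median(col)
        col -= cshift
        overall += cshift
        cdelta = np.median(resid, axis=0)
        resid -= cdelta[None, :]
        col += cdelta
        rshift = np.median(row)
        row -= rshift
        overall += rshift
        if np.max(np.abs(resid - prev)) < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(
    probe_matrix: ProbeMatrix,
    groups: pd.Series | None = None,
    group_order: tuple[str, ...] = (),
    tol: float = 1e-6,
    max_iter: int = 10,
):
    """Summarize probe-level values to one expression value per feature.

    Per feature, an additive probe + sample model is fit by median polish;
    the feature's per-sample expression is the overall effect plus the
    sample (column) effect. Returns a DataFrame, or an
    :class:`ExpressionMatrix` when sample ``groups`` are supplied.
    """
    values = probe_matrix.values
    rows = {}
    for feature in probe_matrix.features:
        probes = probe_matrix.probe_to_feature[probe_matrix.probe_to_feature == feature].index
        block = values.loc[probes].to_numpy(dtype=float)
        if block.shape[0] == 1:
            rows[feature] = block[0]
            continue
        overall, _, col, _ = median_polish(block, tol=tol, max_iter=max_iter)
        rows[feature] = overall + col
    summary = pd.DataFrame.from_dict(rows, orient="index", columns=values.columns)
    if groups is None:
        return summary
    return ExpressionMatrix(summary, groups, group_order)


def floor_shift_background(
    values: pd.DataFrame, noise_quantile: float = 0.02, min_value: float = 1e-3
) -> pd.DataFrame:
    """Optional simplified background correction on the linear scale.

    Subtracts each column's low-quantile noise floor from the unlogged
    intensities and clamps at ``min_value`` before re-logging. A documented
    stand-in for the model-based convolution correction of full RMA; off by
    default in the pipeline.
    """
    linear = np.power(2.0, values.to_numpy(dtype=float))
    floor = np.quantile(linear, noise_quantile, axis=0)
    corrected = np.maximum(linear - floor[None, :], min_value)
    return pd.DataFrame(np.log2(corrected), index=values.index, columns=values.columns)
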