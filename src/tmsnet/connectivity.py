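"""Seed extraction and partial-correlation connectivity mapping.

One coil placement yields one seed region (the half-max field patch), one
weighted-average seed time series, and — after regressing the grand-mean
covariate out of both sides — one whole-surface partial-correlation map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InputError, ParameterError
from .efield import EFieldMap
from .fmri import TimeSeriesMatrix

__all__ = [
    "SeedRegion",
    "ConnectivityMap",
    "extract_seed",
    "weighted_timeseries",
    "make_covariate",
    "partial_corr_map",
    "RESIDUAL_VARIANCE_FLOOR",
]

#: Residual variance below this marks a vertex correlation as undefined.
RESIDUAL_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class SeedRegion:
    """Suprathreshold vertices with their field-derived weights."""

    indices: np.ndarray
    weights: np.ndarray
    normalization: str = "sum"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        w = np.asarray(self.weights, dtype=np.float64)
        if idx.size == 0:
            raise InputError("seed region must be non-empty")
        if w.shape != idx.shape:
            raise InputError("weights must match indices in shape")
        if np.any(w <= 0):
            raise InputError("seed weights must be strictly positive")
        if self.normalization == "sum" and abs(w.sum() - 1.0) > 1e-9:
            raise InputError("sum-normalized seed weights must sum to 1")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "weights", w)

    @property
    def size(self) -> int:
        return self.indices.shape[0]


@dataclass(frozen=True)
class ConnectivityMap:
    """Per-vertex partial correlation; undefined vertices carry NaN."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        defined = np.isfinite(v)
        if np.any(np.abs(v[defined]) > 1.0 + 1e-12):
            raise InputError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def extract_seed(
    field: EFieldMap, threshold_fraction: float = 0.5, normalization: str = "sum"
) -> SeedRegion:
    """Vertices with |E| strictly above ``fraction x max``, weighted by the
    field.  ``normalization="sum"`` divides by the within-seed sum (weighted
    average downstream); ``"max"`` divides by the seed maximum instead.
    """
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold fraction must lie in (0, 1)")
    if normalization not in ("sum", "max"):
        raise ParameterError("normalization must be 'sum' or 'max'")
    vmax = field.values.max() if field.values.size else 0.0
    if vmax <= 0:
        raise DegenerateInputError("cannot threshold an all-zero field")
    mask = field.values > threshold_fraction * vmax
    idx = np.flatnonzero(mask)
    vals = field.values[idx]
    denom = vals.sum() if normalization == "sum" else vals.max()
    return SeedRegion(idx, vals / denom, normalization)


def weighted_timeseries(seed: SeedRegion, ts: TimeSeriesMatrix) -> np.ndarray:
    """Weighted sum of the seed vertices' series: ``s(t) = sum_v w_v x_v(t)``."""
    if seed.indices.max() >= ts.n_vertices:
        raise InputError("seed index out of range for the time-series matrix")
    return seed.weights @ ts.data[seed.indices]


def make_covariate(all_seed_series: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of every configuration's weighted seed series."""
    if len(all_seed_series) == 0:
        raise InputError("need at least one seed series")
    lengths = {np.asarray(s).shape[0] for s in all_seed_series}
    if len(lengths) != 1:
        raise InputError("all seed series must have equal length")
    return np.mean(np.stack([np.asarray(s, float) for s in all_seed_series]), axis=0)


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of rows of x against the design (T, k)."""
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    return x - (design @ beta).T


def partial_corr_map(
    seed_series: np.ndarray,
    ts: TimeSeriesMatrix,
    covariate: np.ndarray,
) -> ConnectivityMap:
    """Partial correlation of every vertex with the seed series, controlling
    for the covariate.

    Both sides are residualized against ``[intercept, covariate]`` by least
    squares, then Pearson-correlated.  Vertices (or a seed) whose residual
    variance falls below ``RESIDUAL_VARIANCE_FLOOR`` are flagged undefined
    (NaN) rather than set to zero.
    """
    s = np.asarray(seed_series, dtype=np.float64).ravel()
    c = np.asarray(covariate, dtype=np.float64).ravel()
    t = ts.n_timepoints
    if s.shape[0] != t:
        raise InputError("seed series length must match the time series")
    if c.shape[0] != t:
        raise InputError("covariate length must match the time series")
    if t < 3:
        raise InputError("need at least 3 timepoints")

    design = np.column_stack([np.ones(t), c])
    seed_res = _residualize(s[None, :], design)[0]
    vert_res = _residualize(ts.data, design)

    seed_ss = float(seed_res @ seed_res)
    vert_ss = np.einsum("ij,ij->i", vert_res, vert_res)
    out = np.full(ts.n_vertices, np.nan)
    if seed_ss / t >= RESIDUAL_VARIANCE_FLOOR:
        ok = vert_ss / t >= RESIDUAL_VARIANCE_FLOOR
        out[ok] = (vert_res[ok] @ seed_res) / np.sqrt(vert_ss[ok] * seed_ss)
        np.clip(out, -1.0, 1.0, out=out)
    return ConnectivityMap(out)
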