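"""Sparsification, network-overlap profiles, zone/orientation grouping, and
group summaries.

A connectivity map is reduced to its top-1% vertices, binarized, and compared
against the parcellation: the network holding the largest share of the kept
vertices is the placement's assigned target.  Placements aggregate into a
3x3 zone grid (four locations per zone) and four 45-degree orientation
windows (three orientations per window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMap
from .errors import DegenerateInputError, InputError, ParameterError
from .surface import NETWORK_NAMES, ParcellationMap

__all__ = [
    "OverlapProfile",
    "TargetingResult",
    "GroupSummary",
    "sparsify",
    "overlap_profile",
    "assign_network",
    "zone_of",
    "orientation_window",
    "summarize",
    "ZONES",
    "WINDOWS",
]

ZONES = tuple(f"Z{i}" for i in range(1, 10))
WINDOWS = tuple(f"W{i}" for i in range(1, 5))


@dataclass(frozen=True)
class OverlapProfile:
    """Share of the kept (binarized) vertices falling in each network.

    ``network_percent[n]`` for n = 1..7 plus the unassigned (label 0) share;
    with the default kept-fraction metric these sum to 100.
    """

    network_percent: np.ndarray  # shape (8,), index = label; [0] = unassigned
    n_kept: int
    metric: str = "kept-fraction"

    def __post_init__(self) -> None:
        p = np.asarray(self.network_percent, dtype=np.float64)
        if p.shape != (8,):
            raise InputError("network_percent must have shape (8,)")
        if np.any(p < 0):
            raise InputError("overlap percentages must be >= 0")
        if self.n_kept < 1:
            raise InputError("profile requires at least one kept vertex")
        if self.metric == "kept-fraction" and abs(p.sum() - 100.0) > 1e-9:
            raise InputError("kept-fraction overlaps must sum to 100")
        object.__setattr__(self, "network_percent", p)

    @property
    def unassigned_percent(self) -> float:
        return float(self.network_percent[0])


@dataclass(frozen=True)
class TargetingResult:
    """Outcome for one coil configuration."""

    row: int
    col: int
    theta_deg: int
    profile: OverlapProfile
    network: int | None
    tied: bool
    zone: str
    window: str

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise InputError(f"zone {self.zone!r} not in {ZONES}")
        if self.window not in WINDOWS:
            raise InputError(f"window {self.window!r} not in {WINDOWS}")
        if self.network is not None:
            expected, _ = assign_network(self.profile)
            if expected != self.network:
                raise InputError("assigned network must be the profile argmax")


def sparsify(
    conn: ConnectivityMap,
    top_fraction: float = 0.01,
    use_absolute: bool = False,
) -> np.ndarray:
    """Binary map keeping the ``max(1, floor(fraction * n_defined))`` defined
    vertices with the highest correlation.

    Ranking uses the signed value by default (``use_absolute`` ranks |r|);
    ties at the cutoff are broken toward the lower vertex index.  Undefined
    (NaN) vertices never compete.
    """
    if not 0 < top_fraction <= 1:
        raise ParameterError("top fraction must lie in (0, 1]")
    defined = np.flatnonzero(conn.defined_mask)
    if defined.size == 0:
        raise DegenerateInputError("connectivity map has no defined vertices")
    vals = conn.values[defined]
    if use_absolute:
        vals = np.abs(vals)
    k = max(1, math.floor(top_fraction * defined.size))
    # lexsort: last key is primary -> descending value, then ascending index.
    order = np.lexsort((defined, -vals))
    kept = defined[order[:k]]
    out = np.zeros(conn.values.shape[0], dtype=np.int8)
    out[kept] = 1
    return out


def overlap_profile(
    binary_map: np.ndarray,
    parcellation: ParcellationMap,
    metric: str = "kept-fraction",
) -> OverlapProfile:
    """Overlap of the kept vertices with each network.

    ``kept-fraction`` (default): 100 * |kept ∩ network| / |kept|, label-0
    vertices contributing to the unassigned share.  ``dice``: the Dice
    coefficient 200 * |kept ∩ network| / (|kept| + |network|) as an
    alternative assignment metric.
    """
    b = np.asarray(binary_map)
    if b.shape[0] != parcellation.n_vertices:
        raise InputError("binary map and parcellation must share one mesh")
    kept = b != 0
    n_kept = int(kept.sum())
    if n_kept == 0:
        raise DegenerateInputError("empty suprathreshold set")
    counts = np.bincount(parcellation.labels[kept], minlength=8).astype(float)
    if metric == "kept-fraction":
        percent = 100.0 * counts / n_kept
    elif metric == "dice":
        sizes = parcellation.network_sizes().astype(float)
        percent = np.divide(
            200.0 * counts,
            n_kept + sizes,
            out=np.zeros(8),
            where=(n_kept + sizes) > 0,
        )
    else:
        raise ParameterError("metric must be 'kept-fraction' or 'dice'")
    return OverlapProfile(percent, n_kept, metric)


def assign_network(profile: OverlapProfile) -> tuple[int | None, bool]:
    """Argmax network (1..7) of an overlap profile.

    The unassigned share never wins.  Returns ``(network, tied)``; exact ties
    go to the lowest network index with ``tied=True``.  If every network
    overlap is zero the result is ``(None, False)`` — a no-assignment flag,
    not an error.
    """
    nets = profile.network_percent[1:]
    best = nets.max()
    if best <= 0.0:
        return None, False
    winners = np.flatnonzero(nets == best) + 1
    return int(winners[0]), winners.size > 1


def zone_of(row: int, col: int) -> str:
    """Zone Z1-Z9 of a grid location: contiguous 2x2 blocks, Z1 at the
    medial-anterior corner, columns advancing laterally, rows posteriorly."""
    if not (0 <= row <= 5 and 0 <= col <= 5):
        raise InputError(f"grid indices ({row}, {col}) out of range 0..5")
    return f"Z{3 * (row // 2) + col // 2 + 1}"


def orientation_window(theta_deg: int) -> str:
    """45-degree orientation window W1-W4 (half-open bins [0,45) ... [135,180))."""
    if theta_deg not in range(0, 180, 15):
        raise InputError(f"theta {theta_deg} not among the simulated orientations")
    return f"W{theta_deg // 45 + 1}"


def _modal(counts: pd.Series) -> list[int]:
    """Networks sharing the maximal count (ties all reported)."""
    if counts.empty or counts.max() == 0:
        return []
    return sorted(int(n) for n, c in counts.items() if c == counts.max())


@dataclass(frozen=True)
class GroupSummary:
    """Frequency tables over a batch of targeting results."""

    overall_percent: pd.Series  # index: network id 1..7 (+ -1 for unassigned)
    zone_counts: pd.DataFrame  # index: zone, columns: network id
    zone_window_counts: pd.DataFrame  # index: (zone, window), columns: network id
    zone_modal: dict[str, list[int]]
    zone_window_modal: dict[tuple[str, str], list[int]]
    n_results: int


def summarize(results: Sequence[TargetingResult]) -> GroupSummary:
    """Per-zone and per-zone-window modal networks plus overall stimulation
    frequencies (percent of configurations assigning each network)."""
    if len(results) == 0:
        raise InputError("cannot summarize an empty result list")
    rows = pd.DataFrame(
        {
            "zone": [r.zone for r in results],
            "window": [r.window for r in results],
            "network": [-1 if r.network is None else r.network for r in results],
        }
    )
    n = len(rows)
    net_ids = list(range(1, 8))

    overall = (100.0 * rows["network"].value_counts() / n).reindex(
        net_ids + [-1], fill_value=0.0
    )

    zone_counts = (
        rows[rows["network"] > 0]
        .groupby(["zone", "network"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=sorted(set(rows["zone"])), columns=net_ids, fill_value=0)
    )
    zw_counts = (
        rows[rows["network"] > 0]
        .groupby(["zone", "window", "network"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=net_ids, fill_value=0)
    )

    zone_modal = {z: _modal(zone_counts.loc[z]) for z in zone_counts.index}
    zw_modal = {tuple(k): _modal(zw_counts.loc[k]) for k in zw_counts.index}
    return GroupSummary(overall, zone_counts, zw_counts, zone_modal, zw_modal, n)


def results_frame(results: Sequence[TargetingResult]) -> pd.DataFrame:
    """Tidy one-row-per-configuration table of a result batch."""
    records = []
    for r in results:
        rec = {
            "row": r.row,
            "col": r.col,
            "theta_deg": r.theta_deg,
            "zone": r.zone,
            "window": r.window,
            "network": 0 if r.network is None else r.network,
            "network_name": NETWORK_NAMES.get(0 if r.network is None else r.network),
            "tied": int(r.tied),
            "n_kept": r.profile.n_kept,
            "unassigned_pct": r.profile.unassigned_percent,
        }
        for n in range(1, 8):
            rec[f"overlap_{NETWORK_NAMES[n].lower()}_pct"] = float(
                r.profile.network_percent[n]
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
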