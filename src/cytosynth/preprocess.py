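"""Normalization, debarcoding, transformation and gating.

The path from a raw acquisition to analysis-ready events: bead-based
sensitivity normalization, assignment of pooled events back to their
barcoded source samples, the variance-stabilizing arcsinh transform
(y = asinh(x / cofactor), cofactor 5 by default), threshold gating for
viability/apoptosis/lineage exclusion, and the raw-count IdU positivity
rule used to quantify DNA-synthesis activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import EventTable, GateRule

__all__ = [
    "TransformParams",
    "arcsinh",
    "inverse_arcsinh",
    "transform_values",
    "bead_normalize",
    "debarcode",
    "apply_gates",
    "idu_positive",
    "otsu_threshold",
    "viability_gates",
]

DEFAULT_COFACTOR = 5.0
DEFAULT_IDU_THRESHOLD = 10.0


@dataclass(frozen=True)
class TransformParams:
    cofactor: float = DEFAULT_COFACTOR

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")


def transform_values(x: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """arcsinh(x / cofactor) on plain arrays."""
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def inverse_values(y: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    return np.sinh(np.asarray(y, dtype=float)) * cofactor


def arcsinh(
    table: EventTable,
    params: TransformParams | float = DEFAULT_COFACTOR,
    channels: Sequence[str] | None = None,
) -> EventTable:
    """Arcsinh-transform selected channels (all by default).

    The transform is strictly monotone, so per-channel medians commute with
    it; applying it twice to the same channel is a state error.
    """
    cofactor = params.cofactor if isinstance(params, TransformParams) else float(params)
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    names = table.channel_names if channels is None else list(channels)
    already = set(names) & set(table.transformed_channels)
    if already:
        raise ValueError(f"channels already transformed: {sorted(already)}")
    out = table.copy()
    for name in names:
        j = out.index_of(name)
        out.values[:, j] = np.arcsinh(out.values[:, j] / cofactor)
    out.transformed_channels = table.transformed_channels | frozenset(names)
    out.transformed = True
    return out


def inverse_arcsinh(
    table: EventTable,
    params: TransformParams | float = DEFAULT_COFACTOR,
    channels: Sequence[str] | None = None,
) -> EventTable:
    """Exact inverse of :func:`arcsinh` on the given channels."""
    cofactor = params.cofactor if isinstance(params, TransformParams) else float(params)
    names = list(table.transformed_channels) if channels is None else list(channels)
    not_transformed = set(names) - set(table.transformed_channels)
    if not_transformed:
        raise ValueError(f"channels are not transformed: {sorted(not_transformed)}")
    out = table.copy()
    for name in names:
        j = out.index_of(name)
        out.values[:, j] = np.sinh(out.values[:, j]) * cofactor
    out.transformed_channels = table.transformed_channels - frozenset(names)
    out.transformed = bool(out.transformed_channels)
    return out


# ---------------------------------------------------------------------------
# bead normalization


def bead_normalize(
    table: EventTable,
    bead_channels: Sequence[str] | None = None,
    window: int = 5000,
    bead_threshold: float = 100.0,
) -> tuple[EventTable, dict]:
    """Correct sensitivity drift against calibration-bead events.

    Bead events are those with every bead channel above ``bead_threshold``
    raw counts. The run is cut into windows of ``window`` events; each
    window's scale is the whole-run bead median divided by the window bead
    median (averaged over bead channels), linearly interpolated over event
    index and applied multiplicatively to all non-bead channels. Returns the
    normalized table (bead events flagged in labels, to be excluded
    downstream) and a report.
    """
    if table.transformed:
        raise ValueError("bead normalization operates on raw counts")
    if bead_channels is None:
        bead_channels = table.channels_of_kind("bead")
    if not bead_channels:
        raise ValueError("no bead channels given or marked in the panel")
    bc = table.columns(bead_channels)
    bead_mask = (bc > bead_threshold).all(axis=1)
    if not bead_mask.any():
        raise ValueError(
            "no bead events found; re-run with normalization skipped if the "
            "acquisition had no calibration beads"
        )

    n = table.n_events
    ref = np.median(bc[bead_mask], axis=0)  # whole-run reference per bead channel
    edges = np.arange(0, n, window)
    centers, scales = [], []
    for lo in edges:
        hi = min(lo + window, n)
        sel = bead_mask[lo:hi]
        if sel.sum() < 3:
            continue
        win_med = np.median(bc[lo:hi][sel], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(win_med > 0, ref / win_med, 1.0)
        centers.append((lo + hi) / 2)
        scales.append(float(np.mean(ratio)))
    if not centers:
        raise ValueError("too few bead events per window; increase window size")
    per_event = np.interp(np.arange(n), centers, scales)

    out = table.copy()
    bead_idx = {table.index_of(c) for c in bead_channels}
    cell_cols = [j for j in range(table.n_channels) if j not in bead_idx]
    out.values[:, cell_cols] *= per_event[:, None]
    if out.labels is None:
        out.labels = pd.DataFrame(index=range(n))
    out.labels["bead_event"] = bead_mask
    report = {
        "n_beads": int(bead_mask.sum()),
        "window": int(window),
        "window_centers": [float(c) for c in centers],
        "window_scales": scales,
        "reference_medians": {c: float(r) for c, r in zip(bead_channels, ref)},
    }
    return out, report


# ---------------------------------------------------------------------------
# debarcoding


def debarcode(
    table: EventTable,
    keys: Sequence[Sequence[str]] | None = None,
    min_separation: float = 1.5,
    cofactor: float = DEFAULT_COFACTOR,
    barcode_channels: Sequence[str] | None = None,
    key_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign pooled events to barcode keys; flag likely doublets.

    Each key is the set of barcode channels that are "high" for one sample
    (k-of-m scheme). Per event the arcsinh-transformed barcode channels are
    sorted; the top-k channels form the candidate key, and the event is
    assigned iff that candidate matches a key and the separation (gap
    between the lowest "high" and highest "low" channel) is at least
    ``min_separation``; otherwise it is unassigned, with events whose
    (k+1)-th channel sits within the separation gap flagged as doublets.

    The separation cutoff carries the entire doublet burden when the key
    set is a full k-of-m design (every candidate matches *some* key), so
    the default sits well above typical doublet gaps (~0.7 transformed
    units for two summed barcodes) and well below singlet gaps (~4.4 at
    200-count barcodes).

    Returns a DataFrame with columns ``sample_id`` (int key index, -1 for
    unassigned), ``separation`` and ``doublet_flag``.
    """
    if keys is None:
        raise ValueError("barcode keys are required")
    key_sets = [frozenset(k) for k in keys]
    if len(set(key_sets)) != len(key_sets):
        raise ValueError("barcode keys must be distinct")
    k_sizes = {len(k) for k in key_sets}
    if len(k_sizes) != 1:
        raise ValueError("all keys must have the same size")
    k = k_sizes.pop()
    if barcode_channels is None:
        barcode_channels = table.channels_of_kind("barcode") or sorted(
            {ch for key in key_sets for ch in key}
        )
    m = len(barcode_channels)
    if k >= m:
        raise ValueError(f"key size k={k} must be smaller than m={m} barcode channels")

    raw = table.columns(barcode_channels)
    if set(barcode_channels) & set(table.transformed_channels):
        y = raw
    else:
        y = np.arcsinh(raw / cofactor)

    order = np.argsort(-y, axis=1)  # descending
    ranked = np.take_along_axis(y, order, axis=1)
    separation = ranked[:, k - 1] - ranked[:, k]

    chan_arr = np.array(barcode_channels, dtype=object)
    lookup = {fs: i for i, fs in enumerate(key_sets)}
    top = order[:, :k]
    sample_id = np.full(table.n_events, -1, dtype=int)
    for i in range(table.n_events):
        cand = frozenset(chan_arr[top[i]])
        sample_id[i] = lookup.get(cand, -1)
    ok = separation >= min_separation
    doublet_flag = ~ok
    sample_id[~ok] = -1

    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "separation": separation,
            "doublet_flag": doublet_flag,
        }
    )
    if key_names is not None:
        names = list(key_names) + ["unassigned"]
        out["sample"] = [names[s] if s >= 0 else "unassigned" for s in sample_id]
    return out


# ---------------------------------------------------------------------------
# gating


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance threshold (for bimodal channels)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(values, dtype=float)))


def viability_gates(
    table: EventTable,
    dead_channel: str = "Cisplatin",
    apoptosis_channels: Sequence[str] = ("cCaspase3",),
    cofactor: float = DEFAULT_COFACTOR,
) -> list[GateRule]:
    """Build drop-gates for cisplatin-positive and apoptotic events.

    Thresholds are placed by Otsu's method between the live and dead/
    apoptotic modes of the arcsinh-transformed channel.
    """
    rules = []
    for ch in (dead_channel, *apoptosis_channels):
        y = transform_values(table.column(ch), cofactor)
        rules.append(
            GateRule(channel=ch, op="gt", threshold=otsu_threshold(y), action="drop",
                     scale="transformed", name=f"exclude {ch}+")
        )
    return rules


def apply_gates(
    table: EventTable,
    rules: Sequence[GateRule],
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[np.ndarray, list[dict]]:
    """Apply threshold gates in order; returns (keep mask, per-rule report).

    ``keep`` rules retain matching events, ``drop`` rules remove them,
    ``flag`` rules only count. The mask always has length n_events and the
    operation is idempotent: re-applying the rules to the gated subset
    removes nothing.
    """
    import operator

    ops = {"gt": operator.gt, "ge": operator.ge, "lt": operator.lt, "le": operator.le}
    mask = np.ones(table.n_events, dtype=bool)
    report = []
    for rule in rules:
        x = table.column(rule.channel)
        if rule.scale == "transformed" and rule.channel not in table.transformed_channels:
            x = transform_values(x, cofactor)
        elif rule.scale == "raw" and rule.channel in table.transformed_channels:
            raise ValueError(f"gate on raw scale but {rule.channel!r} is transformed")
        match = ops[rule.op](x, rule.threshold)
        n_in = int(mask.sum())
        if rule.action == "keep":
            mask &= match
        elif rule.action == "drop":
            mask &= ~match
        report.append(
            {
                "rule": rule.name or f"{rule.action} {rule.channel} {rule.op} {rule.threshold:g}",
                "action": rule.action,
                "events_in": n_in,
                "events_matched": int(match.sum()),
                "events_out": int(mask.sum()),
            }
        )
    return mask, report


def idu_positive(
    table: EventTable,
    threshold: float = DEFAULT_IDU_THRESHOLD,
    channel: str = "IdU",
) -> np.ndarray:
    """Flag cells with more than ``threshold`` raw counts of incorporated IdU.

    The positivity rule is defined on raw ion counts, never transformed
    values; the default of 10 counts should be calibrated on an unlabeled
    control for new cell types.
    """
    if channel in table.transformed_channels:
        raise ValueError("IdU positivity is defined on raw counts; channel is transformed")
    return table.column(channel) > threshold
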