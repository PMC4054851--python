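"""From replicate spot intensities to one categorical state per NotI site.

The chain for one tumor/normal pair is: clamp net intensity per spot,
aggregate replicates by median (requiring ``min_valid`` usable spots per
channel), form log2 tumor/normal ratios, centre the ratios on their median
(negative-control clones excluded), and threshold into MD / AD / RET /
no-data. Boundary equality calls the event state.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import CallState, CallThresholds, NormalizationError, StructuralError

__all__ = [
    "aggregate_replicates",
    "call_cohort",
    "call_pair",
    "call_state",
    "normalize_pair",
    "pair_signals",
]


def aggregate_replicates(spots: pd.DataFrame, min_valid: int = 4) -> float | None:
    """Aggregate replicate spots of one clone+channel into a net intensity.

    Net per spot is max(foreground - background, 0); the clone value is the
    median over unflagged spots, or None (no data) when fewer than
    ``min_valid`` unflagged spots remain.
    """
    ok = spots[spots["flag"] == "ok"]
    if len(ok) < min_valid:
        return None
    net = (ok["foreground"] - ok["background"]).clip(lower=0.0)
    return float(net.median())


def pair_signals(
    spots: pd.DataFrame, thresholds: CallThresholds = CallThresholds()
) -> pd.DataFrame:
    """Per-site net intensities and raw log-ratios for one hybridization pair.

    Returns a DataFrame indexed by clone_id (input order preserved) with
    columns ``net_tumor, net_normal, n_tumor, n_normal, log_ratio``. The
    log-ratio is NaN when either channel lacks ``min_valid`` unflagged spots
    or the normal net intensity is zero, and -inf when the tumor net is zero
    against a positive normal signal.
    """
    clones = pd.Index(spots["clone_id"].unique(), name="clone_id")
    ok = spots[spots["flag"] == "ok"].copy()
    ok["net"] = (ok["foreground"] - ok["background"]).clip(lower=0.0)
    agg = (
        ok.groupby(["clone_id", "channel"], sort=False)["net"]
        .agg(["median", "size"])
        .unstack("channel")
    )
    out = pd.DataFrame(index=clones)
    for channel in ("tumor", "normal"):
        med = agg.get(("median", channel), pd.Series(dtype=float)).reindex(clones)
        cnt = agg.get(("size", channel), pd.Series(dtype=float)).reindex(clones).fillna(0)
        valid = cnt >= thresholds.min_valid
        out[f"net_{channel}"] = med.where(valid)
        out[f"n_{channel}"] = cnt.astype(int)
    nt, nn = out["net_tumor"], out["net_normal"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(nn > 0, nt / nn, np.nan)
        out["log_ratio"] = np.log2(ratio, out=np.full(len(out), np.nan), where=ratio > 0)
    out.loc[(nn > 0) & (nt == 0), "log_ratio"] = -np.inf
    return out


def normalize_pair(signals: pd.DataFrame, control_ids: Iterable[str] = ()) -> pd.DataFrame:
    """Centre the defined log-ratios of one pair on their median.

    Negative-control (non-human DNA) clones are excluded from the median;
    no-data sites are untouched. Raises :class:`NormalizationError` when no
    finite log-ratio is available.
    """
    controls = set(control_ids)
    lr = signals["log_ratio"]
    usable = np.isfinite(lr) & ~signals.index.isin(list(controls))
    if not usable.any():
        raise NormalizationError("no defined log-ratios to normalize against")
    centre = float(lr[usable].median())
    out = signals.copy()
    out["log_ratio"] = lr - centre  # NaN stays NaN, -inf stays -inf
    return out


def call_state(log_ratio: float | None, thresholds: CallThresholds = CallThresholds()) -> CallState:
    """Threshold one centred log-ratio into a call state.

    Boundary equality resolves to the event state (MD below/at the negative
    cutoff, AD above/at the positive cutoff).
    """
    if log_ratio is None or (isinstance(log_ratio, float) and math.isnan(log_ratio)):
        return CallState.NODATA
    if log_ratio <= thresholds.md_log_ratio:
        return CallState.MD
    if log_ratio >= thresholds.ad_log_ratio:
        return CallState.AD
    return CallState.RET


def call_pair(
    spots: pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
    control_ids: Iterable[str] = (),
    normalize: bool = True,
) -> pd.Series:
    """Full chain for one pair: aggregate, normalize, threshold.

    Returns a Series of call tokens indexed by clone_id (controls included,
    typically as no-data since they carry no human signal).

    Median centering assumes the majority of sites are unaltered, as holds
    in this study (typical per-sample burden well under half the array).
    When analysing data where most sites carry events, pass
    ``normalize=False``: a genome-wide alteration is indistinguishable from
    a global channel imbalance once the centre is re-estimated per pair.
    """
    signals = pair_signals(spots, thresholds)
    if normalize:
        signals = normalize_pair(signals, control_ids)
    lr = signals["log_ratio"].to_numpy()
    states = np.full(len(signals), CallState.RET.value, dtype=object)
    states[np.isnan(lr)] = CallState.NODATA.value
    with np.errstate(invalid="ignore"):
        states[lr <= thresholds.md_log_ratio] = CallState.MD.value
        states[lr >= thresholds.ad_log_ratio] = CallState.AD.value
    return pd.Series(states, index=signals.index, name="state")


def call_cohort(
    cohort: Mapping[str, pd.DataFrame],
    thresholds: CallThresholds = CallThresholds(),
    control_ids: Iterable[str] = (),
    drop_controls: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Call every pair of a cohort into a sites x samples matrix.

    All samples must share one clone set; a clone present in one sample and
    absent in another raises :class:`StructuralError` naming the clone.
    """
    controls = set(control_ids)
    matrix: dict[str, pd.Series] = {}
    reference: pd.Index | None = None
    for sample_id, spots in cohort.items():
        calls = call_pair(spots, thresholds, controls, normalize=normalize)
        if drop_controls:
            calls = calls[~calls.index.isin(list(controls))]
        if reference is None:
            reference = calls.index
        elif not calls.index.equals(reference):
            diff = set(calls.index).symmetric_difference(reference)
            raise StructuralError(
                f"sample {sample_id}: clone set differs (e.g. {sorted(diff)[:3]})"
            )
        matrix[sample_id] = calls
    if reference is None:
        return pd.DataFrame(index=pd.Index([], name="clone_id"))
    return pd.DataFrame(matrix, index=reference)
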