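"""k-of-m methylation marker panels: scoring, classification, evaluation,
and exhaustive subset search.

A panel scores a sample by counting its markers in the MD state (no-data
and AD count zero: a biopsy assay cannot assume missing markers positive)
and classifies it positive when the score reaches the threshold ``k``.
Ranking performance is summarized by the Gini coefficient 2*AUC - 1, with
the AUC computed by midranks on the heavily tied integer score.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import CallState, ClassifierMetrics, PanelSpec, StructuralError, ValidationError

__all__ = [
    "classify_sample",
    "evaluate_panel",
    "marker_score",
    "midrank_auc",
    "panel_scores",
    "search_panel",
    "search_panel_greedy",
]


def marker_score(calls: Mapping[str, str], panel: PanelSpec) -> int:
    """Number of panel markers in the MD state for one sample."""
    score = 0
    for clone in panel.marker_clone_ids:
        if clone not in calls:
            raise StructuralError(f"panel marker {clone!r} absent from sample call set")
        if calls[clone] == CallState.MD.value:
            score += 1
    return score


def classify_sample(calls: Mapping[str, str], panel: PanelSpec) -> bool:
    """True (disease-positive) iff the marker score reaches the panel's k."""
    return marker_score(calls, panel) >= panel.k


def panel_scores(matrix: pd.DataFrame, panel: PanelSpec) -> np.ndarray:
    """Marker scores for every sample (column) of a call matrix."""
    missing = [c for c in panel.marker_clone_ids if c not in matrix.index]
    if missing:
        raise StructuralError(f"panel marker(s) absent from matrix: {missing}")
    sub = matrix.loc[list(panel.marker_clone_ids)]
    return (sub == CallState.MD.value).sum(axis=0).to_numpy()


def midrank_auc(positive_scores, negative_scores) -> float:
    """AUC of positives vs negatives with midrank tie handling."""
    pos = np.asarray(positive_scores, float)
    neg = np.asarray(negative_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both cohorts must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def evaluate_panel(
    tumor_matrix: pd.DataFrame, negative_matrix: pd.DataFrame, panel: PanelSpec
) -> ClassifierMetrics:
    """Sensitivity/specificity/accuracy and Gini of a panel.

    Tumors are the positive class; the negative matrix plays the role of
    non-tumor hybridizations (e.g. simulated normal/normal self-pairs).
    """
    pos = panel_scores(tumor_matrix, panel)
    neg = panel_scores(negative_matrix, panel)
    tp = int((pos >= panel.k).sum())
    fp = int((neg >= panel.k).sum())
    return ClassifierMetrics(
        tp=tp,
        fn=int(pos.size - tp),
        tn=int(neg.size - fp),
        fp=fp,
        gini=2.0 * midrank_auc(pos, neg) - 1.0,
    )


def _rank_key(item: tuple[PanelSpec, ClassifierMetrics]):
    panel, m = item
    return (-m.accuracy, -m.sensitivity, panel.marker_clone_ids)


def search_panel(
    tumor_matrix: pd.DataFrame,
    candidate_clone_ids: Iterable[str],
    panel_size: int,
    k: int,
    negative_matrix: pd.DataFrame,
    max_combinations: int = 200_000,
) -> list[tuple[PanelSpec, ClassifierMetrics]]:
    """Exhaustively score every candidate subset of the given size.

    Subsets are ranked by accuracy, ties broken by sensitivity then by
    lexicographic clone order, so the output is deterministic. Raises
    :class:`ValidationError` when the enumeration would exceed
    ``max_combinations`` (use :func:`search_panel_greedy` instead).
    """
    candidates = sorted(set(candidate_clone_ids))
    total = math.comb(len(candidates), panel_size)
    if total > max_combinations:
        raise ValidationError(
            f"{total} subsets exceed the enumeration bound {max_combinations}; "
            "narrow the candidate list or use search_panel_greedy"
        )
    results = []
    for subset in combinations(candidates, panel_size):
        panel = PanelSpec(subset, k)
        results.append((panel, evaluate_panel(tumor_matrix, negative_matrix, panel)))
    results.sort(key=_rank_key)
    return results


def search_panel_greedy(
    tumor_matrix: pd.DataFrame,
    candidate_clone_ids: Iterable[str],
    panel_size: int,
    k: int,
    negative_matrix: pd.DataFrame,
) -> tuple[PanelSpec, ClassifierMetrics]:
    """Forward-selection fallback for candidate lists too large to enumerate."""
    remaining = sorted(set(candidate_clone_ids))
    chosen: list[str] = []
    for _ in range(panel_size):
        best = None
        for c in remaining:
            trial = tuple(sorted(chosen + [c]))
            panel = PanelSpec(trial, min(k, len(trial)))
            item = (panel, evaluate_panel(tumor_matrix, negative_matrix, panel), c)
            if best is None or _rank_key(item[:2]) < _rank_key(best[:2]):
                best = item
        chosen.append(best[2])
        remaining.remove(best[2])
    panel = PanelSpec(tuple(sorted(chosen)), k)
    return panel, evaluate_panel(tumor_matrix, negative_matrix, panel)
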